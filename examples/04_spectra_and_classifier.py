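"""Train and cross-validate the five-class Raman tissue classifier.

Generates a balanced synthetic library (BCC, dermis, fat, EMI, dye)
at SNR 15-30, extracts the 13 unit-normed band-area features and runs
patient-grouped 5-fold cross-validation.
"""

import numpy as np

from msh.classifier import cross_validate
from msh.preprocessing import compute_snr, extract_feature_matrix
from msh.synthetic import generate_spectral_library

library = generate_spectral_library(n_per_class=100, snr_range=(15.0, 30.0), seed=1)
snrs = [compute_snr(s) for s in library if s.meta["class"] != "dye"]
print(f"{len(library)} spectra, 5 classes; tissue SNR "
      f"{np.min(snrs):.1f}-{np.max(snrs):.1f} (median {np.median(snrs):.1f})")

features = extract_feature_matrix(library)
labels = np.array([s.meta["class"] for s in library])
groups = np.array([s.meta["patient_id"] for s in library])

cm = cross_validate(features, labels, groups, k=5, seed=1)
print("\n5-fold grouped cross-validation confusion matrix (rows = truth):")
print(cm.to_dataframe().to_string())
print()
for cls in cm.classes:
    print(f"{cls:7s} sensitivity {cm.sensitivity(cls):6.3f}  "
          f"specificity {cm.specificity(cls):6.3f}")
print()
print("Grouping folds by patient prevents within-patient correlation from")
print("inflating the estimate; near-perfect rates reflect the idealised")
print("class separation of the synthetic bands, not clinical difficulty.")
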