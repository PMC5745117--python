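"""End-to-end pipeline: AF image -> segments -> sampling -> diagnosis.

Mirrors the instrument's automated flow on synthetic inputs: flatten,
background-mask and segment the AF image at the f_B-optimal threshold,
allocate and place the Raman sampling budget (Config 2), measure
spectra (here: the synthetic bridge from the annotation mask), run the
two-round segment diagnosis and emit the sample-level call.
"""

from __future__ import annotations

import numpy as np

from . import diagnosis as dx
from .classifier import ClassifierModel, train_ann
from .io import RunConfig
from .preprocessing import PCADenoiser, extract_feature_matrix
from .sampling import AllocationParams, build_plan
from .segmentation import AFImage, flatten_image, optimize_threshold, segment_at_threshold, tissue_mask
from .synthetic import (
    PhantomConfig,
    default_spectrum_models,
    generate_phantom,
    generate_spectral_library,
    simulate_measurement,
)


def build_classifier(config: RunConfig, seed: int | None = None) -> ClassifierModel:
    """Train the tissue classifier on a synthetic spectral library."""
    seed = config.seed if seed is None else seed
    library = generate_spectral_library(
        config.library_n_per_class, snr_range=(15.0, 30.0), seed=seed
    )
    feats = extract_feature_matrix(library)
    labels = np.array([s.meta["class"] for s in library])
    return train_ann(feats, labels, hidden=config.classifier_hidden, seed=seed)


def build_denoiser(config: RunConfig, seed: int | None = None) -> PCADenoiser:
    """Fit the 50-PC denoising basis on intermediate-quality spectra
    (SNR between 10 and 15), the regime excluded from training."""
    seed = config.seed if seed is None else seed
    n_per_class = max(1, config.denoiser_basis_size // 5)
    basis = generate_spectral_library(
        n_per_class, snr_range=(10.0, 15.0), seed=seed + 1
    )
    return PCADenoiser(config.pca_components).fit(basis)


def run_pipeline(
    config: RunConfig,
    classifier: ClassifierModel | None = None,
    denoiser: PCADenoiser | None = None,
) -> dict:
    """Execute the full synthetic-sample pipeline and return the report.

    The report carries every intermediate the clinical log would:
    threshold, segment count, allocation totals, per-segment outcomes,
    N_BCC and the final decision, plus the config hash.
    """
    phantom_cfg = PhantomConfig(**{"seed": config.seed, **config.phantom})
    image_arr, mask_ann = generate_phantom(phantom_cfg)
    image = AFImage(image_arr, phantom_cfg.pixel_size)

    if classifier is None:
        classifier = build_classifier(config)
    if denoiser is None:
        denoiser = build_denoiser(config)

    # background threshold on the raw image, then flat-field the tissue
    mask = tissue_mask(image, config.background_threshold)
    flat = flatten_image(image, config.flatten_sigma, foreground=mask)
    threshold, curve = optimize_threshold(
        flat, mask, kind=config.objective, grid_size=config.threshold_grid_size
    )
    segmap = segment_at_threshold(flat, mask, threshold)
    if segmap.n_segments == 0:
        report = _report(config, threshold, segmap, None, "BCC-negative", [])
        report["note"] = "no segments found; tumour-free by construction"
        return report

    plan = build_plan(
        segmap,
        flat.intensities,
        AllocationParams(config.n_min, config.n_total),
        placement_config=config.placement_config,
        seed=config.seed,
    )

    models = default_spectrum_models()

    def measure(r: int, c: int):
        # deterministic per-location seed
        sub = np.random.SeedSequence([config.seed, int(r), int(c)])
        return simulate_measurement(
            mask_ann, (r, c), config.target_snr,
            seed=int(sub.generate_state(1)[0] % (2**31 - 1)), models=models,
        )

    image_dx, decision, diagnoses = dx.diagnose_sample(
        segmap, plan, measure, classifier, mask,
        denoiser=denoiser, snr_threshold=config.snr_threshold,
        n_th=config.n_th, seed=config.seed,
    )
    report = _report(config, threshold, segmap, image_dx, decision, diagnoses)
    report["_diagnosis_image"] = image_dx  # in-memory extra, stripped on write
    return report


def _report(config, threshold, segmap, image_dx, decision, diagnoses) -> dict:
    return {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "threshold": float(threshold),
        "n_segments": int(segmap.n_segments),
        "n_bcc": 0 if image_dx is None else int(image_dx.n_bcc),
        "decision": decision,
        "segments": [
            {
                "segment_id": d.segment_id,
                "status": d.status,
                "label": d.label,
                "n_round1": d.n_round1,
                "n_discarded": d.n_discarded,
                "notes": d.notes,
            }
            for d in diagnoses
        ],
    }
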