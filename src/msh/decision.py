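"""Binomial decision model for the sample-level BCC call.

The diagnosis image reduces a tissue sample to ``N_BCC``, the number of
BCC-labelled segments. The sample is called BCC-positive when
``N_BCC >= n_th``. This module predicts the operating characteristics of
that rule from per-spectrum performance, under the simplifying
assumptions that every segment receives the same number of spectra
(``n_spectra``, default 5), a segment is labelled BCC iff at least
``min_bcc_spectra`` (default 2) of its spectra are individually
classified BCC, and segment outcomes are statistically independent.

For a segment that truly contains tumour, a single spectrum lands on
tumour with probability ``h`` (the hit rate) and is then flagged BCC
with probability ``se``; off-tumour spectra are flagged BCC with
probability ``1 - sp``. The per-spectrum BCC probability is therefore

    p = h * se + (1 - h) * (1 - sp)

and per-segment sensitivity is the binomial tail P(Bin(n, p) >= m).
Sample-level rates follow by exact convolution of the true-positive and
false-positive segment-count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "PerformanceInputs",
    "per_spectrum_bcc_prob",
    "per_segment_sensitivity",
    "per_segment_specificity",
    "sample_operating_point",
    "fp_only_detection_prob",
    "operating_table",
    "monte_carlo_check",
]


@dataclass(frozen=True)
class PerformanceInputs:
    """Parameters of the binomial diagnosis model.

    Defaults reproduce the training-set operating point: hit rate 0.6,
    per-spectrum sensitivity 81.8% / specificity 96.3%, 5 spectra per
    segment, the at-least-2 rule, and 150 non-BCC segments per sample.
    """

    hit_rate: float = 0.6
    sensitivity: float = 0.818
    specificity: float = 0.963
    n_spectra: int = 5
    min_bcc_spectra: int = 2
    n_bcc_segments: int = 1
    n_nonbcc_segments: int = 150
    n_th: int = 8

    def __post_init__(self) -> None:
        for name in ("hit_rate", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_bcc_spectra > self.n_spectra:
            raise ValueError("min_bcc_spectra cannot exceed n_spectra")
        if min(self.n_spectra, self.n_bcc_segments, self.n_nonbcc_segments) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_th < 1:
            raise ValueError("n_th must be >= 1")


def per_spectrum_bcc_prob(hit_rate: float, sensitivity: float, specificity: float) -> float:
    """Probability that one spectrum in a tumour-bearing segment is labelled BCC."""
    for v in (hit_rate, sensitivity, specificity):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return hit_rate * sensitivity + (1.0 - hit_rate) * (1.0 - specificity)


def per_segment_sensitivity(p: float, n: int = 5, m: int = 2) -> float:
    """P(at least ``m`` of ``n`` spectra labelled BCC) = P(Bin(n, p) >= m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m > n:
        raise ValueError("m cannot exceed n")
    return float(binom.sf(m - 1, n, p))


def per_segment_specificity(sp: float, n: int = 5, m: int = 2) -> float:
    """P(a tumour-free segment is NOT labelled BCC) = 1 - P(Bin(n, 1-sp) >= m)."""
    return 1.0 - per_segment_sensitivity(1.0 - sp, n, m)


def _segment_rates(inputs: PerformanceInputs) -> tuple[float, float]:
    p = per_spectrum_bcc_prob(inputs.hit_rate, inputs.sensitivity, inputs.specificity)
    seg_se = per_segment_sensitivity(p, inputs.n_spectra, inputs.min_bcc_spectra)
    seg_fp = 1.0 - per_segment_specificity(
        inputs.specificity, inputs.n_spectra, inputs.min_bcc_spectra
    )
    return seg_se, seg_fp

def _detection_pmf(inputs: PerformanceInputs) -> np.ndarray:
    """Exact pmf of N_BCC = T + F by convolution of the two binomials."""
    seg_se, seg_fp = _segment_rates(inputs)
    t = binom.pmf(np.arange(inputs.n_bcc_segments + 1), inputs.n_bcc_segments, seg_se)
    f = binom.pmf(np.arange(inputs.n_nonbcc_segments + 1), inputs.n_nonbcc_segments, seg_fp)
    return np.convolve(t, f)


def sample_operating_point(inputs: PerformanceInputs) -> tuple[float, float]:
    """Per-sample (sensitivity, specificity) of the ``N_BCC >= n_th`` rule.

    Sensitivity is evaluated on a sample with ``n_bcc_segments`` true
    BCC segments plus ``n_nonbcc_segments`` others; specificity on a
    tumour-free sample with ``n_nonbcc_segments`` segments.
    """
    _, seg_fp = _segment_rates(inputs)
    pmf = _detection_pmf(inputs)
    sens = float(pmf[inputs.n_th:].sum())
    spec = float(binom.cdf(inputs.n_th - 1, inputs.n_nonbcc_segments, seg_fp))
    return sens, spec


def fp_only_detection_prob(inputs: PerformanceInputs) -> float:
    """P(sample called positive while every true BCC segment was missed).

    The pathological success mode: all ``N_BCC`` detections are false
    positives, yet the call is correct. Equals P(T = 0) * P(F >= n_th).
    """
    if inputs.n_bcc_segments < 1:
        raise ValueError("requires at least one true BCC segment")
    seg_se, seg_fp = _segment_rates(inputs)
    p_all_missed = float(binom.pmf(0, inputs.n_bcc_segments, seg_se))
    p_fp_alarm = float(binom.sf(inputs.n_th - 1, inputs.n_nonbcc_segments, seg_fp))
    return p_all_missed * p_fp_alarm


def operating_table(inputs: PerformanceInputs, n_th_values: "list[int] | None" = None):
    """Operating points for a range of thresholds, for threshold selection.

    Returns a pandas DataFrame with columns n_th, sample_sensitivity,
    sample_specificity, fp_only_prob.
    """
    import pandas as pd

    if n_th_values is None:
        n_th_values = list(range(1, 21))
    rows = []
    for n_th in n_th_values:
        cur = PerformanceInputs(**{**inputs.__dict__, "n_th": n_th})
        sens, spec = sample_operating_point(cur)
        rows.append(
            {
                "n_th": n_th,
                "sample_sensitivity": sens,
                "sample_specificity": spec,
                "fp_only_prob": fp_only_detection_prob(cur),
            }
        )
    return pd.DataFrame(rows)


def monte_carlo_check(
    inputs: PerformanceInputs, n_sims: int, seed: int
) -> dict[str, tuple[float, float]]:
    """Simulate the segment and sample rules; empirical check of the closed forms.

    Per-spectrum Bernoulli outcomes are drawn for every segment of every
    simulated sample; the at-least-m rule then the N_BCC >= n_th rule
    are applied literally. Returns ``{name: (estimate, standard_error)}``
    for per-segment sensitivity, sample sensitivity, sample specificity
    and the FP-only detection probability.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    p = per_spectrum_bcc_prob(inputs.hit_rate, inputs.sensitivity, inputs.specificity)
    q = 1.0 - inputs.specificity
    n, m = inputs.n_spectra, inputs.min_bcc_spectra

    # Per-spectrum Bernoulli draws aggregated per segment.
    seg_hits = (rng.random((n_sims, n)) < p).sum(axis=1)
    seg_pos = seg_hits >= m

    # Sample level: per-segment spectrum counts drawn as Binomial(n, .),
    # identical in law to summing the individual Bernoulli outcomes.
    t = (rng.binomial(n, p, size=(n_sims, inputs.n_bcc_segments)) >= m).sum(axis=1)
    f = (rng.binomial(n, q, size=(n_sims, inputs.n_nonbcc_segments)) >= m).sum(axis=1)

    def _rate(x: np.ndarray) -> tuple[float, float]:
        r = float(np.mean(x))
        return r, float(np.sqrt(max(r * (1 - r), 1e-300) / n_sims))

    return {
        "per_segment_sensitivity": _rate(seg_pos),
        "sample_sensitivity": _rate(t + f >= inputs.n_th),
        "sample_specificity": _rate(f < inputs.n_th),
        "fp_only_prob": _rate((t == 0) & (f >= inputs.n_th)),
    }
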