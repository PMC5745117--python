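"""Two-round per-segment diagnosis and the sample-level BCC call.

Each AF segment is diagnosed from the Raman spectra measured at its
sampling points. Round 1: spectra with CH2 SNR below 4 are discarded;
a segment losing more than 80% of its spectra is labelled Unclassified.
Retained spectra are PCA-denoised and classified. A segment with no
BCC spectra takes the unanimous class, or is split by nearest-neighbour
regions when classes disagree; a single BCC spectrum is treated as an
outlier and ignored; more than 80% BCC labels the whole segment BCC;
otherwise (at least two BCC spectra but not more than 80%) the segment
enters round 2, where an equal number of fresh points is measured at
new locations, both rounds' retained spectra are pooled, and the
segment is always finalised by nearest-neighbour splitting.

The final diagnosis image colour-codes every tissue pixel; the number
``N_BCC`` of connected BCC-labelled regions drives the per-sample call:
BCC-positive iff ``N_BCC >= n_th`` (default threshold 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from skimage.measure import label as cc_label

from .classifier import ClassifierModel, classify_batch
from .preprocessing import PCADenoiser, Spectrum, compute_snr, extract_feature_matrix
from .sampling import SamplingPlan, place_points_uniform
from .segmentation import SegmentMap
from .synthetic import LABEL_BACKGROUND

# Diagnosis-image label codes.
DX_BACKGROUND = 0
DX_TISSUE = 1  # tissue outside any segment
DX_BCC = 2
DX_DERMIS = 3
DX_FAT = 4
DX_EMI = 5
DX_DYE = 6
DX_UNCLASSIFIED = 7

CLASS_TO_CODE = {"BCC": DX_BCC, "dermis": DX_DERMIS, "fat": DX_FAT,
                 "EMI": DX_EMI, "dye": DX_DYE, "Unclassified": DX_UNCLASSIFIED}
CODE_TO_CLASS = {v: k for k, v in CLASS_TO_CODE.items()}

#: Display colour legend for rendered diagnosis images.
COLOUR_LEGEND = {
    DX_BACKGROUND: (0, 0, 0),
    DX_TISSUE: (235, 225, 210),
    DX_BCC: (220, 30, 30),
    DX_DERMIS: (40, 170, 60),
    DX_FAT: (240, 210, 50),
    DX_EMI: (60, 90, 220),
    DX_DYE: (30, 30, 30),
    DX_UNCLASSIFIED: (150, 150, 150),
}

STATUS_UNCLASSIFIED = "unclassified"
STATUS_SINGLE = "single"
STATUS_SPLIT = "split"
STATUS_NEEDS_ROUND2 = "needs_round2"

SNR_DIAGNOSIS = 4.0
BCC_MAJORITY_FRACTION = 0.8  # strict: "more than 80%"


@dataclass
class SegmentDiagnosis:
    """Outcome of diagnosing one segment."""

    segment_id: int
    status: str
    label: str | None = None  # set when status == "single"
    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))
    point_labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    rounds: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    pixel_labels: np.ndarray | None = None  # per segment pixel, for splits
    n_round1: int = 0
    n_discarded: int = 0
    notes: str = ""


def nearest_neighbour_split(
    segment_pixels: tuple[np.ndarray, np.ndarray],
    points: np.ndarray,
    point_labels: "np.ndarray | list[str]",
) -> np.ndarray:
    """Assign every segment pixel the label of its nearest sampling point.

    Euclidean distance between pixel centres; ties go to the
    lowest-index point. The resulting subregions partition the segment.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    labels = np.asarray(point_labels, dtype=object)
    if len(pts) == 0:
        raise ValueError("nearest-neighbour split requires at least one labelled point")
    if len(pts) != len(labels):
        raise ValueError("points and labels must align")
    pix = np.column_stack(segment_pixels).astype(float)
    d = np.sqrt(((pix[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    owner = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    return labels[owner]


def _classify_points(
    spectra: list[Spectrum],
    classifier: ClassifierModel,
    denoiser: PCADenoiser | None,
) -> np.ndarray:
    if denoiser is not None:
        spectra = denoiser.transform(spectra)
    feats = extract_feature_matrix(spectra)
    labels, _ = classify_batch(classifier, feats)
    return labels


def diagnose_segment_round1(
    segment_id: int,
    segment_pixels: tuple[np.ndarray, np.ndarray],
    points: np.ndarray,
    spectra: list[Spectrum],
    classifier: ClassifierModel,
    denoiser: PCADenoiser | None = None,
    snr_threshold: float = SNR_DIAGNOSIS,
) -> SegmentDiagnosis:
    """Apply the round-1 decision rules to one segment.

    ``points`` are the round-1 sampling locations and ``spectra`` the
    measurements at those locations, in order.
    """
    points = np.asarray(points, dtype=int).reshape(-1, 2)
    if len(spectra) == 0 or len(points) != len(spectra):
        raise ValueError("one spectrum per sampling point is required")
    n_total = len(spectra)
    snr_ok = np.array([compute_snr(s) >= snr_threshold for s in spectra])
    n_disc = int((~snr_ok).sum())

    base = dict(segment_id=segment_id, n_round1=n_total, n_discarded=n_disc)
    if n_disc > BCC_MAJORITY_FRACTION * n_total:
        return SegmentDiagnosis(status=STATUS_UNCLASSIFIED, label="Unclassified",
                                notes="more than 80% of round-1 spectra discarded", **base)

    kept_pts = points[snr_ok]
    kept_spec = [s for s, ok in zip(spectra, snr_ok) if ok]
    labels = _classify_points(kept_spec, classifier, denoiser)

    n_bcc = int((labels == "BCC").sum())
    if n_bcc == 1:
        # a lone BCC spectrum is ignored as an outlier
        keep = labels != "BCC"
        kept_pts, labels = kept_pts[keep], labels[keep]
        base["notes"] = "single BCC spectrum ignored"
        n_bcc = 0
        if len(labels) == 0:
            return SegmentDiagnosis(status=STATUS_UNCLASSIFIED, label="Unclassified", **base)

    rounds = np.ones(len(kept_pts), dtype=int)
    if n_bcc == 0:
        unique = np.unique(labels.astype(str))
        if len(unique) == 1:
            return SegmentDiagnosis(status=STATUS_SINGLE, label=str(unique[0]),
                                    points=kept_pts, point_labels=labels,
                                    rounds=rounds, **base)
        pixel_labels = nearest_neighbour_split(segment_pixels, kept_pts, labels)
        return SegmentDiagnosis(status=STATUS_SPLIT, points=kept_pts,
                                point_labels=labels, rounds=rounds,
                                pixel_labels=pixel_labels, **base)
    if n_bcc > BCC_MAJORITY_FRACTION * len(labels):
        return SegmentDiagnosis(status=STATUS_SINGLE, label="BCC", points=kept_pts,
                                point_labels=labels, rounds=rounds, **base)
    return SegmentDiagnosis(status=STATUS_NEEDS_ROUND2, points=kept_pts,
                            point_labels=labels, rounds=rounds, **base)


def run_round2(
    segment_pixels: tuple[np.ndarray, np.ndarray],
    round1: SegmentDiagnosis,
    round1_points: np.ndarray,
    measure: Callable[[int, int], Spectrum],
    classifier: ClassifierModel,
    denoiser: PCADenoiser | None = None,
    snr_threshold: float = SNR_DIAGNOSIS,
    seed: int = 0,
) -> SegmentDiagnosis:
    """Second measurement round for an ambiguous segment.

    Places as many new points as round 1 used (avoiding all round-1
    locations), measures and SNR-filters them, pools both rounds'
    retained spectra and always finalises the segment by
    nearest-neighbour splitting. With no retained spectra at all the
    segment falls back to Unclassified.
    """
    if round1.status != STATUS_NEEDS_ROUND2:
        raise ValueError("round 2 applies only to segments flagged needs_round2")
    round1_points = np.asarray(round1_points, dtype=int).reshape(-1, 2)
    n_new = round1.n_round1
    new_pts = place_points_uniform(
        segment_pixels, n_new, seed=seed, exclusions=round1_points
    )
    kept_pts = [tuple(p) for p in round1.points]
    kept_labels = list(round1.point_labels)
    rounds = [1] * len(kept_pts)

    new_spectra, new_kept_pts = [], []
    for r, c in new_pts:
        s = measure(int(r), int(c))
        if compute_snr(s) >= snr_threshold:
            new_spectra.append(s)
            new_kept_pts.append((int(r), int(c)))
    if new_spectra:
        new_labels = _classify_points(new_spectra, classifier, denoiser)
        kept_pts.extend(new_kept_pts)
        kept_labels.extend(new_labels)
        rounds.extend([2] * len(new_kept_pts))

    base = dict(segment_id=round1.segment_id, n_round1=round1.n_round1,
                n_discarded=round1.n_discarded)
    if not kept_pts:
        return SegmentDiagnosis(status=STATUS_UNCLASSIFIED, label="Unclassified",
                                notes="no retained spectra after two rounds", **base)
    pts = np.asarray(kept_pts, dtype=int)
    labels = np.asarray(kept_labels, dtype=object)
    pixel_labels = nearest_neighbour_split(segment_pixels, pts, labels)
    notes = "" if new_spectra else "round 2 yielded no retained spectra"
    return SegmentDiagnosis(status=STATUS_SPLIT, points=pts, point_labels=labels,
                            rounds=np.asarray(rounds), pixel_labels=pixel_labels,
                            notes=notes, **base)


@dataclass
class DiagnosisImage:
    """Colour-codable per-pixel diagnosis with the BCC-region count."""

    codes: np.ndarray  # integer grid of DX_* codes
    n_bcc: int
    legend: dict = field(default_factory=lambda: dict(COLOUR_LEGEND))

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros((*self.codes.shape, 3), dtype=np.uint8)
        for code, colour in self.legend.items():
            rgb[self.codes == code] = colour
        return rgb


def assemble_diagnosis(
    diagnoses: list[SegmentDiagnosis],
    segmap: SegmentMap,
    mask: np.ndarray,
) -> DiagnosisImage:
    """Paint segment diagnoses into the tissue mask and count BCC regions.

    ``N_BCC`` is the number of 8-connected BCC-labelled regions in the
    final image; round-2 splitting can therefore contribute several
    regions from a single segment.
    """
    codes = np.full(mask.shape, DX_BACKGROUND, dtype=np.uint8)
    codes[mask] = DX_TISSUE
    by_id = {d.segment_id: d for d in diagnoses}
    for sid in range(1, segmap.n_segments + 1):
        d = by_id.get(sid)
        if d is None:
            continue
        pix = segmap.segment_pixels(sid)
        if d.status in (STATUS_UNCLASSIFIED, STATUS_SINGLE):
            codes[pix] = CLASS_TO_CODE[d.label]
        elif d.status == STATUS_SPLIT:
            patch = np.array([CLASS_TO_CODE[str(x)] for x in d.pixel_labels], dtype=np.uint8)
            codes[pix] = patch
        else:
            raise ValueError(f"segment {sid} was not finalised (status {d.status})")
    n_bcc = int(cc_label(codes == DX_BCC, connectivity=2).max())
    return DiagnosisImage(codes, n_bcc)


def sample_decision(image: DiagnosisImage, n_th: int = 8) -> str:
    """Per-sample call: 'BCC-positive' iff ``N_BCC >= n_th``."""
    if n_th < 1:
        raise ValueError("n_th must be >= 1")
    return "BCC-positive" if image.n_bcc >= n_th else "BCC-negative"


def diagnose_sample(
    segmap: SegmentMap,
    plan: SamplingPlan,
    measure: Callable[[int, int], Spectrum],
    classifier: ClassifierModel,
    mask: np.ndarray,
    denoiser: PCADenoiser | None = None,
    snr_threshold: float = SNR_DIAGNOSIS,
    n_th: int = 8,
    seed: int = 0,
) -> tuple[DiagnosisImage, str, list[SegmentDiagnosis]]:
    """Run the full two-round procedure over every planned segment.

    ``measure`` maps a pixel location to the Raman spectrum recorded
    there (an instrument driver, or the synthetic bridge in tests).
    """
    diagnoses: list[SegmentDiagnosis] = []
    for sid in range(1, segmap.n_segments + 1):
        idx = plan.points_in_segment(sid)
        if len(idx) == 0:
            continue
        pts = np.column_stack([plan.rows[idx], plan.cols[idx]])
        spectra = [measure(int(r), int(c)) for r, c in pts]
        pix = segmap.segment_pixels(sid)
        d1 = diagnose_segment_round1(
            sid, pix, pts, spectra, classifier, denoiser, snr_threshold
        )
        if d1.status == STATUS_NEEDS_ROUND2:
            d1 = run_round2(
                pix, d1, pts, measure, classifier, denoiser, snr_threshold,
                seed=seed + sid,
            )
        diagnoses.append(d1)
    image = assemble_diagnosis(diagnoses, segmap, mask)
    return image, sample_decision(image, n_th), diagnoses
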