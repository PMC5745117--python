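"""Auto-fluorescence image flattening, thresholding and segmentation.

Tumour appears darker than stroma in the AF image, so segments are
connected components of BELOW-threshold tissue pixels. The threshold is
chosen per image by maximising one of two objectives over an intensity
grid: ``f_A = N`` (the segment count) or ``f_B = N * A`` where ``A`` is
the fraction of tissue area captured by the segments. ``f_B`` is the
default: it detects a larger fraction of the tumour at the cost of more
healthy tissue inside the segments.

Segmentation quality against a ground-truth annotation is scored by
``rho`` (fraction of annotated tumour area falling inside segments) and
per-segment ``epsilon`` (fraction of a segment's tissue that is
healthy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .synthetic import LABEL_BCC, LABEL_BACKGROUND

#: Sentinel returned where a quality metric is undefined (e.g. rho on a
#: tumour-free annotation).
NOT_APPLICABLE = float("nan")


@dataclass(frozen=True)
class AFImage:
    """A 2-D AF intensity grid with its physical pixel size (um/pixel)."""

    intensities: np.ndarray
    pixel_size: float = 40.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2:
            raise ValueError("AF image must be 2-D")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("AF intensities must be finite and non-negative")
        object.__setattr__(self, "intensities", arr)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class SegmentMap:
    """A labelled partition of below-threshold tissue into segments.

    ``labels`` holds 0 for pixels in no segment and 1..k for segment
    ids; per-segment pixel areas (and mm^2 equivalents), intensity
    variances and centroids are tabulated for the sampling allocator.
    """

    labels: np.ndarray
    threshold_used: float
    pixel_size: float
    areas_px: np.ndarray  # shape (k,), areas_px[i] = area of segment i+1
    variances: np.ndarray
    centroids: np.ndarray  # shape (k, 2) (row, col)

    @property
    def n_segments(self) -> int:
        return len(self.areas_px)

    @property
    def areas_mm2(self) -> np.ndarray:
        return self.areas_px * (self.pixel_size / 1000.0) ** 2

    def segment_pixels(self, segment_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the pixels in segment ``segment_id`` (1-based)."""
        if not 1 <= segment_id <= self.n_segments:
            raise ValueError(f"segment id {segment_id} out of range 1..{self.n_segments}")
        return np.nonzero(self.labels == segment_id)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "segment_id": np.arange(1, self.n_segments + 1),
                "area_px": self.areas_px,
                "area_mm2": self.areas_mm2,
                "variance": self.variances,
                "centroid_row": self.centroids[:, 0],
                "centroid_col": self.centroids[:, 1],
            }
        )


def flatten_image(
    image: AFImage, sigma: float | None = None, foreground: np.ndarray | None = None
) -> AFImage:
    """Flat-field correction: divide by a Gaussian-blurred copy.

    With a ``foreground`` mask (the background-thresholded tissue), the
    low-pass field is a normalised convolution over foreground pixels
    only — dark background neither bleeds into the tissue estimate nor
    gets rescaled itself. The result is rescaled to preserve the mean
    foreground intensity. Removes slow illumination gradients and
    stitching-scale artefacts; default ``sigma`` is one tenth of the
    image width.
    """
    arr = image.intensities
    if not np.any(arr > 0):
        raise ValueError("cannot flatten an all-zero image")
    if sigma is None:
        sigma = arr.shape[1] / 10.0
    if sigma < 1.0:
        raise ValueError("sigma below 1 pixel is not meaningful")
    fg = np.ones(arr.shape, dtype=bool) if foreground is None else foreground.astype(bool)
    blurred = ndimage.gaussian_filter(np.where(fg, arr, 0.0), sigma)
    weight = ndimage.gaussian_filter(fg.astype(float), sigma)
    low_pass = np.divide(blurred, weight, out=np.ones_like(arr), where=weight > 1e-12)
    low_pass = np.where(low_pass > 1e-12, low_pass, 1.0)
    flattened = np.where(fg, arr / low_pass, arr)
    scale = arr[fg].mean() / flattened[fg].mean()
    flattened = np.where(fg, flattened * scale, arr)
    return AFImage(flattened, image.pixel_size)


def tissue_mask(
    image: AFImage, background_threshold: float, min_speck_area: int = 64
) -> np.ndarray:
    """Foreground tissue mask: pixels >= threshold, small specks removed."""
    arr = image.intensities
    fg = arr >= background_threshold
    if not fg.any():
        raise ValueError("no tissue detected above the background threshold")
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no tissue detected")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_speck_area) + 1
    if keep.size == 0:  # nothing above the speck size: keep the largest
        keep = np.array([int(np.argmax(sizes)) + 1])
    return np.isin(lab, keep)


def default_min_segment_area(pixel_size: float) -> int:
    """Area (px) of a 60 um diameter disc: segments smaller than the
    smallest clinically relevant tumour scale are treated as noise."""
    r_px = 30.0 / pixel_size
    return max(1, int(np.ceil(np.pi * r_px**2)))


def segment_at_threshold(
    image: AFImage,
    mask: np.ndarray,
    t: float,
    min_segment_area: int | None = None,
    connectivity: int = 2,
) -> SegmentMap:
    """Segments = connected components of below-threshold tissue pixels.

    Components smaller than ``min_segment_area`` are discarded; segment
    ids are re-packed to 1..k in raster order of first occurrence. An
    empty segmentation (k = 0) is a valid result.
    """
    arr = image.intensities
    if min_segment_area is None:
        min_segment_area = default_min_segment_area(image.pixel_size)
    dark = mask & (arr < t)
    lab = cc_label(dark, connectivity=connectivity)
    n = lab.max()
    if n == 0:
        return SegmentMap(
            np.zeros_like(lab), t, image.pixel_size,
            np.zeros(0, dtype=int), np.zeros(0), np.zeros((0, 2)),
        )
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(arr), lab, index=idx)
    keep = idx[sizes >= min_segment_area]
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[keep] = np.arange(1, len(keep) + 1)
    labels = relabel[lab]
    k = len(keep)
    if k == 0:
        return SegmentMap(
            labels, t, image.pixel_size, np.zeros(0, dtype=int), np.zeros(0), np.zeros((0, 2))
        )
    new_idx = np.arange(1, k + 1)
    areas = ndimage.sum_labels(np.ones_like(arr), labels, index=new_idx).astype(int)
    with np.errstate(invalid="ignore"):  # ndimage divides by the empty 0-label
        variances = ndimage.variance(arr, labels, index=new_idx)
    centroids = np.array(ndimage.center_of_mass(np.ones_like(arr), labels, index=new_idx))
    return SegmentMap(labels, t, image.pixel_size, areas, np.atleast_1d(variances), centroids)


def threshold_objective(
    image: AFImage, mask: np.ndarray, t: float, kind: str = "f_B",
    min_segment_area: int | None = None,
) -> float:
    """Segmentation objective at threshold ``t``.

    ``f_A`` is the segment count N; ``f_B = N * A`` additionally weights
    by the captured tissue-area fraction A, favouring thresholds that
    retain more tumour.
    """
    if kind not in ("f_A", "f_B"):
        raise ValueError("kind must be 'f_A' or 'f_B'")
    segmap = segment_at_threshold(image, mask, t, min_segment_area=min_segment_area)
    n = segmap.n_segments
    if kind == "f_A":
        return float(n)
    area_fraction = segmap.areas_px.sum() / mask.sum()
    return float(n * area_fraction)


def optimize_threshold(
    image: AFImage,
    mask: np.ndarray,
    kind: str = "f_B",
    grid_size: int = 256,
    min_segment_area: int | None = None,
):
    """Sweep thresholds and return ``(best_threshold, curve)``.

    ``grid_size`` evenly spaced thresholds between the min and max of
    the masked intensities are scored; the argmax of the chosen
    objective is returned, ties broken toward the lowest threshold
    (most conservative segments). ``curve`` is an array of shape
    (grid_size, 2): threshold, objective value.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    vals = image.intensities[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("constant-intensity image: threshold optimisation is degenerate")
    grid = np.linspace(lo, hi, grid_size)
    scores = np.array(
        [threshold_objective(image, mask, t, kind, min_segment_area) for t in grid]
    )
    best = int(np.argmax(scores))  # argmax returns the first (lowest) maximiser
    return float(grid[best]), np.column_stack([grid, scores])


def compute_rho(segmap: SegmentMap, annotation: np.ndarray) -> float:
    """Fraction of annotated tumour area captured by the segmentation.

    rho = Area(detected BCC) / (Area(detected BCC) + Area(missed BCC)),
    detected meaning inside any segment. Returns NaN (not applicable)
    when the annotation contains no tumour.
    """
    bcc = annotation == LABEL_BCC
    total = int(bcc.sum())
    if total == 0:
        return NOT_APPLICABLE
    detected = int((bcc & (segmap.labels > 0)).sum())
    return detected / total


def compute_epsilon(segmap: SegmentMap, annotation: np.ndarray, segment_id: int) -> float:
    """Healthy-tissue fraction of one segment.

    epsilon = Area(healthy tissue) / (Area(BCC) + Area(healthy tissue))
    within the segment; background pixels are excluded from both terms.
    0 for a pure-tumour segment, 1 for a pure-healthy one.
    """
    rows, cols = segmap.segment_pixels(segment_id)
    ann = annotation[rows, cols]
    tissue = ann != LABEL_BACKGROUND
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError(f"segment {segment_id} contains no tissue pixels")
    n_bcc = int((ann == LABEL_BCC).sum())
    n_healthy = n_tissue - n_bcc
    return n_healthy / n_tissue
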