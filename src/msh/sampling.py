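"""Allocation and placement of Raman sampling points within segments.

Every segment receives a minimum number of points, and the remaining
budget is shared in proportion to Var(i) * Area(i) — large,
heterogeneous segments are more likely to contain tumour and get more
points:

    N_sampling(i) = N_min + Var(i)*Area(i) / sum_j Var(j)*Area(j) * N_rest

with N_rest = N_total - k * N_min. Defaults: N_min = 5, N_total = 800.

Two placement configurations are provided. Config 1 pins the first two
points at the segment's intensity extrema and spreads the rest; Config 2
spreads all points uniformly over the segment. Uniform spreading is
realised as farthest-point sampling started at the segment centroid,
which is deterministic and evenly covering; a pure-random mode is
available for Monte-Carlo work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .segmentation import NOT_APPLICABLE, SegmentMap
from .synthetic import LABEL_BCC

CONFIG_EXTREMA = "config1"
CONFIG_UNIFORM = "config2"


@dataclass(frozen=True)
class AllocationParams:
    """Minimum per-segment count and the total sampling budget."""

    n_min: int = 5
    n_total: int = 800

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_total < 1:
            raise ValueError("n_min and n_total must be >= 1")


@dataclass
class SamplingPlan:
    """Planned Raman measurement locations.

    Parallel arrays over points: pixel coordinates, owning segment id,
    and the measurement round (1 or 2).
    """

    rows: np.ndarray
    cols: np.ndarray
    segment_ids: np.ndarray
    rounds: np.ndarray
    placement_config: str = CONFIG_UNIFORM

    @property
    def n_points(self) -> int:
        return len(self.rows)

    def points_in_segment(self, segment_id: int) -> np.ndarray:
        """Indices of plan points belonging to ``segment_id``."""
        return np.flatnonzero(self.segment_ids == segment_id)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "point_id": np.arange(self.n_points),
                "segment_id": self.segment_ids,
                "row": self.rows,
                "col": self.cols,
                "round": self.rounds,
                "config": self.placement_config,
            }
        )


def allocate_points(segmap: SegmentMap, params: AllocationParams) -> np.ndarray:
    """Per-segment sampling counts by the variance-area weighting.

    Fractional shares are rounded by the largest-remainder method so the
    counts sum exactly to ``n_total`` whenever ``k * n_min <= n_total``.
    If the minimum allocation alone overruns the budget, segments are
    served ``n_min`` each in decreasing-area order until the budget runs
    out (with a warning). All-zero weights distribute the surplus
    uniformly (flagged).
    """
    k = segmap.n_segments
    if k < 1:
        raise ValueError("segmentation contains no segments")
    n_min, n_total = params.n_min, params.n_total
    counts = np.zeros(k, dtype=int)
    if k * n_min > n_total:
        warnings.warn(
            f"budget {n_total} cannot give {n_min} points to each of {k} segments; "
            "serving largest segments first",
            stacklevel=2,
        )
        order = np.argsort(-segmap.areas_px, kind="stable")
        remaining = n_total
        for i in order:
            if remaining <= 0:
                break
            counts[i] = min(n_min, remaining)
            remaining -= counts[i]
        return counts

    n_rest = n_total - k * n_min
    weights = segmap.variances * segmap.areas_px
    wsum = weights.sum()
    if wsum <= 0 and n_rest > 0:
        warnings.warn("all Var*Area weights are zero; distributing surplus uniformly",
                      stacklevel=2)
        shares = np.full(k, n_rest / k)
    elif n_rest > 0:
        shares = weights / wsum * n_rest
    else:
        shares = np.zeros(k)

    extra = np.floor(shares).astype(int)
    leftover = n_rest - extra.sum()
    if leftover > 0:
        frac = shares - np.floor(shares)
        order = np.lexsort((np.arange(k), -frac))  # largest remainder, lowest id first
        extra[order[:leftover]] += 1
    return n_min + extra


def _pixel_array(segment_pixels: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    pts = np.column_stack(segment_pixels).astype(float)
    if len(pts) == 0:
        raise ValueError("segment has no pixels")
    return pts


def place_points_uniform(
    segment_pixels: tuple[np.ndarray, np.ndarray],
    n: int,
    seed: int = 0,
    exclusions: np.ndarray | None = None,
    exclusion_radius: float = 1.0,
    method: str = "farthest",
) -> np.ndarray:
    """Spread ``n`` points evenly over a segment's pixels.

    ``method='farthest'`` (default): deterministic farthest-point
    sampling, initialised at the pixel nearest the segment centroid and
    greedily maximising the minimum distance to already-chosen points
    (ties broken at the lowest row-major pixel). ``method='random'``
    draws pixels uniformly without replacement using ``seed``.

    No returned point lies closer than ``exclusion_radius`` to any
    excluded coordinate (used to avoid re-measuring round-1 locations).
    If fewer than ``n`` admissible pixels exist, as many as fit are
    returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pts = _pixel_array(segment_pixels)
    allowed = np.ones(len(pts), dtype=bool)
    if exclusions is not None and len(exclusions):
        exc = np.asarray(exclusions, dtype=float).reshape(-1, 2)
        d = np.sqrt(((pts[:, None, :] - exc[None, :, :]) ** 2).sum(-1))
        allowed &= d.min(axis=1) >= exclusion_radius
    avail = np.flatnonzero(allowed)
    if len(avail) < n:
        warnings.warn(
            f"segment has only {len(avail)} admissible pixels for {n} points",
            stacklevel=2,
        )
        n = len(avail)
    if n == 0:
        return np.zeros((0, 2), dtype=int)

    cand = pts[avail]
    if method == "random":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(cand), size=n, replace=False)
        return cand[np.sort(chosen)].astype(int)
    if method != "farthest":
        raise ValueError("method must be 'farthest' or 'random'")

    centroid = pts.mean(axis=0)
    d0 = np.linalg.norm(cand - centroid, axis=1)
    first = int(np.argmin(d0))  # nearest-to-centroid; argmin takes lowest index on ties
    chosen_idx = [first]
    min_d = np.linalg.norm(cand - cand[first], axis=1)
    for _ in range(1, n):
        nxt = int(np.argmax(min_d))
        chosen_idx.append(nxt)
        min_d = np.minimum(min_d, np.linalg.norm(cand - cand[nxt], axis=1))
    return cand[chosen_idx].astype(int)


def place_points_extrema(
    segment_pixels: tuple[np.ndarray, np.ndarray],
    intensities: np.ndarray,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Config 1: intensity extrema first, then uniform spreading.

    The first two points sit at the segment's minimum- and
    maximum-intensity pixels (ties: lowest row-major index); the
    remaining ``n - 2`` are spread by farthest-point sampling, treating
    the two extremum points as already placed.
    """
    if n < 2:
        raise ValueError("Config 1 requires n >= 2 (extrema pair)")
    pts = _pixel_array(segment_pixels).astype(int)
    vals = np.asarray(intensities, dtype=float)
    if vals.shape[0] != len(pts):
        raise ValueError("intensities must align with segment pixels")
    i_min = int(np.argmin(vals))
    i_max = int(np.argmax(vals))
    if i_max == i_min:  # constant segment: two lowest row-major pixels
        i_min, i_max = 0, min(1, len(pts) - 1)
    seeds = pts[[i_min, i_max]]
    if n == 2:
        return seeds
    rest = _fps_continue(pts.astype(float), seeds.astype(float), n - 2)
    return np.vstack([seeds, rest]).astype(int)


def _fps_continue(cand: np.ndarray, already: np.ndarray, n_more: int) -> np.ndarray:
    """Farthest-point sampling continuing from existing points."""
    min_d = np.min(
        np.linalg.norm(cand[:, None, :] - already[None, :, :], axis=2), axis=1
    )
    out = []
    for _ in range(n_more):
        nxt = int(np.argmax(min_d))
        out.append(cand[nxt])
        min_d = np.minimum(min_d, np.linalg.norm(cand - cand[nxt], axis=1))
    return np.array(out)


def build_plan(
    segmap: SegmentMap,
    image_intensities: np.ndarray,
    params: AllocationParams = AllocationParams(),
    placement_config: str = CONFIG_UNIFORM,
    seed: int = 0,
    method: str = "farthest",
) -> SamplingPlan:
    """Allocate and place round-1 points for every segment."""
    counts = allocate_points(segmap, params)
    rows, cols, seg_ids = [], [], []
    for i in range(segmap.n_segments):
        sid = i + 1
        pix = segmap.segment_pixels(sid)
        n = int(counts[i])
        if n == 0:
            continue
        if placement_config == CONFIG_EXTREMA and n >= 2:
            pts = place_points_extrema(pix, image_intensities[pix], n, seed=seed + sid)
        else:
            pts = place_points_uniform(pix, n, seed=seed + sid, method=method)
        rows.extend(pts[:, 0])
        cols.extend(pts[:, 1])
        seg_ids.extend([sid] * len(pts))
    return SamplingPlan(
        np.asarray(rows, dtype=int),
        np.asarray(cols, dtype=int),
        np.asarray(seg_ids, dtype=int),
        np.ones(len(rows), dtype=int),
        placement_config,
    )


def _bcc_segments(segmap: SegmentMap, annotation: np.ndarray) -> np.ndarray:
    """Ids of segments containing at least one annotated BCC pixel."""
    ids = []
    for sid in range(1, segmap.n_segments + 1):
        pix = segmap.segment_pixels(sid)
        if np.any(annotation[pix] == LABEL_BCC):
            ids.append(sid)
    return np.asarray(ids, dtype=int)


def hit_rate(plan: SamplingPlan, segmap: SegmentMap, annotation: np.ndarray) -> float:
    """Fraction of tumour hits among points in tumour-containing segments.

    Numerator: plan points landing on annotated BCC pixels. Denominator:
    all points allocated to segments containing any BCC. NaN when no
    segment contains tumour.
    """
    bcc_ids = _bcc_segments(segmap, annotation)
    if len(bcc_ids) == 0:
        return NOT_APPLICABLE
    in_bcc_seg = np.isin(plan.segment_ids, bcc_ids)
    denom = int(in_bcc_seg.sum())
    if denom == 0:
        return NOT_APPLICABLE
    on_bcc = annotation[plan.rows, plan.cols] == LABEL_BCC
    return int((in_bcc_seg & on_bcc).sum()) / denom


def missed_bcc_segments(
    plan: SamplingPlan, segmap: SegmentMap, annotation: np.ndarray
) -> int:
    """Segments containing tumour but sampled only on healthy pixels."""
    missed = 0
    on_bcc = annotation[plan.rows, plan.cols] == LABEL_BCC
    for sid in _bcc_segments(segmap, annotation):
        idx = plan.points_in_segment(sid)
        if len(idx) == 0 or not np.any(on_bcc[idx]):
            missed += 1
    return missed
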