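"""Raman spectral preprocessing and band-area feature extraction.

Spectra live on a fixed wavenumber grid, 400-1800 cm^-1 at 2 cm^-1
spacing (701 points). Quality control uses the CH2 deformation band at
1450 cm^-1: SNR is the local-baseline-subtracted band height divided by
the rms noise in the empty 1750-1800 cm^-1 region. Features are areas
of 13 diagnostic Raman bands, each measured above a local linear
baseline drawn through the band-window endpoints, and normalised to
unit Euclidean norm per spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from sklearn.decomposition import PCA

WAVENUMBER_MIN = 400.0
WAVENUMBER_MAX = 1800.0
WAVENUMBER_STEP = 2.0
#: The standard 701-point wavenumber grid (cm^-1).
STANDARD_GRID = np.arange(WAVENUMBER_MIN, WAVENUMBER_MAX + WAVENUMBER_STEP, WAVENUMBER_STEP)

#: Centres (cm^-1) of the 13 diagnostic bands used as classifier features.
FEATURE_BAND_CENTRES = (
    675.0, 680.0, 786.0, 870.0, 906.0, 944.0, 952.0,
    1092.0, 1144.0, 1298.0, 1376.0, 1528.0, 1744.0,
)

SNR_BAND_CENTRE = 1450.0
SNR_BAND_HALF_WIDTH = 20.0
NOISE_REGION = (1750.0, 1800.0)

# SNR retention thresholds for the three operating regimes.
SNR_THRESHOLD_TRAINING = 15.0
SNR_THRESHOLD_VALIDATION = 7.0
SNR_THRESHOLD_DIAGNOSIS = 4.0


@dataclass(frozen=True)
class BandDefinition:
    """A Raman band integration window ``centre +/- half_width`` (cm^-1)."""

    centre: float
    half_width: float = 8.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if not (WAVENUMBER_MIN <= self.centre - self.half_width
                and self.centre + self.half_width <= WAVENUMBER_MAX):
            raise ValueError(
                f"band window {self.centre}+/-{self.half_width} cm^-1 lies outside "
                f"the {WAVENUMBER_MIN:.0f}-{WAVENUMBER_MAX:.0f} cm^-1 grid"
            )


def default_bands() -> list[BandDefinition]:
    """The 13 feature bands: half-width 8 cm^-1, except the adjacent
    675/680 cm^-1 pair which uses 3 cm^-1 to keep the windows disjoint."""
    out = []
    for c in FEATURE_BAND_CENTRES:
        hw = 3.0 if c in (675.0, 680.0) else 8.0
        out.append(BandDefinition(c, hw))
    return out


@dataclass
class Spectrum:
    """A Raman spectrum: ascending wavenumbers (cm^-1) and intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers and intensities must be matching 1-D arrays")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")

    @property
    def on_standard_grid(self) -> bool:
        return self.wavenumbers.shape == STANDARD_GRID.shape and np.allclose(
            self.wavenumbers, STANDARD_GRID
        )


def resample_spectrum(s: Spectrum) -> Spectrum:
    """Linearly interpolate onto the standard 400-1800 cm^-1 / 2 cm^-1 grid."""
    if s.wavenumbers[0] > WAVENUMBER_MIN or s.wavenumbers[-1] < WAVENUMBER_MAX:
        raise ValueError(
            f"spectrum covers {s.wavenumbers[0]:.1f}-{s.wavenumbers[-1]:.1f} cm^-1; "
            f"the full {WAVENUMBER_MIN:.0f}-{WAVENUMBER_MAX:.0f} cm^-1 range is required"
        )
    if s.on_standard_grid:
        return Spectrum(STANDARD_GRID.copy(), s.intensities.copy(), dict(s.meta))
    y = np.interp(STANDARD_GRID, s.wavenumbers, s.intensities)
    return Spectrum(STANDARD_GRID.copy(), y, dict(s.meta))


def remove_cosmic_rays(
    s: Spectrum, window: int = 7, n_mads: float = 5.0, max_width: int = 2
) -> Spectrum:
    """Replace narrow spikes by the running median.

    A point is spike-flagged when it exceeds a ``window``-point median
    filter by more than ``n_mads`` median absolute deviations of the
    residual; only flagged runs of length <= ``max_width`` are replaced,
    so genuine Raman bands (several points wide) are untouched.
    """
    y = s.intensities
    med = median_filter(y, size=window, mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid))
    if mad == 0:
        return Spectrum(s.wavenumbers.copy(), y.copy(), dict(s.meta))
    flagged = resid > n_mads * 1.4826 * mad
    out = y.copy()
    # replace only isolated runs (width <= max_width)
    i = 0
    n = len(flagged)
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            if j - i <= max_width:
                out[i:j] = med[i:j]
            i = j
        else:
            i += 1
    return Spectrum(s.wavenumbers.copy(), out, dict(s.meta))


def _window_slice(wavenumbers: np.ndarray, lo: float, hi: float) -> slice:
    i0 = int(np.searchsorted(wavenumbers, lo, side="left"))
    i1 = int(np.searchsorted(wavenumbers, hi, side="right"))
    if i1 - i0 < 3:
        raise ValueError(f"window {lo}-{hi} cm^-1 contains fewer than 3 grid points")
    return slice(i0, i1)


def compute_snr(s: Spectrum) -> float:
    """CH2-band SNR: baseline-subtracted 1450 cm^-1 height over rms noise.

    Signal: maximum of (intensity - local linear baseline through the
    window endpoints) in 1450 +/- 20 cm^-1. Noise: rms residual of a
    straight-line fit over the empty 1750-1800 cm^-1 region, so a sloped
    but noise-free background contributes nothing. Returns ``inf`` for
    an exactly noise-free spectrum.
    """
    if not s.on_standard_grid:
        raise ValueError("compute_snr requires a spectrum on the standard grid")
    w, y = s.wavenumbers, s.intensities
    sl = _window_slice(w, SNR_BAND_CENTRE - SNR_BAND_HALF_WIDTH, SNR_BAND_CENTRE + SNR_BAND_HALF_WIDTH)
    xw, yw = w[sl], y[sl]
    baseline = yw[0] + (yw[-1] - yw[0]) * (xw - xw[0]) / (xw[-1] - xw[0])
    signal = float(np.max(yw - baseline))

    nsl = _window_slice(w, NOISE_REGION[0], NOISE_REGION[1])
    xn, yn = w[nsl], y[nsl]
    coef = np.polyfit(xn, yn, 1)
    resid = yn - np.polyval(coef, xn)
    noise = float(np.sqrt(np.mean(resid**2)))
    if noise <= 1e-10 * max(1.0, float(np.abs(yn).max())):
        return float("inf")  # noise-free region: SNR is undefined-large
    return signal / noise


def snr_filter(
    spectra: "list[Spectrum]", threshold: float, strict: bool = False
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Partition spectra into (retained, discarded) by CH2 SNR.

    The training regime keeps spectra with SNR strictly above the
    threshold (``strict=True``); validation and diagnosis keep SNR >=
    threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    retained, discarded = [], []
    for s in spectra:
        snr = compute_snr(s)
        ok = snr > threshold if strict else snr >= threshold
        (retained if ok else discarded).append(s)
    return retained, discarded


def moving_average_3x3(raster: np.ndarray) -> np.ndarray:
    """3x3 spatial moving average over a raster of spectra.

    ``raster`` has shape (rows, cols, n_points); each raster position is
    replaced by the mean of its available <= 9 spatial neighbours (edges
    average fewer).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 3:
        raise ValueError("raster must be a (rows, cols, n_points) array")
    from scipy.ndimage import uniform_filter

    # uniform_filter with nearest-edge padding would bias edges; divide
    # summed intensities by the summed count mask instead.
    kernel_sum = np.zeros_like(raster)
    ones = np.ones(raster.shape[:2])
    from scipy.signal import convolve2d

    k = np.ones((3, 3))
    counts = convolve2d(ones, k, mode="same")
    for i in range(raster.shape[2]):
        kernel_sum[:, :, i] = convolve2d(raster[:, :, i], k, mode="same")
    return kernel_sum / counts[:, :, None]


def band_area(s: Spectrum, band: BandDefinition) -> float:
    """Trapezoidal band area above the local linear baseline.

    The baseline is the straight line through the intensities at the two
    window endpoints; the result may be negative for a noisy or
    featureless window. A constant offset or any straight line added to
    the spectrum leaves the area unchanged.
    """
    if not s.on_standard_grid:
        raise ValueError("band_area requires a spectrum on the standard grid")
    sl = _window_slice(s.wavenumbers, band.centre - band.half_width, band.centre + band.half_width)
    x, y = s.wavenumbers[sl], s.intensities[sl]
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return float(np.trapezoid(y - baseline, x))


def extract_features(
    s: Spectrum, bands: "list[BandDefinition] | None" = None
) -> np.ndarray:
    """The 13 band areas, normalised to unit Euclidean norm.

    Scale-invariant: multiplying the spectrum by any positive constant
    leaves the feature vector unchanged.
    """
    if bands is None:
        bands = default_bands()
    areas = np.array([band_area(s, b) for b in bands])
    norm = float(np.linalg.norm(areas))
    if norm == 0.0:
        raise ValueError("featureless spectrum: all band areas are zero")
    return areas / norm


def extract_feature_matrix(spectra: "list[Spectrum]", bands=None) -> np.ndarray:
    """Stack :func:`extract_features` over a list of spectra."""
    return np.vstack([extract_features(s, bands) for s in spectra])


class PCADenoiser:
    """Projection denoiser: mean + top ``n_components`` principal axes.

    The basis is fit once on an independent set of intermediate-quality
    spectra; denoising projects each spectrum onto the retained
    subspace, which is idempotent by construction.
    """

    def __init__(self, n_components: int = 50):
        self.n_components = n_components
        self._pca: PCA | None = None

    def fit(self, basis: "list[Spectrum] | np.ndarray") -> "PCADenoiser":
        mat = basis if isinstance(basis, np.ndarray) else np.vstack([s.intensities for s in basis])
        if mat.shape[0] < self.n_components:
            raise ValueError(
                f"basis has {mat.shape[0]} spectra; >= {self.n_components} required"
            )
        self._pca = PCA(n_components=self.n_components, svd_solver="randomized",
                        random_state=0)
        self._pca.fit(mat)
        return self

    @property
    def components_(self) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("denoiser is not fitted")
        return self._pca.components_

    def transform(self, spectra: "list[Spectrum]") -> list[Spectrum]:
        if self._pca is None:
            raise RuntimeError("denoiser is not fitted")
        mat = np.vstack([s.intensities for s in spectra])
        rec = self._pca.inverse_transform(self._pca.transform(mat))
        return [
            Spectrum(s.wavenumbers.copy(), rec[i], dict(s.meta))
            for i, s in enumerate(spectra)
        ]


def pca_denoise(
    spectra: "list[Spectrum]", basis_set: "list[Spectrum]", n_components: int = 50
) -> list[Spectrum]:
    """Denoise ``spectra`` with a PCA basis fit on ``basis_set`` (50 PCs)."""
    return PCADenoiser(n_components).fit(basis_set).transform(spectra)
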