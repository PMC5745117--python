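"""Seeded phantoms and synthetic Raman spectra.

No public spectral or imaging data accompany the method, so every
downstream stage is exercised on synthetic inputs that reproduce the
two empirical observations the pipeline relies on:

* auto-fluorescence (AF) images in which tumour regions are darker than
  the surrounding stroma, on a textured tissue field over a dark
  background;
* Raman spectra whose class identity is carried by characteristic
  bands — DNA bands at 788/1098 cm^-1 for BCC, collagen bands at
  851/950 cm^-1 and Amide III for dermis, lipid bands at 1298/1744
  cm^-1 for fat, and the surgical-dye bands at 680/748/1144/1528
  cm^-1 — with the CH2 band at 1450 cm^-1 present in all tissue
  classes so that SNR-based quality control applies.

Phantom geometry defaults to 512 x 512 pixels at 40 um/pixel, i.e. a
2 cm x 2 cm field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt, gaussian_filter

from .preprocessing import (
    STANDARD_GRID,
    Spectrum,
)

# Annotation-mask label values.
LABEL_BACKGROUND = 0
LABEL_STROMA = 1
LABEL_BCC = 2
LABEL_DYE = 3

MASK_LABELS = {
    LABEL_BACKGROUND: "background",
    LABEL_STROMA: "stroma",
    LABEL_BCC: "BCC",
    LABEL_DYE: "dye",
}

TISSUE_CLASSES = ("BCC", "dermis", "fat", "EMI", "dye")

#: Tissue class emitted for a mask label when simulating a measurement.
_MASK_TO_CLASS = {LABEL_STROMA: "dermis", LABEL_BCC: "BCC", LABEL_DYE: "dye"}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity statistics of a synthetic AF phantom.

    Intensities are arbitrary AF units; the ordering
    ``background_mean < tumour_mean < stroma_mean`` encodes the
    observation that tumour is darker than stroma and that background is
    separable by a plain intensity threshold.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 40.0  # micrometres / pixel
    stroma_mean: float = 1000.0
    tumour_mean: float = 550.0
    background_mean: float = 40.0
    texture_sd: float = 90.0
    n_tumour_blobs: int = 10
    blob_radius_range: tuple[float, float] = (100.0, 500.0)  # micrometres
    blob_style: str = "micro_nodular"  # or "infiltrative"
    dye_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tumour_mean < self.stroma_mean:
            raise ValueError("tumour_mean must be below stroma_mean (tumour is darker)")
        if not self.background_mean < self.tumour_mean:
            raise ValueError("background_mean must be below tumour_mean")
        if self.blob_radius_range[0] <= 0 or self.blob_radius_range[1] < self.blob_radius_range[0]:
            raise ValueError("blob radii must be positive and ordered")
        if self.n_tumour_blobs < 0:
            raise ValueError("n_tumour_blobs must be >= 0")
        if self.blob_style not in ("micro_nodular", "infiltrative"):
            raise ValueError("blob_style must be 'micro_nodular' or 'infiltrative'")
        if not 0.0 <= self.dye_fraction <= 1.0:
            raise ValueError("dye_fraction must lie in [0, 1]")


def _tissue_support(shape: tuple[int, int]) -> np.ndarray:
    """Elliptical tissue footprint covering most of the field of view."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ry, rx = 0.44 * shape[0], 0.44 * shape[1]
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _stamp_blob(
    mask: np.ndarray, centre: tuple[float, float], radius_px: float,
    style: str, rng: np.random.Generator,
) -> None:
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    if style == "micro_nodular":
        # union of a core disc and a few overlapping satellites
        discs = [(centre, radius_px)]
        for _ in range(3):
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0.3, 0.7) * radius_px
            discs.append(
                ((centre[0] + off * np.sin(ang), centre[1] + off * np.cos(ang)),
                 rng.uniform(0.4, 0.7) * radius_px)
            )
        for (y, x), r in discs:
            mask |= (rr - y) ** 2 + (cc - x) ** 2 <= r**2
    else:  # infiltrative: a thin curved strand of small discs
        n_steps = max(6, int(3 * radius_px))
        ang = rng.uniform(0, 2 * np.pi)
        y, x = centre
        width = max(1.5, 0.18 * radius_px)
        for _ in range(n_steps):
            mask |= (rr - y) ** 2 + (cc - x) ** 2 <= width**2
            ang += rng.normal(0, 0.35)
            step = 2.0 * radius_px / n_steps
            y += step * np.sin(ang)
            x += step * np.cos(ang)


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate a seeded AF phantom and its per-pixel annotation mask.

    Returns ``(image, mask)``: a float intensity grid (stroma texture,
    darker tumour blobs, dark background, a dye arc on the tissue
    boundary) and an integer mask with labels background/stroma/BCC/dye.
    Deterministic for a fixed ``config.seed``; each of the
    ``n_tumour_blobs`` requested tumour blobs is a single connected
    component lying fully inside the tissue.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_shape)
    support = _tissue_support(shape)
    dist_to_edge = distance_transform_edt(support)

    mask = np.full(shape, LABEL_BACKGROUND, dtype=np.uint8)
    mask[support] = LABEL_STROMA

    # tumour blobs: rejection-placed so each stays inside the tissue and
    # clear of the others (components stay disjoint)
    r_lo, r_hi = (r / config.pixel_size for r in config.blob_radius_range)
    max_extent = float(dist_to_edge.max())
    placed: list[tuple[float, float, float]] = []
    for i in range(config.n_tumour_blobs):
        radius_px = rng.uniform(r_lo, r_hi)
        # footprint radius incl. satellites / strand excursions
        extent = 1.8 * radius_px if config.blob_style == "micro_nodular" else 2.6 * radius_px
        if extent + 2 >= max_extent:
            raise ValueError(
                f"blob {i}: radius {radius_px * config.pixel_size:.0f} um exceeds the "
                "tissue extent"
            )
        for attempt in range(2000):
            y = rng.uniform(0, shape[0] - 1)
            x = rng.uniform(0, shape[1] - 1)
            iy, ix = int(round(y)), int(round(x))
            if dist_to_edge[iy, ix] < extent + 2:
                continue
            if all(
                np.hypot(y - py, x - px) > extent + pe + 2 for py, px, pe in placed
            ):
                placed.append((y, x, extent))
                blob = np.zeros(shape, dtype=bool)
                _stamp_blob(blob, (y, x), radius_px, config.blob_style, rng)
                mask[blob & support] = LABEL_BCC
                break
        else:
            raise ValueError(f"blob {i}: could not place a blob of extent {extent:.0f} px")

    # dye: a contiguous arc on the tissue boundary
    if config.dye_fraction > 0:
        boundary = support & ~binary_erosion(support, iterations=2)
        rr, cc = np.nonzero(boundary)
        ang = np.arctan2(rr - (shape[0] - 1) / 2.0, cc - (shape[1] - 1) / 2.0)
        start = rng.uniform(-np.pi, np.pi)
        span = config.dye_fraction * 2 * np.pi
        rel = np.mod(ang - start, 2 * np.pi)
        sel = rel <= span
        dye_pixels = (rr[sel], cc[sel])
        mask[dye_pixels] = LABEL_DYE

    # intensities: per-class means modulated by a multiplicative smooth
    # random field (correlation scale ~5 px)
    texture = gaussian_filter(rng.standard_normal(shape), sigma=5.0)
    texture /= max(texture.std(), 1e-12)
    means = np.full(shape, config.background_mean, dtype=float)
    means[mask == LABEL_STROMA] = config.stroma_mean
    means[mask == LABEL_BCC] = config.tumour_mean
    means[mask == LABEL_DYE] = config.tumour_mean  # dye ink is dark in AF
    rel_sd = config.texture_sd / config.stroma_mean
    image = means * (1.0 + rel_sd * texture)
    np.clip(image, 0.0, None, out=image)
    return image, mask


@dataclass(frozen=True)
class SpectrumModel:
    """Gaussian-band model of one tissue class's Raman spectrum."""

    class_name: str
    band_centres: tuple[float, ...]
    band_heights: tuple[float, ...]
    band_widths: tuple[float, ...]  # Gaussian sigma, cm^-1
    baseline_slope: float = 2e-4  # intensity per cm^-1
    baseline_offset: float = 0.1
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (len(self.band_centres) == len(self.band_heights) == len(self.band_widths)):
            raise ValueError("band_centres/heights/widths lengths differ")
        if self.class_name not in TISSUE_CLASSES:
            raise ValueError(f"unknown class {self.class_name!r}")

    def clean_intensities(self, wavenumbers: np.ndarray | None = None) -> np.ndarray:
        """Noise-free spectrum: Gaussian bands plus linear baseline."""
        w = STANDARD_GRID if wavenumbers is None else np.asarray(wavenumbers)
        y = self.baseline_offset + self.baseline_slope * (w - w[0])
        for c, h, s in zip(self.band_centres, self.band_heights, self.band_widths):
            y = y + h * np.exp(-0.5 * ((w - c) / s) ** 2)
        return y


def default_spectrum_models() -> dict[str, SpectrumModel]:
    """One model per class, with the class-characteristic bands.

    All tissue classes carry the CH2 band at 1450 cm^-1 (so SNR is
    defined), the phenylalanine band at 1004 cm^-1 and Amide I at 1660
    cm^-1; the surgical dye has its own four bands and no CH2 band.
    """
    return {
        "BCC": SpectrumModel(
            "BCC",
            band_centres=(788, 1004, 1098, 1250, 1376, 1450, 1578, 1660),
            band_heights=(1.2, 0.5, 0.9, 0.5, 0.45, 1.0, 0.35, 0.8),
            band_widths=(4, 3, 5, 9, 5, 8, 5, 10),
        ),
        "dermis": SpectrumModel(
            "dermis",
            band_centres=(851, 873, 938, 950, 1004, 1245, 1450, 1660),
            band_heights=(1.1, 0.5, 0.7, 0.8, 0.3, 0.8, 1.0, 0.7),
            band_widths=(5, 5, 5, 5, 3, 9, 8, 10),
        ),
        "fat": SpectrumModel(
            "fat",
            band_centres=(1080, 1298, 1450, 1655, 1744),
            band_heights=(0.3, 1.1, 1.5, 0.35, 0.9),
            band_widths=(6, 5, 8, 8, 6),
        ),
        "EMI": SpectrumModel(
            "EMI",
            band_centres=(906, 1004, 1250, 1340, 1450, 1660),
            band_heights=(0.6, 0.8, 0.5, 0.5, 1.0, 0.9),
            band_widths=(5, 3, 9, 7, 8, 10),
        ),
        "dye": SpectrumModel(
            "dye",
            band_centres=(680, 748, 970, 1144, 1528),
            band_heights=(1.2, 1.0, 0.3, 0.9, 1.0),
            band_widths=(4, 4, 6, 5, 5),
        ),
    }


def _clean_snr_signal(model: SpectrumModel) -> float:
    """Baseline-subtracted CH2 height of the noise-free model spectrum.

    For the dye model (no CH2 band) the largest band height is used
    instead, purely to give the noise scale a reference amplitude.
    """
    from .preprocessing import SNR_BAND_CENTRE, SNR_BAND_HALF_WIDTH

    w = STANDARD_GRID
    y = model.clean_intensities(w)
    sel = (w >= SNR_BAND_CENTRE - SNR_BAND_HALF_WIDTH) & (w <= SNR_BAND_CENTRE + SNR_BAND_HALF_WIDTH)
    xw, yw = w[sel], y[sel]
    baseline = yw[0] + (yw[-1] - yw[0]) * (xw - xw[0]) / (xw[-1] - xw[0])
    signal = float(np.max(yw - baseline))
    if signal < 1e-6:
        signal = float(max(model.band_heights))
    return signal


def generate_spectrum(
    model: SpectrumModel, target_snr: float, seed: int
) -> Spectrum:
    """One synthetic spectrum on the standard grid at a prescribed SNR.

    White Gaussian noise is added with standard deviation chosen so the
    CH2-based SNR statistic equals ``target_snr`` in expectation (the
    noise-region rms estimates the noise sd, and the CH2 signal height
    is fixed by the model).
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    rng = np.random.default_rng(seed)
    clean = model.clean_intensities()
    # The SNR statistic is biased relative to signal/noise_sd: taking the
    # max over the 21-point CH2 window adds ~kappa noise sd to the
    # numerator, and the 2-dof linear fit over the 26-point noise region
    # shrinks the rms by gamma = sqrt(24/26). Invert both so the
    # statistic's expectation lands on target_snr.
    kappa = 1.25
    gamma = np.sqrt(24.0 / 26.0)
    effective = max(gamma * target_snr - kappa, 0.5 * target_snr)
    noise_sd = _clean_snr_signal(model) / effective
    y = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    return Spectrum(
        STANDARD_GRID.copy(),
        y,
        {"class": model.class_name, "target_snr": target_snr, "seed": seed},
    )


def generate_spectral_library(
    n_per_class: int,
    snr_range: tuple[float, float] = (15.0, 30.0),
    seed: int = 0,
    n_patients: int = 10,
    models: dict[str, SpectrumModel] | None = None,
) -> list[Spectrum]:
    """Balanced labelled library over the five classes.

    Each spectrum's ``meta`` carries ``class``, a synthetic
    ``patient_id`` (for patient-grouped cross-validation) and a
    ``spectrum_id``. SNR targets are drawn uniformly from ``snr_range``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if models is None:
        models = default_spectrum_models()
    rng = np.random.default_rng(seed)
    library: list[Spectrum] = []
    for class_name in TISSUE_CLASSES:
        model = models[class_name]
        for j in range(n_per_class):
            snr = rng.uniform(*snr_range)
            s = generate_spectrum(model, snr, seed=int(rng.integers(0, 2**31 - 1)))
            s.meta["patient_id"] = f"P{rng.integers(0, n_patients):03d}"
            s.meta["spectrum_id"] = f"{class_name}-{j:05d}"
            library.append(s)
    return library


def simulate_measurement(
    phantom_mask: np.ndarray,
    location: tuple[int, int],
    target_snr: float,
    seed: int,
    models: dict[str, SpectrumModel] | None = None,
) -> Spectrum:
    """Emit the Raman spectrum a probe would record at ``location``.

    Looks up the annotation class at the pixel (stroma measures as
    dermis) and generates a class-model spectrum at the requested SNR.
    Measuring on background raises, since there is no tissue there.
    """
    r, c = location
    if not (0 <= r < phantom_mask.shape[0] and 0 <= c < phantom_mask.shape[1]):
        raise ValueError(f"location {location} outside the image")
    label = int(phantom_mask[r, c])
    if label == LABEL_BACKGROUND:
        raise ValueError(f"location {location} is background: no tissue to measure")
    if models is None:
        models = default_spectrum_models()
    class_name = _MASK_TO_CLASS[label]
    s = generate_spectrum(models[class_name], target_snr, seed)
    s.meta["location"] = (int(r), int(c))
    return s
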