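"""File formats and run configuration.

Images travel as 16-bit TIFF (intensities) and PNG (label masks) with a
JSON sidecar of generation parameters; spectral libraries as CSV with
one row per spectrum (id, patient, class, then the 701 intensity
columns headed by wavenumber); plans, curves and confusion matrices as
CSV; reports as JSON. The run configuration is a flat, YAML-serialisable
record whose SHA-256 hash is stamped into every report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .preprocessing import (
    STANDARD_GRID,
    SNR_THRESHOLD_DIAGNOSIS,
    SNR_THRESHOLD_TRAINING,
    SNR_THRESHOLD_VALIDATION,
    Spectrum,
)
from .segmentation import AFImage, SegmentMap
from .synthetic import MASK_LABELS, PhantomConfig


@dataclass
class RunConfig:
    """All tunable parameters of an end-to-end run.

    ``mode`` selects one of the three operating regimes: ``training``
    (raster scans, SNR strictly above 15), ``validation`` (at least 20
    points per segment, at most 1200 spectra, SNR >= 7) and
    ``diagnosis`` (800-point budget, SNR >= 4, two rounds).
    """

    mode: str = "diagnosis"
    background_threshold: float = 150.0
    flatten_sigma: float | None = None
    objective: str = "f_B"
    threshold_grid_size: int = 256
    n_min: int = 5
    n_total: int = 800
    placement_config: str = "config2"
    snr_threshold: float = SNR_THRESHOLD_DIAGNOSIS
    snr_strict: bool = False
    target_snr: float = 15.0
    n_th: int = 8
    pca_components: int = 50
    denoiser_basis_size: int = 200
    library_n_per_class: int = 80
    classifier_hidden: int = 20
    seed: int = 0
    phantom: dict = dataclasses.field(default_factory=dict)

    MODE_PRESETS = {
        "training": {"snr_threshold": SNR_THRESHOLD_TRAINING, "snr_strict": True},
        "validation": {"snr_threshold": SNR_THRESHOLD_VALIDATION, "n_min": 20,
                       "n_total": 1200, "snr_strict": False},
        "diagnosis": {"snr_threshold": SNR_THRESHOLD_DIAGNOSIS, "snr_strict": False},
    }

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "RunConfig":
        if mode not in cls.MODE_PRESETS:
            raise ValueError(f"unknown mode {mode!r}")
        params = {"mode": mode, **cls.MODE_PRESETS[mode], **overrides}
        return cls(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# --- phantom / image round trips -------------------------------------------

def write_phantom(directory, image: np.ndarray, mask: np.ndarray,
                  config: PhantomConfig) -> None:
    """16-bit TIFF image + PNG mask + JSON sidecar of the generator config."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scaled = np.clip(image, 0, 65535).astype(np.uint16)
    tifffile.imwrite(d / "af_image.tif", scaled)
    Image.fromarray(mask.astype(np.uint8), mode="L").save(d / "annotation.png")
    sidecar = dataclasses.asdict(config)
    sidecar["mask_labels"] = {str(k): v for k, v in MASK_LABELS.items()}
    (d / "phantom.json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_phantom(directory) -> tuple[AFImage, np.ndarray, dict]:
    """Load a phantom directory back into memory, validating shapes."""
    d = Path(directory)
    arr = tifffile.imread(d / "af_image.tif").astype(float)
    mask = np.asarray(Image.open(d / "annotation.png"), dtype=np.uint8)
    meta = json.loads((d / "phantom.json").read_text())
    if arr.shape != mask.shape:
        raise ValueError(f"image shape {arr.shape} != mask shape {mask.shape}")
    known = {int(k) for k in meta.get("mask_labels", {str(k): v for k, v in MASK_LABELS.items()})}
    unknown = set(np.unique(mask)) - known
    if unknown:
        raise ValueError(f"annotation mask contains unknown label values {sorted(unknown)}")
    return AFImage(arr, float(meta.get("pixel_size", 40.0))), mask, meta


def read_af_image(path, pixel_size: float = 40.0) -> AFImage:
    """Read a grayscale TIFF or PNG as an AF image."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p).astype(float)
    else:
        arr = np.asarray(Image.open(p).convert("I"), dtype=float)
    return AFImage(arr, pixel_size)


# --- spectra ----------------------------------------------------------------

def write_spectra_csv(path, spectra: list[Spectrum]) -> None:
    """One row per spectrum: spectrum_id, patient_id, class, then the
    701 intensity columns headed by their wavenumbers."""
    rows = []
    for i, s in enumerate(spectra):
        if not s.on_standard_grid:
            raise ValueError("spectra must be on the standard grid before export")
        row = {
            "spectrum_id": s.meta.get("spectrum_id", f"S{i:06d}"),
            "patient_id": s.meta.get("patient_id", ""),
            "class": s.meta.get("class", ""),
        }
        row.update({f"{w:.0f}": v for w, v in zip(s.wavenumbers, s.intensities)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spectra_csv(path) -> list[Spectrum]:
    df = pd.read_csv(path)
    wn_cols = [c for c in df.columns if c not in ("spectrum_id", "patient_id", "class")]
    wn = np.array([float(c) for c in wn_cols])
    if wn.min() > STANDARD_GRID[0] or wn.max() < STANDARD_GRID[-1]:
        raise ValueError(
            f"spectra cover {wn.min():.0f}-{wn.max():.0f} cm^-1; "
            "full 400-1800 cm^-1 coverage is required"
        )
    out = []
    for _, row in df.iterrows():
        meta = {k: row[k] for k in ("spectrum_id", "patient_id", "class") if k in row}
        out.append(Spectrum(wn, row[wn_cols].to_numpy(dtype=float), meta))
    return out


# --- segmentation outputs ---------------------------------------------------

def write_segment_map(directory, segmap: SegmentMap, curve: np.ndarray | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(d / "segments.tif", segmap.labels.astype(np.uint16))
    segmap.to_dataframe().to_csv(d / "segments.csv", index=False)
    if curve is not None:
        pd.DataFrame(curve, columns=["threshold", "objective"]).to_csv(
            d / "objective_curve.csv", index=False
        )


# --- reports ----------------------------------------------------------------

def write_report(directory, report: dict, diagnosis_image=None) -> None:
    """JSON report (+ colour PNG of the diagnosis image when given)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    required = {"n_bcc", "decision", "config_hash"}
    missing = required - report.keys()
    if missing:
        raise ValueError(f"report is missing required fields {sorted(missing)}")
    (d / "report.json").write_text(json.dumps(report, indent=2, default=str))
    if diagnosis_image is not None:
        Image.fromarray(diagnosis_image.to_rgb(), mode="RGB").save(d / "diagnosis.png")
        tifffile.imwrite(d / "diagnosis_labels.tif", diagnosis_image.codes)


def read_report(directory) -> dict:
    return json.loads((Path(directory) / "report.json").read_text())
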