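"""Shared fixtures: synthetic libraries, a trained classifier, phantoms.

Session scope keeps the expensive objects (spectral library, trained
network, segmented phantom) built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from msh.classifier import train_ann
from msh.preprocessing import PCADenoiser, extract_feature_matrix
from msh.sampling import AllocationParams, build_plan
from msh.segmentation import AFImage, flatten_image, optimize_threshold, segment_at_threshold, tissue_mask
from msh.synthetic import (
    PhantomConfig,
    default_spectrum_models,
    generate_phantom,
    generate_spectral_library,
)

#: Desk-scale phantom geometry used throughout the suite: the same
#: 2 cm x 2 cm field of view at 80 um/pixel (256 x 256).
SMALL_PHANTOM = dict(image_shape=(256, 256), pixel_size=80.0)


@pytest.fixture(scope="session")
def models():
    return default_spectrum_models()


@pytest.fixture(scope="session")
def library():
    return generate_spectral_library(60, snr_range=(15.0, 30.0), seed=11)


@pytest.fixture(scope="session")
def library_arrays(library):
    feats = extract_feature_matrix(library)
    labels = np.array([s.meta["class"] for s in library])
    groups = np.array([s.meta["patient_id"] for s in library])
    return feats, labels, groups


@pytest.fixture(scope="session")
def trained_model(library_arrays):
    feats, labels, _ = library_arrays
    return train_ann(feats, labels, seed=7)


@pytest.fixture(scope="session")
def denoiser():
    basis = generate_spectral_library(20, snr_range=(10.0, 15.0), seed=13)
    return PCADenoiser(50).fit(basis)


@pytest.fixture(scope="session")
def phantom():
    cfg = PhantomConfig(seed=21, n_tumour_blobs=10, **SMALL_PHANTOM)
    image, mask = generate_phantom(cfg)
    return cfg, image, mask


@pytest.fixture(scope="session")
def segmented_phantom(phantom):
    cfg, image, mask = phantom
    af = AFImage(image, cfg.pixel_size)
    tmask = tissue_mask(af, 150.0)
    flat = flatten_image(af, foreground=tmask)
    threshold, _ = optimize_threshold(flat, tmask)
    segmap = segment_at_threshold(flat, tmask, threshold)
    return cfg, flat, tmask, segmap, mask


@pytest.fixture(scope="session")
def sampling_plan(segmented_phantom):
    _, flat, _, segmap, _ = segmented_phantom
    return build_plan(segmap, flat.intensities, AllocationParams(), seed=21)
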