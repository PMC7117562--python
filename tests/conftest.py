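import warnings

import numpy as np
import pytest

from aicyto import (
    ImagePlane,
    NucleusROI,
    PopulationSpec,
    SceneSpec,
    measure_sample,
    render_scene,
)


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise, texture-free scene: the exact Beer-Lambert regime."""
    spec = SceneSpec(
        shape=(384, 384),
        noise_sd=0.0,
        texture_cv=0.0,
        n_controls=12,
        n_epithelial=24,
        populations=(
            PopulationSpec("2N", 0.5, 1.0, cv=0.0),
            PopulationSpec("4N", 0.5, 2.0, cv=0.0),
        ),
        control_cv=0.0,
        seed=42,
    )
    return spec, *render_scene(spec)


@pytest.fixture(scope="session")
def clean_measurements(clean_scene):
    spec, plane, rois, truth = clean_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ms = measure_sample(plane, rois)
    return ms, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_plane(pixels, bit_depth=8, white_level=None):
    pixels = np.asarray(pixels)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    if white_level is None:
        white_level = float(2**bit_depth - 1)
    return ImagePlane(
        pixels=pixels.astype(dtype), bit_depth=bit_depth, white_level=white_level
    )


def square_roi(roi_id, cell_class, r0, c0, side):
    """Axis-aligned square polygon covering side x side pixel centers."""
    x0, y0 = c0 - 0.5, r0 - 0.5
    x1, y1 = c0 + side - 0.5, r0 + side - 0.5
    return NucleusROI(
        id=roi_id,
        cell_class=cell_class,
        polygon=np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]),
    )
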