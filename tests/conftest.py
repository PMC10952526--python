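"""Shared fixtures: synthetic scenes are expensive, so build them once."""

from __future__ import annotations

import numpy as np
import pytest

from tfm.displacement import compute_piv, correct_drift, validate_and_fill
from tfm.synthetic import SceneConfig, generate_dataset, make_scene


@pytest.fixture(scope="session")
def default_scene():
    """Mid-sized contracting-disk scene with drift, full imaging defaults."""
    cfg = SceneConfig(
        template="contracting_disk",
        peak_traction=170.0,
        radius=30.0,
        drift=(2.6, -1.4),
        seed=11,
    )
    return make_scene(cfg)


@pytest.fixture(scope="session")
def default_piv(default_scene):
    """Drift-corrected, validated PIV field of the default scene."""
    shift, aligned = correct_drift(default_scene.reference, default_scene.deformed)
    field = compute_piv(default_scene.reference, aligned,
                        window_size=20.0, overlap=18.0)
    return shift, validate_and_fill(field)


@pytest.fixture(scope="session")
def quiet_scene():
    """Drift-free, noise-free small scene for estimator-precision checks."""
    cfg = SceneConfig(
        template="contracting_disk",
        peak_traction=150.0,
        radius=18.0,
        image_size=256,
        drift=(0.0, 0.0),
        noise_sd=0.0,
        seed=5,
    )
    return make_scene(cfg)


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, default_scene):
    """The default scene written to disk as a dataset bundle."""
    out = tmp_path_factory.mktemp("scene")
    return generate_dataset(default_scene.config, out / "bundle")


def interp_ground_truth(scene, x, y):
    """Ground-truth displacement (um) interpolated at query nodes."""
    from scipy.interpolate import RegularGridInterpolator

    gt = scene.displacement
    ui = RegularGridInterpolator((gt.y[:, 0], gt.x[0, :]), gt.u,
                                 bounds_error=False, fill_value=None)
    vi = RegularGridInterpolator((gt.y[:, 0], gt.x[0, :]), gt.v,
                                 bounds_error=False, fill_value=None)
    pts = np.column_stack([np.asarray(y).ravel(), np.asarray(x).ravel()])
    return ui(pts).reshape(np.shape(x)), vi(pts).reshape(np.shape(x))
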