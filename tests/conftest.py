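"""Shared fixtures: synthetic runs at several corruption levels and their
full pipeline results.  Session-scoped because simulation plus the full
pipeline on a 512 px scene takes seconds and many tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from melchist.pipeline import RunConfig, run_all
from melchist.synthetic import (
    SceneSpec,
    TONSIL_PANEL,
    TONSIL_TYPES,
    default_tonsil_like_spec,
    simulate_run,
)


def small_spec(seed: int, shape=(192, 192), n_cells=25, **overrides) -> SceneSpec:
    """A quick 192 px tonsil-like scene (25 cells) for unit tests."""
    spec = default_tonsil_like_spec(seed, image_shape=shape, n_cells=n_cells,
                                    **overrides)
    return spec


@pytest.fixture(scope="session")
def clean_scene():
    """Corruption-free default scene: no noise, flat illumination, zero
    shifts, no bleach residual (autofluorescence stays; subtraction removes
    it exactly)."""
    spec = default_tonsil_like_spec(
        11, noise_sd=0.0, illumination_amplitude=0.0,
        bleach_residual_fraction=0.0, max_shift_px=0,
    )
    spec.stage_shifts_px = {}
    run, truth = simulate_run(spec)
    return spec, run, truth


@pytest.fixture(scope="session")
def clean_result(clean_scene, tmp_path_factory):
    _, run, truth = clean_scene
    out = tmp_path_factory.mktemp("e2e_clean")
    return run_all(run, out, RunConfig(seed=5), truth_class_image=truth.class_image)


@pytest.fixture(scope="session")
def lownoise_scene():
    """Default scene with every corruption on and noise_sd = 0.02."""
    spec = default_tonsil_like_spec(21, noise_sd=0.02)
    run, truth = simulate_run(spec)
    return spec, run, truth


@pytest.fixture(scope="session")
def lownoise_result(lownoise_scene, tmp_path_factory):
    _, run, truth = lownoise_scene
    out = tmp_path_factory.mktemp("e2e_lownoise")
    return run_all(run, out, RunConfig(seed=6), truth_class_image=truth.class_image)


@pytest.fixture(scope="session")
def default_scene():
    """The default study conditions (noise_sd = 0.05, all corruptions)."""
    spec = default_tonsil_like_spec(31)
    run, truth = simulate_run(spec)
    return spec, run, truth


@pytest.fixture(scope="session")
def default_result(default_scene, tmp_path_factory):
    _, run, truth = default_scene
    out = tmp_path_factory.mktemp("e2e_default")
    return run_all(run, out, RunConfig(seed=7), truth_class_image=truth.class_image)


def match_cells_to_truth(cells: np.ndarray, truth, margin: int) -> dict[int, int]:
    """Map truth cell index (0-based) -> predicted label at the true center
    (0 when unmatched).  Centers are moved into the cropped frame first."""
    centers = truth.cell_centers_px - margin
    out = {}
    h, w = cells.shape
    for i, (r, c) in enumerate(centers):
        ri, ci = int(round(r)), int(round(c))
        out[i] = int(cells[ri, ci]) if 0 <= ri < h and 0 <= ci < w else 0
    return out
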