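"""Shared fixtures: plasma input, frame schedules, small phantoms.

Heavy objects (a rendered-and-corrected default subject) are session-scoped
so several test modules can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from taupvc import (
    HDHConfig,
    KineticParams,
    PSFModel,
    PhantomSpec,
    RegionGeometry,
    hdh_pvc,
    make_plasma_input,
    render_dynamic_phantom,
)
from taupvc.image import FrameSchedule
from taupvc.phantom import default_frame_schedule


@pytest.fixture(scope="session")
def plasma():
    return make_plasma_input()

@pytest.fixture(scope="session")
def frames():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def mean_region_params():
    """Region kinetics at the default distribution means (CP/hippo V_T ~ 3.5)."""
    return {
        "hippocampus": KineticParams(K1=0.25, k2=0.15, k3=0.03, k4=0.02, VB=0.05),
        "choroid_plexus": KineticParams(K1=0.4375, k2=0.12, k3=0.06, k4=0.02, VB=0.08),
        "background": KineticParams(K1=0.12, k2=0.04, VB=0.03),
    }


@pytest.fixture(scope="session")
def small_spec():
    """Compact 40^3 phantom for fast rendering tests."""
    return PhantomSpec(
        grid_shape=(40, 40, 40),
        geometry=RegionGeometry(hippo_semiaxes_mm=(10.0, 7.0, 6.0)),
        psf_fwhm_mm=0.0,
        noise_scale=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_subject(plasma, mean_region_params):
    """One noise-free default-geometry subject, blurred and HDH-corrected.

    Returns (raw image, corrected image, truth).
    """
    spec = PhantomSpec(psf_fwhm_mm=6.0, noise_scale=0.0, seed=11)
    img, truth = render_dynamic_phantom(spec, mean_region_params, plasma)
    img_pvc, _ = hdh_pvc(img, PSFModel(6.0), HDHConfig())
    return img, img_pvc, truth


@pytest.fixture(scope="session")
def cp_search_shell(default_subject):
    """Anatomical search shell around the hippocampus (10 mm dilation)."""
    _, _, truth = default_subject
    hippo = truth.labels == 1
    struct = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_dilation(hippo, struct, iterations=5) & ~hippo


@pytest.fixture
def short_frames():
    """10-frame schedule covering 0-40 min, for cheap fits."""
    durations = np.array([30, 30, 60, 120, 240, 300, 300, 300, 510, 510], dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)
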