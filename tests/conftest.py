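"""Shared fixtures: small seeded time series, dFC stacks and cohorts."""

import numpy as np
import pytest
from hypothesis import settings

from tdncd import ROITimeSeries, WindowConfig, compute_dfc
from tdncd.synthetic import SyntheticSpec, uniform_group_sizes

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_timeseries(n_frames=60, n_rois=5, seed=0, tr=2.0, **kwargs):
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_frames, n_rois))
    defaults = dict(
        subject_id="sub", site_id="site1", diagnosis="NC", tr_seconds=tr
    )
    defaults.update(kwargs)
    return ROITimeSeries(values=values, **defaults)


@pytest.fixture
def small_ts():
    return make_timeseries()


@pytest.fixture
def small_stack(small_ts):
    # 60 frames, window 20, step 5 -> 9 windows of 5 ROIs
    return compute_dfc(small_ts, WindowConfig(window_seconds=40, step_seconds=10))


@pytest.fixture
def random_stack(small_stack):
    """A synthetic 6-window, 5-ROI stack of valid correlation matrices."""
    rng = np.random.default_rng(42)
    slices = []
    for _ in range(6):
        x = rng.standard_normal((30, 5))
        slices.append(np.corrcoef(x, rowvar=False))
    stack = small_stack
    return type(stack)(
        tensor=np.array(slices),
        window_starts=np.arange(6) * 5,
        window_frames=30,
        step_frames=5,
        tr_seconds=2.0,
    )


def two_group_cohort(
    per_group=15,
    n_sites=4,
    n_rois=40,
    seed=0,
    effect_delta=1.0,
    affected=None,
    n_states=3,
    **kwargs,
):
    """Desk-scale NC/AD cohort spec used by the heavier integration tests."""
    if affected is None:
        affected = {0: 1, 8: 1, 16: 1, 24: -1, 32: -1}
    return SyntheticSpec.desk_scale(
        n_rois=n_rois,
        seed=seed,
        n_states=n_states,
        group_sizes=uniform_group_sizes(n_sites, per_group, ("NC", "AD")),
        affected_rois=affected,
        effect_delta={"NC": 0.0, "MCI": effect_delta / 2, "AD": effect_delta},
        **kwargs,
    )


def null_cohort(per_group=15, n_sites=4, n_rois=40, seed=0, **kwargs):
    """Stationary zero-effect cohort: one latent state, no planted ROIs."""
    return SyntheticSpec.desk_scale(
        n_rois=n_rois,
        seed=seed,
        n_states=1,
        dwell={"NC": 1.0, "MCI": 1.0, "AD": 1.0},
        group_sizes=uniform_group_sizes(n_sites, per_group, ("NC", "AD")),
        effect_delta={"NC": 0.0, "MCI": 0.0, "AD": 0.0},
        **kwargs,
    )
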