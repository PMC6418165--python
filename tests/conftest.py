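"""Shared fixtures: the default task layout, simulated profiles, and the
expensive session-scoped artefacts (full overlap sweep, full synthetic
cohort) reused across test modules."""

import warnings

import numpy as np
import pytest

from coartkin.cohort import analyze_cohort, generate_cohort
from coartkin.layout import default_layout
from coartkin.minjerk import grid_profile, simulate_grid, solve_via_points
from coartkin.stats import summarize
from coartkin.trials import TrialRecord

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)

DT = 1.0 / 160.0


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def timings():
    """Wall-clock durations of the expensive fixtures, by name."""
    return {}


@pytest.fixture(scope="session")
def full_curve(layout, timings):
    """The 551-point overlap sweep (0 to 55%) on the default layout."""
    import time

    t0 = time.perf_counter()
    curve = simulate_grid(layout, n=551)
    timings["grid_551_s"] = time.perf_counter() - t0
    return curve


@pytest.fixture(scope="session")
def cohort(layout):
    """The full default synthetic experiment: 4 groups x 15 subjects."""
    return generate_cohort(n_per_group=15, master_seed=17)


@pytest.fixture(scope="session")
def cohort_measures(cohort):
    return analyze_cohort(cohort)


@pytest.fixture(scope="session")
def cohort_summary(cohort_measures):
    return summarize(cohort_measures)


def make_trial(t, x, y, **kw):
    """A TrialRecord with boilerplate identity fields."""
    defaults = dict(
        subject_id="S01", group="OG", session="pre", block=1, trial=1,
        t=np.asarray(t, float), x=np.asarray(x, float), y=np.asarray(y, float),
    )
    defaults.update(kw)
    return TrialRecord(**defaults)


def simulated_trial(layout, overlap, t_sub=0.5, dt=DT, pad=0.25):
    """A noiseless trial through the optimized via-points at one overlap.

    Returns (TrialRecord, SimTrajectory); the record is padded with
    stationary dwells so the segmentation stage has rest to key on.
    """
    via = solve_via_points(layout, overlap, t_sub=t_sub, dt=dt)
    traj, score, offset, n_pk = grid_profile(layout, overlap, via, t_sub, dt, oversample=1)
    n_pad = int(round(pad / dt))
    xy = np.vstack(
        [np.tile(traj.xy[0], (n_pad, 1)), traj.xy, np.tile(traj.xy[-1], (n_pad, 1))]
    )
    t = np.arange(len(xy)) * dt
    rec = make_trial(t, xy[:, 0], xy[:, 1])
    return rec, traj
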