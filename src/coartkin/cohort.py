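"""Synthetic cohort generator: a full four-group training experiment.

The generator emits the complete two-day protocol — day 1: 60-trial
pre-test, six training blocks, 60-trial post-test; day 2: 60-trial
trained re-test plus mirror and scaled transfer tests — for four groups
of subjects whose ground-truth learning dynamics follow the qualitative
pattern of observation-based learning of this task:

* OG (observation): submovement overlap steps up from 0 within the
  first 5 training trials, then drifts up slowly block by block;
  movement duration drops ~30% at training onset and stays there.
* SOG (slowed observation): same overlap dynamics (slightly larger
  plateau), but movement duration unchanged — coarticulation and speed
  are dissociable.
* RMCG / DPTCG (controls): overlap stays near zero and duration
  unchanged; DPTCG performs 60 physical trials per training block
  instead of 30 (its extra practice buys it nothing, by construction).
* Observation groups pay a transient accuracy cost: the per-trial
  target-miss probability rises at post-test and returns to baseline by
  day 2.  Transfer sessions have elevated miss rates for everyone,
  highest in the mirror condition for the observation groups.

Each physical trial is synthesized by the minimum-jerk superposition
engine at the scheduled overlap (via-points interpolated from a
pre-solved per-layout map), padded with stationary dwells, optionally
warped by a target-miss displacement bump, degraded with Gaussian
sensor noise, and sampled at 160 Hz.  A small fraction of trials gets a
recording gap injected so the exclusion filter has something to catch.
Observation/video trials produce no trajectory rows — only physical
trials are emitted.

Generation is bit-reproducible: the same master seed yields the same
cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .layout import TargetLayout, default_layout, mirror_layout, scale_layout
from .minjerk import MAX_OVERLAP, chain_submovements, solve_via_points, superpose
from .trials import GROUPS, TrialRecord, TrialSet

__all__ = [
    "GroupProfile",
    "CohortDataset",
    "ViaPointMap",
    "default_profiles",
    "generate_subject",
    "generate_cohort",
    "analyze_cohort",
]

TRUTH_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "block",
    "trial",
    "true_overlap",
    "true_duration_s",
    "miss_target",
    "miss_excess_mm",
    "gap_injected",
]

#: protocol sessions in order, with (n_blocks, trials_per_block) resolved
#: per group at generation time
SESSION_ORDER = ("pre", "train", "post", "day2", "mirror", "scaled")


@dataclass
class GroupProfile:
    """Ground-truth generative schedule for one training group.

    Overlap schedule: ``o_plateau`` is reached by a linear ramp over the
    first ``ramp_trials`` trials of training block 1, then drifts by
    ``o_drift`` per block; post-test and all day-2 sessions continue at
    the block-6 level.  Durations are total movement times in s;
    ``dur_trained`` applies from the ramp onward (pre-test uses
    ``dur_pre``).  The scaled transfer runs at ``scaled_factor`` times
    the session duration — target size is unchanged while distances
    shrink 30%, so movements get proportionally faster.  Miss rates and
    excess magnitudes are per-session Bernoulli/exponential parameters
    of the target-miss injection.
    """

    group: str
    train_trials_per_block: int = 30
    test_trials: int = 60
    n_train_blocks: int = 6
    # overlap schedule
    o_pre: float = 0.0
    o_plateau: float = 0.0
    o_drift: float = 0.0
    ramp_trials: int = 5
    o_subject_sd: float = 0.01
    o_trial_sd: float = 0.015
    # duration schedule (s)
    dur_pre: float = 2.0
    dur_trained: float = 2.0
    scaled_factor: float = 0.73
    dur_subject_sd: float = 0.15  # multiplicative trait SD
    dur_trial_sd: float = 0.04  # multiplicative trial-to-trial SD
    # accuracy model
    miss_rate: dict = field(default_factory=dict)  # session -> probability
    miss_excess_mm: dict = field(default_factory=dict)  # session -> exp scale
    # recording artefacts
    gap_rate: float = 0.033
    noise_sd_cm: float = 0.01

    def mean_overlap(self, session: str, block: int, trial: int) -> float:
        """Deterministic (pre-jitter) overlap for one trial."""
        if session == "pre":
            return self.o_pre
        level = self.o_plateau + self.o_drift * (self.n_train_blocks - 1)
        if session == "train":
            if block == 1 and trial <= self.ramp_trials:
                frac = trial / self.ramp_trials
                return self.o_pre + (self.o_plateau - self.o_pre) * frac
            return self.o_plateau + self.o_drift * (block - 1)
        return level  # post, day2, mirror, scaled

    def mean_duration(self, session: str, block: int, trial: int) -> float:
        if session == "pre":
            return self.dur_pre
        if session == "train" and block == 1 and trial <= self.ramp_trials:
            frac = trial / self.ramp_trials
            return self.dur_pre + (self.dur_trained - self.dur_pre) * frac
        base = self.dur_trained
        if session == "scaled":
            return base * self.scaled_factor
        return base

    def session_plan(self) -> list[tuple[str, int, int]]:
        """(session, block, n_trials) in protocol order."""
        plan = [("pre", 1, self.test_trials)]
        plan += [
            ("train", b, self.train_trials_per_block)
            for b in range(1, self.n_train_blocks + 1)
        ]
        plan += [
            (s, 1, self.test_trials) for s in ("post", "day2", "mirror", "scaled")
        ]
        return plan


def default_profiles() -> dict[str, GroupProfile]:
    """The four groups with the study's programmed outcome pattern.

    Overlap plateaus/drifts were calibrated against the simulation's
    score(o) curve so the programmed post-test score gains are ~21 (OG)
    and ~25 (SOG) and the training-block score slopes ~0.73 and ~0.97
    per block; durations use the 2.00 s pre-test and 1.38 s trained
    values, with the ~27% scaled-transfer speedup shared by all groups.
    """
    base_miss = {
        "pre": 0.08,
        "train": 0.08,
        "post": 0.08,
        "day2": 0.08,
        "mirror": 0.60,
        "scaled": 0.75,
    }
    base_excess = {
        "pre": 0.4,
        "train": 0.4,
        "post": 0.4,
        "day2": 0.4,
        "mirror": 0.8,
        "scaled": 1.2,
    }
    obs_miss = dict(base_miss, post=0.65, mirror=0.85)
    obs_excess = dict(base_excess, post=0.5, mirror=2.0)
    return {
        "OG": GroupProfile(
            group="OG",
            o_plateau=0.1944,
            o_drift=0.0029,
            o_subject_sd=0.03,
            dur_trained=1.38,
            miss_rate=obs_miss,
            miss_excess_mm=obs_excess,
        ),
        "SOG": GroupProfile(
            group="SOG",
            o_plateau=0.213,
            o_drift=0.0035,
            o_subject_sd=0.03,
            dur_trained=2.0,
            miss_rate=obs_miss,
            miss_excess_mm=obs_excess,
        ),
        "RMCG": GroupProfile(
            group="RMCG",
            o_plateau=0.0,
            o_drift=0.0,
            o_subject_sd=0.01,
            dur_trained=2.0,
            miss_rate=dict(base_miss),
            miss_excess_mm=dict(base_excess),
        ),
        "DPTCG": GroupProfile(
            group="DPTCG",
            train_trials_per_block=60,
            o_plateau=0.0,
            o_drift=0.0,
            o_subject_sd=0.01,
            dur_trained=2.0,
            miss_rate=dict(base_miss),
            miss_excess_mm=dict(base_excess),
        ),
    }


class ViaPointMap:
    """Smooth interpolant of the via-point solution as a function of overlap.

    Solving the via-point problem per trial would dominate cohort
    generation; instead it is solved once on a coarse overlap grid per
    layout (warm-started sweep) and interpolated with cubic splines.
    Interpolation error is far below both the target radius and the
    sensor noise.
    """

    def __init__(self, layout: TargetLayout, n_grid: int = 23, t_sub: float = 0.5):
        self.layout = layout
        grid = np.linspace(0.0, MAX_OVERLAP, n_grid)
        bs, ds = [], []
        warm = None
        for o in grid:
            via = solve_via_points(layout, float(o), t_sub=t_sub, x0=warm)
            warm = (via.b_prime, via.d_prime)
            bs.append(via.b_prime)
            ds.append(via.d_prime)
        self._b = CubicSpline(grid, np.array(bs), axis=0)
        self._d = CubicSpline(grid, np.array(ds), axis=0)

    def __call__(self, overlap: float) -> tuple[np.ndarray, np.ndarray]:
        o = float(np.clip(overlap, 0.0, MAX_OVERLAP))
        return np.asarray(self._b(o)), np.asarray(self._d(o))


@dataclass
class CohortDataset:
    """All synthetic trials, keyed by session, plus the ground truth."""

    trials: dict[str, TrialSet]
    truth: pd.DataFrame
    master_seed: int

    def all_trials(self) -> list[TrialRecord]:
        return [tr for ts in self.trials.values() for tr in ts.trials]

    @property
    def n_trials(self) -> int:
        return sum(len(ts) for ts in self.trials.values())


def _synth_trial(
    profile: GroupProfile,
    layout: TargetLayout,
    via_map: ViaPointMap,
    subject_id: str,
    session: str,
    block: int,
    trial: int,
    o_true: float,
    dur_true: float,
    rng: np.random.Generator,
    dt: float = 1.0 / 160.0,
    pad_pre_s: float = 0.2,
    pad_post_s: float = 0.5,
) -> tuple[TrialRecord, dict]:
    """One physical trial: superpose, dwell-pad, miss-warp, add noise."""
    t_sub = dur_true / (4.0 - 2.0 * o_true)
    bp, dp = via_map(o_true)
    A, C = layout.center("A"), layout.center("C")
    w = np.stack([A, bp, C, dp, A])
    subs = chain_submovements(w, o_true, t_sub)
    traj = superpose(subs, dt)

    # target-miss injection: push the path radially off one target with a
    # smooth Gaussian displacement bump centred at the closest approach
    miss_target, miss_excess = "", 0.0
    if rng.random() < profile.miss_rate.get(session, 0.0):
        miss_target = rng.choice(["B", "C", "D"])
        centre = layout.center(miss_target)
        d = np.hypot(*(traj.xy - centre).T)
        i_star = int(np.argmin(d))
        # push perpendicular to the local path direction (the clean path
        # runs through the target, so a tangential shift would not miss);
        # near the reversal at C the local speed vanishes, so fall back
        # to the incoming stroke direction
        vdir = traj.vxy[i_star]
        if np.hypot(*vdir) < 1.0:
            j = max(i_star - 8, 0)
            vdir = traj.vxy[j]
        if np.hypot(*vdir) < 1e-9:
            vdir = np.array([1.0, 0.0])
        direction = np.array([-vdir[1], vdir[0]]) / np.hypot(*vdir)
        outward = centre - layout.centers.mean(axis=0)
        if float(direction @ outward) < 0:
            direction = -direction
        miss_excess = float(rng.exponential(profile.miss_excess_mm.get(session, 0.5)))
        wanted_cm = (layout.diameter_mm / 2.0 + miss_excess) / 10.0
        sigma = 0.12  # wide relative to the spline cutoff, so smoothing keeps it
        shape = np.exp(-0.5 * ((traj.t - traj.t[i_star]) / sigma) ** 2)
        # the push leaves the legs of the corner closer to the target than
        # the apex (geometric factor sin of the half-apex angle), so the
        # amplitude is calibrated against the achieved closest approach
        amp_cm = wanted_cm - d[i_star]
        xy = traj.xy
        for _ in range(4):
            xy = traj.xy + (amp_cm * shape)[:, None] * direction
            achieved = float(np.min(np.hypot(*(xy - centre).T)))
            if achieved >= 0.97 * wanted_cm or amp_cm > 6.0 * wanted_cm:
                break
            amp_cm *= wanted_cm / max(achieved, 0.2 * wanted_cm)
    else:
        xy = traj.xy

    n_pre = int(round(pad_pre_s / dt))
    n_post = int(round(pad_post_s / dt))
    xy_full = np.vstack(
        [np.tile(xy[0], (n_pre, 1)), xy, np.tile(xy[-1], (n_post, 1))]
    )
    t_full = np.arange(len(xy_full)) * dt
    xy_full = xy_full + rng.normal(0.0, profile.noise_sd_cm, xy_full.shape)

    gap = False
    if rng.random() < profile.gap_rate:
        # excise ~200 ms mid-movement so the continuity filter trips
        i0 = n_pre + len(xy) // 3
        keep = np.ones(len(t_full), bool)
        keep[i0 : i0 + int(0.2 / dt)] = False
        t_full, xy_full, gap = t_full[keep], xy_full[keep], True

    rec = TrialRecord(
        subject_id=subject_id,
        group=profile.group,
        session=session,
        block=block,
        trial=trial,
        t=t_full,
        x=xy_full[:, 0],
        y=xy_full[:, 1],
        sample_rate_hz=1.0 / dt,
    )
    truth = {
        "subject_id": subject_id,
        "group": profile.group,
        "session": session,
        "block": block,
        "trial": trial,
        "true_overlap": o_true,
        "true_duration_s": dur_true,
        "miss_target": miss_target,
        "miss_excess_mm": miss_excess,
        "gap_injected": gap,
    }
    return rec, truth


def generate_subject(
    profile: GroupProfile,
    layouts: dict[str, TargetLayout],
    via_maps: dict[str, ViaPointMap],
    subject_id: str,
    seed,
) -> tuple[dict[str, list[TrialRecord]], list[dict]]:
    """All physical trials of one subject, plus their ground-truth rows.

    The subject draws a multiplicative duration trait and an additive
    overlap trait once; every trial then jitters the scheduled values.
    """
    rng = np.random.default_rng(seed)
    dur_factor = rng.normal(1.0, profile.dur_subject_sd)
    dur_factor = float(np.clip(dur_factor, 0.6, 1.4))
    o_offset = float(rng.normal(0.0, profile.o_subject_sd))

    by_session: dict[str, list[TrialRecord]] = {}
    truth_rows: list[dict] = []
    for session, block, n_trials in profile.session_plan():
        layout = layouts[session]
        via_map = via_maps[session]
        for trial in range(1, n_trials + 1):
            o_mean = profile.mean_overlap(session, block, trial)
            # the overlap trait only matters once overlap is in play
            o_true = o_mean + (o_offset if o_mean > 0.05 else 0.0)
            o_true += rng.normal(0.0, profile.o_trial_sd)
            o_true = float(np.clip(o_true, 0.0, MAX_OVERLAP))
            dur = profile.mean_duration(session, block, trial) * dur_factor
            dur *= float(np.exp(rng.normal(0.0, profile.dur_trial_sd)))
            dur = float(np.clip(dur, 0.5, 4.0))
            rec, truth = _synth_trial(
                profile, layout, via_map, subject_id, session, block, trial,
                o_true, dur, rng,
            )
            by_session.setdefault(session, []).append(rec)
            truth_rows.append(truth)
    return by_session, truth_rows


def generate_cohort(
    n_per_group: int = 15,
    master_seed: int = 17,
    layout: TargetLayout | None = None,
    profiles: dict[str, GroupProfile] | None = None,
    scale_factor: float = 0.7,
) -> CohortDataset:
    """The full 4-group experiment on the two-day protocol.

    Day-2 transfer sessions use the mirrored and 30%-down-scaled
    layouts.  Per-subject seeds are spawned deterministically from the
    master seed, so regeneration is bit-identical.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    layout = layout or default_layout()
    profiles = profiles or default_profiles()

    layouts = {s: layout for s in ("pre", "train", "post", "day2")}
    layouts["mirror"] = mirror_layout(layout)
    layouts["scaled"] = scale_layout(layout, scale_factor)
    unique_layouts = {
        "trained": layouts["pre"],
        "mirror": layouts["mirror"],
        "scaled": layouts["scaled"],
    }
    maps = {name: ViaPointMap(lay) for name, lay in unique_layouts.items()}
    via_maps = {s: maps["trained"] for s in ("pre", "train", "post", "day2")}
    via_maps["mirror"] = maps["mirror"]
    via_maps["scaled"] = maps["scaled"]

    ss = np.random.SeedSequence(master_seed)
    subject_seeds = ss.spawn(len(profiles) * n_per_group)

    by_session: dict[str, list[TrialRecord]] = {s: [] for s in SESSION_ORDER}
    truth_rows: list[dict] = []
    k = 0
    for gname in GROUPS:
        profile = profiles[gname]
        for i in range(1, n_per_group + 1):
            sid = f"{gname}{i:02d}"
            trials, truths = generate_subject(
                profile, layouts, via_maps, sid, subject_seeds[k]
            )
            k += 1
            for session, recs in trials.items():
                by_session[session].extend(recs)
            truth_rows.extend(truths)

    trial_sets = {
        s: TrialSet(
            trials=by_session[s],
            layout=layouts[s],
            provenance=f"synthetic cohort, session={s}, master_seed={master_seed}",
        )
        for s in SESSION_ORDER
    }
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return CohortDataset(trials=trial_sets, truth=truth, master_seed=master_seed)


def analyze_cohort(ds: CohortDataset, config=None) -> pd.DataFrame:
    """Run the measure pipeline over every session of a cohort."""
    from .measures import analyze_trials

    parts = [analyze_trials(ts, config) for ts in ds.trials.values() if len(ts)]
    return pd.concat(parts, ignore_index=True)
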