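"""Raw samples -> smooth trajectory -> tangential velocity -> movement window.

The raw 160 Hz stylus samples are filtered with least-squares cubic
B-spline regression on a fixed knot grid (a knot every 6 samples), and
velocity is taken analytically from the fitted spline rather than by
finite differences.  Movement onset is the last time, before the first
tangential-velocity peak exceeding 35% of the peak tangential velocity,
at which the velocity is below 5% of the peak; movement end is the last
time it is above 5%.  Both thresholds are relative, so segmentation is
invariant to uniform speed rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline
from scipy.signal import find_peaks

from .errors import OnsetUndetectableError, PreprocessingError
from .trials import TrialRecord

__all__ = [
    "PreprocessConfig",
    "SmoothTrajectory",
    "VelocityProfile",
    "MovementWindow",
    "exclude_trial",
    "smooth_trajectory",
    "tangential_velocity",
    "detect_onset_offset",
    "movement_duration",
    "time_normalize",
    "qualifying_peaks",
]


@dataclass
class PreprocessConfig:
    """Tunables of the preprocessing stage.

    knot_every_samples: spacing of the regression-spline knot grid.
    onset_frac: relative velocity threshold for onset/offset (5% of peak).
    peak_frac: a velocity peak "qualifies" for the onset rule if it
        exceeds this fraction of the peak velocity (35%).
    prominence_frac: minimum peak prominence, as a fraction of the peak
        velocity, for a local maximum to count as a peak at all.  This
        keeps residual noise ripples from being treated as submovements.
    max_gap_samples: a trial whose largest inter-sample gap exceeds this
        many nominal sample periods is excluded as discontinuous.
    """

    knot_every_samples: int = 6
    spline_order: int = 3
    onset_frac: float = 0.05
    peak_frac: float = 0.35
    prominence_frac: float = 0.05
    max_gap_samples: float = 3.0


@dataclass
class SmoothTrajectory:
    """Spline-filtered planar path of one trial.

    ``x_spline``/``y_spline`` are cubic B-splines defined on the full
    recorded interval; derivatives are available analytically.
    """

    t: np.ndarray
    x_spline: BSpline
    y_spline: BSpline
    residual_rms_cm: float

    def position(self, t=None) -> np.ndarray:
        t = self.t if t is None else np.asarray(t)
        return np.column_stack([self.x_spline(t), self.y_spline(t)])

    def velocity(self, t=None) -> np.ndarray:
        t = self.t if t is None else np.asarray(t)
        return np.column_stack(
            [self.x_spline.derivative()(t), self.y_spline.derivative()(t)]
        )

    def speed(self, t=None) -> np.ndarray:
        v = self.velocity(t)
        return np.hypot(v[:, 0], v[:, 1])


@dataclass
class VelocityProfile:
    """Tangential speed of one trial sampled on a time grid (cm/s)."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if len(self.t) != len(self.v):
            raise PreprocessingError("t and v must have equal length")

    @property
    def v_peak(self) -> float:
        return float(np.max(self.v))

    def clipped(self, window: "MovementWindow") -> "VelocityProfile":
        m = (self.t >= window.t_on) & (self.t <= window.t_off)
        return VelocityProfile(self.t[m], self.v[m])


@dataclass
class MovementWindow:
    """Movement onset/offset times in s; duration = t_off - t_on."""

    t_on: float
    t_off: float

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise PreprocessingError(
                f"degenerate movement window [{self.t_on}, {self.t_off}]"
            )

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


def exclude_trial(
    raw: TrialRecord, config: PreprocessConfig | None = None
) -> tuple[bool, str]:
    """Decide whether a trial must be dropped, with a reason.

    A trial is excluded when the stylus position was not recorded
    continuously: any inter-sample gap larger than
    ``max_gap_samples`` nominal sample periods flags it.
    """
    config = config or PreprocessConfig()
    gap_limit = config.max_gap_samples / raw.sample_rate_hz
    max_gap = float(np.max(np.diff(raw.t)))
    if max_gap > gap_limit:
        return True, (
            f"discontinuous recording (max gap {max_gap * 1e3:.0f} ms "
            f"> {gap_limit * 1e3:.0f} ms)"
        )
    return False, ""


def smooth_trajectory(
    raw: TrialRecord, config: PreprocessConfig | None = None
) -> SmoothTrajectory:
    """Least-squares cubic B-spline fit with a knot every 6 samples.

    The knot grid is fixed by sample index (not a tuned smoothing
    penalty); the residual RMS over both coordinates estimates the
    sensor noise level.
    """
    config = config or PreprocessConfig()
    k = config.spline_order
    step = config.knot_every_samples
    t = raw.t
    if raw.n_samples < 2 * step + 2:
        raise PreprocessingError(
            f"{raw.key()}: too few samples ({raw.n_samples}) for knots "
            f"every {step} samples"
        )
    # symmetric reflection padding: an unconstrained least-squares spline
    # lets its derivative blow up in the outermost knot intervals, which
    # corrupts the velocity right where the offset rule looks for the
    # terminal dwell.  Trials start and end at rest, so even reflection
    # is the physically consistent boundary treatment.
    npad = 2 * step
    npad = min(npad, raw.n_samples - 1)
    t_pre = t[0] - (t[1 : npad + 1] - t[0])[::-1]
    t_post = t[-1] + (t[-1] - t[-npad - 1 : -1])[::-1]
    te = np.r_[t_pre, t, t_post]

    def fit(y):
        ye = np.r_[y[1 : npad + 1][::-1], y, y[-npad - 1 : -1][::-1]]
        interior = te[step:-1:step]
        interior = interior[(interior > te[0]) & (interior < te[-1])]
        knots = np.r_[[te[0]] * (k + 1), interior, [te[-1]] * (k + 1)]
        return make_lsq_spline(te, ye, knots, k=k)

    sx, sy = fit(raw.x), fit(raw.y)
    resid = np.concatenate([raw.x - sx(t), raw.y - sy(t)])
    return SmoothTrajectory(
        t=t, x_spline=sx, y_spline=sy, residual_rms_cm=float(np.sqrt(np.mean(resid**2)))
    )


def tangential_velocity(st: SmoothTrajectory) -> VelocityProfile:
    """Tangential speed sqrt(x'^2 + y'^2) from the spline derivatives."""
    return VelocityProfile(t=st.t, v=st.speed())


def qualifying_peaks(vp: VelocityProfile, prominence_frac: float = 0.05) -> np.ndarray:
    """Indices of local speed maxima with prominence >= frac * v_peak."""
    if len(vp.v) < 3:
        return np.array([], dtype=int)
    idx, _ = find_peaks(vp.v, prominence=prominence_frac * vp.v_peak)
    return idx


def detect_onset_offset(
    vp: VelocityProfile, config: PreprocessConfig | None = None
) -> MovementWindow:
    """Apply the relative-threshold onset/offset rule to a speed profile.

    Onset: last sample strictly before the first peak exceeding
    ``peak_frac * v_peak`` whose speed is below ``onset_frac * v_peak``.
    Offset: last sample whose speed exceeds ``onset_frac * v_peak``.
    """
    config = config or PreprocessConfig()
    v, t = vp.v, vp.t
    v_peak = vp.v_peak
    if v_peak <= 0:
        raise OnsetUndetectableError("flat zero velocity profile")
    peaks = qualifying_peaks(vp, config.prominence_frac)
    big = peaks[v[peaks] > config.peak_frac * v_peak]
    if len(big) == 0:
        # the global maximum always exceeds the 35% rule; use it if it is
        # an interior sample (find_peaks ignores array endpoints)
        imax = int(np.argmax(v))
        if 0 < imax < len(v) - 1:
            big = np.array([imax])
        else:
            raise OnsetUndetectableError("no interior velocity peak above threshold")
    first_peak = int(big[0])
    thresh = config.onset_frac * v_peak
    below = np.nonzero(v[:first_peak] < thresh)[0]
    if len(below) == 0:
        raise OnsetUndetectableError(
            "velocity never drops below the onset threshold before the first peak"
        )
    t_on = float(t[below[-1]])
    above = np.nonzero(v > thresh)[0]
    t_off = float(t[above[-1]])
    if not t_on < t_off:
        raise OnsetUndetectableError("onset does not precede offset")
    return MovementWindow(t_on=t_on, t_off=t_off)


def movement_duration(win: MovementWindow) -> float:
    """Movement time in s: offset minus onset."""
    return win.duration


def time_normalize(vp: VelocityProfile, n_points: int) -> VelocityProfile:
    """Resample a profile at ``n_points`` equally spaced normalized times.

    The returned profile lives on [0, 1]; two profiles differing only by
    a uniform time dilation normalize identically.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    u = np.linspace(0.0, 1.0, n_points)
    t0, t1 = vp.t[0], vp.t[-1]
    if t1 <= t0:
        raise PreprocessingError("cannot normalize a zero-length profile")
    return VelocityProfile(t=u, v=np.interp(t0 + u * (t1 - t0), vp.t, vp.v))
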