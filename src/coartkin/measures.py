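"""Trial-level outcome measures for the four-target sequence task.

The central measure is the coarticulation score: 100 times the ratio of
the mean of the first and third tangential-velocity trough heights to
the mean of the peak heights.  A fully segmented movement (four
point-to-point strokes with complete stops at B and D) scores 0; a
fully blended movement approaches 100.  The second trough — at target
C, where the task forces a sharp direction change and hence near-zero
speed — is excluded from the numerator.  When blending removes a
peak/trough pair from the profile altogether, the inflection point of
the merged region supplies both missing heights, so the score keeps
rising smoothly past the merge instead of jumping.

Supporting measures: the number of velocity peaks, the path offset
(mean distance from the straight lines joining the targets, a curvature
proxy), and the spatial error (summed distance from each target's disc
edge to the trajectory's closest approach; zero for a target that is
entered).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoartkinError, MeasureUndefinedError
from .layout import TargetLayout
from .preprocess import (
    MovementWindow,
    PreprocessConfig,
    SmoothTrajectory,
    VelocityProfile,
    detect_onset_offset,
    exclude_trial,
    qualifying_peaks,
    smooth_trajectory,
    tangential_velocity,
)
from .trials import TrialRecord, TrialSet

__all__ = [
    "PeakStructure",
    "find_peak_structure",
    "coarticulation_score",
    "count_velocity_peaks",
    "path_offset",
    "path_offset_xy",
    "spatial_error",
    "spatial_error_xy",
    "normalize_duration",
    "normalize_score",
    "boundary_times",
    "analyze_trial",
    "analyze_trials",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "block",
    "trial",
    "duration_s",
    "coart_score",
    "n_peaks",
    "path_offset_cm",
    "spatial_error_mm",
    "excluded",
    "exclude_reason",
]


@dataclass
class PeakStructure:
    """Ordinal peaks, troughs and inflection substitutions of a profile.

    ``peaks`` holds the up-to-4 largest qualifying local maxima in
    temporal order as (sample index, height).  ``troughs`` maps trough
    ordinal (1..3, one per intermediate target B, C, D) to the real
    (index, height) minimum between flanking peaks.  ``substitutions``
    maps the ordinals whose peak/trough pair fell below the peak
    qualification threshold to ``(index, trough_height, peak_height)``:
    while a residual sub-threshold dip still exists its real minimum
    and maximum are used, and once the region has truly merged the
    inflection point supplies both heights (trough == peak there), so
    the score varies continuously through the merge.  A substituted
    peak height enters the score's denominator alongside the real
    peaks.
    """

    peaks: list[tuple[int, float]]
    troughs: dict[int, tuple[int, float]]
    substitutions: dict[int, tuple[int, float, float]] = field(default_factory=dict)

    def trough_height(self, ordinal: int) -> float:
        if ordinal in self.troughs:
            return self.troughs[ordinal][1]
        if ordinal in self.substitutions:
            return self.substitutions[ordinal][1]
        raise MeasureUndefinedError(f"trough {ordinal} has no height")

    @property
    def effective_peak_heights(self) -> list[float]:
        return [h for _, h in self.peaks] + [
            pk for _, _, pk in self.substitutions.values()
        ]

    @property
    def n_real_peaks(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# peak/trough extraction


def _largest_four(idx: np.ndarray, v: np.ndarray) -> list[int]:
    """Keep the 4 largest peaks (ties to the earlier one), temporal order."""
    if len(idx) <= 4:
        return sorted(int(i) for i in idx)
    order = sorted(range(len(idx)), key=lambda k: (-v[idx[k]], idx[k]))
    kept = sorted(idx[k] for k in order[:4])
    return [int(i) for i in kept]


def _substitute_in(
    v: np.ndarray,
    t: np.ndarray,
    lo: int,
    hi: int,
    kept: list[int],
    v_peak: float,
    sub_prominence_frac: float = 1e-4,
) -> tuple[int, float, float]:
    """Heights standing in for a peak/trough pair lost to blending.

    Two regimes, continuous at the handover: while the blended region
    still contains a residual dip (a local maximum below the peak
    qualification threshold but above a small numeric floor), the real
    sub-peak height and the minimum between it and the neighbouring
    kept peak are used.  Once the region is truly merged the shoulder
    inflection point supplies both heights.
    """
    lo, hi = int(lo), int(hi)
    segment = v[lo : hi + 1]
    if len(segment) >= 3:
        from scipy.signal import find_peaks

        cand, props = find_peaks(segment, prominence=sub_prominence_frac * v_peak)
        cand = cand + lo
        far = [
            (c, p)
            for c, p in zip(cand, props["prominences"])
            if all(abs(c - k) > 2 for k in kept)
        ]
        if far:
            m = max(far, key=lambda cp: cp[1])[0]
            neighbours = [k for k in kept if k != m]
            if neighbours:
                pk = min(neighbours, key=lambda k: abs(k - m))
                a, b = sorted((m, pk))
                j = a + int(np.argmin(v[a : b + 1]))
                return int(j), float(v[j]), float(v[m])
    i, h = _inflection_in(v, t, lo, hi, exclude=kept)
    return i, h, h


def _inflection_in(
    v: np.ndarray, t: np.ndarray, lo: int, hi: int, exclude: list[int], margin: int = 3
) -> tuple[int, float]:
    """Locate the shoulder inflection of a merged peak within [lo, hi].

    A blended pair leaves a shoulder on the flank of the surviving peak:
    a local minimum of |dv/dt| away from the extrema.  If no interior
    |v'| minimum exists, fall back to the zero crossing of the second
    derivative nearest the region centre, then to the flattest point.
    """
    lo, hi = int(lo), int(hi)
    if hi - lo < 2 * margin + 3:
        margin = max(1, (hi - lo) // 4)
    dv = np.gradient(v, t)
    g = np.abs(dv)
    allowed = np.ones(len(v), bool)
    allowed[: lo + margin] = False
    allowed[hi - margin + 1 :] = False
    for e in exclude:
        allowed[max(0, e - margin) : e + margin + 1] = False
    cand = [
        i
        for i in range(lo + 1, hi)
        if allowed[i] and g[i] <= g[i - 1] and g[i] <= g[i + 1]
    ]
    if cand:
        i = min(cand, key=lambda i: g[i])
        return i, float(v[i])
    d2v = np.gradient(dv, t)
    sign_flips = [
        i for i in range(lo + 1, hi) if allowed[i] and d2v[i - 1] * d2v[i] < 0
    ]
    if sign_flips:
        centre = 0.5 * (lo + hi)
        i = min(sign_flips, key=lambda i: abs(i - centre))
        return i, float(v[i])
    interior = [i for i in range(lo + 1, hi) if allowed[i]]
    if not interior:
        interior = list(range(lo + 1, hi)) or [int((lo + hi) // 2)]
    i = min(interior, key=lambda i: g[i])
    return i, float(v[i])


def _assign_ordinals(
    trough_times: list[float], boundaries: np.ndarray
) -> dict[int, int]:
    """Best increasing matching of real troughs to target ordinals 1..3."""
    m = len(trough_times)
    best, best_cost = None, np.inf
    for combo in itertools.combinations(range(3), m):
        cost = sum(abs(trough_times[j] - boundaries[combo[j]]) for j in range(m))
        if cost < best_cost:
            best, best_cost = combo, cost
    return {best[j] + 1: j for j in range(m)}


def find_peak_structure(
    vp: VelocityProfile,
    boundary_times: np.ndarray | None = None,
    prominence_frac: float = 0.05,
) -> PeakStructure:
    """Extract the up-to-4 largest peaks, their troughs, and substitutions.

    ``vp`` must already be clipped to the movement window.
    ``boundary_times`` optionally gives the times of the trajectory's
    closest approach to targets B, C, D; they anchor trough ordinals
    when fewer than 4 peaks survive.  Without them, the deepest trough
    is taken as the one at C (ordinal 2, near zero because of the
    forced direction change) and the rest follow temporal order.
    """
    v, t = vp.v, vp.t
    idx = qualifying_peaks(vp, prominence_frac)
    if len(idx) == 0:
        raise MeasureUndefinedError("no qualifying velocity peaks in window")
    kept = _largest_four(idx, v)

    raw_troughs: list[tuple[int, float]] = []
    for a, b in zip(kept[:-1], kept[1:]):
        j = a + int(np.argmin(v[a : b + 1]))
        raw_troughs.append((j, float(v[j])))

    peaks = [(i, float(v[i])) for i in kept]
    troughs: dict[int, tuple[int, float]] = {}
    substitutions: dict[int, tuple[int, float]] = {}

    if len(kept) == 4:
        for ordinal, tr in enumerate(raw_troughs, start=1):
            troughs[ordinal] = tr
        return PeakStructure(peaks, troughs)

    # fewer than 4 peaks: some pair(s) merged
    if boundary_times is not None:
        mapping = _assign_ordinals([t[j] for j, _ in raw_troughs], np.asarray(boundary_times))
        for ordinal, j in mapping.items():
            troughs[ordinal] = raw_troughs[j]
    else:
        if len(raw_troughs) == 2:
            # deepest trough sits at the forced reversal (ordinal 2)
            deep = int(np.argmin([h for _, h in raw_troughs]))
            if deep == 0:
                troughs[2], troughs[3] = raw_troughs
            else:
                troughs[1], troughs[2] = raw_troughs
        elif len(raw_troughs) == 1:
            troughs[2] = raw_troughs[0]

    assigned = sorted(troughs)
    missing = [k for k in (1, 2, 3) if k not in troughs]
    peak_idx = [i for i, _ in peaks]
    for k in missing:
        # search region bounded by the neighbouring assigned troughs
        lows = [troughs[a][0] for a in assigned if a < k]
        highs = [troughs[a][0] for a in assigned if a > k]
        lo = max(lows) if lows else 0
        hi = min(highs) if highs else len(v) - 1
        if boundary_times is not None:
            # narrow around the expected boundary time
            tau = boundary_times[k - 1]
            half = max((t[hi] - t[lo]) / 2.0, 0.0)
            lo = int(np.searchsorted(t, max(t[lo], tau - half)))
            hi = int(np.searchsorted(t, min(t[hi], tau + half), side="right")) - 1
            lo, hi = max(lo, 0), min(hi, len(v) - 1)
            if hi - lo < 4:
                lo = max(0, lo - 4)
                hi = min(len(v) - 1, hi + 4)
        substitutions[k] = _substitute_in(
            v, t, lo, hi, kept=peak_idx, v_peak=float(np.max(v))
        )
    return PeakStructure(peaks, troughs, substitutions)


def coarticulation_score(ps: PeakStructure) -> float:
    """100 * mean(trough 1, trough 3) / mean(effective peak heights).

    Substituted inflection heights contribute to both numerator (as the
    missing trough) and denominator (as the missing peak).  Trough 2 is
    never included.  With non-negative heights the score lies in
    [0, 100] and is invariant to uniform velocity rescaling.
    """
    den_heights = ps.effective_peak_heights
    den = float(np.mean(den_heights)) if den_heights else 0.0
    if den == 0:
        raise MeasureUndefinedError("mean peak height is zero")
    num = 0.5 * (ps.trough_height(1) + ps.trough_height(3))
    return 100.0 * num / den


def count_velocity_peaks(
    vp: VelocityProfile, prominence_frac: float = 0.05
) -> int:
    """Number of qualifying local speed maxima in the windowed profile."""
    return int(len(qualifying_peaks(vp, prominence_frac)))


# ---------------------------------------------------------------------------
# spatial measures


def _dist_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances of points p (n,2) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.hypot(*(p - a).T)
    u = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + np.outer(u, ab)
    return np.hypot(*(p - proj).T)


def path_offset_xy(xy: np.ndarray, layout: TargetLayout) -> float:
    """Mean distance (cm) of path points to the nearest inter-target line."""
    d = np.min(
        np.stack([_dist_to_segment(xy, a, b) for a, b in layout.segments()]), axis=0
    )
    return float(np.mean(d))


def path_offset(
    st: SmoothTrajectory, layout: TargetLayout, window: MovementWindow | None = None
) -> float:
    """Curvature proxy: mean distance from the straight lines joining
    the targets, over the movement window."""
    t = st.t
    if window is not None:
        t = t[(t >= window.t_on) & (t <= window.t_off)]
    return path_offset_xy(st.position(t), layout)


def spatial_error_xy(xy: np.ndarray, layout: TargetLayout) -> float:
    """Summed miss distance (mm) from each target's edge; 0 if entered."""
    radius = layout.diameter_mm / 2.0
    total = 0.0
    for tgt in layout.targets:
        d_cm = float(np.min(np.hypot(*(xy - tgt.center).T)))
        total += max(0.0, d_cm * 10.0 - radius)
    return total


def spatial_error(
    st: SmoothTrajectory,
    layout: TargetLayout,
    window: MovementWindow | None = None,
    oversample: int = 4,
) -> float:
    """Spatial error of a smoothed trial, in mm.

    The spline is evaluated on an oversampled grid so the closest
    approach is not limited by the 160 Hz sampling.  Target A, the start
    and end point, is counted once like the other three targets.
    """
    t0, t1 = (st.t[0], st.t[-1]) if window is None else (window.t_on, window.t_off)
    n = max(int((t1 - t0) / (st.t[1] - st.t[0])) * oversample, 8)
    tt = np.linspace(t0, t1, n + 1)
    return spatial_error_xy(st.position(tt), layout)


# ---------------------------------------------------------------------------
# normalization conventions


def normalize_duration(value: float, baseline: float) -> float:
    """Percent improvement: 100 * (baseline - value) / baseline."""
    if baseline <= 0:
        raise ValueError(f"baseline duration must be positive, got {baseline}")
    return 100.0 * (baseline - value) / baseline


def normalize_score(value: float, baseline: float) -> float:
    """Score difference (no division — baselines are often near zero)."""
    return value - baseline


# ---------------------------------------------------------------------------
# per-trial pipeline


def boundary_times(
    st: SmoothTrajectory, layout: TargetLayout, window: MovementWindow
) -> np.ndarray:
    """Times of the path's closest approach to B, C, D within the window."""
    t = st.t[(st.t >= window.t_on) & (st.t <= window.t_off)]
    xy = st.position(t)
    out = []
    for lbl in ("B", "C", "D"):
        d = np.hypot(*(xy - layout.center(lbl)).T)
        out.append(t[int(np.argmin(d))])
    return np.array(out)


def analyze_trial(
    raw: TrialRecord,
    layout: TargetLayout,
    config: PreprocessConfig | None = None,
) -> dict:
    """Run the full measure pipeline on one trial; returns a MeasureRow dict.

    Excluded or unanalyzable trials yield a row with ``excluded=True``
    and NaN measures rather than raising.
    """
    config = config or PreprocessConfig()
    row = {
        "subject_id": raw.subject_id,
        "group": raw.group,
        "session": raw.session,
        "block": raw.block,
        "trial": raw.trial,
        "duration_s": np.nan,
        "coart_score": np.nan,
        "n_peaks": np.nan,
        "path_offset_cm": np.nan,
        "spatial_error_mm": np.nan,
        "excluded": False,
        "exclude_reason": "",
    }
    flagged, reason = exclude_trial(raw, config)
    if flagged:
        row["excluded"], row["exclude_reason"] = True, reason
        return row
    try:
        st = smooth_trajectory(raw, config)
        vp = tangential_velocity(st)
        win = detect_onset_offset(vp, config)
        clipped = vp.clipped(win)
        bt = boundary_times(st, layout, win)
        ps = find_peak_structure(clipped, boundary_times=bt, prominence_frac=config.prominence_frac)
        row["duration_s"] = win.duration
        row["coart_score"] = coarticulation_score(ps)
        row["n_peaks"] = count_velocity_peaks(clipped, config.prominence_frac)
        row["path_offset_cm"] = path_offset(st, layout, win)
        row["spatial_error_mm"] = spatial_error(st, layout, win)
    except CoartkinError as exc:
        row["excluded"], row["exclude_reason"] = True, str(exc)
    return row


def analyze_trials(
    tset: TrialSet, config: PreprocessConfig | None = None
) -> pd.DataFrame:
    """Analyze every trial of a TrialSet; one MeasureRow per trial."""
    rows = [analyze_trial(tr, tset.layout, config) for tr in tset.trials]
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
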