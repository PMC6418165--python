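"""Per-block summaries and the group-level statistical battery.

Aggregation follows the study conventions: per (subject, session,
block) the *median* of movement duration and spatial error (both
heavy-tailed) and the *mean* of coarticulation score, path offset and
peak count.  Normalized variants use each subject's own pre-test
baseline — percent improvement for duration and path offset, plain
difference for the coarticulation score (baselines sit near zero, so a
ratio would explode).

Tests: mixed-design ANOVA (between factor: group; within factor:
session or block; Greenhouse-Geisser correction when the within factor
has three or more levels), per-subject regression slopes over training
blocks followed by group-level t-tests, and a non-parametric battery
(Friedman / Wilcoxon / Kruskal-Wallis / Mann-Whitney) for the spatial
error, which is zero-inflated and far from normal.  Post-hoc pairwise
comparisons are Bonferroni-corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import DesignError

__all__ = [
    "StatResult",
    "summarize",
    "mixed_anova",
    "slope_analysis",
    "nonparametric_battery",
    "transfer_analysis",
    "effect_p",
    "pcol",
    "paired_session_tests",
    "posthoc",
    "bonferroni",
    "null_interaction_rate",
]

def pcol(table: pd.DataFrame) -> str:
    """Name of the uncorrected p-value column in a pingouin table."""
    for c in ("p_unc", "p-unc"):
        if c in table.columns:
            return c
    raise KeyError("no p-value column found")


def effect_p(st: "StatResult", source: str) -> float:
    """Uncorrected p-value of one ANOVA source (e.g. 'Interaction')."""
    tab = st.table
    return float(tab.loc[tab["Source"] == source, pcol(tab)].iloc[0])


#: central tendency per measure, following the figure captions
AGG = {
    "duration_s": "median",
    "spatial_error_mm": "median",
    "coart_score": "mean",
    "path_offset_cm": "mean",
    "n_peaks": "mean",
}


@dataclass
class StatResult:
    """One test: its table plus free-form extras (post-hocs, notes)."""

    name: str
    table: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __repr__(self) -> str:  # keep console output compact
        return f"<StatResult {self.name}: {len(self.table)} rows>"


# ---------------------------------------------------------------------------
# aggregation


def summarize(measures: pd.DataFrame, binning: str | None = None) -> pd.DataFrame:
    """Per-(subject, group, session, block [, bin]) summary table.

    ``binning='5trial'`` adds a 5-trial bin key (trials 1-5 -> bin 1,
    6-10 -> bin 2, ...).  Excluded trials are dropped before
    aggregation; a key whose trials were all excluded yields NaNs.
    Normalized columns (``norm_duration_pct``, ``norm_score``,
    ``norm_path_offset_pct``) are relative to the subject's own
    pre-test summary.
    """
    df = measures[~measures["excluded"].astype(bool)].copy()
    keys = ["subject_id", "group", "session", "block"]
    if binning == "5trial":
        df["bin"] = (df["trial"] - 1) // 5 + 1
        keys = keys + ["bin"]
    out = (
        df.groupby(keys, sort=False, observed=True)
        .agg({col: how for col, how in AGG.items() if col in df.columns})
        .reset_index()
    )

    pre = out[out["session"] == "pre"]
    base = pre.groupby("subject_id").agg(
        base_duration=("duration_s", "mean"),
        base_score=("coart_score", "mean"),
        base_offset=("path_offset_cm", "mean"),
    )
    out = out.merge(base, on="subject_id", how="left")
    out["norm_duration_pct"] = 100.0 * (out["base_duration"] - out["duration_s"]) / out[
        "base_duration"
    ]
    out["norm_score"] = out["coart_score"] - out["base_score"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["norm_path_offset_pct"] = (
            100.0 * (out["path_offset_cm"] - out["base_offset"]) / out["base_offset"]
        )
    return out.drop(columns=["base_duration", "base_score", "base_offset"])


def _session_means(tbl: pd.DataFrame, dv: str, sessions) -> pd.DataFrame:
    """One row per subject x session (averaging over blocks/bins)."""
    sub = tbl[tbl["session"].isin(sessions)]
    return (
        sub.groupby(["subject_id", "group", "session"], sort=False, observed=True)[dv]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# parametric battery


def mixed_anova(
    tbl: pd.DataFrame,
    dv: str,
    within: str = "session",
    between: str = "group",
    subject: str = "subject_id",
    correction: bool | str = "auto",
) -> StatResult:
    """Mixed-design ANOVA with group as the between-subjects factor.

    Subjects with a missing cell are dropped listwise.  With >= 3
    within levels the Greenhouse-Geisser corrected p-value is reported
    alongside the uncorrected one.
    """
    data = tbl[[subject, between, within, dv]].dropna()
    data = (
        data.groupby([subject, between, within], sort=False, observed=True)[dv]
        .mean()
        .reset_index()
    )
    n_levels = data[within].nunique()
    counts = data.groupby(subject, observed=True)[within].nunique()
    complete = counts[counts == n_levels].index
    data = data[data[subject].isin(complete)]
    cell_sizes = data.groupby([between, within], observed=True)[subject].nunique()
    if (cell_sizes < 2).any():
        raise DesignError("every group x level cell needs at least 2 subjects")
    if correction == "auto":
        # sphericity is only at stake with >= 3 within levels
        correction = bool(n_levels >= 3)
    if np.ptp(data[dv].to_numpy()) == 0:
        # a constant dv carries no effects; every F is 0/0
        table = pd.DataFrame(
            {
                "Source": [between, within, "Interaction"],
                "F": np.nan,
                "p_unc": 1.0,
            }
        )
    else:
        table = pg.mixed_anova(
            data=data, dv=dv, within=within, subject=subject, between=between,
            correction=correction,
        )
    return StatResult(
        name=f"mixed_anova({dv}: {between} x {within})",
        table=table,
        extras={"n_subjects": int(data[subject].nunique()), "data": data},
    )


def slope_analysis(
    tbl: pd.DataFrame,
    dv: str,
    over: str = "block",
    session: str = "train",
    one_tailed_positive: bool = False,
) -> StatResult:
    """Per-subject linear slope of ``dv`` over training blocks.

    Group level: one-sample t-test of the slopes against zero,
    one-tailed (slope > 0) for the coarticulation measures, two-tailed
    otherwise.
    """
    sub = tbl[tbl["session"] == session].dropna(subset=[dv])
    rows = []
    for (sid, grp), g in sub.groupby(["subject_id", "group"], sort=False, observed=True):
        g = g.groupby(over, observed=True)[dv].mean()
        if len(g) < 3:
            raise DesignError(f"subject {sid}: needs >= 3 blocks for a slope")
        slope = float(np.polyfit(g.index.to_numpy(float), g.to_numpy(float), 1)[0])
        rows.append({"subject_id": sid, "group": grp, "slope": slope})
    slopes = pd.DataFrame(rows)
    out = []
    for grp, g in slopes.groupby("group", sort=False, observed=True):
        alternative = "greater" if one_tailed_positive else "two-sided"
        if np.ptp(g["slope"].to_numpy()) == 0 and g["slope"].iloc[0] == 0:
            t, p = 0.0, 1.0  # exactly flat series: no evidence either way
        else:
            t, p = sps.ttest_1samp(g["slope"], 0.0, alternative=alternative)
        out.append(
            {
                "group": grp,
                "mean_slope": g["slope"].mean(),
                "se_slope": g["slope"].sem(),
                "t": float(t),
                "df": len(g) - 1,
                "p": float(p),
                "alternative": alternative,
            }
        )
    return StatResult(
        name=f"slope({dv} over {over})",
        table=pd.DataFrame(out),
        extras={"subject_slopes": slopes},
    )


def paired_session_tests(
    tbl: pd.DataFrame,
    dv: str,
    a: str = "pre",
    b: str = "post",
    correct_across_groups: bool = True,
) -> pd.DataFrame:
    """Per-group paired t-tests of session ``b`` against session ``a``.

    The classic interaction follow-up: which groups actually changed?
    Returns mean gain (b - a), t, df, raw and Bonferroni-corrected p
    (family = the four groups).
    """
    data = _session_means(tbl, dv, (a, b))
    wide = data.pivot_table(
        index=["subject_id", "group"], columns="session", values=dv, observed=True
    ).dropna()
    rows = []
    groups = list(wide.index.get_level_values("group").unique())
    for grp in groups:
        w = wide.xs(grp, level="group")
        gain = w[b] - w[a]
        t, p = sps.ttest_rel(w[b], w[a])
        rows.append(
            {
                "group": grp,
                "mean_gain": float(gain.mean()),
                "se_gain": float(gain.sem()),
                "t": float(t),
                "df": len(w) - 1,
                "p_raw": float(p),
                "p_bonf": bonferroni(p, len(groups)) if correct_across_groups else p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# non-parametric battery (spatial error)


def nonparametric_battery(
    tbl: pd.DataFrame,
    dv: str = "spatial_error_mm",
    sessions: tuple[str, ...] = ("pre", "post", "day2"),
) -> StatResult:
    """Friedman per group over sessions + between-group Kruskal-Wallis.

    Post-hoc Wilcoxon signed-rank tests between session pairs (within
    each group with a significant Friedman test) and Mann-Whitney U
    between groups per session, Bonferroni corrected.
    """
    data = _session_means(tbl, dv, sessions)
    wide_all = data.pivot_table(
        index=["subject_id", "group"], columns="session", values=dv, observed=True
    ).dropna()
    if wide_all.empty:
        raise DesignError("no complete subjects for the non-parametric battery")

    fried_rows = []
    wilcoxon_rows = []
    for grp, w in wide_all.groupby(level="group", sort=False, observed=True):
        cols = [w[s].to_numpy() for s in sessions]
        stacked = np.column_stack(cols)
        if np.all(np.ptp(stacked, axis=1) == 0):
            chi2, p = 0.0, 1.0  # every subject constant across sessions
        else:
            chi2, p = sps.friedmanchisquare(*cols)
        fried_rows.append(
            {"group": grp, "chi2": float(chi2), "df": len(sessions) - 1, "p": float(p)}
        )
        pairs = list(itertools.combinations(sessions, 2))
        for a, b in pairs:
            da, db = w[a].to_numpy(), w[b].to_numpy()
            if np.all(da == db):
                stat, pw = 0.0, 1.0
            else:
                stat, pw = sps.wilcoxon(da, db, zero_method="wilcox")
            wilcoxon_rows.append(
                {
                    "group": grp,
                    "pair": f"{a} vs {b}",
                    "W": float(stat),
                    "p_raw": float(pw),
                    "p_bonf": bonferroni(pw, len(pairs)),
                }
            )

    kw_rows = []
    mw_rows = []
    groups = list(wide_all.index.get_level_values("group").unique())
    for s in sessions if len(groups) >= 2 else ():
        samples = [wide_all.xs(g, level="group")[s].to_numpy() for g in groups]
        if np.ptp(np.concatenate(samples)) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
        kw_rows.append({"session": s, "H": float(h), "df": len(groups) - 1, "p": float(p)})
        pairs = list(itertools.combinations(range(len(groups)), 2))
        for i, j in pairs:
            if np.ptp(np.concatenate([samples[i], samples[j]])) == 0:
                u, pu = 0.5 * len(samples[i]) * len(samples[j]), 1.0
            else:
                u, pu = sps.mannwhitneyu(samples[i], samples[j])
            mw_rows.append(
                {
                    "session": s,
                    "pair": f"{groups[i]} vs {groups[j]}",
                    "U": float(u),
                    "p_raw": float(pu),
                    "p_bonf": bonferroni(pu, len(pairs)),
                }
            )
    return StatResult(
        name=f"nonparametric({dv})",
        table=pd.DataFrame(fried_rows),
        extras={
            "wilcoxon": pd.DataFrame(wilcoxon_rows),
            "kruskal": pd.DataFrame(kw_rows),
            "mannwhitney": pd.DataFrame(mw_rows),
        },
    )


# ---------------------------------------------------------------------------
# transfers & post-hocs


def transfer_analysis(tbl: pd.DataFrame) -> dict[str, StatResult]:
    """Day-2 battery over (trained re-test, mirror, scaled).

    Mixed ANOVAs on normalized duration, score difference, normalized
    path offset and peak count, plus the spatial-error non-parametrics.
    """
    sessions = ("day2", "mirror", "scaled")
    present = set(tbl["session"].unique())
    missing = [s for s in sessions if s not in present]
    if missing:
        raise DesignError(f"transfer sessions missing from the table: {missing}")
    out: dict[str, StatResult] = {}
    for dv in ("norm_duration_pct", "norm_score", "norm_path_offset_pct", "n_peaks"):
        sub = _session_means(tbl, dv, sessions).rename(columns={dv: "value"})
        sub["session"] = pd.Categorical(sub["session"], categories=sessions)
        out[dv] = mixed_anova(sub, "value", within="session")
        out[dv].name = f"transfer mixed_anova({dv})"
    out["spatial_error_mm"] = nonparametric_battery(
        tbl, "spatial_error_mm", sessions=sessions
    )
    return out


def bonferroni(p: float, n_comparisons: int) -> float:
    """Family-wise corrected p: multiply by the comparison count, cap at 1."""
    return float(min(1.0, p * n_comparisons))


def posthoc(
    st: StatResult,
    dv: str | None = None,
    within: str = "session",
    between: str = "group",
    parametric: bool = True,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise follow-ups of a mixed ANOVA.

    Uses the subject-level data cached on the StatResult; returns the
    pingouin pairwise table with corrected p-values.
    """
    data = st.extras.get("data")
    if data is None:
        raise DesignError("posthoc needs a StatResult produced by mixed_anova")
    dv = dv or data.columns[-1]
    return pg.pairwise_tests(
        data=data,
        dv=dv,
        within=within,
        between=between,
        subject="subject_id",
        padjust="bonf",
        parametric=parametric,
        interaction=True,
    )


# ---------------------------------------------------------------------------
# calibration of the interaction test


def null_interaction_rate(
    n_datasets: int = 500,
    n_per_group: int = 15,
    n_groups: int = 4,
    n_sessions: int = 2,
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the session x group interaction on null data.

    Simulates summary tables with a random subject intercept but no
    group, session or interaction effect, and returns the fraction of
    datasets whose interaction p-value falls below ``alpha``.  Should
    sit near ``alpha`` if the test is calibrated.
    """
    rng = np.random.default_rng(seed)
    n_sub = n_groups * n_per_group
    groups = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    sessions = [f"s{j}" for j in range(n_sessions)]
    rejections = 0
    for _ in range(n_datasets):
        intercepts = rng.normal(0.0, subject_sd, n_sub)
        rows = []
        for i in range(n_sub):
            for s in sessions:
                rows.append(
                    {
                        "subject_id": f"sub{i}",
                        "group": groups[i],
                        "session": s,
                        "value": intercepts[i] + rng.normal(0.0, noise_sd),
                    }
                )
        df = pd.DataFrame(rows)
        table = pg.mixed_anova(
            data=df, dv="value", within="session", subject="subject_id",
            between="group",
        )
        p = float(table.loc[table["Source"] == "Interaction", pcol(table)].iloc[0])
        rejections += p < alpha
    return rejections / n_datasets
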