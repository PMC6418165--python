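"""Summaries and the statistical battery, against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coartkin.errors import DesignError
from coartkin.stats import (
    StatResult,
    bonferroni,
    effect_p,
    mixed_anova,
    nonparametric_battery,
    paired_session_tests,
    posthoc,
    slope_analysis,
    summarize,
    transfer_analysis,
)


def measures_frame(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("duration_s", 1.0),
        ("coart_score", 0.0),
        ("n_peaks", 4),
        ("path_offset_cm", 0.0),
        ("spatial_error_mm", 0.0),
        ("excluded", False),
    ):
        if col not in df.columns:
            df[col] = default
    return df


def trial_rows(subject, group, session, values, block=1, **extra):
    return [
        dict(
            subject_id=subject, group=group, session=session, block=block,
            trial=i + 1, **{k: v for k, v in extra.items()}, **val,
        )
        for i, val in enumerate(values)
    ]


# ---------------------------------------------------------------------------


class TestSummarize:
    def test_identical_trials_pass_through(self):
        rows = trial_rows(
            "S1", "OG", "pre", [dict(duration_s=2.0, coart_score=5.0)] * 10
        )
        tbl = summarize(measures_frame(rows))
        assert len(tbl) == 1
        assert tbl.duration_s.iloc[0] == 2.0
        assert tbl.coart_score.iloc[0] == 5.0
        assert tbl.norm_duration_pct.iloc[0] == 0.0
        assert tbl.norm_score.iloc[0] == 0.0

    def test_median_robust_to_outlier(self):
        vals = [dict(duration_s=2.0)] * 9 + [dict(duration_s=50.0)]
        tbl = summarize(measures_frame(trial_rows("S1", "OG", "pre", vals)))
        assert tbl.duration_s.iloc[0] == 2.0

    def test_trial_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = [dict(duration_s=d, coart_score=s) for d, s in rng.normal(5, 1, (20, 2))]
        a = summarize(measures_frame(trial_rows("S1", "OG", "pre", vals)))
        b = summarize(measures_frame(trial_rows("S1", "OG", "pre", vals[::-1])))
        pd.testing.assert_frame_equal(a, b)

    def test_excluded_trials_dropped(self):
        vals = [dict(duration_s=2.0, excluded=False)] * 5 + [
            dict(duration_s=99.0, excluded=True)
        ]
        tbl = summarize(measures_frame(trial_rows("S1", "OG", "pre", vals)))
        assert tbl.duration_s.iloc[0] == 2.0

    def test_five_trial_bins(self):
        vals = [dict(duration_s=float(i >= 5))
                for i in range(10)]  # 0 for trials 1-5, 1 for 6-10
        tbl = summarize(
            measures_frame(trial_rows("S1", "OG", "train", vals)), binning="5trial"
        )
        assert list(tbl["bin"]) == [1, 2]
        assert list(tbl.duration_s) == [0.0, 1.0]


# ---------------------------------------------------------------------------


def closed_form_mixed_anova(data):
    """Textbook sums-of-squares for a balanced 2-factor mixed design."""
    groups = sorted(data.group.unique())
    sessions = sorted(data.session.unique())
    a, k = len(groups), len(sessions)
    n = data.subject_id.nunique() // a
    grand = data.value.mean()
    m_g = data.groupby("group").value.mean()
    m_s = data.groupby("session").value.mean()
    m_gs = data.groupby(["group", "session"]).value.mean()
    m_subj = data.groupby("subject_id").value.mean()
    subj_group = data.groupby("subject_id").group.first()

    ss_group = n * k * sum((m_g[g] - grand) ** 2 for g in groups)
    ss_subj = k * sum((m_subj[s] - m_g[subj_group[s]]) ** 2 for s in m_subj.index)
    ss_session = a * n * sum((m_s[s] - grand) ** 2 for s in sessions)
    ss_inter = n * sum(
        (m_gs[(g, s)] - m_g[g] - m_s[s] + grand) ** 2 for g in groups for s in sessions
    )
    ss_err = sum(
        (row.value - m_gs[(row.group, row.session)]
         - m_subj[row.subject_id] + m_g[row.group]) ** 2
        for row in data.itertuples()
    )
    ms = {
        "group": ss_group / (a - 1),
        "subj": ss_subj / (a * (n - 1)),
        "session": ss_session / (k - 1),
        "inter": ss_inter / ((a - 1) * (k - 1)),
        "err": ss_err / (a * (n - 1) * (k - 1)),
    }
    return {
        "F_group": ms["group"] / ms["subj"],
        "F_session": ms["session"] / ms["err"],
        "F_inter": ms["inter"] / ms["err"],
    }


class TestMixedAnova:
    def build(self, effect=0.0, seed=0, n=6):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("OG", "RMCG"):
            for i in range(n):
                sid = f"{g}{i}"
                intercept = rng.normal(0, 1)
                for s in ("pre", "post"):
                    bump = effect if (g == "OG" and s == "post") else 0.0
                    rows.append(
                        dict(subject_id=sid, group=g, session=s,
                             value=intercept + bump + rng.normal(0, 0.5))
                    )
        return pd.DataFrame(rows)

    def test_matches_closed_form_oracle(self):
        data = self.build(effect=1.0, seed=3)
        st = mixed_anova(data, "value")
        oracle = closed_form_mixed_anova(data)
        tab = st.table.set_index("Source")
        assert tab.loc["group", "F"] == pytest.approx(oracle["F_group"], rel=1e-6)
        assert tab.loc["session", "F"] == pytest.approx(oracle["F_session"], rel=1e-6)
        assert tab.loc["Interaction", "F"] == pytest.approx(oracle["F_inter"], rel=1e-6)

    def test_identical_groups_zero_interaction(self):
        data = self.build(effect=0.0, seed=1)
        # make the two groups literally identical subject-by-subject
        og = data[data.group == "OG"].copy()
        rm = og.copy()
        rm["group"] = "RMCG"
        rm["subject_id"] = rm["subject_id"].str.replace("OG", "RMCG")
        st = mixed_anova(pd.concat([og, rm]), "value")
        tab = st.table.set_index("Source")
        assert tab.loc["Interaction", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_programmed_interaction_detected(self):
        st = mixed_anova(self.build(effect=2.0, seed=2), "value")
        assert effect_p(st, "Interaction") < 0.001

    def test_tiny_cell_rejected(self):
        data = self.build(n=2)
        data = data[~((data.group == "RMCG") & (data.subject_id == "RMCG1"))]
        with pytest.raises(DesignError):
            mixed_anova(data, "value")


class TestSlopes:
    def make_tbl(self, slopes_by_group, noise=0.0, seed=0, n=5):
        rng = np.random.default_rng(seed)
        rows = []
        for g, slope in slopes_by_group.items():
            for i in range(n):
                for b in range(1, 7):
                    rows.append(
                        dict(subject_id=f"{g}{i}", group=g, session="train",
                             block=b, coart_score=slope * b + rng.normal(0, noise))
                    )
        return pd.DataFrame(rows)

    def test_exact_linear_series(self):
        tbl = self.make_tbl({"OG": 0.73})
        st = slope_analysis(tbl, "coart_score", one_tailed_positive=True)
        assert st.table.mean_slope.iloc[0] == pytest.approx(0.73, abs=1e-12)

    def test_flat_series_is_null(self):
        tbl = self.make_tbl({"RMCG": 0.0})
        st = slope_analysis(tbl, "coart_score", one_tailed_positive=True)
        assert st.table.t.iloc[0] == 0.0
        assert st.table.p.iloc[0] == 1.0

    def test_needs_three_blocks(self):
        tbl = self.make_tbl({"OG": 1.0})
        with pytest.raises(DesignError):
            slope_analysis(tbl[tbl.block <= 2], "coart_score")


class TestNonparametrics:
    def test_identical_columns_chi2_zero(self):
        rows = []
        for i in range(6):
            for s in ("pre", "post", "day2"):
                rows.append(dict(subject_id=f"S{i}", group="OG", session=s,
                                 block=1, spatial_error_mm=float(i)))
        tbl = pd.DataFrame(rows)
        res = nonparametric_battery(tbl)
        assert res.table.chi2.iloc[0] == 0.0
        assert res.table.p.iloc[0] == 1.0

    def test_friedman_hand_ranks(self):
        """3 subjects x 3 conditions, every subject ranks them 1<2<3:
        chi2 = 12/(3*3*4) * (3^2+6^2+9^2) - 3*3*4 = 6."""
        rows = []
        for i, base in enumerate((0.0, 5.0, 10.0)):
            for j, s in enumerate(("pre", "post", "day2")):
                rows.append(dict(subject_id=f"S{i}", group="OG", session=s,
                                 block=1, spatial_error_mm=base + j))
        res = nonparametric_battery(pd.DataFrame(rows))
        assert res.table.chi2.iloc[0] == pytest.approx(6.0)

    def test_identical_groups_no_difference(self):
        rows = []
        for g in ("RMCG", "DPTCG"):
            for i in range(8):
                for s in ("pre", "post", "day2"):
                    rows.append(dict(subject_id=f"{g}{i}", group=g, session=s,
                                     block=1, spatial_error_mm=0.0))
        res = nonparametric_battery(pd.DataFrame(rows))
        assert (res.extras["mannwhitney"].p_raw == 1.0).all()


class TestPosthocCorrection:
    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.01, 1) == 0.01
        assert bonferroni(0.01, 4) == pytest.approx(0.04)
        assert bonferroni(0.4, 6) == 1.0  # capped

    def test_paired_session_tests_direction(self):
        rows = []
        rng = np.random.default_rng(4)
        for g, gain in (("OG", 20.0), ("RMCG", 0.0)):
            for i in range(8):
                base = rng.normal(2, 0.5)
                for s, v in (("pre", base), ("post", base + gain + rng.normal(0, 1))):
                    rows.append(dict(subject_id=f"{g}{i}", group=g, session=s,
                                     block=1, coart_score=v))
        out = paired_session_tests(pd.DataFrame(rows), "coart_score")
        out = out.set_index("group")
        assert out.loc["OG", "p_bonf"] < 0.01
        assert out.loc["RMCG", "p_bonf"] > 0.1
        assert out.loc["OG", "mean_gain"] == pytest.approx(20.0, abs=1.5)


class TestTransfers:
    def test_no_programmed_transfer_effect(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in ("OG", "RMCG"):
            for i in range(8):
                base = rng.normal(10, 2)
                for s in ("pre", "day2", "mirror", "scaled"):
                    rows.append(dict(
                        subject_id=f"{g}{i}", group=g, session=s, block=1,
                        duration_s=2.0, coart_score=base + rng.normal(0, 0.5),
                        n_peaks=4.0, path_offset_cm=0.5, spatial_error_mm=0.0,
                    ))
        tbl = summarize(measures_frame(rows).assign(trial=1, excluded=False))
        out = transfer_analysis(tbl)
        assert effect_p(out["norm_score"], "session") > 0.05

    def test_missing_session_rejected(self):
        rows = trial_rows("S1", "OG", "day2", [dict(duration_s=1.0)])
        with pytest.raises(DesignError):
            transfer_analysis(summarize(measures_frame(rows)))
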