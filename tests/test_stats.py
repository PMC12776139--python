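"""Welch t, Pearson, Sidak, and the mixed factorial ANOVA partitioning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sertflow.stats import mixed_anova, pearson, sidak, welch_t
from sertflow.types import ValidationError


class TestWelch:
    def test_equal_n_equal_variance_matches_student(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 1, 12)
        ours = welch_t(x, y)
        t_student, p_student = sps.ttest_ind(x, y, equal_var=True)
        # with equal n the Welch statistic equals the pooled Student statistic
        assert ours.statistic == pytest.approx(float(t_student), abs=1e-12)

    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        res = welch_t(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_three_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 9.0])
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 3 + vy / 3
        t_expected = (x.mean() - y.mean()) / np.sqrt(se2)
        df_expected = se2**2 / ((vx / 3) ** 2 / 2 + (vy / 3) ** 2 / 2)
        res = welch_t(x, y)
        assert res.statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.df == pytest.approx(df_expected, abs=1e-12)
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_expected), df_expected), abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(1)
        n_reps = 2000
        rejections = 0
        for _ in range(n_reps):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            rejections += welch_t(x, y).p < 0.05
        assert abs(rejections / n_reps - 0.05) <= 0.02


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 5.0, 2.0])
        r_expected = np.corrcoef(x, y)[0, 1]
        res = pearson(x, y)
        assert res.statistic == pytest.approx(r_expected, abs=1e-12)
        t = r_expected * np.sqrt(1 / (1 - r_expected**2))  # df = n - 2 = 1
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 1), abs=1e-12)

    def test_zero_variance_flagged(self):
        res = pearson(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))
        assert np.isnan(res.statistic) and "zero_variance" in res.flags

    def test_null_independent_pairs(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            if abs(pearson(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)).statistic) < 0.08:
                hits += 1
        assert hits >= 38


class TestSidak:
    def test_identity_at_m1(self):
        assert sidak(alpha=0.05, m=1) == pytest.approx(0.05)
        assert sidak(p=0.2, m=1) == pytest.approx(0.2)

    def test_alpha_closed_form(self):
        assert sidak(alpha=0.05, m=5) == pytest.approx(0.010206, abs=1e-6)

    def test_adjusted_p_monotone_in_raw_p(self):
        ps = np.linspace(0.0, 1.0, 101)
        adj = sidak(p=ps, m=7)
        assert (np.diff(adj) >= 0).all()
        assert adj.max() <= 1.0

    def test_alpha_antitone_in_m(self):
        levels = [sidak(alpha=0.05, m=m) for m in range(1, 10)]
        assert (np.diff(levels) < 0).all()

    def test_invalid_m_rejected(self):
        with pytest.raises(ValidationError):
            sidak(alpha=0.05, m=0)


def balanced_mixed_table(rng, n_per_group=8, weeks=(0, 1, 4), effect=0.0, subject_sd=0.5):
    rows = []
    for g, group in enumerate(["water", "DID"]):
        for s in range(n_per_group):
            sid = f"{group}{s}"
            u = rng.normal(0, subject_sd)
            for w in weeks:
                rows.append({"subject": sid, "group": group, "week": w,
                             "y": u + effect * g + rng.normal(0, 1)})
    return pd.DataFrame(rows)


def brute_force_split_plot(df):
    """Classical balanced split-plot sums of squares, computed from cell means."""
    M = df["y"].mean()
    Mg = df.groupby("group")["y"].mean()
    Mw = df.groupby("week")["y"].mean()
    Mgw = df.groupby(["group", "week"])["y"].mean()
    Ms = df.groupby("subject")["y"].mean()
    subj_group = df.groupby("subject")["group"].first()
    n_w = df["week"].nunique()
    n_g = df["group"].nunique()
    n_subj = df["subject"].nunique()
    n_per = n_subj // n_g
    SS_group = n_per * n_w * ((Mg - M) ** 2).sum()
    SS_subj = n_w * sum((Ms[s] - Mg[subj_group[s]]) ** 2 for s in Ms.index)
    SS_week = n_per * n_g * ((Mw - M) ** 2).sum()
    SS_int = n_per * sum((Mgw[(g, w)] - Mg[g] - Mw[w] + M) ** 2 for g, w in Mgw.index)
    SS_err = sum((r.y - Ms[r.subject] - Mgw[(r.group, r.week)] + Mg[r.group]) ** 2
                 for r in df.itertuples())
    df_subj = n_subj - n_g
    df_err = df_subj * (n_w - 1)
    return {
        "group": (SS_group / (n_g - 1)) / (SS_subj / df_subj),
        "week": (SS_week / (n_w - 1)) / (SS_err / df_err),
        "week:group": (SS_int / ((n_w - 1) * (n_g - 1))) / (SS_err / df_err),
    }


class TestMixedAnova:
    def test_identical_groups_give_zero_group_F(self):
        rows = []
        for group in ["water", "DID"]:
            for s in range(4):
                for w in (0, 1):
                    rows.append({"subject": f"{group}{s}", "group": group, "week": w,
                                 "y": float(s + w)})
        res = mixed_anova(pd.DataFrame(rows), between=["group"], within=["week"], response="y")
        f_group = res.table.set_index("effect").loc["group", "F"]
        assert f_group == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_split_plot_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = balanced_mixed_table(rng, n_per_group=6)
        res = mixed_anova(df, between=["group"], within=["week"], response="y")
        ours = res.table.set_index("effect")["F"]
        oracle = brute_force_split_plot(df)
        for effect, F in oracle.items():
            assert ours[effect] == pytest.approx(F, rel=1e-9)

    def test_one_between_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = balanced_mixed_table(rng, n_per_group=7)
        ours = mixed_anova(df, between=["group"], within=["week"], response="y")
        theirs = pg.mixed_anova(data=df, dv="y", within="week", between="group",
                                subject="subject")
        t = ours.table.set_index("effect")
        ref = theirs.set_index("Source")
        assert t.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert t.loc["week", "F"] == pytest.approx(ref.loc["week", "F"], rel=1e-9)
        assert t.loc["week:group", "F"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_between_only_reduces_to_one_way_anova(self):
        rng = np.random.default_rng(9)
        rows = []
        for group in ("a", "b", "c"):
            for s in range(6):
                rows.append({"subject": f"{group}{s}", "group": group,
                             "y": float(rng.normal(0, 1))})
        df = pd.DataFrame(rows)
        res = mixed_anova(df, between=["group"], within=[], response="y")
        F, p = sps.f_oneway(*[df.loc[df.group == g, "y"] for g in ("a", "b", "c")])
        row = res.table.iloc[0]
        assert row["F"] == pytest.approx(float(F), rel=1e-9)
        assert row["p"] == pytest.approx(float(p), rel=1e-9)

    def test_incomplete_subject_excluded_listwise(self):
        rng = np.random.default_rng(2)
        df = balanced_mixed_table(rng, n_per_group=5)
        df = df.drop(df[(df.subject == "water0") & (df.week == 4)].index)
        res = mixed_anova(df, between=["group"], within=["week"], response="y")
        assert res.meta["excluded_subjects"] == ["water0"]
        assert res.meta["n_subjects"] == 9

    def test_one_subject_per_cell_rejected(self):
        rows = []
        for group in ("a", "b"):
            rows.append({"subject": f"{group}0", "group": group, "y": 1.0})
        with pytest.raises(ValidationError):
            mixed_anova(pd.DataFrame(rows), between=["group"], within=[], response="y")

    def test_null_rejection_rates_calibrated(self):
        rng = np.random.default_rng(11)
        n_reps = 800
        rej = {"group": 0, "week": 0, "week:group": 0}
        for _ in range(n_reps):
            df = balanced_mixed_table(rng, n_per_group=6, weeks=(0, 1, 4))
            res = mixed_anova(df, between=["group"], within=["week"], response="y")
            for _, r in res.table.iterrows():
                rej[r["effect"]] += r["p"] < 0.05
        for effect, k in rej.items():
            assert abs(k / n_reps - 0.05) <= 0.025, effect

    def test_injected_group_effect_has_power(self):
        rng = np.random.default_rng(21)
        detected = 0
        for _ in range(40):
            df = balanced_mixed_table(rng, n_per_group=10, effect=1.0, subject_sd=0.5)
            res = mixed_anova(df, between=["group"], within=["week"], response="y")
            p = res.table.set_index("effect").loc["group", "p"]
            detected += p < 0.05
        assert detected / 40 > 0.5
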