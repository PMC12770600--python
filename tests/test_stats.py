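"""Tests for the group-statistics layer (contrasts, FDR, ANOVA, hierarchy)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from neurotimescales import (
    fdr_bh,
    network_mean_int,
    rm_anova_oneway,
    spearman_hierarchy,
    two_way_anova,
    welch_t,
)


def welch_oracle(a, b):
    """Textbook Welch formula, evaluated independently."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        a, b = [1.0, 2, 3, 4], [2.0, 3, 4, 5]
        res = welch_t(a, b)
        t, df = welch_oracle(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=14)
        fwd = welch_t(a, b)
        rev = welch_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.p_raw == pytest.approx(rev.p_raw)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestFdrBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert fdr_bh([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 30)))
            assert np.all(fdr_bh(p) >= p - 1e-12)

    def test_shrinking_a_p_never_reduces_rejections(self):
        p = np.array([0.01, 0.04, 0.2, 0.8])
        base = np.sum(fdr_bh(p) < 0.05)
        p2 = p.copy()
        p2[2] = 0.03
        assert np.sum(fdr_bh(p2) < 0.05) >= base

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.5])


class TestSpearmanHierarchy:
    def test_identical_orderings(self):
        x = np.arange(8, dtype=float)
        assert spearman_hierarchy(x, x).rho == pytest.approx(1.0)

    def test_reversed_orderings(self):
        x = np.arange(8, dtype=float)
        res = spearman_hierarchy(x, x[::-1])
        assert res.rho == pytest.approx(-1.0)
        assert res.p_method == "permutation"
        assert res.p < 0.001

    def test_matches_rank_formula_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.permutation(8).astype(float)
            b = rng.permutation(8).astype(float)
            d = sps.rankdata(a) - sps.rankdata(b)
            closed_form = 1 - 6 * np.sum(d**2) / (8 * (64 - 1))
            assert spearman_hierarchy(a, b).rho == pytest.approx(closed_form)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_hierarchy(np.arange(8.0), np.arange(7.0))


def rm_anova_oracle(values):
    """Independent loop-based partitioned-SS oracle for the within-subject F."""
    n, k = values.shape
    grand = values.mean()
    ss_factor = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subject = sum(k * (values[i, :].mean() - grand) ** 2 for i in range(n))
    ss_total = sum((v - grand) ** 2 for v in values.ravel())
    ss_err = ss_total - ss_factor - ss_subject
    return (ss_factor / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def long_table(values):
    n, k = values.shape
    return pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "session": np.tile(np.arange(k), n),
            "int": values.ravel(),
        }
    )


class TestRmAnova:
    def test_no_session_effect_gives_zero_f(self):
        values = np.tile(np.array([[1.0], [2.0], [5.0]]), (1, 4))
        res = rm_anova_oneway(long_table(values))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_partitioned_ss_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(3, 3)) + rng.normal(size=(1, 3))
        res = rm_anova_oneway(long_table(values))
        assert res.statistic == pytest.approx(rm_anova_oracle(values), abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        values = rng.normal(size=(8, 5))
        res = rm_anova_oneway(long_table(values))
        pg = pingouin.rm_anova(
            data=long_table(values), dv="int", within="session", subject="subject"
        )
        assert res.statistic == pytest.approx(float(pg["F"].iloc[0]), abs=1e-8)
        assert res.p_raw == pytest.approx(float(pg["p_unc"].iloc[0]), abs=1e-8)

    def test_unbalanced_names_missing_cells(self):
        table = long_table(np.zeros((3, 3))).drop(index=[4])
        with pytest.raises(ValueError, match="missing"):
            rm_anova_oneway(table)


def outcome_network_table(rng, outcome_shift=0.0):
    rows = []
    for outcome, n_subj in (("good", 6), ("poor", 9)):
        for s in range(n_subj):
            for net in ("A", "B", "C", "D"):
                rows.append(
                    {
                        "outcome": outcome,
                        "network": net,
                        "int": rng.normal() + (outcome_shift if outcome == "poor" else 0),
                    }
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_null_calibration(self):
        """On no-effect data the outcome main effect rejects at ~alpha."""
        rng = np.random.default_rng(5)
        rejections = 0
        fs = []
        for _ in range(200):
            res = two_way_anova(outcome_network_table(rng))
            outcome_f = res[0]
            fs.append(outcome_f.statistic)
            rejections += outcome_f.p_raw < 0.05
        assert 1 <= rejections <= 24  # binomial(200, 0.05) central range
        assert 0.5 < np.mean(fs) < 1.8

    def test_additive_effect_recovered(self):
        rng = np.random.default_rng(6)
        res = two_way_anova(outcome_network_table(rng, outcome_shift=1.5))
        by_label = {r.label.split(": ")[1]: r for r in res}
        assert by_label["outcome"].p_raw < 0.001
        assert by_label["outcome x network"].p_raw > 0.05

    def test_balanced_type2_equals_type1(self):
        rng = np.random.default_rng(7)
        table = outcome_network_table(rng).rename(columns={"int": "_value"})
        model = ols("_value ~ C(outcome) * C(network)", data=table).fit()
        typ1 = anova_lm(model, typ=1)
        res = two_way_anova(table.rename(columns={"_value": "int"}))
        assert res[0].statistic == pytest.approx(typ1.loc["C(outcome)", "F"])
        assert res[1].statistic == pytest.approx(typ1.loc["C(network)", "F"])

    def test_single_level_factor_rejected(self):
        rng = np.random.default_rng(8)
        table = outcome_network_table(rng)
        with pytest.raises(ValueError):
            two_way_anova(table[table["outcome"] == "good"])


class TestNetworkMeans:
    def hand_table(self):
        return pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2", "s2"],
                "group": ["control"] * 4,
                "outcome": ["n/a"] * 4,
                "session": [1] * 4,
                "roi": ["A1", "B1", "A1", "B1"],
                "network": ["A", "B", "A", "B"],
                "int": [1.0, 3.0, 2.0, 5.0],
            }
        )

    def test_hand_computed_means(self):
        out = network_mean_int(self.hand_table(), "control", 1).set_index("network")
        assert out.loc["A", "int_mean"] == pytest.approx(1.5)
        assert out.loc["B", "int_mean"] == pytest.approx(4.0)
        assert out.loc["A", "int_sd"] == pytest.approx(np.std([1, 2], ddof=1))

    def test_single_subject_sd_is_zero(self):
        table = self.hand_table().iloc[:2]
        out = network_mean_int(table, "control", 1).set_index("network")
        assert out.loc["A", "int_mean"] == 1.0
        assert out.loc["A", "int_sd"] == 0.0

    def test_roi_order_invariance(self):
        table = self.hand_table()
        shuffled = table.iloc[[3, 1, 0, 2]].reset_index(drop=True)
        a = network_mean_int(table, "control", 1)
        b = network_mean_int(shuffled, "control", 1)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            network_mean_int(self.hand_table(), "patient", 3)
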