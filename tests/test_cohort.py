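"""Cohort-level arithmetic and statistical helpers."""

import numpy as np
import pytest

import pkgfluct as pf
from pkgfluct import PairedCohort, ValidationError


class TestDeltaPercent:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(38.0, 32.7, 13.9), (42.0, 23.0, 45.2), (10.0, 10.0, 0.0)],
    )
    def test_values(self, before, after, expected):
        assert round(pf.delta_percent(before, after), 1) == expected

    def test_agrees_with_referenced_improvement_at_zero_reference(self):
        assert pf.delta_percent(63, 50) == pytest.approx(pf.referenced_improvement(63, 50, 0))


class TestEffectSize:
    def test_pooled_formula(self):
        # hand computation: 13 / sqrt((22^2 + 24^2)/2) = 0.5647
        assert pf.effect_size(63, 22, 50, 24) == pytest.approx(13 / np.sqrt(530), abs=1e-12)
        assert round(pf.effect_size(63, 22, 50, 24), 2) == 0.56

    def test_equal_means_zero(self):
        assert pf.effect_size(10, 3, 10, 5) == 0.0

    def test_alternative_formulas(self):
        assert pf.effect_size(14, 13, 6.2, 4.3, formula="baseline") == pytest.approx(7.8 / 13)
        paired = pf.effect_size(14, 13, 6.2, 4.3, formula="paired", correlation=0.0)
        assert paired == pytest.approx(7.8 / np.sqrt(13**2 + 4.3**2))
        with pytest.raises(ValidationError):
            pf.effect_size(1, 1, 1, 1, formula="nope")


class TestWelchT:
    def test_identical_groups_statistic_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = pf.welch_t(x, x)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_welch_formula(self):
        x = np.array([12.1, 14.3, 11.8, 15.2, 13.3, 12.9])
        y = np.array([10.4, 9.8, 11.1, 10.9, 9.5])
        t, p = pf.welch_t(x, y)
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        from scipy.stats import t as t_dist

        p_hand = 2 * t_dist.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert p == pytest.approx(p_hand, abs=1e-10)

    def test_shifted_gaussians_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            x = rng.normal(0, 1, 50)
            y = rng.normal(1, 1, 50)
            _, p = pf.welch_t(x, y)
            hits += p < 0.01
        assert hits >= 190


class TestPearsonCi:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, _ = pf.pearson_ci(x, x)
        assert r == pytest.approx(1.0)

    def test_independent_gaussians_near_zero(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            r, _ = pf.pearson_ci(x, y)
            hits += abs(r) < 0.2
        assert hits >= 95

    def test_ci_width_matches_fisher_closed_form(self):
        # rho ~ 0.4, n = 170: z-interval width = tanh(z+h) - tanh(z-h) ~ 0.26
        rng = np.random.default_rng(2)
        n = 170
        x = rng.normal(size=n)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.normal(size=n)
        r, (lo, hi) = pf.pearson_ci(x, y)
        z, h = np.arctanh(r), 1.959963984540054 / np.sqrt(n - 3)
        assert lo == pytest.approx(np.tanh(z - h), abs=1e-12)
        assert hi == pytest.approx(np.tanh(z + h), abs=1e-12)
        assert hi - lo == pytest.approx(0.26, abs=0.03)

    def test_agrees_with_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        r, (lo, hi) = pf.pearson_ci(x, y)
        ref = pingouin.corr(x, y)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        ref_lo, ref_hi = ref["CI95"].iloc[0]
        assert lo == pytest.approx(ref_lo, abs=5e-3)
        assert hi == pytest.approx(ref_hi, abs=5e-3)


class TestOtherTests:
    def test_mann_whitney_and_chi_square_run(self):
        u, p = pf.mann_whitney([1, 2, 3, 4], [10, 11, 12, 13])
        assert p < 0.05
        stat, p = pf.chi_square([[20, 5], [5, 20]])
        assert p < 0.01

    def test_anova_sidak_adjustment_increases_p(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 1, 30) for mu in (0.0, 0.2, 1.0)]
        res = pf.anova_sidak(*groups)
        assert res["p"] < 0.05
        for pair in res["pairwise"]:
            assert pair["p_sidak"] >= pair["p_raw"]
            assert pair["p_sidak"] == pytest.approx(1 - (1 - pair["p_raw"]) ** 3)


class TestTransitionTable:
    def test_identical_vectors_fully_unchanged(self):
        classes = ["NFC", "NFU", "FC_P", "FU_WO"]
        table = pf.transition_table(classes, classes)
        assert table.percent_unchanged == 100.0
        assert table.n == 4

    def test_hand_built_moves_match_enumeration(self):
        before = ["NFU"] * 5 + ["NFC"] * 3 + ["FC_P"] * 2
        after = ["FC_P"] * 3 + ["NFU"] * 2 + ["NFC"] * 3 + ["FC_P"] * 2
        table = pf.transition_table(before, after)
        assert table.counts.loc["NFU", "FC_P"] == 3
        assert table.counts.loc["NFU", "NFU"] == 2
        assert table.counts.loc["NFC", "NFC"] == 3
        assert table.counts.to_numpy().sum() == 10
        assert table.percent_unchanged == pytest.approx(70.0)

    def test_row_sums_are_before_counts(self):
        rng = np.random.default_rng(5)
        classes = list(pf.ALL_CLASSES)
        before = rng.choice(classes, 50)
        after = rng.choice(classes, 50)
        table = pf.transition_table(before, after)
        for cls in classes:
            assert table.counts.loc[cls].sum() == int((before == cls).sum())


class TestTreatmentChangeTable:
    def test_columns_and_values(self):
        rng = np.random.default_rng(6)
        before = rng.normal(60, 20, 40)
        after = before - rng.normal(12, 5, 40)
        table = pf.treatment_change_table([PairedCohort("ptb", before, after)])
        row = table.iloc[0]
        assert row["measure"] == "ptb"
        assert row["delta_pct"] == pytest.approx(
            100 * (before.mean() - after.mean()) / before.mean()
        )
        assert row["p_welch"] < 0.05

    def test_requires_two_subjects(self):
        with pytest.raises(ValidationError):
            PairedCohort("x", [1.0], [2.0])
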