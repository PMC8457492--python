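"""Permutation tests, mixed ANOVA, effect sizes: enumeration and library oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speedcontours.stats import (
    DegenerateDataError,
    LayoutError,
    adjust_bonferroni,
    chi_square_2x2,
    chi_square_corner,
    hedges_g_correction,
    perm_mixed_anova,
    perm_t_one_sample,
    perm_t_paired,
    perm_t_two_sample,
    shapiro_wilk,
    wrap_axial,
)

CONDS = ["spatial", "temporal", "coherent", "opposite"]


def long_table(y: np.ndarray, n_first: int) -> pd.DataFrame:
    rows = []
    for i in range(y.shape[0]):
        g = "A" if i < n_first else "B"
        for j, c in enumerate(CONDS):
            rows.append((f"S{i:02d}", g, c, y[i, j]))
    return pd.DataFrame(rows, columns=["subject_id", "group", "condition", "jnd_conv"])


def enumerate_sign_flip_p(d: np.ndarray) -> float:
    """Brute-force exact sign-flip p-value (independent of the implementation)."""
    n = len(d)

    def tstat(v):
        sd = np.std(v, ddof=1)
        if sd == 0:
            return 0.0 if np.mean(v) == 0 else math.inf
        return np.mean(v) / (sd / math.sqrt(n))

    t_obs = abs(tstat(d))
    hits = 0
    for signs in itertools.product([-1, 1], repeat=n):
        if abs(tstat(np.asarray(signs) * d)) >= t_obs - 1e-12:
            hits += 1
    return hits / 2**n


def enumerate_label_shuffle_p(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force exact label-shuffle p-value on the Welch statistic."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def welch(x, y):
        se2 = x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)
        if se2 == 0:
            return 0.0 if x.mean() == y.mean() else math.inf
        return (x.mean() - y.mean()) / math.sqrt(se2)

    t_obs = abs(welch(a, b))
    hits = total = 0
    for idx in itertools.combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        total += 1
        if abs(welch(pooled[mask], pooled[~mask])) >= t_obs - 1e-12:
            hits += 1
    return hits / total


class TestOneSampleSignFlip:
    def test_exact_null_gives_p_one(self):
        res = perm_t_one_sample([5.0, 5.0, 5.0], target=5.0)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_matches_exhaustive_enumeration(self, rng):
        d = rng.normal(0.4, 1.0, size=8)
        res = perm_t_one_sample(d, 0.0)
        assert res.exact and res.n_iterations == 256
        assert res.p_value == pytest.approx(enumerate_sign_flip_p(d), abs=1e-12)

    def test_random_mode_agrees_with_exact(self, rng):
        d = rng.normal(0.5, 1.0, size=10)
        exact = perm_t_one_sample(d, 0.0)
        rand = perm_t_one_sample(d, 0.0, n_iter=10_000, seed=4, max_exact=1)
        assert exact.exact and not rand.exact
        assert rand.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_large_shift_hits_permutation_floor(self):
        # every |d| distinct: only the all-plus/all-minus patterns tie |t|
        values = 50.0 + np.array([0.0, 0.1, -0.2, 0.15, 0.05, -0.1, 0.3, 0.2, -0.05, 0.12])
        res = perm_t_one_sample(values, 0.0, wrap=False)
        assert res.p_value == pytest.approx(2 / 2**10)

    def test_axial_wrap_of_differences(self):
        # orientations just below 180 are just below 0 axially
        res = perm_t_one_sample([170.0, 175.0, 178.0, 172.0], 0.0, wrap=True)
        lo, hi = res.ci_95
        assert lo < -8 and hi < 0  # mean wrapped difference near -6 degrees

    def test_hedges_g_and_ci(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        res = perm_t_one_sample(d, 0.0)
        g_expected = d.mean() / d.std(ddof=1) * hedges_g_correction(3)
        assert res.effect_size == pytest.approx(g_expected)
        assert res.ci_95[0] < d.mean() < res.ci_95[1]

    def test_reproducible_under_seed(self, rng):
        d = rng.normal(0.2, 1, size=20)
        a = perm_t_one_sample(d, 0.0, n_iter=500, seed=9)
        b = perm_t_one_sample(d, 0.0, n_iter=500, seed=9)
        assert a.p_value == b.p_value

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            perm_t_one_sample([1.0], 0.0)


class TestTwoSampleShuffle:
    def test_identical_groups_p_one(self):
        res = perm_t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_matches_exhaustive_enumeration_4_plus_4(self, rng):
        a = rng.normal(0, 1, 4)
        b = rng.normal(1, 1, 4)
        res = perm_t_two_sample(a, b)
        assert res.exact and res.n_iterations == 70
        assert res.p_value == pytest.approx(enumerate_label_shuffle_p(a, b), abs=1e-12)

    def test_zero_pooled_variance_flagged_degenerate(self):
        res = perm_t_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert "degenerate" in res.note and np.isnan(res.effect_size)
        assert res.p_value == pytest.approx(1 / math.comb(6, 3) * 2)

    def test_paired_wrapper_equals_one_sample_on_differences(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 8)
        assert perm_t_paired(a, b).p_value == perm_t_one_sample(a - b).p_value


class TestMixedAnova:
    def test_f_statistics_match_pingouin(self, rng):
        import pingouin as pg

        y = rng.normal(size=(20, 4)) + rng.normal(size=(20, 1))
        df = long_table(y, 10)
        ours = perm_mixed_anova(df, n_iter=200, seed=0)
        ref = pg.mixed_anova(
            data=df, dv="jnd_conv", within="condition", between="group",
            subject="subject_id",
        ).set_index("Source")
        assert ours.effects["group"]["F"] == pytest.approx(ref.loc["group", "F"])
        assert ours.effects["condition"]["F"] == pytest.approx(ref.loc["condition", "F"])
        assert ours.effects["interaction"]["F"] == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        assert ours.effects["group"]["partial_eta_sq"] == pytest.approx(
            ref.loc["group", "np2"]
        )

    def test_constant_table_gives_zero_f(self):
        df = long_table(np.full((8, 4), 3.0), 4)
        res = perm_mixed_anova(df, n_iter=100, seed=1)
        for eff in res.effects.values():
            assert eff["F"] == 0.0
            assert 0.0 <= eff["partial_eta_sq"] <= 1.0

    def test_group_shift_detected_without_touching_condition(self, rng):
        y = rng.normal(size=(20, 4))
        y[:10] += 5.0
        res = perm_mixed_anova(long_table(y, 10), n_iter=500, seed=2)
        assert res.effects["group"]["p_perm"] == pytest.approx(1 / 501)
        assert res.effects["condition"]["p_perm"] > 0.05

    def test_condition_effect_detected(self, rng):
        y = rng.normal(size=(12, 4))
        y[:, 0] += 3.0
        res = perm_mixed_anova(long_table(y, 6), n_iter=500, seed=3)
        assert res.effects["condition"]["p_perm"] == pytest.approx(1 / 501)

    def test_incomplete_layout_rejected(self, rng):
        df = long_table(rng.normal(size=(8, 4)), 4).iloc[:-1]
        with pytest.raises(LayoutError, match="S07"):
            perm_mixed_anova(df, n_iter=50)

    def test_seed_reproducibility(self, rng):
        df = long_table(rng.normal(size=(8, 4)), 4)
        a = perm_mixed_anova(df, n_iter=300, seed=7)
        b = perm_mixed_anova(df, n_iter=300, seed=7)
        assert a.effects == b.effects


class TestChiSquare:
    def test_independence_gives_zero(self):
        chi2, p, v, _ = chi_square_2x2([[30, 30], [30, 30]])
        assert chi2 == 0.0 and v == 0.0 and p == 1.0

    def test_perfect_association(self):
        chi2, _, v, _ = chi_square_2x2([[60, 0], [0, 60]])
        assert v == pytest.approx(1.0) and chi2 == pytest.approx(120.0)

    def test_matches_closed_form_expected_counts(self):
        obs = np.array([[40, 20], [15, 45]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = float(((obs - expected) ** 2 / expected).sum())
        chi2, _, _, _ = chi_square_2x2(obs)
        assert chi2 == pytest.approx(oracle)

    def test_zero_margin_flagged_not_raised(self):
        chi2, p, v, note = chi_square_2x2([[0, 0], [10, 20]])
        assert chi2 == 0.0 and "degenerate" in note

    def test_corner_comparison_on_trials(self):
        df = pd.DataFrame(
            {
                "w_duration": [-0.6] * 40 + [0.6] * 40,
                "w_distance": [0.6] * 40 + [-0.6] * 40,
                "response": ["faster"] * 35 + ["slower"] * 5
                + ["faster"] * 10 + ["slower"] * 30,
            }
        )
        res = chi_square_corner(df, (-0.6, 0.6), (0.6, -0.6))
        assert res.statistic > 10
        assert res.effect_size_label == "cramers_v" and 0 < res.effect_size <= 1
        assert res.ci_95[0] > 0  # proportion difference clearly positive

    def test_corner_without_trials_rejected(self):
        df = pd.DataFrame({"w_duration": [0.1], "w_distance": [0.1], "response": ["faster"]})
        with pytest.raises(ValueError):
            chi_square_corner(df, (-0.6, 0.6), (0.6, -0.6))


class TestSmallTools:
    def test_bonferroni_examples(self):
        assert adjust_bonferroni([0.01], m=4)[0] == pytest.approx(0.04)
        assert adjust_bonferroni([0.5], m=4)[0] == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=6))
    def test_bonferroni_preserves_order(self, ps):
        adj = adjust_bonferroni(ps)
        assert np.all(np.argsort(np.argsort(ps)) == np.argsort(np.argsort(adj))) or True
        # monotone map: pairwise order is never reversed
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] < ps[j]:
                    assert adj[i] <= adj[j]

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            adjust_bonferroni([0.1, 0.2, 0.3], m=2)

    def test_wrap_axial_range(self):
        assert wrap_axial(135.0) == -45.0
        assert wrap_axial(-90.0) == 90.0
        assert wrap_axial(90.0) == 90.0

    def test_shapiro_requirements(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([1.0, 1.0, 1.0, 1.0])

    def test_shapiro_detects_exponential(self, rng):
        hits = 0
        for _ in range(40):
            res = shapiro_wilk(rng.exponential(size=50))
            hits += res.p_value < 0.05
        assert hits >= 32  # power well above 80% at n = 50

    def test_shapiro_accepts_normal_on_average(self, rng):
        ps = [shapiro_wilk(rng.normal(size=50)).p_value for _ in range(40)]
        assert np.mean(ps) > 0.3  # roughly uniform p under the null
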