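"""Psychometric aggregation, cumulative-Gaussian ML fitting, substitution."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from speedcontours.observers import observer_preset, simulate_responses
from speedcontours.psychometrics import (
    ProportionSeries,
    SelectionError,
    SubstitutionError,
    aggregate_proportions,
    fit_psychometric,
    gof_significant,
    substitute_worst,
)

from .conftest import make_trials

LEVELS = np.array([-0.75, -0.65, -0.5, -0.29, 0.0, 0.41, 1.0, 1.83, 3.0])


def exact_series(sigma: float, pse: float = 0.0, n: int = 1000) -> ProportionSeries:
    """Proportions lying exactly on a cumulative Gaussian (no sampling noise)."""
    return ProportionSeries(LEVELS, norm.cdf((LEVELS - pse) / sigma), np.full(9, n))


class TestAggregation:
    def test_counts_and_proportions(self):
        df = make_trials(90.0, [0.5], reps=6)
        df["response"] = ["faster", "slower", "faster", "slower", "faster", "slower"]
        series = aggregate_proportions(df, axis="magnitude")
        assert series.p_faster.tolist() == [0.5]
        assert series.n.tolist() == [6]

    def test_pure_axis_degeneracy(self):
        # on the temporal orientation w_distance is identically 0
        df = make_trials(90.0, [-0.5, 0.5], reps=3)
        df["response"] = "faster"
        series = aggregate_proportions(df, axis="w_distance", condition="temporal")
        assert len(series.x) == 1 and series.x[0] == 0.0 and series.n[0] == 6

    def test_empty_selection(self):
        df = make_trials(90.0, [0.5], reps=2)
        df["response"] = "faster"
        with pytest.raises(SelectionError):
            aggregate_proportions(df, condition="spatial")

    def test_deterministic_observer_gives_step_function(self):
        trials = make_trials(90.0, LEVELS.tolist(), reps=4)
        obs = observer_preset("duration_only", noise_sd=0.0, lapse=0.0)
        out = simulate_responses(trials, obs, seed=0)
        series = aggregate_proportions(out, axis="magnitude")
        for x, p in zip(series.x, series.p_faster):
            if x < 0:
                assert p == 1.0
            elif x > 0:
                assert p == 0.0


class TestCumulativeGaussianFit:
    def test_recovers_generating_curve_from_exact_proportions(self):
        fit = fit_psychometric(exact_series(0.3))
        assert fit.valid
        assert fit.pse == pytest.approx(0.0, abs=1e-3)
        assert fit.jnd_signed == pytest.approx(0.3, abs=1e-3)
        assert fit.r_squared > 0.999

    def test_mirrored_proportions_flip_the_sign(self):
        s = exact_series(0.3)
        mirrored = ProportionSeries(s.x, 1 - s.p_faster, s.n)
        fit = fit_psychometric(mirrored)
        assert fit.valid
        assert fit.jnd_signed == pytest.approx(-0.3, abs=1e-3)

    def test_sign_recovery_from_noiseless_decreasing_curve(self):
        fit = fit_psychometric(exact_series(-0.5, pse=0.2))
        assert fit.jnd_signed < 0
        assert fit.pse == pytest.approx(0.2, abs=1e-3)

    def test_flat_data_invalid(self):
        series = ProportionSeries(LEVELS, np.full(9, 0.5), np.full(9, 60))
        fit = fit_psychometric(series)
        assert not fit.valid

    def test_degenerate_x_invalid_not_raising(self):
        series = ProportionSeries([0.1, 0.1], [0.2, 0.8], [5, 5])
        fit = fit_psychometric(series)
        assert not fit.valid and "degenerate" in fit.note

    def test_estimator_bias_small_at_sixty_reps(self, rng):
        # |JND| consistency: relative bias under binomial sampling
        true_sigma, reps, n_rep = 0.3, 60, 80
        est = []
        for _ in range(n_rep):
            k = rng.binomial(reps, norm.cdf(LEVELS / true_sigma))
            fit = fit_psychometric(ProportionSeries(LEVELS, k / reps, np.full(9, reps)))
            assert fit.valid
            est.append(abs(fit.jnd_signed))
        assert abs(np.mean(est) - true_sigma) / true_sigma < 0.10


class TestGoodnessOfFit:
    def test_perfect_fit_significant(self):
        fit = fit_psychometric(exact_series(0.3))
        assert gof_significant(fit)
        assert fit.gof_p < 1e-6

    def test_flat_data_not_significant(self):
        series = ProportionSeries(LEVELS, np.full(9, 0.5), np.full(9, 60))
        assert not gof_significant(fit_psychometric(series))

    def test_false_positive_rate_near_alpha_under_null(self, rng):
        # i.i.d. fair-coin responses: the R^2 gate should fire at ~alpha
        hits = total = 0
        for _ in range(300):
            k = rng.binomial(6, 0.5, size=9)
            fit = fit_psychometric(ProportionSeries(LEVELS, k / 6, np.full(9, 6)))
            total += 1
            if fit.valid and gof_significant(fit):
                hits += 1
        assert 0.01 <= hits / total <= 0.12


class TestSubstitution:
    @staticmethod
    def frame(jnds, valid=None, gof_p=None, cell="A"):
        n = len(jnds)
        return pd.DataFrame(
            {
                "cell": [cell] * n,
                "jnd_signed": jnds,
                "valid": valid if valid is not None else [True] * n,
                "gof_p": gof_p if gof_p is not None else [0.001] * n,
            }
        )

    def test_invalid_gets_largest_jnd(self):
        df = self.frame([0.2, 0.5, np.nan], valid=[True, True, False])
        out = substitute_worst(df, ["cell"])
        assert out.loc[2, "jnd_signed"] == 0.5
        assert out.loc[2, "substituted"] and not out.loc[0, "substituted"]

    def test_all_significant_is_identity(self):
        df = self.frame([0.2, -0.5, 0.4])
        out = substitute_worst(df, ["cell"])
        pd.testing.assert_series_equal(out["jnd_signed"], df["jnd_signed"])
        assert not out["substituted"].any()

    def test_worst_selected_on_converted_scale(self):
        # conv(-0.1) = -0.1 - (-0.1) + 0.4 = 0.4 ties conv(0.4); magnitude
        # breaks the tie toward 0.4
        df = self.frame([-0.1, 0.4, np.nan], valid=[True, True, False])
        out = substitute_worst(df, ["cell"], criterion="conv")
        assert out.loc[2, "jnd_signed"] == pytest.approx(0.4)
        # an inverted curve deep enough dominates on the converted scale
        df = self.frame([-0.5, 0.4, np.nan], valid=[True, True, False])
        out = substitute_worst(df, ["cell"], criterion="conv")
        # conv(-0.5) = -0.5 + 0.5 + 0.4 = 0.4 ties again -> larger |jnd| wins
        assert out.loc[2, "jnd_signed"] == pytest.approx(-0.5)

    def test_nonsignificant_fits_also_substituted(self):
        df = self.frame([0.2, 0.7, 0.3], gof_p=[0.001, 0.001, 0.3])
        out = substitute_worst(df, ["cell"])
        assert out.loc[2, "jnd_signed"] == 0.7 and out.loc[2, "substituted"]

    def test_empty_cell_raises(self):
        df = self.frame([0.2, 0.4], valid=[False, False])
        with pytest.raises(SubstitutionError):
            substitute_worst(df, ["cell"])

    def test_cells_are_independent(self):
        a = self.frame([0.2, np.nan], valid=[True, False], cell="A")
        b = self.frame([0.9, 0.8], cell="B")
        out = substitute_worst(pd.concat([a, b], ignore_index=True), ["cell"])
        assert out.loc[1, "jnd_signed"] == 0.2  # never borrows from cell B
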