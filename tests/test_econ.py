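"""Bootstrap ICER machinery: point ratios, draws, quadrants, CEAC."""

import itertools
import math

import numpy as np
import pytest

from trialcea.econ import (ArmData, BootstrapDraws, bootstrap_pairs, ceac,
                           default_lambda_grid, evaluate_contrast,
                           icer_point, icer_summary)
from trialcea.synthetic import synthetic_arm_data


class TestPointICER:
    def test_simple_ratio(self):
        icer, undefined = icer_point(1100.0, 0.02, 1000.0, 0.01)
        assert icer == pytest.approx(10_000.0)
        assert not undefined

    def test_equal_costs_give_zero(self):
        icer, undefined = icer_point(500.0, 0.3, 500.0, 0.1)
        assert icer == 0.0 and not undefined

    def test_zero_effect_difference_flagged_not_raised(self):
        icer, undefined = icer_point(600.0, 0.2, 500.0, 0.2)
        assert undefined and math.isnan(icer)

    def test_published_means_ratio(self):
        # printed cost means and improvement proportions: the point ICER
        # (not the bootstrap median) is dC / d(proportion improved)
        icer, _ = icer_point(2814.0, 25 / 88, 2558.0, 13 / 87)
        assert icer == pytest.approx(256.0 / (25 / 88 - 13 / 87))
        assert icer == pytest.approx(1900.8, abs=1.0)


class TestBootstrapPairs:
    def test_constant_data_degenerate_draws(self):
        a1 = ArmData(np.full(5, 120.0), np.full(5, 0.4))
        a0 = ArmData(np.full(5, 100.0), np.full(5, 0.1))
        draws = bootstrap_pairs(a1, a0, B=50, seed=0)
        assert np.allclose(draws.dC, 20.0)
        assert np.allclose(draws.dE, 0.3)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        a1 = synthetic_arm_data(30, 1000.0, 0.3, rng)
        a0 = synthetic_arm_data(30, 900.0, 0.2, rng)
        d1 = bootstrap_pairs(a1, a0, B=200, seed=11)
        d2 = bootstrap_pairs(a1, a0, B=200, seed=11)
        assert np.array_equal(d1.dC, d2.dC)
        assert np.array_equal(d1.dE, d2.dE)

    def test_bootstrap_mean_consistent_with_truth(self):
        """With true dC=200 and dE=0.02 at n=500 the mean of the draws
        lands within 3 Monte-Carlo SEs of the truth."""
        rng = np.random.default_rng(7)
        a1 = synthetic_arm_data(500, 1200.0, 0.0, rng, qaly_mean=0.17)
        a0 = synthetic_arm_data(500, 1000.0, 0.0, rng, qaly_mean=0.15)
        draws = bootstrap_pairs(a1, a0, B=2000, seed=5)
        se_c = math.sqrt(a1.costs.var() / a1.n + a0.costs.var() / a0.n)
        se_e = math.sqrt(a1.effects.var() / a1.n + a0.effects.var() / a0.n)
        assert abs(draws.dC.mean() - 200.0) < 3 * se_c
        assert abs(draws.dE.mean() - 0.02) < 3 * se_e

    def test_small_n_enumeration_oracle(self):
        """At n<=6 per arm the bootstrap mean of dC converges to the exact
        mean over all with-replacement resamples."""
        c1 = np.array([10.0, 40.0, 70.0, 100.0])
        c0 = np.array([5.0, 20.0, 35.0])
        # exact: average resample mean per arm over all n^n index tuples
        def enum_mean(values):
            n = len(values)
            sums = [np.mean([values[i] for i in idx])
                    for idx in itertools.product(range(n), repeat=n)]
            return np.mean(sums)
        exact = enum_mean(c1) - enum_mean(c0)
        a1 = ArmData(c1, np.zeros(4))
        a0 = ArmData(c0, np.zeros(3))
        draws = bootstrap_pairs(a1, a0, B=100_000, seed=2)
        se = draws.dC.std() / math.sqrt(draws.B)
        assert abs(draws.dC.mean() - exact) < 3 * se

    def test_tiny_arm_rejected(self):
        a1 = ArmData(np.array([1.0]), np.array([0.0]))
        a0 = ArmData(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match="n >= 2"):
            bootstrap_pairs(a1, a0, B=10, seed=0)


class TestICERSummary:
    def test_symmetric_draws_quarter_each_quadrant(self):
        draws = BootstrapDraws(dC=np.array([1.0, 1.0, -1.0, -1.0] * 10),
                               dE=np.array([1.0, -1.0, 1.0, -1.0] * 10))
        res = icer_summary(draws)
        assert res.quadrants == {"NE": 0.25, "NW": 0.25,
                                 "SE": 0.25, "SW": 0.25}

    def test_all_northeast(self):
        draws = BootstrapDraws(dC=np.ones(50), dE=np.ones(50))
        res = icer_summary(draws)
        assert res.quadrants["NE"] == 1.0
        assert sum(res.quadrants.values()) == 1.0

    def test_quadrants_sum_to_one_with_boundary_ties(self):
        rng = np.random.default_rng(0)
        dE = rng.normal(0, 1, 999)
        dE[::3] = 0.0  # boundary mass
        draws = BootstrapDraws(dC=rng.normal(0, 1, 999), dE=dE)
        res = icer_summary(draws)
        assert sum(res.quadrants.values()) == pytest.approx(1.0, abs=1e-12)
        assert res.n_zero_effect == 333

    def test_median_uses_mid_rule(self):
        dE = np.ones(100)
        dC = np.arange(1.0, 101.0)
        res = icer_summary(BootstrapDraws(dC=dC, dE=dE))
        assert res.median_icer == pytest.approx(50.5)
        assert res.ci_lower <= res.median_icer <= res.ci_upper

    def test_too_few_draws_rejected(self):
        draws = BootstrapDraws(dC=np.ones(10), dE=np.ones(10))
        with pytest.raises(ValueError, match="B >= 40"):
            icer_summary(draws)


class TestCEAC:
    def test_dominant_draws_curve_is_one(self):
        draws = BootstrapDraws(dC=-np.ones(100), dE=np.ones(100))
        curve = ceac(draws, [0.0, 1000.0, 50_000.0])
        assert (curve.probability == 1.0).all()

    def test_value_at_zero_is_probability_of_saving(self):
        rng = np.random.default_rng(1)
        draws = BootstrapDraws(dC=rng.normal(50, 100, 4000),
                               dE=rng.normal(0.01, 0.02, 4000))
        curve = ceac(draws, default_lambda_grid())
        assert curve.at(0.0) == (draws.dC < 0).mean()

    def test_limit_is_probability_of_positive_effect(self):
        rng = np.random.default_rng(2)
        draws = BootstrapDraws(dC=rng.normal(50, 100, 4000),
                               dE=rng.normal(0.01, 0.02, 4000))
        huge = ceac(draws, [1e12]).probability[0]
        assert huge == pytest.approx((draws.dE > 0).mean(), abs=1e-12)

    def test_step_at_the_icer(self):
        draws = BootstrapDraws(dC=np.full(100, 100.0),
                               dE=np.full(100, 0.01))
        curve = ceac(draws, [0.0, 9999.0, 10_000.0, 10_001.0])
        assert list(curve.probability) == [0.0, 0.0, 0.0, 1.0]  # tie: not acceptable

    def test_monotone_when_effects_nonnegative(self):
        rng = np.random.default_rng(3)
        draws = BootstrapDraws(dC=rng.normal(0, 50, 1000),
                               dE=np.abs(rng.normal(0.01, 0.01, 1000)))
        curve = ceac(draws, default_lambda_grid())
        assert (np.diff(curve.probability) >= 0).all()

    def test_descending_grid_rejected(self):
        draws = BootstrapDraws(dC=np.ones(10), dE=np.ones(10))
        with pytest.raises(ValueError, match="ascending"):
            ceac(draws, [100.0, 0.0])


class TestEvaluateContrast:
    @staticmethod
    def _ce_frame(n=60, seed=0, dominance=False):
        import pandas as pd
        rng = np.random.default_rng(seed)
        rows = []
        for arm, cost, p in (("CBT", 2800.0, 0.28), ("PST", 2700.0, 0.26),
                             ("WL", 2600.0 if not dominance else 3200.0,
                              0.15)):
            data = synthetic_arm_data(n, cost, p, rng)
            for c, e in zip(data.costs, data.effects):
                rows.append({"arm": arm, "total": c,
                             "qaly_total": 0.15 + 0.05 * e
                             + rng.normal(0, 0.01),
                             "clinically_significant": e})
        return pd.DataFrame(rows)

    def test_unknown_contrast_and_effect_rejected(self):
        ce = self._ce_frame()
        with pytest.raises(ValueError, match="contrast"):
            evaluate_contrast(ce, "CBT-PST")
        with pytest.raises(ValueError, match="effect_kind"):
            evaluate_contrast(ce, "CBT-WL", effect_kind="days")

    def test_point_contrasts_are_linear(self):
        ce = self._ce_frame(n=80, seed=4)
        res = {c: evaluate_contrast(ce, c, "qaly", B=50, seed=1)
               for c in ("CBT-WL", "PST-WL", "PST-CBT")}
        assert res["PST-WL"].icer.dC - res["CBT-WL"].icer.dC == \
            pytest.approx(res["PST-CBT"].icer.dC, abs=1e-9)
        assert res["PST-WL"].icer.dE - res["CBT-WL"].icer.dE == \
            pytest.approx(res["PST-CBT"].icer.dE, abs=1e-12)

    def test_built_in_dominance_concentrates_southeast(self):
        """A cheaper, more effective intervention should land nearly all
        bootstrap replicates in the southeast quadrant as n grows."""
        ce = self._ce_frame(n=600, seed=5, dominance=True)
        res = evaluate_contrast(ce, "CBT-WL", "rcsc", B=1000, seed=2)
        assert res.icer.quadrants["SE"] > 0.95
        # dominance also means an acceptability curve pinned near one
        assert res.ceac.at(10_000.0) > 0.95

    def test_rcsc_on_degenerate_cohort(self):
        import pandas as pd
        ce = pd.DataFrame({
            "arm": ["CBT"] * 5 + ["WL"] * 5,
            "total": [100.0] * 5 + [50.0] * 5,
            "qaly_total": [0.16] * 5 + [0.15] * 5,
            "clinically_significant": [1.0] * 5 + [0.0] * 5,
        })
        res = evaluate_contrast(ce, "CBT-WL", "rcsc", B=100, seed=0)
        assert res.icer.point_icer == pytest.approx(50.0)
        assert np.allclose(res.draws.dC, 50.0)
        assert np.allclose(res.draws.dE, 1.0)
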