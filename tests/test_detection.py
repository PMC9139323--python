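"""LoB/LoD/LoQ estimators against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from assayval.core import Measurement, to_frame
from assayval.detection import (cochran_c_test, estimate_detection_limits,
                                estimate_lob, estimate_lod, estimate_loq)
from assayval.simulate import simulate_detection_panels


class TestLoB:
    def test_all_zero_blanks_give_zero_by_either_method(self):
        zeros = [0.0] * 25
        assert estimate_lob(zeros, method="parametric")[0] == 0.0
        assert estimate_lob(zeros, method="nonparametric")[0] == 0.0

    def test_nonparametric_rank_position_oracle(self):
        # B = 20 blanks: rank position 0.5 + 20*0.95 = 19.5, i.e. the mean
        # of the 19th and 20th order statistics
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 50, 20)
        lob, method = estimate_lob(values, method="nonparametric")
        srt = np.sort(values)
        assert method == "nonparametric"
        assert lob == pytest.approx((srt[18] + srt[19]) / 2, abs=1e-12)

    def test_parametric_closed_form(self):
        # construct a sample with exact mean 10 and sd 2
        rng = np.random.default_rng(1)
        v = rng.normal(size=40)
        v = (v - v.mean()) / v.std(ddof=1)  # mean 0, sd 1 exactly
        values = 10.0 + 2.0 * v
        lob, _ = estimate_lob(values, method="parametric")
        z = stats.norm.ppf(0.95)
        assert lob == pytest.approx(10.0 + z * 2.0, abs=1e-9)
        assert lob == pytest.approx(13.29, abs=0.01)

    def test_fewer_than_20_blanks_rejected(self):
        with pytest.raises(ValueError, match="20"):
            estimate_lob([1.0] * 19)

    def test_nonparametric_invariant_under_pool_relabeling(self):
        rng = np.random.default_rng(2)
        vals = rng.gamma(2.0, 3.0, 40)
        rows_a = [Measurement(f"BLK{i % 4 + 1}", "c", float(v), replicate=i + 1)
                  for i, v in enumerate(vals)]
        rows_b = [Measurement("BLKx", "c", float(v), replicate=i + 1)
                  for i, v in enumerate(vals)]
        assert estimate_lob(to_frame(rows_a), method="nonparametric") == \
            estimate_lob(to_frame(rows_b), method="nonparametric")


class TestCochran:
    def test_equal_variances_statistic_and_pass(self):
        res = cochran_c_test([2.0, 2.0, 2.0, 2.0], df_per_group=10)
        assert res.statistic == pytest.approx(0.25)
        assert res.pass_flag

    def test_dominant_group_fails(self):
        res = cochran_c_test([99.0, 0.4, 0.3, 0.3], df_per_group=10)
        assert res.statistic > 0.95
        assert not res.pass_flag

    def test_degenerate_all_zero_variances(self):
        with pytest.raises(ValueError, match="degenerate"):
            cochran_c_test([0.0, 0.0, 0.0], df_per_group=5)

    def test_critical_value_matches_simulated_null_quantile(self):
        # simulation oracle: 95th percentile of max-variance share across
        # k=4 Gaussian groups with df=10 each
        k, df, n_sim = 4, 10, 100_000
        rng = np.random.default_rng(7)
        variances = rng.chisquare(df, size=(n_sim, k))  # ~ df * sample var
        c = variances.max(axis=1) / variances.sum(axis=1)
        empirical = np.quantile(c, 0.95)
        crit = cochran_c_test([1.0] * k, df_per_group=df).critical_value
        # union-bound closed form vs Monte-Carlo quantile
        assert crit == pytest.approx(empirical, abs=0.01)


class TestLoD:
    @staticmethod
    def _panels(means, sd, reps=45, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for p, mean in enumerate(means):
            raw = rng.normal(size=reps)
            raw = (raw - raw.mean()) / raw.std(ddof=1)
            for i, v in enumerate(mean + sd * raw):
                rows.append(Measurement(f"LOW{p + 1}", "c", float(max(v, 0)),
                                        day=i % 3 + 1, replicate=i + 1,
                                        lot=f"L{i % 3 + 1}"))
        return to_frame(rows)

    def test_zero_spread_pools_return_lob(self):
        panels = self._panels([20.0, 30.0], sd=0.0)
        lod, method = estimate_lod(panels, lob=15.0)
        assert method == "classical"
        assert lod == 15.0

    def test_classical_path_matches_hand_formula(self):
        # homogeneous pools (identical sd) keep Cochran happy
        panels = self._panels([20.0, 25.0, 30.0, 40.0], sd=2.0)
        lob = 15.0
        lod, method = estimate_lod(panels, lob=lob)
        assert method == "classical"
        n, j = 45 * 4, 4
        f = n - j
        # every pool was standardized to sd exactly 2.0
        sd_pooled = 2.0
        c_p = stats.norm.ppf(0.95) / (1 - 1 / (4 * f))
        assert lod == pytest.approx(lob + c_p * sd_pooled, abs=1e-9)

    def test_variant_path_matches_exhaustive_scan(self):
        # wildly heterogeneous spreads force the Cochran test to fail
        panels = self._panels([20.0, 25.0, 30.0, 40.0], sd=0.5, seed=3)
        hi = self._panels([22.0], sd=12.0, seed=4)
        hi["pool_id"] = "LOW9"
        import pandas as pd
        panels = pd.concat([panels, hi], ignore_index=True)
        lob = 21.0
        lod, method = estimate_lod(panels, lob=lob)
        assert method == "nonparametric_variant"
        # oracle: scan pools in order of mean for >= 95% exceedance
        expected = None
        groups = sorted(panels.groupby("pool_id"),
                        key=lambda kv: kv[1]["value"].mean())
        for _, sub in groups:
            v = sub["value"].to_numpy()
            if (v > lob).mean() >= 0.95:
                expected = v.mean()
                break
        assert expected is not None
        assert lod == pytest.approx(expected, abs=1e-12)

    def test_no_qualifying_pool_raises(self):
        panels = self._panels([20.0, 22.0], sd=0.2, seed=5)
        hi = self._panels([21.0], sd=9.0, seed=6)
        hi["pool_id"] = "LOW9"
        import pandas as pd
        panels = pd.concat([panels, hi], ignore_index=True)
        with pytest.raises(ValueError, match="not reached"):
            estimate_lod(panels, lob=60.0)


class TestLoQ:
    @staticmethod
    def _pool(pool, mean, spread, lot="L1", days=2, reps=2):
        rows = []
        for d in range(1, days + 1):
            for r, v in enumerate((mean - spread, mean + spread)[:reps]):
                rows.append(Measurement(pool, "c", float(v), day=d,
                                        replicate=r + 1, lot=lot))
        return rows

    def test_minimum_qualifying_pool_mean(self):
        # CVs approx 35%, 14%, 7% for means 20/30/40: rule forces LoQ = 30
        rows = (self._pool("A", 20, 5.0) + self._pool("B", 30, 3.0)
                + self._pool("C", 40, 2.0))
        loq, per_lot = estimate_loq(to_frame(rows))
        assert loq == 30.0
        assert per_lot == {"L1": 30.0}

    def test_overall_loq_is_max_over_lots(self):
        rows = (self._pool("A", 25, 0.5, lot="LA")
                + self._pool("B", 22, 0.5, lot="LB"))
        loq, per_lot = estimate_loq(to_frame(rows))
        assert per_lot == {"LA": 25.0, "LB": 22.0}
        assert loq == 25.0

    def test_all_pools_over_threshold_is_error(self):
        rows = self._pool("A", 20, 8.0) + self._pool("B", 30, 12.0)
        with pytest.raises(ValueError, match="L1"):
            estimate_loq(to_frame(rows))

    def test_adding_a_lot_never_decreases_overall_loq(self):
        base = self._pool("A", 25, 0.5, lot="LA")
        extra = self._pool("B", 40, 0.5, lot="LB")
        loq_one, _ = estimate_loq(to_frame(base))
        loq_two, _ = estimate_loq(to_frame(base + extra))
        assert loq_two >= loq_one


def test_full_chain_orders_limits_on_simulated_panels():
    panels = to_frame(simulate_detection_panels(
        seed=11, blank_mean=10, blank_sd=3,
        low_means=[20, 25, 30, 40], low_cv=8))
    blanks = panels[panels.pool_id.str.startswith("BLK")]
    low = panels[panels.pool_id.str.startswith("LOW")]
    limits = estimate_detection_limits(blanks, low, "creatinine")
    assert limits.consistent
    assert limits.lob <= limits.lod <= limits.loq
    assert limits.loq == max(limits.per_lot_loq.values())


def test_lob_nominal_exceedance_rate():
    # Gaussian blanks: ~5% of fresh blanks exceed the estimated LoB; a
    # large estimation panel keeps the LoB's own sampling error small
    rng = np.random.default_rng(13)
    lob, _ = estimate_lob(rng.normal(10, 2, 2000), method="parametric")
    fresh = rng.normal(10, 2, 10_000)
    rate = (fresh > lob).mean()
    assert abs(rate - 0.05) < 0.015
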