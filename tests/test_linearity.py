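"""Polynomial-hierarchy linearity assessment against normal-equation oracles."""

import numpy as np
import pytest

from assayval.core import Measurement, to_frame
from assayval.linearity import (LinearityCriteria, assess_linearity,
                                degree_of_nonlinearity,
                                fit_polynomial_hierarchy)
from assayval.simulate import assigned_concentration, simulate_linearity_series


def _exact_polyfit(x, y, order):
    """Least squares by exact-rational normal equations (Fraction arithmetic)."""
    from fractions import Fraction

    xs = [Fraction(float(v)) for v in x]
    ys = [Fraction(float(v)) for v in y]
    p = order + 1
    ata = [[sum(xi ** (i + j) for xi in xs) for j in range(p)] for i in range(p)]
    atb = [sum(xi ** i * yi for xi, yi in zip(xs, ys)) for i in range(p)]
    # Gaussian elimination over the rationals
    for col in range(p):
        piv = max(range(col, p), key=lambda r: abs(ata[r][col]))
        ata[col], ata[piv] = ata[piv], ata[col]
        atb[col], atb[piv] = atb[piv], atb[col]
        for r in range(col + 1, p):
            f = ata[r][col] / ata[col][col]
            for c in range(col, p):
                ata[r][c] -= f * ata[col][c]
            atb[r] -= f * atb[col]
    beta = [Fraction(0)] * p
    for r in range(p - 1, -1, -1):
        acc = atb[r] - sum(ata[r][c] * beta[c] for c in range(r + 1, p))
        beta[r] = acc / ata[r][r]
    return [float(b) for b in beta]


def _series(values_by_level):
    rows = []
    for lev, vals in values_by_level.items():
        for i, v in enumerate(vals):
            if v is None:
                rows.append(Measurement("LIN", "c", None, status="no_result",
                                        level=lev, replicate=i + 1))
            else:
                rows.append(Measurement("LIN", "c", float(v),
                                        level=lev, replicate=i + 1))
    return to_frame(rows)


class TestPolynomialHierarchy:
    def test_exact_line_recovers_slope_and_intercept(self):
        x = np.repeat(np.arange(1.0, 8.0), 2)
        y = 2.0 * x + 1.0
        h = fit_polynomial_hierarchy(x, y)
        assert h.coefficients[1] == pytest.approx([1.0, 2.0], abs=1e-9)
        assert h.coefficients[2][2] == pytest.approx(0.0, abs=1e-8)
        assert h.nonlinear_p_values["b2"] > 0.05
        assert h.nonlinear_p_values["b3"] > 0.05

    def test_pure_quadratic_is_detected_and_fit_exactly(self):
        x = np.repeat(np.arange(1.0, 7.0), 3)
        y = x ** 2
        h = fit_polynomial_hierarchy(x, y)
        assert h.nonlinear_p_values["b2"] < 1e-6
        assert h.coefficients[2] == pytest.approx([0.0, 0.0, 1.0], abs=1e-8)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = np.repeat(np.sort(rng.uniform(1, 10, 6)), 2)
            y = rng.normal(5 + 2 * x + 0.3 * x ** 2, 0.5)
            h = fit_polynomial_hierarchy(x, y)
            for order in (1, 2, 3):
                # exact-rational normal equations as independent solver
                beta = _exact_polyfit(x, y, order)
                assert h.coefficients[order] == pytest.approx(beta, abs=1e-8)

    def test_insufficient_levels_skip_higher_orders(self):
        x = np.repeat(np.arange(1.0, 5.0), 2)  # 4 distinct levels
        h = fit_polynomial_hierarchy(x, 2 * x)
        assert 3 not in h.coefficients
        assert any("order 3" in s for s in h.skipped)


class TestAssessment:
    def test_eleven_level_exact_line_passes(self):
        assigned = {i: assigned_concentration(20, 870, 11, i) for i in range(11)}
        series = _series({i: [assigned[i]] * 3 for i in range(11)})
        v = assess_linearity(series, assigned)
        assert v.pass_flag
        assert v.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert v.degree_of_nonlinearity is None
        assert v.lol == 870.0

    def test_constructed_curvature_fails_nonlinearity_rule(self):
        # quadratic departure sized (via the closed-form OLS projection)
        # to exceed the 10% relative-deviation limit
        assigned = {i: float(10 + 10 * i) for i in range(11)}
        xs = np.array([assigned[i] for i in range(11)])
        curvature = 0.012
        truth = xs + curvature * (xs - xs.mean()) ** 2
        # oracle: project the curved response onto a straight line and
        # measure the max relative deviation of the quadratic fit from it
        v1 = np.vander(np.repeat(xs, 3), 2, increasing=True)
        beta1 = np.linalg.solve(v1.T @ v1, v1.T @ np.repeat(truth, 3))
        lin = np.vander(xs, 2, increasing=True) @ beta1
        oracle_degree = float(np.max(np.abs(truth - lin) / np.abs(lin)) * 100)
        assert oracle_degree > 10.0

        series = _series({i: [truth[i]] * 3 for i in range(11)})
        v = assess_linearity(series, assigned)
        assert not v.pass_flag
        assert any("non-linearity" in r for r in v.reasons)
        assert v.degree_of_nonlinearity == pytest.approx(oracle_degree, rel=1e-6)

    def test_four_valid_levels_fail_consecutive_minimum(self):
        assigned = {i: float(10 + 10 * i) for i in range(4)}
        series = _series({i: [assigned[i]] * 3 for i in range(4)})
        v = assess_linearity(series, assigned)
        assert not v.pass_flag
        assert any("need 5" in r for r in v.reasons)

    def test_missing_level_breaks_consecutive_run(self):
        assigned = {i: float(10 + 10 * i) for i in range(11)}
        data = {i: [assigned[i]] * 3 for i in range(11)}
        data[5] = [None, None, None]  # level lost entirely
        v = assess_linearity(_series(data), assigned)
        # the longest run is levels 6..10: still 5 consecutive, LoL = top
        assert v.lol == assigned[10]
        assert not v.pass_flag  # level 5 itself violates the missing rule

    def test_noisy_level_cv_violation_reported(self):
        assigned = {i: float(100 + 20 * i) for i in range(6)}
        data = {i: [assigned[i] * f for f in (0.8, 1.0, 1.2)] for i in range(6)}
        v = assess_linearity(_series(data), assigned)
        assert any("repeatability CV" in r for r in v.reasons)

    def test_all_levels_missing_is_error(self):
        assigned = {i: float(i + 1) for i in range(5)}
        series = _series({i: [None] for i in range(5)})
        with pytest.raises(ValueError):
            assess_linearity(series, assigned)


def test_verdict_invariant_under_unit_rescaling():
    assigned = {i: assigned_concentration(20, 870, 11, i) for i in range(11)}
    series = to_frame(simulate_linearity_series(20, 870, 11, 3, 0.0, 2.0, seed=6))
    v_umol = assess_linearity(series, assigned)
    # µmol/L -> mmol/L on the assigned axis
    assigned_mmol = {k: v / 1000.0 for k, v in assigned.items()}
    v_mmol = assess_linearity(series, assigned_mmol)
    assert v_umol.pass_flag == v_mmol.pass_flag
    assert v_umol.pearson_r == pytest.approx(v_mmol.pearson_r, abs=1e-12)
    b1_umol = v_umol.hierarchy.coefficients[1][1]
    b1_mmol = v_mmol.hierarchy.coefficients[1][1]
    assert b1_mmol == pytest.approx(1000.0 * b1_umol, rel=1e-9)


def test_nonlinearity_rejection_rate_near_nominal_smoke():
    # small smoke run; the 1,000-run nominal-rate check lives in acceptance
    assigned = {i: assigned_concentration(50, 500, 11, i) for i in range(11)}
    hits = 0
    for seed in range(60):
        s = to_frame(simulate_linearity_series(50, 500, 11, 3, 0.0, 3.0,
                                               seed=seed))
        ok = s[s.status == "ok"]
        x = ok.level.map(assigned).to_numpy(float)
        h = fit_polynomial_hierarchy(x, ok.value.to_numpy(float))
        if h.nonlinear_p_values["b2"] < 0.05:
            hits += 1
    assert hits <= 10  # ~5% nominal; allow generous binomial slack
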