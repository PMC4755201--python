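"""Conditional bias/MSE formulas and their exact constrained maximizers."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaptbias import (
    DesignSpec,
    Regime,
    conditional_bias,
    conditional_mse,
    conditional_mse_balanced,
    grid_maximize,
    maximize_conditional_bias,
    maximize_conditional_mse,
)
from conftest import random_design

INF = math.inf
zfloat = st.floats(-4, 4, allow_nan=False)


@pytest.mark.parametrize(
    "z0,z1,r0,r1,design,expected",
    [
        (0.0, 0.0, 3.0, 0.2, DesignSpec(), 0.0),
        (0.0, 1.0, 1.0, 0.0, DesignSpec(), 1.0),
        (-1.0, 1.0, INF, 0.0, DesignSpec(n=4, sigma=2.0), 1.0),
    ],
)
def test_conditional_bias_values(z0, z1, r0, r1, design, expected):
    assert conditional_bias(z0, z1, r0, r1, design) == pytest.approx(expected, abs=1e-14)


@pytest.mark.parametrize(
    "z0,z1,r0,r1,expected",
    [
        (0.0, 0.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 1.0, 0.5),
        (1.0, 2.0, 0.0, 1.0, 0.25),
    ],
)
def test_conditional_mse_values(z0, z1, r0, r1, expected):
    design = DesignSpec()
    assert conditional_mse(z0, z1, r0, r1, design) == pytest.approx(expected, abs=1e-14)


def test_negative_ratio_rejected():
    with pytest.raises(ValueError):
        conditional_bias(0.0, 0.0, -0.5, 1.0, DesignSpec())
    with pytest.raises(ValueError):
        conditional_mse(0.0, 0.0, 1.0, -2.0, DesignSpec())


@pytest.mark.parametrize(
    "y,r,expected",
    [(0.0, 0.0, 0.0), (0.0, 1.0, 0.5), (1.0, 1.0, 1.0)],
)
def test_balanced_mse_values(y, r, expected):
    assert conditional_mse_balanced(y, r, DesignSpec()) == pytest.approx(expected, abs=1e-14)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(z0=zfloat, z1=zfloat, r=st.floats(0, 100))
def test_balanced_mse_equals_general_on_diagonal(z0, z1, r):
    """Balanced reduction agrees with the general CMSE at r0 = r1, exactly."""
    design = DesignSpec(n=7.0, sigma=2.5)
    y = (z1 - z0) / math.sqrt(2.0)
    full = conditional_mse(z0, z1, r, r, design)
    red = conditional_mse_balanced(y, r, design)
    assert red == pytest.approx(full, rel=1e-12, abs=1e-12)


@settings(derandomize=True, deadline=None, max_examples=100)
@given(z0=zfloat, z1=zfloat)
def test_mse_at_zero_ratios_is_squared_bias(z0, z1):
    design = DesignSpec(n=3.0, sigma=1.7)
    b = conditional_bias(z0, z1, 0.0, 0.0, design)
    m = conditional_mse(z0, z1, 0.0, 0.0, design)
    assert m == pytest.approx(b**2, rel=1e-12, abs=1e-12)


class TestMaximizeBias:
    def test_flexible_opposite_signs(self):
        # sign rules: z1>0 -> r1=r_min, z0<0 -> r0=r_min; both stage-1 terms kept
        d = maximize_conditional_bias(-1.0, 1.0, DesignSpec())
        assert d.value == pytest.approx(2.0)
        assert (d.r0_star, d.rs_star) == (0.0, 0.0)

    def test_flexible_both_terms_suppressed(self):
        d = maximize_conditional_bias(1.0, -1.0, DesignSpec())
        assert d.value == pytest.approx(0.0, abs=1e-14)
        assert math.isinf(d.r0_star) and math.isinf(d.rs_star)

    def test_equal_negative_difference(self):
        d = maximize_conditional_bias(2.0, 1.0, DesignSpec(regime=Regime.EQUAL))
        assert d.value == pytest.approx(0.0, abs=1e-14)
        assert math.isinf(d.r0_star) and d.r0_star == d.rs_star

    def test_tie_break_smallest_ratios(self):
        d = maximize_conditional_bias(0.0, 0.0, DesignSpec(r_min=0.5, r_max=3.0))
        assert d.value == 0.0
        assert (d.r0_star, d.rs_star) == (0.5, 0.5)

    def test_fixed_control_constraint(self):
        des = DesignSpec(regime=Regime.FIXED_CONTROL, r0_fixed=1.0, r_max=2.0)
        d = maximize_conditional_bias(0.7, 0.9, des)
        assert d.r0_star == 1.0
        assert d.rs_star == 1.0  # z1 > 0 -> smallest feasible treatment ratio


class TestMaximizeMse:
    def test_equal_interior_stationary_point(self):
        # y=0: maximize 2r/(1+r)^2, max 1/2 at r=1
        d = maximize_conditional_mse(0.0, 0.0, DesignSpec(regime=Regime.EQUAL))
        assert d.value == pytest.approx(0.5)
        assert d.r0_star == pytest.approx(1.0)

    def test_equal_boundary_when_stationary_excluded(self):
        des = DesignSpec(regime=Regime.EQUAL, r_min=2.0, r_max=3.0)
        d = maximize_conditional_mse(0.0, 0.0, des)
        assert d.value == pytest.approx(4.0 / 9.0)
        assert d.r0_star == pytest.approx(2.0)

    def test_degenerate_box_returns_only_point(self):
        des = DesignSpec(r_min=0.0, r_max=0.0)
        for z0, z1 in [(1.0, 2.0), (-0.3, 0.8)]:
            d = maximize_conditional_mse(z0, z1, des)
            assert d.value == pytest.approx((z1 - z0) ** 2)


def _u_step(design, num):
    lo = 1.0 / (1.0 + min(design.r_max, 50.0))
    hi = 1.0 / (1.0 + design.r_min)
    return (hi - lo) / (num - 1)


@pytest.mark.parametrize("measure", ["bias", "mse"])
def test_maximizers_agree_with_grid_oracle(measure, rng):
    """Candidate maxima dominate and match a dense grid everywhere."""
    num = 201
    fn = maximize_conditional_bias if measure == "bias" else maximize_conditional_mse
    for _ in range(400):
        design = random_design(rng)
        z0, z1 = rng.normal(scale=2.0, size=2)
        cand = fn(z0, z1, design).value
        grid = grid_maximize(measure, z0, z1, design, num=num).value
        # the grid never beats the exact candidate set
        assert cand >= grid - 1e-9 * (1.0 + abs(grid))
        # and the candidate value is attainable: within grid resolution
        du = _u_step(design, num)
        lip = (abs(z0) + abs(z1)) if measure == "bias" else (
            2.0 * (abs(z0) + abs(z1)) ** 2 + 2.0
        )
        assert cand <= grid + 2.0 * lip * du + 1e-9


def test_maximizer_dominates_random_feasible_points(rng):
    for _ in range(300):
        design = random_design(rng, regime=Regime.FLEXIBLE)
        z0, z1 = rng.normal(scale=2.0, size=2)
        hi = min(design.r_max, 50.0)
        r0 = rng.uniform(design.r_min, hi, size=100)
        r1 = rng.uniform(design.r_min, hi, size=100)
        vb = conditional_bias(z0, z1, r0, r1, design)
        vm = conditional_mse(z0, z1, r0, r1, design)
        assert maximize_conditional_bias(z0, z1, design).value >= vb.max() - 1e-12
        assert maximize_conditional_mse(z0, z1, design).value >= vm.max() - 1e-12


def test_regime_nesting_pointwise(rng):
    """EQUAL <= TRT_GE_CTRL <= FLEXIBLE at every interim point (nested sets)."""
    for _ in range(200):
        r_min = float(rng.uniform(0, 1.5))
        r_max = float(np.inf if rng.random() < 0.3 else r_min + rng.uniform(0, 3))
        z0, z1 = rng.normal(scale=2.0, size=2)
        vals = {}
        for reg in (Regime.EQUAL, Regime.TRT_GE_CTRL, Regime.FLEXIBLE):
            des = DesignSpec(regime=reg, r_min=r_min, r_max=r_max)
            vals[reg] = (
                maximize_conditional_bias(z0, z1, des).value,
                maximize_conditional_mse(z0, z1, des).value,
            )
        for i in range(2):
            assert vals[Regime.EQUAL][i] <= vals[Regime.TRT_GE_CTRL][i] + 1e-12
            assert vals[Regime.TRT_GE_CTRL][i] <= vals[Regime.FLEXIBLE][i] + 1e-12


def test_grid_maximize_degenerate_and_empty():
    des = DesignSpec(r_min=1.0, r_max=1.0)
    d = grid_maximize("bias", 0.3, 1.1, des, num=5)
    assert d.value == pytest.approx(conditional_bias(0.3, 1.1, 1.0, 1.0, des))
    with pytest.raises(ValueError):
        grid_maximize("bias", 0.0, 0.0, des, num=0)


def test_design_validation():
    with pytest.raises(ValueError):
        DesignSpec(k=0)
    with pytest.raises(ValueError):
        DesignSpec(r_min=2.0, r_max=1.0)
    with pytest.raises(ValueError):
        DesignSpec(regime=Regime.FIXED_CONTROL)  # r0_fixed missing
    with pytest.raises(ValueError):
        DesignSpec(r0_fixed=1.0)  # only meaningful under FIXED_CONTROL
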