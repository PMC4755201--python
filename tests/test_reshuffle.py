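"""Reshuffling variant: candidate sets, maximizers, dense-grid agreement."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adaptbias import (
    ReshufflingSpec,
    maximize_reshuffle_bias,
    maximize_reshuffle_mse,
    reshuffle_bias_candidates,
    reshuffle_conditional_bias,
    reshuffle_conditional_mse,
)

SPEC = ReshufflingSpec(k=1, t=0.5)  # w_t = 2
zfloat = st.floats(-4, 4, allow_nan=False)


def test_w_t_values():
    assert SPEC.w_t == pytest.approx(2.0)
    assert ReshufflingSpec(k=3, t=0.5).w_t == pytest.approx(4.0)
    assert ReshufflingSpec(k=1, t=0.25).w_t == pytest.approx(2 * (1 / 0.25 - 1))


def test_conditional_bias_values():
    assert reshuffle_conditional_bias(0.0, 0.0, 0.3, SPEC) == 0.0
    # z0=-1, z1=1, v=1/2, w=2: sqrt(2) * (1/2 + 1/2)
    assert reshuffle_conditional_bias(-1.0, 1.0, 0.5, SPEC) == pytest.approx(math.sqrt(2.0))
    # t -> 1: no second stage, value -> (sigma/sqrt(n_g)) (z1 - z0)
    late = ReshufflingSpec(k=1, t=1 - 1e-9)
    assert reshuffle_conditional_bias(-1.0, 1.0, 0.7, late) == pytest.approx(2.0, rel=1e-6)


def test_conditional_mse_values():
    # z0=z1=0, v=1/2, w=2: (1/(t n_g)) (1/4 + 1/4) = 2 * 1/2
    assert reshuffle_conditional_mse(0.0, 0.0, 0.5, SPEC) == pytest.approx(1.0)
    late = ReshufflingSpec(k=1, t=1 - 1e-9)
    assert reshuffle_conditional_mse(1.0, 3.0, 0.2, late) == pytest.approx(4.0, rel=1e-6)


def test_v_out_of_range_rejected():
    with pytest.raises(ValueError):
        reshuffle_conditional_bias(0.0, 0.0, 1.2, SPEC)
    with pytest.raises(ValueError):
        reshuffle_conditional_mse(0.0, 0.0, -0.1, SPEC)


@settings(derandomize=True, deadline=None, max_examples=200)
@given(z0=zfloat, z1=zfloat, v=st.floats(0, 1))
def test_mse_exchange_symmetry(z0, z1, v):
    """Swapping the groups mirrors the allocation: CMSE(z0,z1,v)=CMSE(z1,z0,1-v)."""
    a = reshuffle_conditional_mse(z0, z1, v, SPEC)
    b = reshuffle_conditional_mse(z1, z0, 1.0 - v, SPEC)
    assert a == pytest.approx(b, rel=1e-12, abs=1e-12)


class TestBiasCandidates:
    def test_same_signs_boundaries_only(self):
        assert reshuffle_bias_candidates(1.0, 2.0, SPEC) == [0.0, 1.0]
        assert reshuffle_bias_candidates(-1.0, -2.0, SPEC) == [0.0, 1.0]

    def test_antidiagonal_positive_control_has_half(self):
        # z0 = -z1 > 0: quadratic degenerates, v = 1/2 maximizes
        cands = reshuffle_bias_candidates(1.0, -1.0, SPEC)
        assert 0.5 in cands
        d = maximize_reshuffle_bias(1.0, -1.0, SPEC)
        assert d.rs_star == 0.5

    def test_antidiagonal_negative_control_boundary(self):
        # z0 = -z1 < 0: boundaries coincide as the maximizer
        cands = reshuffle_bias_candidates(-1.0, 1.0, SPEC)
        assert 0.5 not in cands
        d = maximize_reshuffle_bias(-1.0, 1.0, SPEC)
        assert d.rs_star in (0.0, 1.0)
        v0 = reshuffle_conditional_bias(-1.0, 1.0, 0.0, SPEC)
        v1 = reshuffle_conditional_bias(-1.0, 1.0, 1.0, SPEC)
        assert d.value == pytest.approx(max(v0, v1))

    def test_opposite_signs_interior_roots(self):
        cands = reshuffle_bias_candidates(-0.5, 2.0, SPEC)
        interior = [v for v in cands if 0 < v < 1 and v != 0.5]
        for v in interior:  # stationary: z1 (1+vw)^2 + z0 (1+(1-v)w)^2 = 0
            w = SPEC.w_t
            assert 2.0 * (1 + v * w) ** 2 - 0.5 * (1 + (1 - v) * w) ** 2 == pytest.approx(
                0.0, abs=1e-9
            )

    def test_window_clipping_drops_outside_candidates(self):
        spec = ReshufflingSpec(k=1, t=0.5, v_max=0.5)
        cands = reshuffle_bias_candidates(1.0, -1.0, spec)
        assert cands == [0.0, 0.5]


@pytest.mark.parametrize("v_max", [1.0, 0.5])
def test_maximizers_match_dense_grid(v_max, rng):
    spec = ReshufflingSpec(k=1, t=0.5, v_max=v_max)
    vgrid = np.linspace(spec.v_min, spec.v_max, 10_001)
    for _ in range(400):
        z0, z1 = rng.normal(scale=2.0, size=2)
        gb = float(reshuffle_conditional_bias(z0, z1, vgrid, spec).max())
        cb = maximize_reshuffle_bias(z0, z1, spec).value
        assert cb == pytest.approx(gb, rel=1e-6, abs=1e-9)
        gm = float(reshuffle_conditional_mse(z0, z1, vgrid, spec).max())
        cm = maximize_reshuffle_mse(z0, z1, spec).value
        assert cm == pytest.approx(gm, rel=1e-6, abs=1e-9)


def test_maximize_mse_exchange_symmetry(rng):
    for _ in range(100):
        z0, z1 = rng.normal(scale=2.0, size=2)
        a = maximize_reshuffle_mse(z0, z1, SPEC).value
        b = maximize_reshuffle_mse(z1, z0, SPEC).value
        assert a == pytest.approx(b, rel=1e-10)


def test_restricted_window_never_exceeds_full(rng):
    half = ReshufflingSpec(k=1, t=0.5, v_max=0.5)
    for _ in range(100):
        z0, z1 = rng.normal(scale=2.0, size=2)
        assert (
            maximize_reshuffle_mse(z0, z1, half).value
            <= maximize_reshuffle_mse(z0, z1, SPEC).value + 1e-12
        )
        assert (
            maximize_reshuffle_bias(z0, z1, half).value
            <= maximize_reshuffle_bias(z0, z1, SPEC).value + 1e-12
        )


def test_spec_validation():
    with pytest.raises(ValueError):
        ReshufflingSpec(t=0.0)
    with pytest.raises(ValueError):
        ReshufflingSpec(v_min=0.6, v_max=0.5)
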