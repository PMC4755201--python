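"""Maximum bias B*, maximum MSE MSE* and RMSE* by integrating the
worst-case conditional quantities over the interim-outcome distribution.

Ratio designs are standardized by the first-stage standard error
``sqrt(2 sigma^2 / n)``; reshuffling designs by the fixed-design standard
error ``sqrt(2 sigma^2 / n_g)``.  The two bases are not comparable and
every result carries its basis explicitly.

For k > 1 the worst-case arm for the bias is the one with the largest
interim mean, so B* reduces to a 2-D integral against
``phi(z0) k Phi(zs)^(k-1) phi(zs)``.  No such reduction exists for the
MSE: the selected arm is the argmax of the worst-case conditional MSE,
and the (k+1)-dimensional expectation is computed as an outer quadrature
over z0 of E[max over k arms], the inner expectation via the discretized
distribution function of W = CMSE~(z0, Z).
"""
from __future__ import annotations

import math

from scipy import stats

from . import reshuffle as _resh
from . import worst_case as _wc
from ._quad import expect2d, expect_max
from .design import DesignSpec, MaximumResult, Measure, Regime, ReshufflingSpec

__all__ = [
    "max_bias_closed_form",
    "max_bias",
    "max_mse",
    "max_bias_reshuffle",
    "max_mse_reshuffle",
    "selection_reference",
]

_PHI0 = stats.norm.pdf(0.0)  # 1/sqrt(2 pi)


class ClosedFormUnavailable(ValueError):
    """Raised when no closed form exists for the requested design: use max_bias."""


def max_bias_closed_form(design: DesignSpec) -> MaximumResult:
    """Closed-form maximum bias for k = 1.

    EQUAL:          sqrt(2) (sigma/sqrt n) phi(0) (1/(1+r_min) - 1/(1+r_max))
    FLEXIBLE:       2 (sigma/sqrt n) phi(0) (1/(1+r_min) - 1/(1+r_max))
    FIXED_CONTROL:  (sigma/sqrt n) phi(0) (1/(1+r0) - 1/(1+r_max))

    Raises :class:`ClosedFormUnavailable` for k > 1 or TRT_GE_CTRL.
    """
    if design.k != 1:
        raise ClosedFormUnavailable("closed form only for k=1; use max_bias")
    scale = design.sigma / math.sqrt(design.n)
    if design.regime is Regime.EQUAL:
        value = math.sqrt(2.0) * scale * _PHI0 * (design.u_hi - design.u_lo)
    elif design.regime is Regime.FLEXIBLE:
        value = 2.0 * scale * _PHI0 * (design.u_hi - design.u_lo)
    elif design.regime is Regime.FIXED_CONTROL:
        u0f = 1.0 / (1.0 + design.r0_fixed)
        value = scale * _PHI0 * (u0f - design.u_lo)
    else:
        raise ClosedFormUnavailable("no closed form for TRT_GE_CTRL; use max_bias")
    basis = design.se1
    return MaximumResult(value=value, standardized=value / basis, basis=basis,
                         abs_error=0.0, n_evals=0, measure=Measure.BIAS)


def _bias_result(value_unitless, scale, basis, err_unitless, nev):
    value = scale * value_unitless
    return MaximumResult(
        value=value,
        standardized=value / basis,
        basis=basis,
        abs_error=abs(scale * err_unitless) / basis,
        n_evals=nev,
        measure=Measure.BIAS,
    )


def max_bias(design: DesignSpec, panels: int = 16, nodes: int = 20) -> MaximumResult:
    """Maximum bias by 2-D quadrature, any k >= 1 and any regime.

    The integrand's kinks lie on the axes and the diagonal z1 = z0; inner
    panel edges are placed there, so the quadrature is effectively exact.
    The error estimate is the difference from a half-resolution pass.
    """
    kern = lambda z0, z1: _wc._bias_max(z0, z1, design)[0]
    splits = lambda z0: (z0,)
    fine, nev = expect2d(kern, design.k, splits, panels=panels, nodes=nodes)
    coarse, nev2 = expect2d(kern, design.k, splits, panels=max(panels // 2, 4), nodes=nodes)
    scale = design.sigma / math.sqrt(design.n)
    return _bias_result(fine, scale, design.se1, fine - coarse, nev + nev2)


def _mse_result(value_unitless, scale, basis, err_unitless, nev):
    value = scale * value_unitless
    std = math.sqrt(max(value, 0.0)) / basis
    err_std = abs(math.sqrt(max(scale * (value_unitless + abs(err_unitless)), 0.0)) / basis - std)
    return MaximumResult(value=value, standardized=std, basis=basis,
                         abs_error=err_std, n_evals=nev, measure=Measure.MSE)


def max_mse(design: DesignSpec, panels: int = 32, nodes: int = 16,
            ngrid: int = 4000) -> MaximumResult:
    """Maximum MSE; ``standardized`` reports RMSE* over the first-stage SE.

    k = 1 uses nested panel quadrature; k > 1 the argmax-over-arms
    expectation via the discretized distribution of the worst-case
    conditional MSE (see module docstring).
    """
    kern = lambda z0, z1: _wc._mse_max(z0, z1, design)[0]
    if design.k == 1:
        splits = lambda z0: (z0, -z0)
        fine, nev = expect2d(kern, 1, splits, panels=panels, nodes=nodes)
        coarse, nev2 = expect2d(kern, 1, splits, panels=max(panels // 2, 4), nodes=nodes)
    else:
        fine, nev = expect_max(kern, design.k, ngrid=ngrid)
        coarse, nev2 = expect_max(kern, design.k, ngrid=ngrid // 2)
    scale = design.sigma**2 / design.n
    return _mse_result(fine, scale, design.se1, fine - coarse, nev + nev2)


def max_bias_reshuffle(spec: ReshufflingSpec, panels: int = 16, nodes: int = 20) -> MaximumResult:
    """Maximum bias under reshuffling; k > 1 uses the order-statistic
    reduction (the worst-case arm is the largest interim mean)."""
    kern = lambda z0, z1: _resh._bias_max(z0, z1, spec)[0]
    splits = lambda z0: (-z0,)
    fine, nev = expect2d(kern, spec.k, splits, panels=panels, nodes=nodes)
    coarse, nev2 = expect2d(kern, spec.k, splits, panels=max(panels // 2, 4), nodes=nodes)
    scale = spec.sigma / math.sqrt(spec.t * spec.n_g)
    return _bias_result(fine, scale, spec.se_fixed, fine - coarse, nev + nev2)


def max_mse_reshuffle(spec: ReshufflingSpec, panels: int = 24, nodes: int = 16,
                      ngrid: int = 4000) -> MaximumResult:
    """Maximum MSE under reshuffling; no order-statistic shortcut for k > 1
    (the worst-case arm need not have the largest interim mean)."""
    kern = lambda z0, z1: _resh._mse_max(z0, z1, spec)[0]
    if spec.k == 1:
        splits = lambda z0: (z0, -z0)
        fine, nev = expect2d(kern, 1, splits, panels=panels, nodes=nodes)
        coarse, nev2 = expect2d(kern, 1, splits, panels=max(panels // 2, 4), nodes=nodes)
    else:
        fine, nev = expect_max(kern, spec.k, ngrid=ngrid)
        coarse, nev2 = expect_max(kern, spec.k, ngrid=ngrid // 2)
    scale = spec.sigma**2 / (spec.t * spec.n_g)
    return _mse_result(fine, scale, spec.se_fixed, fine - coarse, nev + nev2)


def selection_reference(spec: ReshufflingSpec, measure: Measure | str = Measure.BIAS) -> MaximumResult:
    """Selection-only comparator for the reshuffling curves.

    An adaptive design that selects one of k arms at time t but performs a
    *fixed* balanced second stage of ``(1 - t) n_g (k + 1) / 2`` patients
    per group, i.e. a ratio design with first stage ``t n_g`` and
    ``r_min = r_max = (1 - t)(k + 1)/(2 t)``, restandardized to the
    fixed-design basis ``sqrt(2 sigma^2 / n_g)``.
    """
    measure = Measure(measure)
    r_fix = (1.0 - spec.t) * (spec.k + 1) / (2.0 * spec.t)
    design = DesignSpec(k=spec.k, n=spec.t * spec.n_g, sigma=spec.sigma,
                        r_min=r_fix, r_max=r_fix, regime=Regime.FLEXIBLE)
    res = max_bias(design) if measure is Measure.BIAS else max_mse(design)
    # res.standardized uses sqrt(2 sigma^2/(t n_g)); rescale to n_g basis
    std = res.standardized / math.sqrt(spec.t)
    return MaximumResult(value=res.value, standardized=std, basis=spec.se_fixed,
                         abs_error=res.abs_error / math.sqrt(spec.t),
                         n_evals=res.n_evals, measure=measure)
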