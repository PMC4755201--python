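"""Conditional bias and MSE of the two-stage MLE, and their worst case.

Given standardized first-stage means ``z0`` (control) and ``z1`` (selected
treatment), the pooled MLE of the treatment-control difference has

    conditional bias  CB  = (sigma/sqrt(n)) * ( z1/(1+r1) - z0/(1+r0) )
    conditional MSE   CMSE = (sigma^2/n) * [ (z1/(1+r1) - z0/(1+r0))^2
                                             + r1/(1+r1)^2 + r0/(1+r0)^2 ]

as functions of the second-to-first-stage ratios ``(r0, r1)``.  The worst
case maximizes these over the regime-feasible set of ratios.

All maximizers work in ``u = 1/(1+r)`` coordinates, where the feasible set
is a box (or wedge), the bias is linear per coordinate (so its maximum sits
at a vertex), and the MSE is quadratic per coordinate (so its stationary
points solve linear equations).  This yields the full candidate list: for a
flexible box, 4 vertices + 4 edge stationary points + 1 interior stationary
point.
"""
from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .design import DesignSpec, Measure, Regime, WorstCaseDecision

__all__ = [
    "conditional_bias",
    "conditional_mse",
    "conditional_mse_balanced",
    "maximize_conditional_bias",
    "maximize_conditional_mse",
    "grid_maximize",
]

_EPS = 1e-12


def _u_of_r(r):
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("second-to-first-stage ratios must be >= 0")
    with np.errstate(divide="ignore"):
        return np.where(np.isinf(r), 0.0, 1.0 / (1.0 + r))


def _r_of_u(u: float) -> float:
    return math.inf if u == 0.0 else 1.0 / u - 1.0


# ---------------------------------------------------------------------------
# pointwise conditional quantities


def conditional_bias(z0, z1, r0, r1, design: DesignSpec):
    """Conditional bias of the MLE difference given the interim outcome.

    ``r = inf`` is allowed: the corresponding stage-1 term vanishes.
    Returns outcome units.
    """
    u0, u1 = _u_of_r(r0), _u_of_r(r1)
    scale = design.sigma / math.sqrt(design.n)
    return scale * (np.asarray(z1, float) * u1 - np.asarray(z0, float) * u0)


def conditional_mse(z0, z1, r0, r1, design: DesignSpec):
    """Conditional MSE of the MLE difference given the interim outcome.

    The second-stage sampling variance contributes ``r/(1+r)^2`` per group,
    which is ``u (1-u)`` in ``u = 1/(1+r)`` coordinates.  Returns squared
    outcome units.
    """
    u0, u1 = _u_of_r(r0), _u_of_r(r1)
    z0, z1 = np.asarray(z0, float), np.asarray(z1, float)
    scale = design.sigma**2 / design.n
    return scale * ((z1 * u1 - z0 * u0) ** 2 + u1 * (1 - u1) + u0 * (1 - u0))


def conditional_mse_balanced(y, r, design: DesignSpec):
    """Conditional MSE under balanced second stages, ``r0 = r1 = r``.

    ``y = (z1 - z0)/sqrt(2)`` is the standardized first-stage difference.
    Equals ``conditional_mse(z0, z1, r, r, design)`` identically.
    """
    u = _u_of_r(r)
    y = np.asarray(y, float)
    return (2.0 * design.sigma**2 / design.n) * (y**2 * u**2 + u * (1 - u))


# ---------------------------------------------------------------------------
# vectorized worst-case kernels (unitless, u coordinates)


def _bias_vertices(design: DesignSpec) -> list[tuple[float, float]]:
    """Vertex candidates (u0, u1) of the feasible region for the bias."""
    lo, hi = design.u_lo, design.u_hi
    reg = design.regime
    if reg is Regime.FLEXIBLE:
        return [(lo, lo), (lo, hi), (hi, lo), (hi, hi)]
    if reg is Regime.EQUAL:
        return [(lo, lo), (hi, hi)]
    if reg is Regime.TRT_GE_CTRL:
        # wedge u1 <= u0 (i.e. r1 >= r0): three vertices
        return [(lo, lo), (hi, lo), (hi, hi)]
    # FIXED_CONTROL: u0 fixed, u1 in [u(r_max), u(r0_fixed)]
    u0f = 1.0 / (1.0 + design.r0_fixed)
    return [(u0f, lo), (u0f, u0f)]


def _bias_max(z0, z1, design: DesignSpec):
    """Worst-case unitless conditional bias, vectorized.

    Returns ``(g, u0, u1)`` arrays broadcast from ``z0, z1`` where
    ``g = max(z1 u1 - z0 u0)`` over the feasible vertices.
    """
    z0, z1 = np.broadcast_arrays(np.asarray(z0, float), np.asarray(z1, float))
    cands = _bias_vertices(design)
    vals = np.stack([z1 * u1 - z0 * u0 for u0, u1 in cands])
    idx = np.argmax(vals, axis=0)
    u0s = np.array([c[0] for c in cands])[idx]
    u1s = np.array([c[1] for c in cands])[idx]
    return np.take_along_axis(vals, idx[None], 0)[0], u0s, u1s


def _mse_point(z0, z1, u0, u1):
    return (z1 * u1 - z0 * u0) ** 2 + u1 * (1 - u1) + u0 * (1 - u0)


def _stat_u1(z0, z1, u0):
    """Stationary u1 given u0: solves (2 z1^2 - 2) u1 = 2 z0 z1 u0 - 1."""
    den = 2.0 * z1**2 - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (2.0 * z0 * z1 * u0 - 1.0) / den
    return np.where(np.abs(den) < _EPS, np.nan, out)


def _stat_u0(z0, z1, u1):
    return _stat_u1(z1, z0, u1)


def _stat_joint(z0, z1):
    """Interior joint stationary point of the CMSE, if the system is regular."""
    a11 = 2.0 * z1**2 - 2.0
    a12 = -2.0 * z0 * z1
    a22 = 2.0 * z0**2 - 2.0
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        u1 = (-a22 + a12) / det
        u0 = (-a11 + a12) / det
    bad = np.abs(det) < _EPS
    return np.where(bad, np.nan, u0), np.where(bad, np.nan, u1)


def _mse_candidates(z0, z1, design: DesignSpec):
    """Candidate (u0, u1) pairs for the worst-case CMSE, with feasibility.

    Yields broadcastable arrays; infeasible or undefined entries are NaN.
    """
    lo, hi = design.u_lo, design.u_hi
    reg = design.regime
    shape = np.broadcast(z0, z1).shape
    full = lambda v: np.broadcast_to(np.asarray(v, float), shape)

    if reg is Regime.FLEXIBLE:
        for a in (lo, hi):
            for b in (lo, hi):
                yield full(a), full(b)
            yield full(a), _stat_u1(z0, z1, a)
            yield _stat_u0(z0, z1, a), full(a)
        yield _stat_joint(z0, z1)
    elif reg is Regime.EQUAL:
        d2 = (z1 - z0) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            us = 1.0 / (2.0 - d2)  # u of r^(1) = 1 - (z1 - z0)^2
        us = np.where(d2 < 2.0, us, np.nan)
        for u in (full(lo), full(hi), us):
            yield u, u
    elif reg is Regime.TRT_GE_CTRL:
        # vertices of the wedge u1 <= u0
        for a, b in ((lo, lo), (hi, lo), (hi, hi)):
            yield full(a), full(b)
        # diagonal u0 = u1 (the balanced stationary candidate)
        d2 = (z1 - z0) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            us = np.where(d2 < 2.0, 1.0 / (2.0 - d2), np.nan)
        yield us, us
        # edges u0 = hi and u1 = lo
        yield full(hi), _stat_u1(z0, z1, hi)
        yield _stat_u0(z0, z1, lo), full(lo)
        # interior point, feasible only if u1 <= u0
        u0i, u1i = _stat_joint(z0, z1)
        ok = u1i <= u0i
        yield np.where(ok, u0i, np.nan), np.where(ok, u1i, np.nan)
    else:  # FIXED_CONTROL
        u0f = 1.0 / (1.0 + design.r0_fixed)
        yield full(u0f), full(lo)
        yield full(u0f), full(u0f)
        yield full(u0f), _stat_u1(z0, z1, u0f)


def _mse_bounds(design: DesignSpec):
    if design.regime is Regime.FIXED_CONTROL:
        u0f = 1.0 / (1.0 + design.r0_fixed)
        return design.u_lo, u0f
    return design.u_lo, design.u_hi


def _mse_max(z0, z1, design: DesignSpec):
    """Worst-case unitless conditional MSE, vectorized.

    Returns ``(g, u0, u1)`` with ``g`` the maximum of
    ``(z1 u1 - z0 u0)^2 + u1(1-u1) + u0(1-u0)`` over feasible candidates.
    """
    z0, z1 = np.broadcast_arrays(np.asarray(z0, float), np.asarray(z1, float))
    lo, hi = _mse_bounds(design)
    best = np.full(z0.shape, -np.inf)
    bu0 = np.empty(z0.shape)
    bu1 = np.empty(z0.shape)
    for u0, u1 in _mse_candidates(z0, z1, design):
        ok = (
            np.isfinite(u0)
            & np.isfinite(u1)
            & (u0 >= lo - _EPS)
            & (u0 <= hi + _EPS)
            & (u1 >= lo - _EPS)
            & (u1 <= hi + _EPS)
        )
        u0c = np.clip(u0, lo, hi)
        u1c = np.clip(u1, lo, hi)
        val = np.where(ok, _mse_point(z0, z1, u0c, u1c), -np.inf)
        upd = val > best
        best = np.where(upd, val, best)
        bu0 = np.where(upd, u0c, bu0)
        bu1 = np.where(upd, u1c, bu1)
    return best, bu0, bu1


# ---------------------------------------------------------------------------
# scalar maximizers with deterministic tie-breaking


def _tie_break(cands: Iterable[tuple[float, float, float]]) -> tuple[float, float, float]:
    """Pick max value; ties resolved to lexicographically smallest (r0, r1).

    Smaller r means larger u, so among near-ties we take the largest
    (u0, u1) pair.
    """
    cands = list(cands)
    vmax = max(v for v, _, _ in cands)
    tol = 1e-12 * (1.0 + abs(vmax))
    near = [(u0, u1) for v, u0, u1 in cands if v >= vmax - tol]
    u0, u1 = max(near)
    return vmax, u0, u1


def maximize_conditional_bias(z0: float, z1: float, design: DesignSpec) -> WorstCaseDecision:
    """Global maximizer of the conditional bias over the feasible ratios.

    The bias is linear in each ``u = 1/(1+r)``, so the maximum sits at a
    vertex of the feasible region; the sign rules of the flexible case
    (``r1 = r_min`` for ``z1 > 0`` else ``r_max``; ``r0 = r_max`` for
    ``z0 > 0`` else ``r_min``) are recovered automatically, and boundary
    inputs ``z = 0`` are handled by evaluating every vertex.
    """
    cands = [
        (z1 * u1 - z0 * u0, u0, u1) for u0, u1 in _bias_vertices(design)
    ]
    g, u0, u1 = _tie_break(cands)
    scale = design.sigma / math.sqrt(design.n)
    return WorstCaseDecision(s=1, r0_star=_r_of_u(u0), rs_star=_r_of_u(u1), value=scale * g)


def maximize_conditional_mse(z0: float, z1: float, design: DesignSpec) -> WorstCaseDecision:
    """Global maximizer of the conditional MSE over the feasible ratios.

    Enumerates vertices, per-edge stationary points, and the interior joint
    stationary point (linear solves in ``u`` coordinates); under EQUAL the
    interior candidate is ``r = 1 - (z1 - z0)^2`` clipped to the bounds.
    """
    lo, hi = _mse_bounds(design)
    z0a, z1a = np.asarray(z0, float), np.asarray(z1, float)
    cands = []
    for u0, u1 in _mse_candidates(z0a, z1a, design):
        u0, u1 = float(u0), float(u1)
        if not (math.isfinite(u0) and math.isfinite(u1)):
            continue
        if not (lo - _EPS <= u0 <= hi + _EPS and lo - _EPS <= u1 <= hi + _EPS):
            continue
        u0c, u1c = min(max(u0, lo), hi), min(max(u1, lo), hi)
        cands.append((float(_mse_point(z0a, z1a, u0c, u1c)), u0c, u1c))
    g, u0, u1 = _tie_break(cands)
    scale = design.sigma**2 / design.n
    return WorstCaseDecision(s=1, r0_star=_r_of_u(u0), rs_star=_r_of_u(u1), value=scale * g)


# ---------------------------------------------------------------------------
# brute-force oracle


def grid_maximize(
    measure: Measure | str,
    z0: float,
    z1: float,
    design: DesignSpec,
    num: int = 201,
    r_cap: float = 50.0,
) -> WorstCaseDecision:
    """Exhaustive maximum over a finite ratio grid (test oracle).

    The grid covers ``[r_min, min(r_max, r_cap)]`` plus the point
    ``r_max`` itself, so an infinite bound is represented exactly.  Grid
    points are uniform in ``u = 1/(1+r)``, where the objectives are
    polynomial, so the resolution-induced error is uniformly bounded by
    the Lipschitz constant in ``u`` times the ``u`` step.
    """
    measure = Measure(measure)
    if num < 1:
        raise ValueError("empty grid")

    def axis(lo: float, hi_: float) -> np.ndarray:
        u_lo = 1.0 / (1.0 + min(hi_, r_cap))
        u_hi = 1.0 / (1.0 + lo)
        us = np.linspace(u_lo, u_hi, num)
        vals = 1.0 / us - 1.0
        return np.unique(np.append(vals, hi_))

    reg = design.regime
    if reg is Regime.FIXED_CONTROL:
        r0s = np.array([design.r0_fixed])
        r1s = axis(design.r0_fixed, design.r_max)
    else:
        r0s = axis(design.r_min, design.r_max)
        r1s = r0s
    R0, R1 = np.meshgrid(r0s, r1s, indexing="ij")
    if reg is Regime.EQUAL:
        R0 = R1 = r0s
    feas = np.ones(np.shape(R0), bool)
    if reg is Regime.TRT_GE_CTRL:
        feas = R1 >= R0
    if measure is Measure.BIAS:
        vals = conditional_bias(z0, z1, R0, R1, design)
    else:
        vals = conditional_mse(z0, z1, R0, R1, design)
    vals = np.where(feas, vals, -np.inf)
    flat = int(np.argmax(vals))
    r0b = float(np.ravel(R0)[flat]) if np.ndim(R0) else float(R0)
    r1b = float(np.ravel(R1)[flat])
    return WorstCaseDecision(s=1, r0_star=r0b, rs_star=r1b, value=float(np.ravel(vals)[flat]))
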