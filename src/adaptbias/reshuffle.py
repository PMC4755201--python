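"""Worst-case conditional bias/MSE under fixed-total-size reshuffling.

With a fixed total of ``(k+1) n_g`` patients and an interim analysis at
fraction ``t``, the pre-planned second-stage patients are reallocated: a
fraction ``v`` to the control, ``1 - v`` to the selected treatment.  With
``w_t = (k+1)/t - (k+1)`` the conditional bias and MSE take the same
``u``-weighted form as in the ratio designs with

    u1 = 1/(1 + (1-v) w_t),   u0 = 1/(1 + v w_t),

so one scalar ``v`` controls both groups.  The bias stationarity condition
is a quadratic in ``v`` with closed-form roots; the MSE stationarity
condition reduces to a cubic whose coefficients are assembled by polynomial
arithmetic and solved numerically.
"""
from __future__ import annotations

import math

import numpy as np

from .design import ReshufflingSpec, WorstCaseDecision

__all__ = [
    "reshuffle_conditional_bias",
    "reshuffle_conditional_mse",
    "reshuffle_bias_candidates",
    "maximize_reshuffle_bias",
    "maximize_reshuffle_mse",
]

_IMAG_TOL = 1e-9


def _check_v(v):
    v = np.asarray(v, float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("allocation fraction v must lie in [0, 1]")
    return v


def _uv(v, w):
    """(u1, u0) weights for allocation fraction v."""
    return 1.0 / (1.0 + (1.0 - v) * w), 1.0 / (1.0 + v * w)


def reshuffle_conditional_bias(z0, z1, v, spec: ReshufflingSpec):
    """Conditional bias under reshuffling, outcome units."""
    v = _check_v(v)
    u1, u0 = _uv(v, spec.w_t)
    scale = spec.sigma / math.sqrt(spec.t * spec.n_g)
    return scale * (np.asarray(z1, float) * u1 - np.asarray(z0, float) * u0)


def reshuffle_conditional_mse(z0, z1, v, spec: ReshufflingSpec):
    """Conditional MSE under reshuffling, squared outcome units."""
    v = _check_v(v)
    u1, u0 = _uv(v, spec.w_t)
    z0, z1 = np.asarray(z0, float), np.asarray(z1, float)
    scale = spec.sigma**2 / (spec.t * spec.n_g)
    return scale * ((z1 * u1 - z0 * u0) ** 2 + u1 * (1 - u1) + u0 * (1 - u0))


# ---------------------------------------------------------------------------
# bias candidates


def _bias_stationary_roots(z0, z1, w):
    """Roots of z1 (1+vw)^2 + z0 (1+(1-v)w)^2 = 0, vectorized.

    These exist only when z0 and z1 have opposite signs; for
    ``z0 = -z1 > 0`` the quadratic degenerates to the single root
    ``v = 1/2``.  Closed form (equivalently obtained from the printed
    two-root formula): ``[z0(w+1) - z1 +/- (w+2) sqrt(-z0 z1)] / (w (z0+z1))``.
    """
    z0, z1 = np.asarray(z0, float), np.asarray(z1, float)
    prod = -z0 * z1
    s = z0 + z1
    with np.errstate(divide="ignore", invalid="ignore"):
        sq = np.sqrt(np.where(prod > 0, prod, np.nan))
        num = z0 * (w + 1.0) - z1
        v_plus = (num + (w + 2.0) * sq) / (w * s)
        v_minus = (num - (w + 2.0) * sq) / (w * s)
        # degenerate z0 = -z1: linear equation, root 1/2
        deg = np.abs(s) < 1e-14
        half = np.where(deg & (z0 > 0), 0.5, np.nan)
    v_plus = np.where(deg, half, v_plus)
    v_minus = np.where(deg, np.nan, v_minus)
    return v_plus, v_minus


def reshuffle_bias_candidates(z0: float, z1: float, spec: ReshufflingSpec) -> list[float]:
    """Eligible allocation-fraction candidates for the worst-case bias.

    The set {v(1), v(2) (quadratic roots, opposite signs only), v(3)=1/2
    (for z0 = -z1 > 0), v(4)=0, v(5)=1} intersected with
    [v_min, v_max]; candidates outside the window are dropped, not
    projected (the window endpoints are candidates themselves).
    """
    w = spec.w_t
    out = [spec.v_min, spec.v_max]
    vp, vm = _bias_stationary_roots(np.float64(z0), np.float64(z1), w)
    for v in (float(vp), float(vm)):
        if math.isfinite(v) and spec.v_min <= v <= spec.v_max:
            out.append(v)
    return sorted(set(out))


def maximize_reshuffle_bias(z0: float, z1: float, spec: ReshufflingSpec) -> WorstCaseDecision:
    """Worst-case conditional bias over the candidate allocation fractions."""
    cands = reshuffle_bias_candidates(z0, z1, spec)
    vals = [float(reshuffle_conditional_bias(z0, z1, v, spec)) for v in cands]
    best = max(vals)
    tol = 1e-12 * (1.0 + abs(best))
    best_v = min(v for v, val in zip(cands, vals) if val >= best - tol)
    return WorstCaseDecision(s=1, r0_star=math.nan, rs_star=best_v, value=best)


def _bias_max(z0, z1, spec: ReshufflingSpec):
    """Vectorized worst-case unitless bias; returns (g, v*)."""
    z0, z1 = np.broadcast_arrays(np.asarray(z0, float), np.asarray(z1, float))
    w = spec.w_t

    def val(v):
        u1, u0 = _uv(v, w)
        return z1 * u1 - z0 * u0

    vp, vm = _bias_stationary_roots(z0, z1, w)
    best = np.full(z0.shape, -np.inf)
    bv = np.empty(z0.shape)
    for v in (np.full(z0.shape, spec.v_min), np.full(z0.shape, spec.v_max), vp, vm):
        ok = np.isfinite(v) & (v >= spec.v_min) & (v <= spec.v_max)
        vc = np.clip(np.where(ok, v, spec.v_min), spec.v_min, spec.v_max)
        g = np.where(ok, val(vc), -np.inf)
        upd = g > best
        best = np.where(upd, g, best)
        bv = np.where(upd, vc, bv)
    return best, bv


# ---------------------------------------------------------------------------
# MSE candidates: cubic stationarity polynomial


def _poly_basis(w: float):
    """Coefficient vectors (ascending) of A, B and their products.

    A = 1 + (1-v) w, B = 1 + v w as polynomials in v.
    """
    P = np.polynomial.polynomial
    A = np.array([1.0 + w, -w])
    B = np.array([1.0, w])
    A2, B2 = P.polymul(A, A), P.polymul(B, B)
    return {
        "A": A,
        "B": B,
        "A3": P.polymul(A2, A),
        "B3": P.polymul(B2, B),
        "A2B": P.polymul(A2, B),
        "AB2": P.polymul(A, B2),
    }


def _mse_cubic_coeffs(z0, z1, basis):
    """Ascending coefficients (n, 4) of the cleared stationarity polynomial.

    p(v) = 2 z1^2 B^3 + 2 z0 z1 (A^2 B - A B^2) - 2 z0^2 A^3
           + (A - 2) B^3 - (B - 2) A^3
    (the quartic terms of the last two products cancel, leaving a cubic).
    """
    P = np.polynomial.polynomial

    def pad(p, n=4):
        out = np.zeros(n)
        out[: len(p)] = p
        return out

    A3, B3 = pad(basis["A3"]), pad(basis["B3"])
    cross = pad(basis["A2B"]) - pad(basis["AB2"])
    # z-independent part; its degree-4 terms cancel analytically
    c_full = np.zeros(5)
    p1 = P.polymul(P.polysub(basis["A"], [2.0]), basis["B3"])
    p2 = P.polymul(P.polysub(basis["B"], [2.0]), basis["A3"])
    c_full[: len(p1)] += p1
    c_full[: len(p2)] -= p2
    cpart = c_full[:4]

    z0 = np.asarray(z0, float)[..., None]
    z1 = np.asarray(z1, float)[..., None]
    return 2.0 * z1**2 * B3 + 2.0 * z0 * z1 * cross - 2.0 * z0**2 * A3 + cpart


def _real_cubic_roots(coeffs):
    """Real roots of batched cubics, ascending coeffs (n, 4) -> (n, 3).

    Uses batched companion-matrix eigenvalues; lower-degree degenerate rows
    fall back to the quadratic/linear formula.  Non-real roots (relative
    imaginary part above 1e-9) come back as NaN.
    """
    coeffs = np.atleast_2d(coeffs)
    n = coeffs.shape[0]
    roots = np.full((n, 3), np.nan)
    scale = np.max(np.abs(coeffs), axis=1)
    scale = np.where(scale == 0, 1.0, scale)
    c = coeffs / scale[:, None]
    cubic = np.abs(c[:, 3]) > 1e-12
    if np.any(cubic):
        cc = c[cubic]
        comp = np.zeros((cc.shape[0], 3, 3))
        comp[:, 1, 0] = 1.0
        comp[:, 2, 1] = 1.0
        comp[:, :, 2] = -cc[:, :3] / cc[:, 3:4]
        ev = np.linalg.eigvals(comp)
        ok = np.abs(ev.imag) <= _IMAG_TOL * (1.0 + np.abs(ev))
        roots[cubic] = np.where(ok, ev.real, np.nan)
    quad = ~cubic & (np.abs(c[:, 2]) > 1e-12)
    if np.any(quad):
        a, b, c0 = c[quad, 2], c[quad, 1], c[quad, 0]
        disc = b**2 - 4 * a * c0
        with np.errstate(invalid="ignore"):
            sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        roots[quad, 0] = (-b + sq) / (2 * a)
        roots[quad, 1] = (-b - sq) / (2 * a)
    lin = ~cubic & ~quad & (np.abs(c[:, 1]) > 1e-12)
    if np.any(lin):
        roots[lin, 0] = -c[lin, 0] / c[lin, 1]
    return roots


def _mse_max(z0, z1, spec: ReshufflingSpec):
    """Vectorized worst-case unitless CMSE under reshuffling; (g, v*)."""
    z0, z1 = np.broadcast_arrays(np.asarray(z0, float), np.asarray(z1, float))
    shape = z0.shape
    w = spec.w_t

    def val(v):
        u1, u0 = _uv(v, w)
        return (z1.ravel() * u1 - z0.ravel() * u0) ** 2 + u1 * (1 - u1) + u0 * (1 - u0)

    basis = _poly_basis(w)
    coeffs = _mse_cubic_coeffs(z0.ravel(), z1.ravel(), basis)
    roots = _real_cubic_roots(coeffs)

    best = np.full(z0.size, -np.inf)
    bv = np.empty(z0.size)
    cand = [np.full(z0.size, spec.v_min), np.full(z0.size, spec.v_max)]
    cand += [roots[:, i] for i in range(roots.shape[1])]
    for v in cand:
        ok = np.isfinite(v) & (v >= spec.v_min) & (v <= spec.v_max)
        vc = np.clip(np.where(ok, v, spec.v_min), spec.v_min, spec.v_max)
        g = np.where(ok, val(vc), -np.inf)
        upd = g > best
        best = np.where(upd, g, best)
        bv = np.where(upd, vc, bv)
    return best.reshape(shape), bv.reshape(shape)


def maximize_reshuffle_mse(z0: float, z1: float, spec: ReshufflingSpec) -> WorstCaseDecision:
    """Worst-case conditional MSE over cubic-root and boundary candidates."""
    g, v = _mse_max(np.float64(z0), np.float64(z1), spec)
    scale = spec.sigma**2 / (spec.t * spec.n_g)
    return WorstCaseDecision(s=1, r0_star=math.nan, rs_star=float(v), value=scale * float(g))
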