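"""Monte-Carlo trial simulator: the independent oracle for the integrals.

Simulates the full two-stage adaptive trial at the sufficient-statistic
level: stage-1 group means are drawn for all k+1 groups, the adaptation
rule (arm selection + second-stage allocation) is applied to the
standardized interim means, and the pooled MLE error is formed.  Writing
``u = 1/(1+r)``, the error of the treatment-control MLE difference is

    e = (sigma/sqrt(n1)) [ zs*u1 + sqrt(u1(1-u1)) eps_s
                           - z0*u0 - sqrt(u0(1-u0)) eps_0 ]

because the stage-2 contribution ``(1-u)(xbar2 - mu)`` is normal with
variance ``u (1-u) sigma^2 / n1``.  This handles r = 0 and r = inf exactly
(the stage-2 variance term vanishes) and avoids integer rounding of the
stage-2 sizes, matching the ratio-based theory.

The true means ``mu`` cancel exactly in ``e``; worst-case bias and MSE are
therefore invariant, bitwise, under a common shift of all arms.
"""
from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np

from . import reshuffle as _resh
from . import worst_case as _wc
from .design import DesignSpec, Regime, ReshufflingSpec
from .integrate import max_bias, max_bias_reshuffle, max_mse, max_mse_reshuffle

__all__ = ["Rule", "SimulationSpec", "SimulationResult", "simulate_trials",
           "mc_vs_integral_report"]


class Rule(str, enum.Enum):
    WORST_CASE_BIAS = "worst_case_bias"
    WORST_CASE_MSE = "worst_case_mse"


AnyDesign = Union[DesignSpec, ReshufflingSpec]


@dataclass(frozen=True)
class SimulationSpec:
    """Replication settings for the trial simulator.

    ``rule`` is a :class:`Rule` or a callable implementing a user
    adaptation rule.  For a ratio design the callable maps
    ``(z0, zmat)`` with ``zmat`` of shape (n_sims, k) to arrays
    ``(s, r0, rs)`` (arm indices 0-based, ratios); for a reshuffling design
    to ``(s, v)``.
    """

    design: AnyDesign
    mu: Sequence[float]
    n_sims: int
    seed: int
    rule: Rule | Callable = Rule.WORST_CASE_BIAS

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        mu = np.asarray(self.mu, float)
        if mu.shape != (self.design.k + 1,):
            raise ValueError(f"mu must have length k+1={self.design.k + 1}")
        object.__setattr__(self, "mu", mu)
        if not callable(self.rule):
            object.__setattr__(self, "rule", Rule(self.rule))


@dataclass(frozen=True)
class SimulationResult:
    bias_hat: float
    mse_hat: float
    bias_se: float
    mse_se: float
    n_sims: int
    seed: int

    def to_json(self, spec: SimulationSpec | None = None) -> str:
        rec = {k: getattr(self, k) for k in
               ("bias_hat", "mse_hat", "bias_se", "mse_se", "n_sims", "seed")}
        if spec is not None:
            d = spec.design
            rec["design"] = {f: getattr(d, f) for f in d.__dataclass_fields__}
            rec["design"]["type"] = type(d).__name__
            rec["mu"] = list(np.asarray(spec.mu, float))
            rec["rule"] = spec.rule.value if isinstance(spec.rule, Rule) else "user"
        return json.dumps(rec, default=str)


def _ratio_feasible(design: DesignSpec, r0, rs):
    lo, hi = design.r_min, design.r_max
    ok = (rs >= lo) & (rs <= hi)
    reg = design.regime
    if reg is Regime.FIXED_CONTROL:
        ok &= r0 == design.r0_fixed
        ok &= rs >= design.r0_fixed
    else:
        ok &= (r0 >= lo) & (r0 <= hi)
        if reg is Regime.EQUAL:
            ok &= r0 == rs
        elif reg is Regime.TRT_GE_CTRL:
            ok &= rs >= r0
    return ok


def _u_of_r(r):
    with np.errstate(divide="ignore"):
        return np.where(np.isinf(r), 0.0, 1.0 / (1.0 + np.asarray(r, float)))


def simulate_trials(spec: SimulationSpec) -> SimulationResult:
    """Run the two-stage trial ``n_sims`` times and estimate bias and MSE.

    Uses a counter-based Philox generator keyed by ``seed`` with a fixed
    draw layout (one matrix of standard normals), so results are bitwise
    reproducible.
    """
    design = spec.design
    k, n = design.k, spec.n_sims
    rng = np.random.Generator(np.random.Philox(key=spec.seed))
    Z = rng.standard_normal((n, k + 3))
    z0 = Z[:, 0]
    zmat = Z[:, 1 : k + 1]
    eps0, epss = Z[:, k + 1], Z[:, k + 2]

    reshuffling = isinstance(design, ReshufflingSpec)
    if callable(spec.rule) and not isinstance(spec.rule, Rule):
        out = spec.rule(z0, zmat)
        if reshuffling:
            s, v = (np.asarray(a) for a in out)
            bad = ~((v >= design.v_min) & (v <= design.v_max))
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(f"user rule returned infeasible allocation at replicate {i}: v={v[i]}")
            u1, u0 = _resh._uv(v, design.w_t)
        else:
            s, r0, rs = (np.asarray(a) for a in out)
            bad = ~_ratio_feasible(design, r0, rs)
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(
                    f"user rule returned infeasible allocation at replicate {i}: "
                    f"r0={r0[i]}, rs={rs[i]}"
                )
            u0, u1 = _u_of_r(r0), _u_of_r(rs)
        s = s.astype(int)
        if np.any((s < 0) | (s >= k)):
            i = int(np.argmax((s < 0) | (s >= k)))
            raise ValueError(f"user rule selected invalid arm at replicate {i}: s={s[i]}")
        zs = zmat[np.arange(n), s]
    elif spec.rule is Rule.WORST_CASE_BIAS:
        # worst-case arm = largest interim mean (order-statistic reduction)
        s = np.argmax(zmat, axis=1)
        zs = zmat[np.arange(n), s]
        if reshuffling:
            _, v = _resh._bias_max(z0, zs, design)
            u1, u0 = _resh._uv(v, design.w_t)
        else:
            _, u0, u1 = _wc._bias_max(z0, zs, design)
    else:  # WORST_CASE_MSE: arm with the largest worst-case conditional MSE
        if reshuffling:
            g = np.stack([_resh._mse_max(z0, zmat[:, i], design)[0] for i in range(k)])
        else:
            g = np.stack([_wc._mse_max(z0, zmat[:, i], design)[0] for i in range(k)])
        s = np.argmax(g, axis=0)
        zs = zmat[np.arange(n), s]
        if reshuffling:
            _, v = _resh._mse_max(z0, zs, design)
            u1, u0 = _resh._uv(v, design.w_t)
        else:
            _, u0, u1 = _wc._mse_max(z0, zs, design)

    n1 = design.t * design.n_g if reshuffling else design.n
    scale = design.sigma / math.sqrt(n1)
    e = scale * (
        zs * u1 + np.sqrt(u1 * (1 - u1)) * epss - z0 * u0 - np.sqrt(u0 * (1 - u0)) * eps0
    )
    bias_hat = float(e.mean())
    mse_hat = float((e**2).mean())
    bias_se = float(e.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    mse_se = float((e**2).std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return SimulationResult(bias_hat, mse_hat, bias_se, mse_se, n, spec.seed)


def mc_vs_integral_report(
    design: AnyDesign,
    rule: Rule | str = Rule.WORST_CASE_BIAS,
    n_sims: int = 10**6,
    seed: int = 0,
) -> dict:
    """Compare the quadrature value with the Monte-Carlo estimate.

    Returns a record with the standardized integral, the MC estimate and
    its standard error (on the outcome scale used by the integral), and the
    z-score of the discrepancy.
    """
    rule = Rule(rule)
    reshuffling = isinstance(design, ReshufflingSpec)
    if rule is Rule.WORST_CASE_BIAS:
        res = max_bias_reshuffle(design) if reshuffling else max_bias(design)
    else:
        res = max_mse_reshuffle(design) if reshuffling else max_mse(design)
    sim = simulate_trials(
        SimulationSpec(design=design, mu=np.zeros(design.k + 1),
                       n_sims=n_sims, seed=seed, rule=rule)
    )
    if rule is Rule.WORST_CASE_BIAS:
        est, se = sim.bias_hat, sim.bias_se
    else:
        est, se = sim.mse_hat, sim.mse_se
    return {
        "measure": "bias" if rule is Rule.WORST_CASE_BIAS else "mse",
        "integral_value": res.value,
        "integral_standardized": res.standardized,
        "mc_estimate": est,
        "mc_se": se,
        "z_score": (est - res.value) / se,
        "n_sims": n_sims,
        "seed": seed,
    }
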