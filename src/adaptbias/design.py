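"""Domain types for two-stage adaptive designs with treatment selection.

A trial starts with ``k`` experimental arms and a common control, all with
first-stage per-group size ``n`` and known outcome standard deviation
``sigma``.  At an interim analysis one arm ``s`` and the control continue;
their second-stage sizes are ``r_s * n`` and ``r_0 * n`` where the
second-to-first-stage ratios may depend on the interim data, subject to a
constraint regime.  The reshuffling variant instead fixes the total sample
size and reallocates the pre-planned second-stage patients between the
selected arm and the control.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Regime",
    "Measure",
    "DesignSpec",
    "ReshufflingSpec",
    "InterimOutcome",
    "WorstCaseDecision",
    "MaximumResult",
]


class Regime(str, enum.Enum):
    """Constraint regime for the second-stage allocation ratios.

    FLEXIBLE
        ``r_0`` and ``r_s`` vary independently in ``[r_min, r_max]``.
    EQUAL
        Balanced second stage, ``r_s = r_0``.
    TRT_GE_CTRL
        Treatment group at least as large as control, ``r_s >= r_0``.
    FIXED_CONTROL
        ``r_0`` fixed at ``r0_fixed``; ``r_s`` varies in
        ``[r0_fixed, r_max]``.
    """

    FLEXIBLE = "flexible"
    EQUAL = "equal"
    TRT_GE_CTRL = "trt_ge_ctrl"
    FIXED_CONTROL = "fixed_control"


class Measure(str, enum.Enum):
    BIAS = "bias"
    MSE = "mse"


def _as_regime(value) -> Regime:
    if isinstance(value, Regime):
        return value
    return Regime(str(value).lower().replace("-", "_"))


@dataclass(frozen=True)
class DesignSpec:
    """An adaptive design with ratio-based sample-size reassessment.

    Parameters
    ----------
    k : int
        Number of experimental arms (>= 1).
    n : float
        First-stage per-group sample size (> 0).
    sigma : float
        Known outcome standard deviation (> 0).
    r_min, r_max : float
        Bounds for the second-to-first-stage ratios; ``0 <= r_min <= r_max``
        and ``r_max`` may be ``inf``.
    regime : Regime
        Constraint regime for ``(r_0, r_s)``.
    r0_fixed : float, optional
        Control ratio, required iff ``regime`` is ``FIXED_CONTROL``.
    """

    k: int = 1
    n: float = 1.0
    sigma: float = 1.0
    r_min: float = 0.0
    r_max: float = math.inf
    regime: Regime = Regime.FLEXIBLE
    r0_fixed: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "regime", _as_regime(self.regime))
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError(f"k must be an integer >= 1, got {self.k}")
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.r_min <= self.r_max:
            raise ValueError("need 0 <= r_min <= r_max")
        if self.regime is Regime.FIXED_CONTROL:
            if self.r0_fixed is None or self.r0_fixed < 0:
                raise ValueError("FIXED_CONTROL requires r0_fixed >= 0")
            if self.r0_fixed > self.r_max:
                raise ValueError("need r0_fixed <= r_max")
        elif self.r0_fixed is not None:
            raise ValueError("r0_fixed is only meaningful under FIXED_CONTROL")

    # 1/(1+r) coordinates used throughout the maximizers: u is strictly
    # decreasing in r, maps [0, inf] onto [0, 1], and turns the variance
    # term r/(1+r)^2 into u(1-u).
    @property
    def u_lo(self) -> float:
        return 0.0 if math.isinf(self.r_max) else 1.0 / (1.0 + self.r_max)

    @property
    def u_hi(self) -> float:
        return 1.0 / (1.0 + self.r_min)

    @property
    def se1(self) -> float:
        """First-stage standard error of the treatment-control difference."""
        return math.sqrt(2.0 * self.sigma**2 / self.n)


@dataclass(frozen=True)
class ReshufflingSpec:
    """Fixed-total-sample-size design with second-stage reallocation.

    A per-group total of ``n_g`` patients is pre-planned over both stages
    for each of the ``k + 1`` groups; the interim analysis happens after a
    fraction ``t`` of them.  The pre-planned second-stage patients,
    ``(1 - t) * n_g * (k + 1)`` in total, are then split: a fraction ``v``
    to the control and ``1 - v`` to the selected treatment, with
    ``v_min <= v <= v_max``.
    """

    k: int = 1
    n_g: float = 1.0
    t: float = 0.5
    sigma: float = 1.0
    v_min: float = 0.0
    v_max: float = 1.0

    def __post_init__(self):
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError(f"k must be an integer >= 1, got {self.k}")
        if self.n_g <= 0:
            raise ValueError("n_g must be > 0")
        if not 0.0 < self.t < 1.0:
            raise ValueError("t must lie strictly between 0 and 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.v_min < self.v_max <= 1.0:
            raise ValueError("need 0 <= v_min < v_max <= 1")

    @property
    def w_t(self) -> float:
        """Second-stage weight constant ``(k + 1)/t - (k + 1)``.

        For ``k = 1`` this is the classical ``2 (1/t - 1)``.
        """
        return (self.k + 1) / self.t - (self.k + 1)

    @property
    def se_fixed(self) -> float:
        """Standard error of a fixed design with per-group size ``n_g``."""
        return math.sqrt(2.0 * self.sigma**2 / self.n_g)


@dataclass(frozen=True)
class InterimOutcome:
    """Standardized first-stage means: control ``z0`` and treatments ``z``."""

    z0: float
    z: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "z", np.atleast_1d(np.asarray(self.z, float)))

    def validate(self, design) -> None:
        if self.z.shape != (design.k,):
            raise ValueError(
                f"interim outcome has {self.z.size} treatment means, design has k={design.k}"
            )


@dataclass(frozen=True)
class WorstCaseDecision:
    """Worst-case arm selection and second-stage allocation.

    ``value`` is the achieved conditional bias (outcome units) or
    conditional MSE (outcome units squared).  For ratio designs the
    allocation is ``(r0_star, rs_star)``; reshuffling designs store the
    allocation fraction in ``rs_star`` (with ``r0_star = 1 - rs_star``
    meaningless there, set to ``nan``).
    """

    s: int
    r0_star: float
    rs_star: float
    value: float


@dataclass(frozen=True)
class MaximumResult:
    """An integrated maximum bias or MSE.

    ``value`` is in outcome units (bias) or squared outcome units (MSE);
    ``standardized`` is ``value / basis`` for a bias and
    ``sqrt(value) / basis`` for an MSE, where ``basis`` is the two-group
    standard error used for reporting.  ``abs_error`` is a numerical-error
    estimate for ``standardized`` obtained from a coarser recomputation.
    """

    value: float
    standardized: float
    basis: float
    abs_error: float = math.nan
    n_evals: int = 0
    measure: Measure = Measure.BIAS

    def __post_init__(self):
        if not math.isnan(self.abs_error) and self.abs_error < 0:
            raise ValueError("abs_error must be >= 0")
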