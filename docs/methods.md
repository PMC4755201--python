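# Methods

## Model and worst-case principle

Outcomes are `X_{i,j,l} ~ N(μ_i, σ²)` with known `σ`; `i = 0` is control,
`i = 1…k` experimental; `j` indexes the stage. Stage 1 is balanced with
`n` per group. After the interim analysis one arm `s` and control continue
with second-to-first-stage ratios `r_s, r_0 ∈ [r_min, r_max]` (possibly
`∞`), chosen by an unspecified data-driven rule. The estimand is
`μ_s − μ_0`, estimated by the pooled MLE difference. Because the
conditional distribution of the stage-2 means given the interim data is
known, the conditional bias and conditional MSE given the standardized
interim means are available in closed form, and the worst case over all
adaptation rules is obtained by maximizing pointwise and integrating over
the interim distribution. The resulting `B*` and `MSE*` are upper bounds
over the whole rule class and do not depend on the true means: the
conditional quantities are functions of the standardized deviations only.

## Exact maximization in u-coordinates

All maximizers substitute `u = 1/(1+r) ∈ [0, 1]`, which maps the feasible
ratio interval to a box (`u = 0` represents `r = ∞` exactly, so infinite
bounds need no truncation), and turns the variance term `r/(1+r)²` into
`u(1−u)`.

* **Bias.** `z_1 u_1 − z_0 u_0` is linear per coordinate, so the maximum
  sits at a vertex of the feasible box (flexible: 4 vertices), wedge
  (`r_1 ≥ r_0`: 3 vertices), diagonal (balanced: 2 points) or segment
  (fixed control: 2 points). Vertex enumeration reproduces the sign rules
  (`r̃_1 = r_min` for `z_1 > 0`, etc.) and handles `z = 0` boundaries by
  construction.
* **MSE.** The objective is quadratic per coordinate; stationarity is a
  *linear* equation per coordinate and a 2×2 linear system jointly. The
  candidate set is therefore: 4 vertices, 4 edge stationary points, 1
  interior joint stationary point (9 candidates for the flexible box).
  Under balancing the interior candidate reduces to
  `r = 1 − (z_1 − z_0)²`; under a fixed control only the treatment edge
  remains (3 candidates). Singular systems (e.g. `|z| = 1` making an edge
  objective linear) return no interior candidate; the boundaries cover
  those cases.
* **Reshuffling.** One fraction `v` drives both groups through
  `u_1 = 1/(1+(1−v)w_t)`, `u_0 = 1/(1+v w_t)`, `w_t = (k+1)/t − (k+1)`.
  Bias stationarity is the quadratic `z_1(1+vw)² + z_0(1+(1−v)w)² = 0`
  with closed-form roots (existing only for opposite signs; `v = 1/2`
  in the degenerate antidiagonal case `z_0 = −z_1 > 0`); boundary
  candidates `v_min, v_max` complete the set. MSE stationarity clears
  denominators to a cubic (the quartic terms cancel analytically); its
  coefficients are assembled by polynomial arithmetic and solved by
  batched companion-matrix eigenvalues, discarding roots with relative
  imaginary part above 1e-9. Candidates outside `[v_min, v_max]` are
  dropped, not projected.

Ties among maximizing allocations are broken toward the lexicographically
smallest `(r_0, r_1)` (smallest `v`), making decisions deterministic.

A brute-force oracle (`grid_maximize`) evaluates the objective on a grid
uniform in `u` covering `[r_min, min(r_max, 50)] ∪ {r_max}`; uniformity in
`u` gives a resolution-independent Lipschitz error bound. Property tests
assert the candidate maximizers dominate the grid everywhere and exceed it
by no more than the grid's resolution tolerance, on 10⁴ random
configurations.

## Integration

Interim outcomes are integrated over `|z| ≤ 8` (normal tail mass
< 1e-15) with nested panel Gauss–Legendre rules. The worst-case
conditional quantities are piecewise smooth with kinks on known lines
(the axes, the diagonal `z_1 = z_0`, the antidiagonal `z_1 = −z_0`);
inner panel edges are placed at those locations for each outer node, so
panel integrands are smooth and convergence is spectral. Defaults: 16
outer panels × 20 nodes for bias (closed-form agreement ≈ 1e-14), 32 × 16
for k = 1 MSE. Every result carries an `abs_error` estimate from a
half-resolution recomputation and the evaluation count.

For `k > 1` the worst-case arm for the *bias* is the one with the largest
interim mean (the maximized conditional bias is increasing in `z_s` under
every regime), so `B*_k` is a 2-D integral against
`φ(z_0)·kΦ(z_s)^{k−1}φ(z_s)`. No such reduction exists for the MSE (the
worst-case conditional MSE is not monotone in `z_s`), so the
(k+1)-dimensional expectation is computed as an outer quadrature over
`z_0` of `E[max_i W_i]` with `W = g(z_0, Z)`, evaluated from the
discretized distribution of `W` on a 4000-cell grid of `z` with exact
normal cell masses: sorting the values and cumulating masses gives
`E[max of k] = Σ w_(j) (C_j^k − C_{j−1}^k)`. The scheme is fully
deterministic with `O(h²)` accuracy; halving the grid supplies the error
estimate. The same machinery serves the reshuffling MSE for `k > 1`,
whose selection is likewise an argmax of the worst-case conditional MSE.

Closed forms used for validation and fast paths (k = 1): flexible
`2(σ/√n)φ(0)(1/(1+r_min) − 1/(1+r_max))`; balanced, the same with `√2`
in place of 2; fixed control `(σ/√n)φ(0)(1/(1+r_0) − 1/(1+r_max))`. At
`r_min = r_max` the design is non-adaptive: `B* = 0` and
`MSE* = 2σ²/(n(1+r))` exactly.

## Standardization

Ratio designs are standardized by the first-stage standard error
`√(2σ²/n)`; reshuffling designs by the fixed-design error `√(2σ²/n_g)`.
The two bases are not numerically comparable and every `MaximumResult`
carries its basis explicitly. `selection_reference` maps a reshuffling
configuration to its selection-only comparator — interim selection at `t`
with a fixed balanced second stage of `(1−t)n_g(k+1)/2` per group,
i.e. a ratio design with first stage `t·n_g` and
`r_min = r_max = (1−t)(k+1)/(2t)` — and rescales its standardized value
by `1/√t` onto the `n_g` basis.

## Monte-Carlo simulator

The simulator is the independent oracle: it draws stage-1 data for all
`k+1` groups, applies the selection and allocation rule at the realized
interim outcome, draws the stage-2 contribution, and averages the MLE
error. It works at the sufficient-statistic level: with `u = 1/(1+r)`,
the stage-2 contribution to the estimator error is
`(1−u)(x̄_2 − μ) ~ N(0, u(1−u)σ²/n)`, which is exact for fractional
`r·n` and degenerates correctly at `r = 0` and `r = ∞` (variance zero).
Ratios are treated as real numbers throughout — the theory is stated in
ratios, and integer rounding would bias the oracle. Randomness comes from
one counter-based Philox stream keyed by the seed with a fixed draw
layout, so runs are bitwise reproducible; the error expression never
materializes `μ + deviation`, so a common shift of all true means changes
nothing, bitwise — the simulator inherits the theory's mean-independence
exactly rather than approximately. What the simulator does *not* emulate:
patient-level data, unknown variance, non-normal endpoints, or
accrual/timing logistics; agreement between simulator and quadrature
therefore validates the mathematics of the worst case, not the behavior
of any real trial's adaptation rule.

User-supplied rules are supported (vectorized callable from interim
outcomes to arm and allocation); infeasible output fails hard naming the
first violating replicate.

## Problem sizes and tolerances

Default quadrature sizes (above) resolve third-decimal reported values
with two or more orders of magnitude to spare; the acceptance script runs
all headline quantities in seconds. Monte-Carlo validation uses 10⁶
replicates, giving standard errors around 1e-3 on standardized scales,
and accepts |z| ≤ 3. Printed-value comparisons use ±0.005 (half-ULP of
3-decimal printing) plus the reported integration error.

## Known limitations and open points

* Two cells of the published summary table are internally inconsistent
  (the balanced-regime bias for k = 4 at `r_min = 0` printed as 0.882,
  and for k = 5 at `r_min = 1` printed as 0.488); the recomputed values
  (0.822, 0.448) respect the regime-nesting bounds the printed ones
  violate and look like digit transpositions. The table reproduction
  annotates these cells instead of asserting them. A third mild deviation
  (k = 5 fixed-control RMSE at `r_min = 1`: printed 0.926, recomputed
  0.929) is reported with its deviation.
* The textual sequence "0.08, 0.16, 0.32" for `r_max = 2` is ambiguous in
  its source context between the balanced and the `r_1 ≥ r_0` constraint;
  recomputation resolves it to `r_1 ≥ r_0` (0.080/0.161/0.321; balanced
  gives 0.066/0.133/0.266).
* Selection of more than one treatment, unknown variance, and
  bias-adjusted estimators are out of scope.
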