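# adaptbias

Worst-case bias and mean squared error of the maximum-likelihood estimate
in two-stage adaptive clinical trials with interim treatment selection and
data-driven sample-size reassessment.

## The problem

A two-stage trial starts with `k` experimental arms and a common control,
`n` patients per group in stage 1, normally distributed outcomes with known
standard deviation `σ`. At an interim analysis one arm `s` and the control
continue, with second-stage sizes `r_s·n` and `r_0·n` chosen *based on the
interim data*. The pooled MLE of the treatment effect,

    x̄_i = (x̄_{i,1} + r_i x̄_{i,2}) / (1 + r_i),    i = 0, s,

is biased when the ratios depend on the data — and in practice the
adaptation rule is not pre-specified, so the bias of any particular rule is
unknowable in advance. This package computes the *worst case* over all
rules: at each interim outcome `(z_0, z_1, …, z_k)` (standardized stage-1
means) it maximizes the conditional bias

    CB = (σ/√n) · ( z_s/(1+r_s) − z_0/(1+r_0) )

or the conditional MSE

    CMSE = (σ²/n) · [ ( z_s/(1+r_s) − z_0/(1+r_0) )² + r_s/(1+r_s)² + r_0/(1+r_0)² ]

over the feasible ratios, and integrates over the interim distribution to
obtain the maximum bias `B*` and maximum MSE `MSE*`. These bound every
adaptation rule in the feasible class and are independent of the unknown
true means. Feasibility regimes: fully flexible ratios in
`[r_min, r_max]`, balanced (`r_s = r_0`), treatment-at-least-control
(`r_s ≥ r_0`), and fixed control (`r_0` preset). A *reshuffling* variant
fixes the total sample size and reallocates the pre-planned second-stage
patients between the selected arm (fraction `1−v`) and control (`v`).

Results are reported standardized: `B*/√(2σ²/n)` and `√MSE*/√(2σ²/n)`
(first-stage standard error of the effect estimate), or `√(2σ²/n_g)` for
reshuffling designs.

## Worked example

```python
from adaptbias import DesignSpec, ReshufflingSpec, max_bias, max_mse, max_bias_reshuffle

# one arm vs control, completely unrestricted reassessment
print(max_bias(DesignSpec()).standardized)          # 0.5642
print(max_mse(DesignSpec()).standardized)           # 1.1292  (RMSE*)

# two arms, selection + flexible reassessment
print(max_bias(DesignSpec(k=2)).standardized)       # 0.7637
print(max_mse(DesignSpec(k=2)).standardized)        # 1.3198

# fixed total size, interim halfway, free reallocation
print(max_bias_reshuffle(ReshufflingSpec(k=1, t=0.5)).standardized)  # 0.4022
```

The first number says: with one arm and no restriction on the
second-to-first-stage ratios, the most adversarial reassessment rule
biases the MLE upward by 0.564 first-stage standard errors on average.
Adding a second arm raises this to 0.764 (selection bias compounds
reassessment bias). The worst-case RMSE of 1.129 means the trial can end
up *less* precise than a first-stage-only analysis; bounding
`r_min ≥ 0.5` brings RMSE* down to 0.86 (see `examples/worst_case_mse.py`).

The `examples/` scripts each run one capability end to end; the `adaptbias`
CLI exposes the same computations (`compute`, `table1`, `curves`,
`simulate`, `validate`):

```
adaptbias compute --measure bias --k 1 --regime flexible --rmin 0 --rmax inf
standardized bias: 0.5642  (basis 1.41421, est. error 2.4e-16)
```

Every maximizer is verified against a brute-force grid oracle, every
integral against a closed form where one exists, and everything against an
independent Monte-Carlo trial simulator (`adaptbias.simulate_trials`).

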