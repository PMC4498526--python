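# Methods

## The model

`lhda` couples feature weighting and classification through a single local
learning rule. Samples `x_i ∈ R^D` carry class labels `y_i ∈ {1..c}`; a
nonnegative weight vector `w` defines the metric

    d(p, q) = wᵀ|p − q| = Σ_j w_j |p_j − q_j|,

a feature-weighted Manhattan distance. For a query `x` and a class `j`, the
*local hyperplane* is the convex hull of the query's `k` nearest same-class
neighbors `h_1..h_k` (columns of `H`), and the hull distance is

    d(x, LH_j(x|w)) = min_α wᵀ|x − Hα|,   Σα_i = 1, α ≥ 0.

The classifier (FHKNN — feature-weighted hyperplane k-nearest-neighbor)
assigns `c* = argmin_j d(x, LH_j(x|w))`, ties to the smaller label. The hull
interpolates between neighbors, which makes the rule far less sensitive to
sampling sparsity than plain k-NN while remaining local.

Weights are learned by minimizing a smoothed leave-one-out margin error with
an l1 penalty:

    J(w) = (1/N) Σ_i S_β(R(x_i)) + λ‖w‖₁,   w > 0,

where `R(x) = d(x, NH) / d(x, NM)` is the ratio of distances to the
nearest-hit hyperplane (own class, query excluded) and the nearest-miss
hyperplane (the closest foreign-class hyperplane), and
`S_β(z) = 1/(1 + e^{β(1−z)})` is a sigmoid surrogate for the 0/1 error
indicator (`R < 1` means the hyperplane rule classifies the sample
correctly). Substituting `w = v²` elementwise makes nonnegativity structural
and turns the l1 penalty into the smooth `λ‖v‖₂²`; the gradient is

    ∂J/∂v = (2λ·1 + (2/N) Σ_i γ_i g_i) ⊗ v,
    γ_i = S′_β(R_i)·R_i,
    g_i = |x_i − s_NH|/d(x_i, NH) − |x_i − s_NM|/d(x_i, NM),

with `s` the hull projection points and `⊗` the Hadamard product. Note
`wᵀg_i = 0`: the margin force only redistributes weight *between* features;
the penalty alone controls the overall scale. Since margin ratios are
invariant to rescaling `w`, classification depends only on the weight
profile, not its scale.

## The spanning-coefficient solve

The hull projection is a linear program. Rather than the primal with one
slack per feature (D slack rows), we solve the dual

    max uᵀx − s   s.t.  Hᵀu ≤ s·1,  −w ≤ u ≤ w,

which has only `k` general constraints; the optimal multipliers of those
constraints are exactly `α` (their sum is forced to 1 by stationarity in
`s`). A bounded-variable revised simplex specialized to this structure keeps
a `k×k` basis regardless of `D` (~100 µs at D≈200 versus ~2 ms for a general
LP solver — the difference between hours and minutes over a full benchmark).
Every solve is certified by strong duality: the primal value recomputed from
the returned `α` must meet the dual objective to 1e-7 relative, otherwise
the solve is redone with SciPy's HiGHS interface. Returned coefficients are
clipped to `[0,1]` and renormalized to absorb round-off (simplex feasibility
tolerance 1e-9).

A `surrogate` mode is also provided: minimizing the linear upper bound
`αᵀz`, `z_i = wᵀ|x − h_i|`, whose optimum is the vertex at the single
nearest neighbor (ties split uniformly). It reduces the hyperplane to 1-NN
geometry and exists for comparison; `exact` is the default because it
realizes the stated hull objective.

## Optimization loop

Learning alternates, EM-style:

1. **Estimation.** Under the current `w`, fit every training sample's
   nearest-hit hyperplane (own class, self excluded — leave-one-out
   semantics) and nearest-miss hyperplane (minimum-distance foreign class).
2. **Descent.** One gradient step on `v` with backtracking: starting from
   `η`, the step is halved (≤30 times) until the objective does not
   increase. Candidates are pre-screened on the frozen-hyperplane surface
   (cheap, no refitting) and then accepted against the full objective with
   hyperplanes re-estimated at the candidate; the accepted candidate's
   re-estimation is reused as the next round's step 1, so a successful
   iteration costs exactly one estimation pass.

Where the nearest hyperplanes and their coefficients are unique, the
frozen-coefficient gradient equals the gradient of the full objective (the
distances are minima over `α`, so derivatives pass through the minimizers —
Danskin's theorem); the loop is therefore a plain monotone descent and the
recorded objective trace never increases. Iteration stops when
`‖w^{t+1} − w^t‖₁ < tol`, when no acceptable step remains (a stall at a
local minimum), or at `max_iter`.

Degenerate margins are regularized: `d(x,NM) = 0` with `d(x,NH) > 0` sets
`R = ratio_cap` (default 1e6; the sigmoid saturates, so the exact cap value
is immaterial); both distances zero sets `R = 1`; a zero distance inside
`g_i` drops that ratio term (the sample contributes no direction there).
These rules keep the objective finite on data with duplicated points.

## Initialization

Descent from a uniform start (`w_j = 1/D`) is reliable when informative
features are a sizable fraction of the metric. With hundreds of irrelevant
dimensions, however, the initial metric is noise-dominated, and the
multiplicative update (`∂J/∂v ∝ v`) lets chance local structure in noise
features self-reinforce: in spiral benchmarks with ≥100 noise features, one
or both informative features collapsed to zero weight in most runs across a
wide hyperparameter range, the classic failure mode of hard
nearest-neighbor Relief-family updates. The informative basin itself is wide
and stable — a run started from any weakly informative metric recovers both
spiral features and suppresses ≥99 % of noise weights.

The default initialization therefore seeds the search by univariate
screening: each feature is scored by its own 1-NN leave-one-out accuracy
`a_j` (scale-invariant, deterministic, O(ND log N)), and

    w_j^{(0)} ∝ ((a_j − a_0)_+ + 0.02)²,

with `a_0` the majority-class frequency (chance level). The floor of 0.02
keeps every feature weakly alive so signal visible only in combination can
still be picked up during descent; with no feature beating chance the start
degenerates to near-uniform. `init="uniform"` restores the plain start.

## Defaults

| parameter | default | role |
|---|---|---|
| `k` | 3 | neighbors per hull; small k keeps hulls local and cost `O(ckND)` per estimation pass |
| `λ` | 1.0 | l1 pressure; sets the fixed-point scale of `w` (profile is scale-invariant) |
| `β` | 5.0 | sigmoid slope; moderate values keep gradients informative away from `R = 1` |
| `η` | 0.1 | initial step; backtracking removes sensitivity |
| `max_iter` | 100 | alternation rounds (typically converges in 15–40) |
| `tol` | 1e-4 | l1 change of `w` declaring convergence |
| `ratio_cap` | 1e6 | degenerate-margin substitute |
| `τ` | 0.01 | relative weight cut defining the selected feature subset |

The learner is deterministic given data and configuration; randomness enters
only through data generation and CV fold assignment, both seeded.

## Synthetic benchmarks

`generate_fermat_spiral` draws class 1 as `(r cos θ, r sin θ)` with
`r = √θ`, `θ ~ U[0.25, 4π]` (two interleaved windings, the origin excluded),
and class 2 as the point-reflected arm with independent angles; the two
informative features are standardized to zero mean and unit variance so
signal and noise share scale, and `noise_dim` i.i.d. standard-normal columns
are appended. Labels are thus fully determined by the first two features,
through purely local structure: no univariate statistic separates the
classes strongly (the screening scores of the informative features are only
~0.63 against a 0.5 chance level), which is exactly what makes the benchmark
a stress test for feature weighting. Unweighted 1-NN on the two informative
features alone exceeds 95 % leave-one-out accuracy at 200 samples per class.

What the spiral does *not* emulate about real expression data: correlated
noise, batch structure, heavy-tailed measurement error, and class imbalance.
Passing it demonstrates that the learner can find a purely local
low-dimensional signal under many irrelevant dimensions — not that it is
robust to those artifacts. `generate_blobs` provides trivially separable
Gaussian fixtures for unit tests.

## Evaluation protocols

`loocv` and `kfold_cv` score the classifier at *fixed* weights (learn once,
then cross-validate the classifier in the weighted space — the protocol
appropriate for comparing classifiers given a weighting).
`inner_loocv_loop` re-runs the entire weight learning inside every split,
so no held-out information touches training — the leakage-free protocol for
reporting feature-selection performance. 10-fold splits are stratified by
default (per-class fold sizes differ by at most one); an unstratified mode
exists, and with `folds = N` it coincides with leave-one-out. The t-test
prefilter for two-class expression matrices uses the pooled-variance Student
form by default (Welch optional), drops features with zero variance in both
classes (statistic undefined), and keeps `p < 0.05`.

## Benchmark scale and observed behavior

The packaged benchmark (`lhda.benchmark`, also driven by
`scripts/acceptance.py`) uses 200 samples per class and noise dimensions
{0, 50, 100, 200} with three seeded repeats — sizes at which the full
learn-then-cross-validate protocol completes in about a minute on one CPU.
At these sizes the learner converges in 15–40 alternation rounds, recovers
both informative spiral features in the top weights, drives ≥99 % of noise
features below 1 % of the maximum weight, and holds 93–98 % cross-validated
accuracy across the noise grid.

## Known limitations

- The objective is piecewise smooth and non-convex; descent finds a local
  minimum, and the screening start is a heuristic for landing in the right
  basin, not a guarantee. Signals invisible both univariately and to the
  initial metric can still be missed.
- Hull distances in `exact` mode can degenerate (distance 0) when a query
  lies inside a neighbor hull, which is increasingly common as the effective
  metric dimension drops; the margin rules handle this, but k should stay
  small relative to class sizes.
- Prediction cost is `O(ckND)` per query plus `c` small LP solves; there is
  no index structure, so very large training sets are slow.
- Multi-class nearest-miss uses the minimum over foreign classes; with many
  classes and small k this can make margins optimistic.
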