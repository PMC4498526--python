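# lhda — local hyperplane-based discriminant analysis

Joint feature weighting and classification for high-dimensional labeled
data, the regime typical of gene-expression studies: thousands of features,
tens to hundreds of samples, and only a small subset of features carrying
class signal. Instead of selecting features first and classifying second,
`lhda` learns a per-feature weight vector *by* optimizing the classifier it
will be used with, so the two tasks share one objective.

## The method

Distances are feature-weighted Manhattan: `d(p,q) = Σ_j w_j |p_j − q_j|`.
The classifier (FHKNN) assigns a sample to the class whose *local
hyperplane* — the convex hull of the sample's k nearest neighbors within
that class — is closest:

    c* = argmin_j  min_α  wᵀ|x − H_j α|,    Σα = 1, α ≥ 0,

where the columns of `H_j` are the k nearest class-`j` neighbors of `x`.
The inner minimization is solved exactly as a small linear program.

The weights minimize a sigmoid-smoothed, l1-penalized leave-one-out margin
error

    J(w) = (1/N) Σ_i S_β(R(x_i)) + λ‖w‖₁,    R(x) = d(x, NH) / d(x, NM),

with NH the nearest-hit hyperplane (own class, sample excluded), NM the
nearest-miss hyperplane (closest foreign class), and
`S_β(z) = 1/(1+e^{β(1−z)})`. Writing `w = v²` keeps weights nonnegative and
makes the penalty smooth; gradient descent on `v` alternates with
hyperplane re-estimation. Features that do not help the margin are driven
to (near-)zero weight, so the learned vector doubles as a feature selector
(`w_j ≥ τ·max w`, τ = 0.01 by default). See `docs/methods.md` for the full
account, including the dual-simplex hull solver and the univariate screening
initialization.

## Worked example

The stress test for any feature weighter: two classes that are perfectly
predictable from two features with purely *local* structure (interleaved
spiral arms), buried under 100 irrelevant standard-normal features.

```python
import numpy as np
from lhda import LHDAConfig, SpiralConfig, fit, generate_fermat_spiral, loocv

data = generate_fermat_spiral(SpiralConfig(n_per_class=200, noise_dim=100, seed=7))
model, trace = fit(data)

w = model.weights.normalized().w
print(f"converged in {trace.iterations_run} iterations "
      f"(final objective {trace.objective_values[-1]:.4f})")
print(f"selected {model.n_selected} of {data.n_features} features")
for j in np.argsort(-w)[:5]:
    print(f"  {data.feature_names[j]:12s} {w[j]:.4f}")
result = loocv(data, model.weights, model.config)
print(f"LOOCV accuracy in the learned metric: {result.accuracy:.4f}")
```

Output:

```
converged in 16 iterations (final objective 0.0674)
selected 3 of 102 features
  spiral_2     0.5095
  spiral_1     0.4820
  noise_0064   0.0079
  noise_0087   0.0005
  noise_0080   0.0001
LOOCV accuracy in the learned metric: 0.9750
```

The two informative features absorb 99 % of the weight mass, the hundred
noise features are driven to (near-)zero, and the hyperplane classifier in
the learned metric recovers the spiral labels almost perfectly — for
comparison, unweighted 1-NN on the raw 102-dimensional data is close to
chance.

## Command line

Every step is also available as a subcommand over CSV/TSV tables
(samples in rows with a `label` column, or gene-by-sample matrices via
`--genes-in-rows`):

```
lhda simulate --kind spiral --noise-dim 100 --seed 7 --out spiral.csv
lhda filter   --data expr.csv --alpha 0.05 --out filtered.csv   # t-test prefilter
lhda fit      --data spiral.csv --weights-out weights.tsv --trace-out trace.json
lhda cv       --data spiral.csv --scheme loo --weights weights.tsv --out cv.json
lhda cv       --data spiral.csv --scheme inner-loo --out cv.json  # leakage-free
lhda predict  --train train.csv --test test.csv --weights weights.tsv --out pred.tsv
```

All outputs are byte-reproducible given the same inputs and seeds.

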