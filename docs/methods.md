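# Methods

## Effect-size measures

All seven measures operate on an r×c table of joint counts `a_ij` with
margins `a_i.`, `a_.j` and total `n`. Four are functions of the Pearson
chi-square statistic χ² = Σ (O−E)²/E against the independence model
(φ² = χ²/n):

| measure | formula | range |
|---|---|---|
| Cohen's w | √(χ²/n) = φ | ≥ 0, can exceed 1 beyond 2 levels of association |
| Cramér's V | √(φ²/min(r−1, c−1)) | [0, 1] |
| Tschuprow's T | √(φ²/√((r−1)(c−1))) | [0, 1] on square tables |
| Pearson's c | √(χ²/(χ²+n)) | [0, 1), strictly < 1 |

Three are proportional-reduction-in-error / information measures, all
directional with the **row variable as the dependent variable by default**
(`direction="column-given-row"` transposes):

- **Goodman–Kruskal τ** — (n Σ_ij a_ij²/a_.j − Σ_i a_i.²)/(n² − Σ_i a_i.²),
  the reduction in classification-error probability using squared cell
  probabilities. Equals φ² on every 2×2 table.
- **Theil's U** — (H(X) − H(X|Y))/H(X) = I(X;Y)/H(X); invariant to the
  logarithm base because it is a ratio; 0·log 0 ≡ 0.
- **Goodman–Kruskal λ** — (E₁ − E₂)/E₁ with E₁ = n − max_i a_i. and
  E₂ = Σ_j (a_.j − max_i a_ij), the reduction in modal-prediction errors.

Numerical conventions: cells with zero expected count are skipped in the
chi-square and Cohen's-w sums (they carry no information and arise on
fixed-shape resamples with empty levels); τ, U and λ raise on a constant
dependent variable, and `compute_all` converts those errors to NaN flags so
that the assembly step can drop and count the affected repeat.

Tschuprow's T is implemented in its standard fourth-root form — the form
consistent with the numerical identities T = w/((r−1)(c−1))^¼ used in the
test suite. Cramér's V defaults to the plain formula; `bias_correct=True`
switches to the Bergsma small-sample correction
(φ²_corr = max(0, φ² − (r−1)(c−1)/(n−1)) with correspondingly shrunk
effective dimensions), which some software reports by default; the two can
differ visibly at n = 1000 for small effects, so both are exposed.

## Intuitionistic fuzzy c-means

Objects x_k are clustered by iterating

1. μ_ik = [Σ_j (d(x_k,v_i)/d(x_k,v_j))^(2/(f−1))]⁻¹ (Euclidean d;
   a zero-distance object gets crisp membership);
2. u_ik = (1 − μ_ik^α)^(1/α), μ*_ik = 1 − u_ik;
3. v_i = Σ_k (μ*_ik)^f x_k / Σ_k (μ*_ik)^f;

until the maximum absolute center displacement drops below ε.

Parameter defaults and rationale:

- **f = 2** (fuzziness): the conventional choice, also the stated setting
  of the reference analyses.
- **α = 2** (intuitionistic exponent): no canonical value exists; 2 is the
  common choice in the IFCM literature. α = 1 makes μ* = μ exactly
  (classical FCM), which the tests use as an internal oracle.
- **ε = 1e−6**, max 100 iterations: the center-displacement criterion is
  scale-appropriate for effect sizes living in [0, 1]; on 7 objects the
  loop converges in a few dozen iterations.
- **Initialization**: c distinct data points sampled without replacement
  under the seed — reproducible, scale-free, and immune to the
  duplicate-center singularity of the membership formula (duplicate centers
  raise rather than silently degenerate).
- **No feature scaling**: all seven measures already share the [0, 1]
  scale; rescaling would distort exactly the magnitude separation the
  clustering is meant to detect.

## Meta functions, scoring, selection

Weights per cluster are normalised adjusted memberships
w_ij = μ*_ij/Σ_j μ*_ij, so each function is a convex combination of the
method series and its predictions are bounded by the per-repeat min/max
method values. The truth series is the per-repeat mean of the seven
methods; MAPE = mean |y−ŷ|/y and bias = mean (ŷ−y)/y (an absolute-bias
variant sits behind a flag). Repeats with zero truth are dropped from both
scores with a logged count. Ties in MAPE break toward the lower function
index, and ties in the cluster-count search toward the smaller c. The
cluster count is searched over 2…5 by default (any sub-range of [1, 7] is
accepted).

For a raw categorical dataset the pipeline bootstraps t resamples (same
size as the data, with replacement, fixed level sets so the table shape
never changes), derives weights from the resamples, and applies the best
function's weights to the measures of the **full** dataset to produce the
combined effect size — resampling informs the weights, not the final
measure values.

## Synthetic data generator

`SimulationSpec` draws independent multinomial tables: N = 1000
observations per table over uniform cell probabilities, t = 1000 repeats by
default (2×3, 2×4 and 3×4 are the standard shapes). Uniform independence
reproduces the regime the method is usually demonstrated in — small,
noisy effect sizes with the chi-square family an order of magnitude above
the PRE family. A user-supplied joint probability matrix can inject real
association. What the generator does *not* emulate: dependence between
repeats, structural zeros, ordinal structure, or the covariate makeup of
any real dataset — so passing tests demonstrate the estimator's mechanics
and internal consistency, not its behaviour on any particular study.

## Known limitations and measured behaviour

- Under independent-uniform generation the cross-method mean falls in the
  gap between the two magnitude families, so the best function — which
  concentrates its weights within one cluster — tracks the mean's
  *fluctuations* well (its MAPE is roughly a third of the worst single
  measure's) but carries a systematic relative offset of about +30% at
  2×3, n = 1000. A convex combination can only be unbiased against the
  cross-method mean if its weights straddle the families, which
  cluster-concentrated weights by construction rarely do. The acceptance
  suite states the ±10% bias bound and records this as a failing check
  rather than weakening it.
- The seven series are strongly collinear within the chi-square family
  (V, c, w differ only by smooth monotone maps), so cluster contents are
  stable but the split of T between families can vary with the seed.
- MAPE is undefined when the truth is exactly zero; such repeats are
  dropped, which can bias scores on data where all measures vanish often.
- IFCM inherits FCM's sensitivity to outlying method series; a
  possibilistic variant is out of scope.

## Problem sizes used in the checks

The test suite runs simulations at t ≤ 200 repeats and n ≤ 6000
observations per table, and the end-to-end pipeline check uses 2×3 tables
at n = 1000, t = 200 — sizes chosen so the full suite completes in a few
seconds while leaving the multinomial noise regime identical to the
full-scale t = 1000 setting (per-repeat measures do not depend on t; only
score variance does).
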