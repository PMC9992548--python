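# Methods

`panelnet` implements a two-wave symptom-network analysis for ordinal
questionnaire items — 7 anxiety items (GAD-7), 7 depression items (short
CES-D) and 3 loneliness items (UCLA-3) — together with a synthetic panel
generator that provides ground truth for every estimator in the package.

## Generative model for synthetic panels

Each item is a discretized latent Gaussian score. For wave 1 the latent
vector is drawn from `N(0, Sigma_1)` where `Sigma_1` is the correlation
matrix implied by a precision matrix `K = I − W`: `W` places the configured
partial correlation on every structural edge, so with a unit diagonal the
implied partial correlation at an edge equals its configured weight exactly
(`pcor_ij = −K_ij / sqrt(K_ii K_jj)`).

Within each community the structural edges form a **ring** (each item tied
to its two neighbours; complete for communities of three or fewer items).
This is a deliberate choice: a complete 7-clique of equal partial
correlations is only positive definite below `1/6 ≈ 0.167`, so the default
weight of 0.25 forces a sparse within-community topology. Four bridge edges
(default weight 0.15) connect the communities, patterned on the
anxiety–depression and depression–loneliness overlaps this kind of data
shows.

Wave 2 is `z2 = A z1 + e` with `A = B^T`, where `B[s, t]` is the
standardized effect of item `s` at T1 on item `t` at T2 (autoregressive
effects on the diagonal, default 0.3; three default cross paths
`L3→A1 = 0.35`, `D6→L2 = 0.30`, `L2→A1 = 0.25`). Two residual designs are
available:

* `t2_structure="matched"` (default): the noise covariance is chosen so the
  marginal T2 latent correlation matrix equals the one implied by the
  configured T2 network. The T2 contemporaneous network then has known
  ground truth, at the cost of *correlated* T2 residuals.
* `t2_structure="diagonal_residual"`: `z2 = A z1 +` independent noise
  topping each variance up to 1. This is the data-generating process the
  cross-lagged path model assumes, so fit indices are meaningful under it;
  the T2 network is then whatever the cross paths induce.

Both designs keep all latent variances at 1, so configured coefficients are
standardized. Items are discretized at the standard-normal quartile cuts
shifted by `threshold_skew` (default 0.8): anxiety and loneliness items pile
up in the lowest category, reverse-keyed depression items in the highest,
mimicking the heavy floor/ceiling skew of these instruments in
general-population surveys.

**What the generator does not emulate:** polytomous items with
item-specific loadings, missingness, attrition between waves (panels are
fully paired), and the unequal wave sizes of real longitudinal surveys.
Passing recovery tests therefore show the estimators work under the model's
own assumptions, not that real survey data satisfy them.

## Preprocessing

*Descriptives* report mean, SD (n−1), moment-based skewness and excess
kurtosis, and each item's Pearson correlation with the sum of the remaining
items of its own instrument (item-rest correlation).

*Goldbricker screening* flags redundant item pairs: for every pair with
`|r| ≥ 0.50`, each remaining item yields a Steiger test of the two dependent
correlations (back-transformed average correlation in the covariance term);
a pair is redundant when fewer than 25% of these tests are significant at
`alpha = 0.01`. The alpha/threshold defaults are the conventional ones; they
are recorded in the report metadata because nothing in the analysis design
fixes them.

*Nonparanormal transform*: each column's mid-ranks `r` map to
`Phi^{-1}(r/(n+1))`, Winsorized at `delta_n = 1/(4 n^{1/4} sqrt(pi log n))`,
then centred and scaled to unit variance. Mid-ranks keep the transform well
defined and symmetric on heavily tied ordinal data; the transform is
strictly monotone in the ranks and idempotent.

## Contemporaneous network estimation

The estimator is the graphical lasso on the correlation matrix of the
transformed scores: maximize `log det K − tr(SK) − lambda Σ_{i≠j}|K_ij|`
(diagonal unpenalized; duality-gap tolerance 1e−4, at most 1000 sweeps, and
the inner per-column lasso solved to 1e−7 so the gap estimate is reliable).
Edges are the implied partial correlations.

The penalty comes from a **rotation criterion**: each of 20 rotations
permutes the rows of every column independently, destroying all cross-column
dependence while preserving marginals; `lambda*` is the mean over rotations
of the maximum absolute off-diagonal correlation, and the smallest value of
a 100-point log-spaced path (down to `0.01 lambda_max`) at or above
`lambda*` is used. The mean-of-maxima aggregation sits at the centre of the
null-max distribution, so roughly half of null datasets let one borderline
edge through — the specificity guarantee is "at most a couple of spurious
edges", not "none". EBIC (`gamma = 0.5`) is available as an alternative
criterion. Because the rotation selection does not depend on the path fits,
`estimate_network` fits the glasso only at the selected penalty; the full
path is exposed separately for diagnostics.

Regularization shrinks edge weights toward zero: a generating partial
correlation of 0.25 is estimated near 0.17 at `n = 2000`. Bootstrap
confidence intervals therefore cover the estimator's own population value,
not the generating weight.

## Communities

*Spinglass*: signed Potts Hamiltonian with configuration null models for
the positive and negative layers, minimized by simulated annealing
(geometric cooling 1 → 0.01, factor 0.99, resolution `gamma = 1`), restarted
500 times by default with the minimum-Hamiltonian configuration returned and
ties broken toward the lexicographically smallest canonical labeling. The
annealer runs per connected component (it cannot handle disconnected
graphs); two-node components are solved directly.

*Weighted clique percolation*: all k-cliques of the nonzero-edge graph are
enumerated (defaults `k = 4`, intensity `I = 0.08`); a clique is retained
when the geometric mean of its **absolute** edge weights reaches `I`
(estimated networks here are almost entirely positive; a signed variant
would only change pathological cases); retained cliques sharing `k−1` nodes
chain into communities. Nodes in two or more communities are the percolated
bridge symptoms. Note the default ring truth has no 4-cliques at all — on
synthetic data `k = 3` is the informative setting, while `k = 4` matches the
analysis design for dense empirical networks.

## Centralities

One-step expected influence is the signed sum of a node's edge weights;
two-step adds the edge-weighted one-step values of its neighbours
(`EI2 = EI1 + W·EI1`). Bridge variants restrict the same sums to edges that
cross the spinglass partition of the same wave. Predictability is the
in-sample `R^2` of each node's transformed scores regressed on its
nonzero-edge neighbours (empty neighbourhood gives 0; collinear neighbour
blocks fall back to the minimum-norm fit with a warning).

## Network comparison

The permutation test pools the rows of the two groups, reassigns group
labels, and re-estimates both networks per permutation with the full
pipeline (transform, rotation selection, glasso). Statistics: maximum
absolute edge difference `M` and absolute global-strength difference `S`,
with `p = (1 + #{perm ≥ obs}) / (1 + n_perm)` so Monte-Carlo p-values are
never zero. Per-edge and per-node expected-influence differences are tested
the same way, Holm-corrected within each family. With 200 permutations the
type-I error of `M` at the 5% level is ≈ 3–4% on calibration simulations
(slightly conservative, as expected for a maximum statistic).

Caveat: comparing two waves of the *same* participants violates the
independent-groups exchangeability the permutation scheme assumes; the test
is implemented as the published design applies it, and paired-panel p-values
should be read descriptively.

## Cross-lagged panel network

Every T2 item is lasso-regressed on all 17 T1 items (nonparanormal scores,
standardized, so coefficients are standardized betas). Each outcome gets a
100-value log-spaced path from its own `lambda_max` down to
`1e−4 lambda_max`; 10-fold cross-validation (folds seeded) picks the lambda
with minimum mean squared error. The minimum-CV rule is deliberately kept as
the default because it is the canonical rule for this analysis; it is
liberal — at `n = 4000` it retains dozens of tiny (< 0.04) spurious paths
alongside the true ones. `selection_rule="1se"` gives the conservative
alternative (largest lambda within one standard error of the minimum),
which screens pure-noise outcomes to exactly zero.

In-prediction is `1 − SSE/SST` of the selected model per T2 item (the
deviance-ratio convention, guaranteed in `[0, 1]` in sample). Out-prediction
sums a T1 item's squared outgoing coefficients, excluding the autoregressive
path by default — the statistic targets cross-node influence; a flag
includes it.

Fit indices refit the selected structure without penalty by maximum
likelihood on the 2p-variable covariance: T1 block saturated, retained paths
free, T2 residuals uncorrelated — under which the ML estimates are
equation-wise OLS on each outcome's support. `chi^2 = (n−1) F_ML`; CFI/TLI
against the independence baseline (CFI and TLI capped at 1, and defined as 1
when the baseline chi-square does not exceed its degrees of freedom); RMSEA
`= sqrt(max(chi^2 − df, 0)/(df (n−1)))`; SRMR is the RMS standardized
residual over the lower triangle. Under the matched T2 design the
uncorrelated-residual assumption is wrong by construction and CFI lands
around 0.7 — a feature worth knowing: fit indices only certify the path
model when the residual structure is plausible.

## Stability

Edge CIs: nonparametric row bootstrap, the full estimator re-run per
replicate (penalty reselected — the intervals measure end-to-end
variability), percentile 95% intervals. The CS coefficient drops
`q ∈ {0.05, …, 0.75}` of the cases, re-estimates on each subsample, and
correlates the statistic vector (edge weights or EI1) with the full-sample
vector; CS is the largest tested `q` at which ≥ 95% of replicates correlate
≥ 0.7, and 0 if none. The grid and the 0.7/95% rule are the field-standard
definition.

## Problem sizes and seeds

Default analyses run at `n = 2000–4000` simulated participants; calibration
simulations use 200 replications of 200 permutations at `n = 500–1000` per
group, and stability runs 50–100 replicates per drop proportion — sizes at
which every recovery and calibration check is comfortably inside its
tolerance on a single CPU. All randomness flows from explicit seeds: the
pipeline derives per-stage seeds from one global seed via fixed documented
offsets, and igraph's annealer is seeded through the standard-library RNG
per restart.

## Known limitations

* Within-community ground-truth topology is a ring; dense empirical
  networks will exercise the clique-percolation machinery more than the
  default synthetic truth does.
* The Goldbricker alpha/threshold and the spinglass annealing schedule are
  conventional defaults, not design-fixed values.
* The rotation criterion's aggregation (mean of per-rotation maxima) is a
  documented choice; implementations differ and the selected penalty —
  hence network density — shifts accordingly.
* The independent-groups comparison test is anti-conservative on paired
  panels (shared participants).
* Minimum-CV lasso selection retains many near-zero cross-lagged paths;
  use the 1-SE rule when a sparse temporal network is the goal.
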