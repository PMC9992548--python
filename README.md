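# panelnet

Two-wave psychopathology symptom-network analysis for ordinal questionnaire
data: regularized partial-correlation networks, overlapping communities,
bridge centralities, permutation network comparison, stability analysis, and
a lasso cross-lagged panel network — with a synthetic two-wave panel
generator that provides known ground truth for every estimator.

## Who this is for

Researchers analysing anxiety (GAD-7), depression (CES-D) and loneliness
(UCLA-3) items — or any small set of ordinal symptom items — across two
survey waves, who want the full pipeline reproducible and testable without
access to restricted microdata. Real panel data load from a wide CSV
(`A1_T1 … L3_T2`, one row per participant); the bundled generator stands in
for them everywhere else.

## The models

**Contemporaneous network.** Items are Gaussianized by the nonparanormal
(shrunken-ECDF) transform; a Gaussian graphical model is estimated by the
graphical lasso, maximizing

```
log det K − tr(SK) − λ Σ_{i≠j} |K_ij|
```

with the penalty chosen by a rotation criterion (mean over 20
column-permutations of the maximal spurious correlation). Edge weights are
partial correlations `w_ij = −K_ij / √(K_ii K_jj)`. Communities come from
signed spinglass annealing (500 restarts, minimum Hamiltonian) and — for
overlap — weighted clique percolation (`k = 4`, intensity `I = 0.08`), where
a clique's intensity is the geometric mean of its edge weights. Node-level
summaries are one/two-step expected influence (`EI1(i) = Σ_j w_ij`,
`EI2 = EI1 + W·EI1`), their bridge variants restricted to cross-community
edges, and predictability (variance explained by network neighbours). Two
networks are compared by a permutation test on the maximum edge difference
and global strength (Holm-corrected edge tests), and stability by
case-dropping CS coefficients.

**Temporal network.** Each T2 item is lasso-regressed on all T1 items over a
100-value λ path with 10-fold CV (minimum-CV rule); nonzero coefficients
form a directed cross-lagged network with autoregressive effects on the
diagonal, summarized by in-prediction (R² of each T2 item) and
out-prediction (sum of squared outgoing betas), plus ML fit indices
(χ², CFI, TLI, RMSEA, SRMR) for the selected path structure.

## Worked example

```bash
python examples/02_estimate_network.py
```

```
selected penalty lambda = 0.0670
edges estimated nonzero: 24 (generating network has 21)
true edges recovered:    100% with 100% sign agreement
edge-weight correlation with truth: 0.980
false-edge rate among true zeros:   0.026
```

The generating network (17 items, three communities, within-community
partial correlations of 0.25 and four 0.15 bridges) is recovered at
`n = 2000`: every true edge survives with the correct sign, weights
correlate 0.98 with the truth, and 2.6% of the true zeros admit a (tiny)
spurious edge. Weights are shrunk toward zero by the penalty — that is the
price of the false-edge control.

```bash
python examples/05_cross_lagged_network.py
```

```
strongest cross-lagged paths (standardized betas, lasso-selected):
source_T1 target_T2   beta  autoregressive
       L3        A1  0.303           False
       D6        L2  0.184           False
       L2        A1  0.178           False
...
most-predicted T2 item: A1 (inPred = 0.223)
most-predictive T1 item: L3 (outPred = 0.092)
```

The three configured cross paths (`L3→A1 = 0.35`, `D6→L2 = 0.30`,
`L2→A1 = 0.25`) are the three strongest estimated paths, attenuated by
discretization and shrinkage; the loneliness item L3 emerges as the most
predictive wave-1 item and nervousness A1 as the most predicted wave-2
item — the directed loneliness-to-anxiety pattern the model was configured
to produce.

The other examples cover descriptives and redundancy screening (`01`),
communities and centralities (`03`), and the two-wave comparison test
(`04`). A thin CLI wraps the same pipeline
(`panelnet --out run --seed 7 full`); see `panelnet --help`.

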