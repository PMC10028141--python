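# Methods

## Model

The package estimates Gaussian graphical models (GGMs) over item-level
questionnaire data: 9 depression items (PHQ-9, each 0–3), 7 anxiety
items (GAD-7, 0–3), and 10 post-traumatic stress items (TSQ, 0/1) — 26
symptom nodes.  Edges are partial correlations: for a precision matrix
K, the weight of edge (i, j) is w_ij = −κ_ij / √(κ_ii·κ_jj), so a zero
entry encodes conditional independence given all other symptoms.

Estimation maximizes the L1-penalized Gaussian log-likelihood

    log det K − trace(S·K) − λ Σ_{i≠j} |κ_ij|

(graphical lasso; the diagonal is unpenalized by default, matching
common EBIC-glasso practice).  The penalty λ is selected by the
Extended Bayesian Information Criterion

    EBIC = −2l + E·log n + 4·E·γ·log p,     l = (n/2)(log det K − trace(S·K)),

scanning a descending log-spaced path of 100 values from
λ_max = max off-diagonal |S| down to λ_max/100 and taking the
exhaustive minimum, ties resolved toward the sparser model (larger λ).
γ defaults to 0.5, the field's standard sparsity preference.  The
log-likelihood drops additive constants, so EBIC values are comparable
only within one dataset.

### Solver

The solver is the classical block coordinate-descent graphical lasso:
each column update solves an L1-penalized regression on the current
working covariance W by coordinate descent, warm-started along the λ
path.  Convergence is declared when the largest change in W over a full
sweep drops below `convergence_tol` (default 1e−6, default cap 10,000
sweeps); non-convergence raises an error carrying the sweep count and
last change.  At λ = 0 the closed form K = S⁻¹ is used.  The inner
loops are numba-compiled because the permutation and bootstrap stages
re-run the full path tens of thousands of times.  Entries with
|w| < 1e−7 are treated as structural zeros when counting edges
(coordinate descent leaves numerical dust); no other thresholding or
refitting is applied to the selected model.

The test suite cross-checks the solver against direct Nelder–Mead
maximization of the penalized likelihood for p ∈ {2, 3} (tolerance
1e−5) and against `sklearn.covariance.graphical_lasso` at p = 10.

## Correlation input

The default association matrix is Pearson on the raw integer scores —
fast, deterministic, and adequate when all items share a scale.
Spearman and a two-step polychoric/tetrachoric estimator are
selectable; the polychoric option fixes thresholds at inverse-normal
cumulative marginal proportions and maximizes the bivariate-normal cell
likelihood over the single latent correlation by bounded scalar search
on (−0.999, 0.999), clamping (with a warning) when a degenerate table
makes the likelihood unbounded.  Pearson on discretized data
attenuates latent correlations (roughly 20% for 4-level items, more for
binary ones); polychoric is consistent for the latent correlation and
is therefore used in the edge-recovery check.  Any non-positive-definite
matrix is repaired by eigenvalue clipping at 1e−8 followed by
re-standardization to unit diagonal, iterated to idempotence and
flagged on the result.

## Centrality

Four per-node indices, each also z-standardized across nodes
(population SD; a constant vector standardizes to zeros):

* strength Σ_j |w_ij| and one-step expected influence Σ_j w_ij (signed);
* closeness and betweenness on edge lengths 1/|w_ij| (sign ignored),
  the standard distance transform in psychometric networks.  Closeness
  is the inverse of the **sum** (not mean) of distances and is 0 for a
  node with any unreachable partner; betweenness uses Brandes counting,
  fractional on ties, summed over unordered pairs.

Rankings break ties lexicographically by node name.

## Bootstrap accuracy and stability

Edge accuracy uses a non-parametric case bootstrap (resampling rows
with replacement at full n, default 1,000 replicates) with percentile
CIs — percentile rather than BCa because it matches common bootnet
usage and is directly verifiable.  Bootstrapped difference tests
declare an edge pair (or node pair, per index) different when the
percentile interval of the per-replicate difference excludes zero; no
multiplicity correction is applied (descriptive, as in standard
practice).  Note the percentile CI covers the estimator's own
probability limit: for penalized estimates that limit is shrunk toward
zero relative to the unpenalized partial correlation.

Case-dropping stability re-estimates the network on subsamples without
replacement over a grid of drop proportions (default 10 equal steps,
0.05–0.75) and correlates each subsample's centrality vector with the
full-sample one.  The correlation-stability coefficient (CS-C) is the
largest drop proportion at which at least 95% of subsamples correlate
≥ 0.7; it takes values on the grid, so 0.75 is its cap.  Replicates
whose centrality vector is constant (correlation undefined) are
dropped and counted.  Replicate RNG streams are spawned from the master
seed, making results bit-reproducible and order-independent.

## Network comparison test

The permutation NCT compares two groups on network structure
M = max |w_ij^A − w_ij^B|, global strength S = |Σ|w^A| − Σ|w^B||, and
individual edges.  Each iteration pools all rows, re-splits them at the
original sizes, and re-estimates both networks with identical settings.
P-values use add-one smoothing, p = (1 + #{permuted ≥ observed})/(1 +
iterations), so they are never exactly zero; per-edge p-values get
Holm–Bonferroni step-down adjustment.  The pooled rows are ordered by a
canonical group key, so swapping the two arguments reproduces the
identical permutation set and p-values.  Per-edge tests run on all
upper-triangle pairs by default; the `observed` option restricts to
edges nonzero in either estimated network, which matters for
Holm-corrected detection when the iteration count bounds the smallest
attainable p-value at 1/(iterations + 1).

## Descriptive statistics

Prevalence CIs are Wald intervals (p̂ ± z·√(p̂(1−p̂)/n), reported in
percent); both Wald and Wilson reproduce the published subgroup
intervals at 2-decimal rounding, so the simpler interval is the
default and Wilson is a flag away.  Chi-square tests of independence
use the Pearson statistic with no continuity correction (which
reproduces the published 242.4 for the sex × group table exactly).
One-way ANOVA F is reconstructed from per-group (n, mean, SD) and
equals the raw-data F whenever the summaries are exact; with published
summaries rounded to 2 decimals, agreement is to that rounding (e.g.,
the depression-scale F computes to 298.4 against a printed 299.1).
Cronbach's alpha uses the standard k/(k−1)·(1 − Σ item variances /
total variance) with n−1 denominators.

## Synthetic data generator

The generator emulates a three-group (EA/PA/SA: emotional, physical,
sexual abuse) symptom study with sizes 1,191 / 1,272 / 3,479.  Each
group has a latent unit-variance Gaussian vector whose sparse true
partial-correlation network is block-structured into depression,
anxiety, and PTSD communities (default: within-block weight 0.25 at
density 0.2, three fixed cross-block bridges at 0.12; the implied
precision is made positive definite by uniform off-diagonal shrinkage,
erroring below a 0.05 shrinkage bound).  Group differences are additive
edge overrides on the shared base network (+0.25 by default): PTSD–PTSD
edges for SA, suicide-item edges for EA, anxiety edges for PA.
Observed scores cut the latent values at fixed per-group thresholds
(three cut-points for 0–3 items, one for 0/1 items), shared across
respondents within a group.  The default cut-points were calibrated
once so simulated scale totals land near the emulated cohort's group
means (EA ≈ 11 on the depression total, SA ≈ 7) — calibration, not
validation.  Sampling uses PCG64 with one sub-stream per group derived
from the master seed by a fixed integer offset; identical seeds give
byte-identical CSVs.

What the generator does **not** emulate: respondent-level threshold
heterogeneity, covariates (age, sex), item-level measurement error
beyond thresholding, missingness, or the overlap of abuse categories.
Passing tests therefore demonstrate correctness of the estimators under
the latent-Gaussian threshold model, not fidelity of any conclusion
about the real cohort.

## Verification problem sizes

The heavier checks run at sizes chosen to keep the whole suite quick
while leaving clear statistical margins: edge recovery uses one 10-node
network at n = 5,000 (polychoric input; sensitivity and specificity
≥ 0.9); permutation-test calibration uses 200 repetitions of 200
iterations on an 8-node network at n = 300 per group (rejection rates
within 3 binomial SEs of 0.05); power uses the full-size three-group
study with 2,000 iterations; stability uses 50 subsamples per drop
proportion at n = 4,000 (grid cap 0.75 reached for strength and
expected influence) and n = 700 (betweenness no more stable than
strength).

## Known limitations

* The published cohort's network-level numbers (edge weights, EI
  rankings, NCT p = 0.015/0.019, CS-C ≈ 0.51/0.28 for
  betweenness/closeness) depend on non-public raw data; the pipeline
  covers them qualitatively through the simulation properties above.
  CS-C values off the drop grid are not representable under the
  standard grid definition.
* Pearson input understates latent associations on ordinal data;
  polychoric is available but slower and can be unstable with sparse
  cells.
* No bridge centrality, two-step expected influence, moderated or
  mixed graphical models, covariate adjustment, or centrality-invariance
  NCT variant.
* Respondents flagged for multiple abuse types are not allocated to a
  single group by the package; the flag set is exposed and the analysis
  groups are the caller's decision.
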