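# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of the `deltaomics` pipeline.

## Analysis unit and data model

Every analysis consumes *delta variables*: week6 − baseline within-subject
changes, aligned by subject identifier (never row order).  A block is one
data source as a subjects × features matrix; seven classes are supported
(clinical, lifestyle, MGS, fecal/urine/serum metabolome, transcriptome).

**Missing data.**  The upstream study does not state its missing-data
handling, so the pipeline adopts its own policy: features missing in more
than 20 % of subjects are dropped with a warning; remaining gaps are
median-imputed per feature (robust at n ≈ 27).  Zero-variance delta features
are excluded from all model fits (their correlations are undefined) and
logged.

## Canonical-mode PLS

Two-block PLS with symmetric deflation models the blocks as exchangeable
rather than predictor/response.  Components are extracted by NIPALS power
alternation on the residual matrices (convergence when the x-weight change
drops below 1e−12, at most 500 iterations — non-convergence yields the best
iterate with a warning, which on pure-noise blocks is benign); both blocks
are deflated by regression on their own variate.  Columns are centered and
scaled to unit variance (ddof = 1) internally, so the similarity is
invariant to affine rescaling of any input column.  The weight-vector sign
is fixed by forcing the first non-zero element of u_h positive, for
reproducibility across linear-algebra backends.

**Number of components.**  H = 2 by default (the dimension at which such
fits are routinely plotted and the default of the standard two-block PLS
implementations); configurable.

**Association coefficient.**  No closed formula is canonical in the
literature, so the package defines sim(i,j) = Σ_h cor(x_i, ξ_h)·cor(y_j, ξ_h)
over the X-block variates.  This choice is sign-preserving, reduces exactly
to the Pearson correlation when p = q = 1, and is bounded by 1 (the variates
are mutually orthogonal, so each correlation vector has squared norm ≤ 1 and
Cauchy–Schwarz applies).  An averaged-variate variant ((ξ+ω)/2) is available
behind a flag.  Thresholding keeps |sim| ≥ τ (boundary ties kept); default
per-pair thresholds are |0.7| for lifestyle and MGS pairs and |0.75| for
metabolome and transcriptome pairs.  Sparse MGS blocks are pre-filtered to
features non-zero in ≥ 2 subjects.

## Data reduction

"Top 20 %" is interpreted as a *variable* ranking: within each thresholded
network, non-clinical variables are ranked by their best absolute
association and the top ⌈0.2·m⌉ kept (ceiling, so a non-empty network never
selects nothing); the union across networks is deduplicated keeping the best
score.  An edge-ranking alternative is available behind a flag, since the
wording of the two descriptions of this step conflicts.  Clinical-side
variables enter through the unconditional anchor list (the 10 IS markers,
adipocyte diameter, NEFA) rather than through ranking, so the IS cluster is
always present downstream.

## Spectral consensus reconstruction

**Relevance graph.**  Pairwise dependence is measured by Gaussian-copula
mutual information: ρ_g = 2·sin(π·ρ_S/6) from the Spearman correlation and
MI = −½·ln(1 − ρ_g²) nats, capped at ln n.  At n = 27 histogram plug-in
estimators are badly biased; the copula estimator is consistent for any
monotone dependence.  An equal-frequency binning plug-in remains available.

**Subsets.**  The symmetric normalized Laplacian of the MI-weighted graph is
eigendecomposed per connected component; the ⌈0.14·p⌉ eigenvectors of
smallest eigenvalue (excluding the trivial constant one) each select the
variables with |coordinate| ≥ 0.03.  Both parameters are plain configuration
values; their semantics (fraction of the spectrum; coordinate cut-off
controlling subset size) are this package's reconstruction of a sparsely
documented upstream convention, and a count interpretation of 0.03 (subsets
of ⌈0.03·p⌉ ≈ 4 variables) was rejected as too small to reconstruct on.
Each subset is then augmented with every member's strongest-MI neighbour
(approximate Markov-blanket closure): a subset that omits the variable most
strongly dependent with its members cannot explain away indirect
dependencies, which measurably floods the consensus with spurious edges.
Subsets smaller than 3 are merged into their strongest-MI neighbour's
subset, and every variable is guaranteed coverage.

**Engines.**  Three deterministic engines span the main reconstruction
families:

* `shrink_pcor` — Ledoit–Wolf shrinkage covariance, full partial
  correlations, Fisher-z tests at level α (degrees of freedom
  n − (m−2) − 3, clamped with a warning when the conditioning set exceeds
  the sample — unavoidable at n = 27 with large subsets);
* `mi_dpi` — the significant-MI graph (Spearman Fisher-z at level α) pruned
  by the data-processing inequality: in every triangle the strictly weakest
  edge is dropped (tolerance 1), all removals decided on the input graph;
* `pc_skeleton` — constraint-based skeleton with marginal and order-1
  Fisher-z tests, conditioning candidates restricted to the current
  neighbourhood of either endpoint.

**Consensus.**  Within a subset an edge's votes are the number of engines
reporting it; edges with ≥ quorum (default 2 of 3, a majority) are kept, and
a pair evaluated in several subsets takes its maximum vote.  Edge sign is
the sign of the pair's Spearman correlation (neutral when exactly zero).
The consensus skeleton is undirected: two of the three engines carry no
orientation information, so no arrows are emitted.  Everything is
deterministic given the data and configuration.

## Contribution analysis

Targets (revised QUICKI and HOMA-B deltas by default) are continuous, so
plain linear regression is used.  The predictor pool is the main cluster
(largest connected component, ties broken by edge count) of the consensus
network, minus all IS-marker features (mutually redundant with the targets)
and serum features annotated as glucose (near-tautological with glycemic
targets).  Predictors are grouped by block class; each class's mean 10-fold
cross-validated MSE is computed with a seeded permutation fold assignment
(no stratification — the target is continuous), ridge-stabilized with
λ = 1e−6·p only when the class has at least as many predictors as a training
fold; shares are normalized inverse MSEs, share_c = (1/MSE_c)/Σ(1/MSE), so
they sum to 1 and are invariant to rescaling all MSEs.  All class members
found in the main cluster are used (the upstream description does not state
any further selection).

## Paired change testing

The within-subject baseline/week-6 comparisons use the Wilcoxon signed-rank
test, two-sided, zeros dropped.  For ≤ 25 non-zero pairs the exact null
distribution of the positive rank sum is enumerated by dynamic programming
over the 2^m sign assignments, with mid-ranks for ties (doubled ranks are
integers, so the distribution is an exact subset-sum convolution); the
upstream software's tie convention is unknown, and this one is stated
explicitly.  Beyond 25 pairs a normal approximation with tie and continuity
corrections is used; it agrees with enumeration to < 0.01 at n = 20.  An
all-zero difference vector returns p = 1 with a warning.  BH adjustment is
applied independently within each class of variable, and significance at
FDR 5 % is reported as a flag column — no rows are deleted.

## Synthetic-data generator

The generator emulates the study's *shape* — seven delta blocks with the
published dimensions (45 clinical with 10 IS markers; 63 lifestyle; 741 MGS;
835/562/180 metabolome features; 7,560 transcript probes; 27 subjects) — and
plants known structure for testing:

* a latent per-subject factor s ~ N(0,1), the unobserved IS improvement;
* ten clinical markers loading ±effect·s with alternating signs; the first
  (a revised-QUICKI-like primary index) carries noise sd 0.1σ — surrogate
  indexes are deterministic transforms of the same fasting measurements, so
  one near-noiseless, mutually redundant proxy is realistic — while the
  other nine carry noise sd σ; adipocyte diameter and NEFA load ∓effect·s;
* per non-clinical block, n_planted features (default 4–6) of the form
  effect·s + r + σ·ε, where r is a unit-variance chain Gaussian-graphical
  residual (neighbour partial correlation 0.45) over the block's planted
  set; an isolated planted feature carries no residual, so at σ = 0 it is an
  exact affine function of s;
* all other features are independent N(0, 1) noise.

The recorded truth graph E* is the conditional-dependence structure the
model implies for the observables: the within-block chains, plus a star from
the primary index to every other feature loading on s (conditioning on the
primary index — an almost exact proxy of s — removes every other
latent-induced pairwise dependence, so those star edges are the only
latent-induced edges that survive conditioning).  The chain precision
matrices are checked positive definite at construction.  Deltas are
generated directly (every analysis consumes deltas); a two-time-point mode
(week6 = baseline + delta) exercises the delta computation, and an optional
prevalence mask sparsifies non-planted MGS features.

Defaults where the study reports no value: effect = 1, σ = 0.5 — chosen once
for testability (planted features then correlate ≈ 0.67 with the latent
factor, so at n = 27 only a minority of planted associations clear the
|0.75| threshold, qualitatively matching the published funnel in which < 6 %
of variables were retained).  What the generator does **not** emulate:
compositionality and sequencing depth of MGS abundances, spectral peak-shape
artifacts, heavy-tailed or skewed marginals, block-specific missingness.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure under Gaussian-ish conditions, not
performance guarantees on real multi-omics data.

## Problem sizes used in the tests

The suite exercises the full 27 × 9,986 paper-dimension pipeline once (it
completes in well under a minute); structure-recovery checks run at the mini
feature counts (145 variables) with n = 200 and σ = 0.3, where engine test
thresholds are well separated from the planted effect sizes; calibration
checks use 1,000 simulated null datasets.  These sizes are the package's
choices for sharp, fast checks.

## Known limitations

* The association-coefficient formula and the SCS subset-parameter semantics
  are reconstructions of sparsely documented upstream conventions (flagged
  above); results are reported with the formulas stated.
* Order-1 PC and DPI pruning cannot separate chains of length 2 from direct
  edges in all configurations; the consensus inherits whatever two engines
  agree on.
* Inverse-MSE shares are a descriptive decomposition, not causal effect
  estimates; with p ≈ n the ridge-stabilized fits make shares seed-dependent
  at the margin (the fold seed is part of the configuration).
* At n = 27 the PLS networks are dominated by sampling variability near the
  thresholds; the pipeline reports counts and networks but no inferential
  guarantees at that stage.
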