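# Methods

`consub` derives consensus molecular subtypes of an expression cohort from
the agreement of several independent clustering methods, and trains a
rank-based single-sample classifier on the result. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Input model

All stages operate on a genes × samples matrix of log-scale expression
(log2 microarray intensity or log-TPM), fully imputed upstream: missing or
non-numeric values are rejected at load, never imputed here. Training-domain
selection (e.g. restricting to ER+ or ER− samples by an annotation column)
is a caller decision; the pipeline itself is agnostic to what the samples
are.

## The six subtyping methods

Each method = a gene filter + an unsupervised clusterer + an automatic
choice of the cluster number k in 2..8.

| id | gene filter | clusterer | k selection |
|----|-------------|-----------|-------------|
| A | MAD > 0.5 | hierarchical, average linkage, 1−Pearson; consensus over 1000 resamples of 90% of **genes** | consensus-CDF plateau |
| B | top 15% by variance | hierarchical, Ward, 1−Pearson; 1000 resamples of 90% of **samples** | consensus-CDF plateau |
| C | variance-test p < 0.01, then top 10% by CV | hierarchical, Ward; 1000 resamples of 90% of genes **and** samples | consensus-CDF plateau |
| D | top 5% by IQR | PAM (k-medoids) on 1−Pearson | gap statistic, one-SE rule |
| E | SD > {0.5, 0.8, 1.0, 1.1} (four candidate gene sets) | NMF, 30 random restarts | error-curve elbow per gene set; gene set by cophenetic coefficient |
| F | IQR > 1.2 | NMF, 30 random restarts | error-curve elbow |

Notes on individual pieces:

* **MAD** is the raw `median(|v_i − median(v)|)`, no 1.4826 consistency
  factor. **IQR** uses linear interpolation between order statistics.
* **The "variance test"** screening in method C is a one-sided chi-squared
  test of each gene's sample variance against the median of all per-gene
  variances (H0: σ² ≤ median). The screen's role is to discard
  average-or-quieter genes before ranking by CV; any reasonable
  variance-screening test would serve.
* **Ward on 1−Pearson** applies the Lance–Williams Ward update directly to
  the given dissimilarities (scipy's behaviour), mirroring what the common
  array-analysis stacks do even though the input is not Euclidean.
* **Top-fraction filters keep ties**: every gene tied with the cutoff value
  is retained, so output is independent of gene order.

### Consensus clustering and the CDF-area plateau

For each resample the filtered matrix is re-clustered and, for every k, the
co-clustering of each sample pair is recorded. The consensus entry is the
fraction of co-clustering resamples among resamples co-including the pair
(with gene-only resampling every pair is always co-included and the diagonal
is exactly 1). A sample pair never co-included is an error, not a silent
NaN. The area under the consensus CDF is computed exactly as
`1 − mean(off-diagonal entries)`.

k is chosen from the relative area gains `delta(k) = (A(k) − A(k−1)) /
A(k−1)`. An absolute threshold on `delta` is not a reliable plateau test:
after the true k, splitting a real cluster keeps shifting fractional
consensus mass and produces gains of 3–6% indefinitely under sample
resampling. What identifies the end of structure empirically is *dominance*:
gains at and below the true k are several-fold larger than every later gain.
The rule is therefore: select the **largest k whose gain is ≥ 0.025 and at
least twice every later gain**; if no k qualifies, the smallest k. The
largest selectable k is one below the top of the range, because declaring a
plateau requires at least one later gain as evidence. On planted-structure
cohorts the gain at true k is typically 5–15× the following gains, so the
factor of two is not delicate.

### PAM and the gap statistic

PAM is the classical build (greedy min-cost seeding) + swap (best
single-swap descent to convergence) algorithm on the 1−Pearson matrix; ties
break to the lowest index. The within-cluster dispersion is
`W_k = Σ_clusters (Σ pairwise d) / (2 n_c)`; reference datasets draw each
gene uniformly over its observed range and re-run the full distance+PAM
pipeline. k is the smallest with `gap(k) ≥ gap(k+1) − se(k+1)` (one-SE
rule), falling back to argmax gap. 100 reference datasets at full scale, 20
at desk scale.

### NMF: rank from the error elbow, gene set from the cophenetic coefficient

Log expression is shifted to non-negative by subtracting the global minimum
(only when the minimum is negative); between-sample contrasts are untouched.
Factorization uses multiplicative updates minimizing Frobenius error
(scikit-learn's `mu` solver) from random initializations, in float32. Each
run labels every sample by its dominant metagene; the run-to-run consensus
matrix of these labels, clustered by average linkage, gives the cophenetic
coefficient for each (gene set, k). Final sample labels are read from the
winning gene set's consensus matrix (average-linkage cut at the chosen
rank) rather than from any single factorization — the minimum-error run's
dominant-metagene assignment is occasionally an outlier partition even when
the consensus is clean. Candidate gene sets that coincide (thresholds below
the bulk of the dispersion distribution) are detected and computed once.

Selection is two-stage. **Within a gene set** the rank is the elbow of the
best-reconstruction-error curve: the per-k error drop collapses to a flat
noise-fitting rate once k exceeds the effective rank, so the chosen k is
the largest whose drop is ≥ 5% of the total error range and at least twice
every later drop (smallest k if none qualifies — the same dominance logic
as the consensus-CDF rule). **Between gene sets** the one whose consensus
at its chosen rank has the highest cophenetic coefficient wins; ties prefer
the smaller rank, then the earlier gene set.

The division of labour is deliberate. On weakly filtering gene sets the
run-consensus stability saturates near 1 for every k at or above the
effective rank, and its ordering between neighbouring ks is then decided by
a few thousandths — measured on planted-structure cohorts this ordering
picks the wrong rank about half the time regardless of restart count,
while the error-curve slope change at the true rank remains 5–10× the
noise-fitting rate. Between gene sets the cophenetic differences are large
(order 0.01–0.1) and the coefficient is the right arbiter of which gene
set yields coherent clusters at all. Both diagnostics are what a
practitioner reads off the consensus heatmap and cophenetic plots; the
automation separates them by where each is sharp.

Convergence matters for both diagnostics: undertrained runs (loose
tolerance or a low iteration cap) scatter into local minima whose label
noise *increases* with k and biases any consensus metric toward large k.
All profiles run to relative-error change < 1e-5 (1e-6 at full scale) with
a 500-iteration cap.

A single run makes the consensus trivially 0/1 and the coefficient is 1 by
construction; a constant consensus is likewise reported as 1.

## The subtype network

All subtypes from all methods become nodes. Every **cross-method** node
pair is tested for sample overlap with a one-sided hypergeometric test
(same-method subtypes are disjoint by construction and never tested);
Benjamini–Hochberg adjustment is applied once across the whole set of tested
pairs, and edges keep adjusted p < 0.001.

**MCL** runs on the binary significance adjacency with self-loops of weight
1, expansion 2, entrywise-power inflation followed by column normalization,
and pruning of entries < 1e-5 (a column emptied by pruning gets its
self-loop restored). Convergence is a max-change residual < 1e-8; clusters
are read off attractor rows, overlapping attractor basins are merged, and
uncovered nodes become singletons. Clusters can never span disconnected
components.

**Stability** is assessed by resampling 80% of the samples 1000 times (100
at desk scale), rebuilding the network on each subsample and re-running MCL.
The co-cluster frequency of a node pair is counted over the iterations where
both nodes retain at least one sample, so small subtypes are not deflated by
absence. The subsampled networks do not depend on the inflation factor, so
one set of them serves the whole inflation sweep; this is identical to
recomputing per inflation. A node's stability score is its mean frequency
with its cluster mates (undefined, and recorded as missing, for singleton
clusters).

**Inflation selection** sweeps 1.0–10.0 in steps of 0.25. Each partition is
scored by the silhouette of the nodes under dissimilarity 1 − frequency,
averaged with the stability scores as weights; nodes in singleton clusters
contribute nothing (logged). An inflation is disqualified when any
multi-node cluster would retain fewer than `min_core = 50` core samples —
singleton clusters are exempt, since a one-subtype cluster essentially never
reaches per-sample significance and would otherwise disqualify every
inflation whenever the graph leaves one subtype unconnected. Among the
qualifying inflations the *maximal plateau* is the contiguous run of grid
points within 0.01 of the maximum silhouette containing that maximum; the
lowest inflation on the run is chosen.

## Core samples

A cluster C of subtypes (K of the N subtype nodes overall) defines a
consensus subtype. For a sample labelled by n methods with q of those labels
inside C, the over-representation p-value is `P(X ≥ q)` for
X ~ Hypergeometric(N, K, n) — the population is the subtype nodes, the
sample's per-method labels are the draws. The sample is core to C when
p < 0.05 (raw; no multiplicity correction across the per-sample tests).
When several clusters are significant the smallest p wins; an exact tie
leaves the sample unclassified — deterministic and conservative. The
parameterization is isolated in one function (`core_sample_p`) so
alternatives can be swapped.

## Multi-kTSP classifier

A TSP votes by the within-sample order of two genes, so every layer is
invariant under strictly increasing per-sample transforms — the property
that makes the classifier applicable to one sample at a time with no
renormalization against a cohort.

* **Pair statistic**: Δ = |P(X_i > X_j | A) − P(X_i > X_j | B)| estimated by
  within-class frequencies; ties in Δ break by the secondary rank statistic
  |mean within-sample rank gap in A − in B|.
* **Binary kTSP fit**: pairs are chosen greedily by descending (Δ, rank
  score) under gene-disjointness. k is selected from odd {3, 5, 7, 9} by
  internal stratified cross-validated accuracy (up to 5 folds, capped by the
  smallest class), taking the smallest k within 0.01 of the best. The
  greedy candidate ordering is exact whenever there are ≤ 4000 candidate
  pairs; above that the shortlist is taken by Δ first, which can only
  permute ties straddling the shortlist boundary.
* **Multiclass**: one binary model per unordered class pair; a sample takes
  the unique modal pairwise prediction, else "tie".
* **Ensemble**: the candidate pool is the 1500 most-varying genes of the
  training matrix (variance; the whole matrix if smaller, logged). Member e
  draws 75% of the pool without replacement with generator
  `default_rng([seed, e])`, so member e is identical across runs and across
  ensemble sizes; an m-member ensemble is literally the first m members.
  Ensemble prediction tallies the sub-model labels excluding sub-model
  ties, and returns the unique modal label or "tie".
* **Training protocol**: unclassified samples are excluded; the rest are
  split 75/25 *stratified by consensus label* (a deliberate deviation from a
  plain random split, protecting small subtypes in modest cohorts). One
  maximal ensemble is fitted and truncated to each m in the grid; the
  selected m is the smallest whose test accuracy is within 0.005 of the
  grid maximum. Accuracy counts "tie" as an error; Cohen's kappa is
  computed on the same predictions.
* **Serialization**: versioned JSON with the pool, the per-member gene
  subsets, and every pair with its vote direction — sufficient for exact
  replay; two runs with the same data and seed produce byte-identical
  files.

The per-class greater-than count matrices are accumulated once per (class,
fold) block, so the full fit and all cross-validation folds reuse one pass
over the samples.

## Synthetic cohorts

The generator plants k subtypes as disjoint blocks of marker genes whose
mean is shifted by `effect` in that subtype's samples, over i.i.d. Gaussian
noise on the log scale; a fraction of samples can carry no signal
("unclassifiable"). Defaults: 300 samples × 2000 genes, 4 subtypes, 50
markers each, effect 2.0 (log2 units), noise SD 1.0, baseline 7.0.

What it deliberately does **not** emulate: per-gene dispersion
heterogeneity (every gene shares one noise SD, so dispersion filters are
much less selective than on real cohorts — the hardest regime for the
NMF-based methods), correlated noise and batch effects, heavy-tailed
platform artifacts, and partially overlapping marker programs. Passing the
planted-recovery benchmarks therefore demonstrates the machinery is correct
and calibrated on well-specified structure; it does not certify performance
on any real cohort.

System-fixture generation (for the network stage in isolation) derives
several subtype systems from one latent partition with per-sample label
corruption at rate 1 − agreement.

## Scale profiles

Every resampling count is part of the configuration; nothing is scaled
silently, and the profile name is recorded in the provenance log.

| parameter | `full` | `desk` |
|-----------|---------|--------|
| consensus resamples (A–C) | 1000 | 100 |
| gap references (D) | 100 | 20 |
| NMF restarts (E, F) | 30 | 10 |
| NMF tolerance | 1e-6 | 1e-5 |
| network stability iterations | 1000 | 100 |

## Determinism

Every stochastic stage derives its generators as
`numpy.random.default_rng([seed, counter])` with documented counter ranges
(consensus resample r; gap reference 10000+b; ensemble member e; stability
iteration t; split class 50000+i), so any single step can be replayed in
isolation. Artifacts are written with fixed float formats and sorted JSON
keys, and the provenance log records seeds and parameters but no wall-clock
values, so a rerun with the same inputs is byte-identical. Timing
information goes to the log stream only.

## Known limitations

* The cophenetic rank selection for NMF resolves thin margins by restart
  count; on data with very weak structure it remains the least stable of
  the six methods.
* The CDF-plateau dominance rule cannot certify the top of the k range
  (a plateau needs at least one later gain as evidence).
* MCL operates on the binary significance adjacency; p-value-weighted
  variants are out of scope.
* Continuous subtype scores (mixed-subtype samples) are out of scope; the
  classifier returns a single label or "tie".
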