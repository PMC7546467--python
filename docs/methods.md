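# Methods

## Model

`scmethclust` fits a hierarchical mixture of Bernoulli (two-state
categorical) distributions to a ternary cell × CpG matrix X with entries
in {0, 1, missing}.  Latent structure:

* **Z**ₙ ∈ {1..K} — the epiclone (cluster) of cell *n*;
  P(Zₙ = k) = πₖ, **π** ~ Dirichlet(α⁰).
* **G**₍ₖᵣₗ₎ ∈ {0, 1} — the hidden methylation state of cluster *k* at
  locus *l* of region *r*; within a region the states are i.i.d.
  categorical with propensity **μ**₍ₖᵣ₎ ~ Dirichlet(β⁰).  Regions encode
  the biological expectation that methylation propensity is locally
  shared (CpG islands are coherently methylated or not); the region-free
  variant is the exact special case R = 1.
* ε — a 2×2 misclassification channel between hidden and observed
  states, P(X = t | G = s) = ε₍ₛₜ₎, each row εₛ ~ Dirichlet(γₛ⁰).  This
  absorbs sequencing and bisulfite-conversion error.

Observed entries are conditionally independent given (Z, G); missing
entries are assumed missing completely at random and contribute nothing
to the likelihood (they are integrated out exactly).

## Inference

Mean-field variational Bayes over the factored posterior
q(Z) q(G) q(π) q(μ) q(ε), maximizing

    ELBO(q) = E_q[log p(X, Z, G, Θ)] − E_q[log q].

One sweep updates, in fixed order:

1. q(G):  log φ₍ₖₘₛ₎ ∝ E[log μ₍ₖ,r(m),ₛ₎] + Σₙ ψₙₖ E[log ε₍ₛ,Xₙₘ₎]
   over observed entries;
2. q(Z):  log ψₙₖ ∝ E[log πₖ] + Σₘ Σₛ φ₍ₖₘₛ₎ E[log ε₍ₛ,Xₙₘ₎];
3. conjugate Dirichlet posteriors (α*, β*, γ*) from the expected counts.

Dirichlet log-expectations use digamma differences; all products are in
the log domain with per-row max subtraction.  Any fixed update order
keeps the ELBO non-decreasing; this order puts the state posteriors
before the assignment posteriors so a one-hot initial partition
immediately shapes the epigenotypes.  Convergence: relative ELBO change
< 1e-6 (default), cap 1000 sweeps; non-convergence is flagged, not
fatal.  Cells with no observed entry are retained — their
responsibilities converge to the posterior-mean mixture weights — and
are flagged on the model object.

Defaults (all exposed): α⁰ = 1 symmetric, β⁰ = (1, 1),
γ⁰ = ((99, 1), (1, 99)).  The diagonal-biased γ⁰ starts the error
channel near the identity; with a flat error prior the labels "hidden
state 1 means methylated" would be only weakly identified and the error
rate could absorb genuine signal.  The prior corresponds to ~1% expected
error, the typical scale of bisulfite miscalls.

MAP outputs: per-cell argmax responsibilities (ties to the lowest
index), relabeled consecutively; per-(cluster, locus) argmax states; the
occupied-cluster count c ≤ K.

### Model selection

DIC = 2·D̄ − D̂ with the conditional deviance D = −2 log p(X | Z, G, ε):
D̄ averages under the variational factors, D̂ plugs in the MAP labels,
MAP epigenotypes and posterior-mean ε.  Among many restarts (informed
partitions first — three hierarchical baselines cut at 1..Kmax plus one
density-based partition, 31 at Kmax = 10 — then random starts with an
initial cluster count uniform on {1..Kmax}), the minimum DIC per
recommended c forms a curve over c.  The longest prefix in which each
step still decreases the DIC by ≥ 0.2% (relative) is retained; both axes
are rescaled to [0, 1]; the selected c is the retained point farthest
from the chord.

One geometric subtlety: when the curve flattens, the flattening point is
the elbow, but it is also where the decreasing prefix ends — as a chord
endpoint its distance would be zero and the rule would systematically
return one cluster too few.  The first point *failing* the decrease test
therefore anchors the far end of the chord (it is itself never
selectable), making the corner visible.  On replicated synthetic data
(50 cells × 1,000 loci, 3 epiclones, 50% missing) this selects the
generating epiclone count in 10/10 replicates; without the anchor the
selection oscillates between 2 and 3.

Ties among runs at the selected c: lowest DIC, then highest ELBO, then
lowest run id.  Per-run seeds spawn deterministically from the master
seed.

### Imputation

Missing entry (n, m) is completed three ways: *unadjusted* — argmax
state of the cell's MAP cluster; *adjusted* — argmax of the
responsibility-weighted mixture Σₖ ψₙₖ φ₍ₖₘ·₎; *naive* — majority vote of
observed values among MAP cluster-mates, falling back to the overall
column majority and then to 0.  Observed entries always pass through.

## Bulk-guided refinement

A bulk profile gives per-CpG methylated counts b_m out of depth D; the
aggregate of the completed single-cell matrix is comparable via
D·(methylated-cell fraction).  The score is the L1 residual
Σ |D·frac − b_m| over CpGs in regions whose MAP epigenotypes differ
between clusters (CpGs shared by all clusters carry no assignment
information).  Starting from a given configuration, 10 sweeps visit the
uncertain cells (max responsibility < 0.99) in random order and propose
moving each to a uniformly chosen candidate cluster (responsibility
≥ 0.01), re-imputing that cell's missing entries from the destination
epigenotype.  Improving moves are always kept; worsening moves are kept
with probability 0.2; the best configuration ever visited is returned,
so the returned score never exceeds the initial one and the number of
clusters never grows.  The 0.99 / 0.01 thresholds are package defaults,
exposed as parameters.

The refinement is corrective, not creative: when uncertain cells start
misassigned it repairs prevalences (verified on synthetic data with bulk
generated from the truth), but from an already-correct start the score's
optimum can sit a few cells away from the truth because the estimated
epigenotypes carry per-locus noise at high missingness.

## Non-probabilistic baselines

All pairwise statistics use pairwise-complete observations; undefined
pairs (no overlap, or zero variance for correlation) are filled with the
mean of the defined entries and logged (a strict-failure flag exposes
the alternative).

* Euclidean (region-based): distances between cells' region mean
  methylation vectors, then complete linkage on the rows of the distance
  matrix (the two-stage construction tempers sparsity-driven noise).
* Hamming (CpG-based): proportion of discordant commonly-observed CpGs,
  then Ward linkage on the dissimilarity rows with Euclidean row
  distances.
* Pearson (CpG-based): 1 − r over commonly-observed CpGs, then Ward
  linkage with the same 1 − r dissimilarity applied to the
  correlation-matrix rows.

Trees are cut at 1..Kmax; the cluster number is the Calinski-Harabasz
argmax on the same feature rows the linkage used (K = 1 and K = N
excluded, ties to the smaller K).  The density hook projects region
means onto ≤ 20 principal components and hands them to any
features → labels callable; the default is HDBSCAN with noise points
attached to the nearest cluster centroid.  When a method fails on
over-sparse input, column-mean pre-imputation (binary entries rounded,
ties to 1, blank columns set to 0.5) allows a rerun.

## Pre-processing

Fractional methylation calls binarize at 0.5, inclusive (≥ 0.5 → 1).
Regions are BED 0-based half-open; calls are 1-based forward-strand C
coordinates; containment tests pos − 1 ∈ [start, end).  Duplicate calls
at one position within a cell merge by summed counts.  Region filters,
in order: drop regions empty in all cells; drop regions with mean
missing proportion ≥ 95%; keep regions with ≥ 5% of CpGs observed in all
cells or (default) in ≥ 10% of cells.  The "5% coverage" is interpreted
as the fraction of a region's CpGs observed (the alternative read-depth
interpretation is not representable in a binarized matrix).  Variable
regions are then selected by the IQR of per-cell region mean methylation
(cells without data in a region are excluded from that region's IQR),
either by threshold or by ranking IQR-descending (ties: larger region
first, then genomic order) and keeping the shortest prefix reaching a
target CpG count.  Differentially methylated regions between two bulks
use region-pooled counts, a two-sided Fisher exact test (regions under 5
reads in either sample excluded) and Benjamini-Hochberg control.

## Synthetic data generator

The generator emulates clonal tumour structure: epiclone profiles arise
from an ancestor-descendant chain.  The root draws each locus
Bernoulli(0.5); each descendant inverts every locus of `n_diff_regions`
regions chosen uniformly without replacement (per step; steps are
independent, so non-adjacent clones can coincide with small probability
— at the default single flipped region out of ten, about 1 in 10
three-clone datasets has clone 3 equal to clone 1).  A chain rather than
a random tree makes "regions different between adjacent clusters" an
exact knob; inverting rather than resampling guarantees adjacent clones
differ at every locus of a flipped region.

Cells draw labels i.i.d. from the clone frequencies; a fraction
`cell_variability` of each cell's loci is flipped (cell-to-cell
variability); each entry is flipped independently with `error_rate` and
masked missing completely at random with `missing_prop`.  Matched bulk
counts are Binomial(D, methylated-cell fraction) per CpG.

Defaults are the standard simulation condition used throughout the
package's tests: 100 cells, 10,000 loci in 100 regions (region size
100), 3 epiclones with balanced frequencies, missing proportion 0.8, no
cell variability, one region different between consecutive clones,
error rate 0.01 (a realistic bisulfite miscall scale), bulk depth 60.
What the generator does **not** emulate: read-level data, non-CpG
methylation, chromosome structure, copy-number signal, or informative
(non-MCAR) missingness — so passing tests demonstrate correctness of the
machinery under the stated generative assumptions, not robustness to
every artefact of real sc-WGBS libraries.

## Evaluation

V-measure = harmonic mean of homogeneity h = 1 − H(true|pred)/H(true)
and completeness = 1 − H(pred|true)/H(pred) (natural logs; h := 1 when
the truth has a single class, symmetrically for completeness; V := 0
when both vanish).  Prevalence MAE matches clusters one-to-one by
maximum contingency overlap (Hungarian assignment; unmatched clusters
pair with frequency-0 phantoms) and averages the absolute frequency
differences.  Hamming distances are proportions of discordant entries —
cell-level variants restrict to originally-missing entries.  The
uncertainty true-positive rate calls a cell truly ambiguous iff its true
clone's epigenotype restricted to the cell's observed loci coincides
with another clone's, flags cells with max responsibility < 0.95, and
reports the flagged fraction of the ambiguous.  The co-clustering table
gives, per true class, the percentage distribution over predicted
clusters (rows sum to 100).

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so each study completes in seconds to a few minutes on one CPU
while preserving the regime of interest:

* generator calibration: 20 replicates of 100 cells × 1,000 loci;
* cluster-number recovery: 10 replicates of 50 cells × 1,000 loci in 10
  regions at 50% missing, 50 restarts each, Kmax = 10;
* parameter recovery: 200 cells × 500 loci, 2 epiclones, 20% missing;
* bulk mechanics: 150 cells × 200 loci at 95% missing (to populate the
  uncertain set).

Numerical conventions: argmax ties break to the lowest index; ELBO
tolerance 1e-6; normalization checks hold to 1e-12; DIC is finite
whenever the posterior-mean error rates are interior to (0, 1), which
the positive γ⁰ guarantees.  Degenerate inputs: an all-missing matrix is
fitted (priors only), a single-cluster model labels every cell 1, and
empty filter results raise informative errors rather than returning
empty objects.

## Known limitations

* The exact-enumeration check of the variational posterior holds where
  the exact posterior is decisive; on near-symmetric instances
  mean-field legitimately extremizes ambiguous assignments.
* DIC is a heuristic selector: on very flat curves the elbow can sit one
  cluster early/late; inspecting the stored DIC curve is recommended.
* The bulk score assumes the bulk was sequenced from the same cell
  population; compositional shifts between bulk and single-cell
  libraries bias the refinement.
* MCAR missingness is an idealization; coverage in real sc-WGBS is
  locally correlated.
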