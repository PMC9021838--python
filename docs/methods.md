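# Methods

This note documents the models and procedures implemented in `geneshift`,
the defaults and why they were chosen, the numerical details, and what the
synthetic benchmarks do and do not demonstrate.

## Data model

The input is a genes × samples matrix of FPKM values over a two-condition,
replicated time course: T ordered time points (default grid 0, 12, 24, 48,
72 h), m replicates per condition (default 3). Every analysis unit is a
*per-replicate trajectory* — one gene × condition × replicate series on the
time grid. Replicates are never averaged; agreement between them is instead
used as the qualification criterion for between-condition comparison.

## Preprocessing

* **Off-profile rule.** A gene-condition is unexpressed when at least
  `min_zero_replicates` (default 1) replicates are exactly 0 FPKM at every
  time point. The test runs on raw FPKM before normalization because
  quantile normalization does not preserve exact zeros. The default of 1 is
  deliberately permissive (a single flat-zero replicate disqualifies the
  profile from clustering); setting it to m demands all replicates be
  silent.
* **Quantile normalization** maps each sample column onto the across-sample
  mean of per-rank sorted values; ties receive the mean of the reference
  values over their tied ranks. The procedure is idempotent on tie-free
  data. At very small gene counts (tens of genes) the per-column rank
  remapping measurably distorts trajectory shapes; integration tests
  therefore use ≥ 80 genes.
* **log2(x + 1)** stabilizes variance; all clustering happens on this
  scale.

## Soft-DTW K-means (coarse pass)

Soft-DTW with squared-difference ground cost and smoothing γ (default 1.0)
scores all monotone alignments of two series:
`−γ log Σ_paths exp(−cost/γ)`. The dynamic program and its forward/backward
gradient are implemented batched over pairs; with T = 5 the T × T lattice
loops are negligible.

* **Pooling.** Trajectories of both conditions and all replicates are
  clustered together, so control and treated labels live in one comparable
  space — the between-condition comparison is undefined otherwise.
* **Initialization.** Restarts (default `n_init` 5) seed centroids with
  k-means++ D² sampling (Euclidean surrogate for seeding distances only).
  Uniform sampling of k trajectories was tried first and regularly left the
  Lloyd iterations in local optima at the true k on 2,000-trajectory
  benchmarks (ARI ≈ 0.7 instead of ≈ 1.0); D² seeding removed the failure
  mode at no measurable cost.
* **Updates.** Assignment is nearest centroid under soft-DTW; the centroid
  update is the soft-DTW barycenter, minimized by gradient descent with a
  backtracking line search (monotone objective; stop at relative
  improvement < 1e−5 or 20 inner iterations). Empty clusters are reseeded
  with the worst-fitting trajectory. Iteration stops when the assignment is
  stable or after `max_iter` (50).

## k selection

Each k in the grid is scored with Davies-Bouldin (ascending),
Calinski-Harabasz (descending) and silhouette (descending) on the
trajectories as fixed-length Euclidean vectors (delegating to
scikit-learn); the chosen k is the best mean rank, ties to the smallest k.
The mean-rank consensus is this package's rule — the three indices
frequently disagree and some single combination had to be fixed; it is
recorded in the k-selection report. A soft-DTW silhouette is available as
an option but is not the default. By default the indices score the coarse
partition; `eval_after_fine` scores the post-refinement labels instead (the
costlier protocol).

Selecting k *above* the true structure is the expensive error in this
two-step design: the fine pass can split but never merge across coarse
clusters, and a shape split across two coarse clusters destroys replicate
consistency for every gene of that shape. The smallest-k tie-break and the
fine pass's ability to split merged clusters both lean against that error.

## DP-GP refinement (fine pass)

Each coarse cluster is refined with a Dirichlet-process mixture of
Gaussian processes: each sub-cluster has a latent mean
f ~ GP(0, k_SE(σ_f², ℓ)) on the time grid and members are f plus i.i.d.
N(0, σ_n²) noise. The marginal likelihood of an n-member cluster uses the
exchangeable decomposition

    log p(y_1..n) = log N(ȳ; 0, K + σ_n²/n I)
                    − (n−1)T/2 · log(2πσ_n²) − T/2 · log n − SS_w/(2σ_n²),

algebraically equal to the dense nT-dimensional Gaussian but requiring only
a T × T Cholesky factor, which is cached per cluster size. A jitter of
1e−8·σ_f² is added to the kernel diagonal.

Inference is collapsed Gibbs over the CRP partition (concentration α = 1):
an item joins an existing sub-cluster with probability ∝ size ×
marginal-likelihood ratio, or opens a new one ∝ α × its singleton marginal.
Default 1,000 sweeps, first half burned; post-burn-in partitions accumulate
the posterior co-clustering matrix, and the returned partition is the
sampled partition with least squared distance to that matrix. Given the
seed the sampler is fully deterministic.

**Hyperparameters.** Standalone, `estimate_hyperparams` uses
empirical-Bayes defaults: σ_f² = pooled member variance (floor 1e−4),
σ_n² = σ_f²/4, ℓ = half the time-grid span. Inside the full model the
noise is instead estimated from the replicate structure — pooled
across-replicate residual variance per (gene, condition, time point) — and
σ_f² is the pooled member variance in excess of that noise. The σ_f²/4
heuristic is biased in both directions (it over-splits flat clusters,
where members have little variance, and under-splits clusters holding two
shapes, where pooled variance conflates signal with noise); the replicate
residual is an unbiased noise estimate the model has direct access to.
Hyperparameters are estimated once per coarse cluster and held fixed
across sweeps, keeping the sampler fast and deterministic.

## Replicate sorting and shift classification

A gene-condition's consensus label is the label shared by ≥ `min_agree`
replicates (`min_agree` must exceed m/2 so the consensus is unique; 3/3
strict and 2/3 loose are the modes for triplicates). OFF status takes
precedence over clustering: an off profile is never clustered and its label
is OFF regardless of sorting. Consensus label pairs map to categories:

| control | treated | category |
|---|---|---|
| OFF | dynamic | A (off → dynamic) |
| dynamic | OFF | B (dynamic → off) |
| dynamic | different dynamic | C |
| dynamic | same dynamic | non-shift |
| OFF | OFF | off-in-both (excluded from shift statistics) |
| any unqualified side | — | unqualified |

The summary counts satisfy shift = A + B + C and qualified = shift +
non-shift by construction. Qualified genes sharing one (control, treated)
label signature form trajectory sets, named `{prefix}{rank}` by descending
size (ties by signature string). An optional, off-by-default filter drops
shifts whose label-centroid difference is ≥ 80% concentrated at the first
time point — baseline-only differences usually reflect pre-treatment noise
rather than response; the threshold is a declared heuristic.

One global `min_agree` applies to both conditions; mixed per-condition
modes are not supported.

## Hold-out validation

The final dynamic labelling is validated by a stratified 70/30 split:
classes with < 2 members are excluded (they cannot appear on both sides),
a classifier is trained on the 70% and scored on the 30% with a confusion
matrix and support-weighted F1. The classifier is pluggable; the default is
a 1-nearest-neighbour classifier under soft-DTW, chosen because it needs no
deep-learning backend while exercising the same contract. Weighted F1 is
reported because the class sizes are strongly unbalanced.

## Enrichment

One-sided (enrichment direction) Fisher exact tests on the 2×2 set ×
term table, where the background defaults to all genes of the input matrix;
only terms annotating ≥ 1 set member are tested, and singleton sets are
skipped. Benjamini-Hochberg runs within each annotation vocabulary (GO,
KEGG, ... ) separately by default, matching how per-vocabulary results are
usually reported; a global mode is available. Default significance
threshold p_adj < 0.001. GO-hierarchy ancestor propagation is out of scope.

## Synthetic data generator

The generator emulates the target study design: 5 time points, 3
replicates, 2 conditions, a parametric library of up to 8 trajectory
shapes on the log2 scale (late-up, early-up, transient peaks at 24/48 h,
monotone down, down-then-up, flat low/high; pairwise L2 separation well
above 4× the default noise sd of 0.1), a configurable fraction of off
profiles (exact zeros in every replicate) and injected shifts of all three
categories. Noise is Gaussian on the log2(FPKM+1) scale and mapped back by
2^x − 1 clipped at 0, so the analysis-scale noise model is exactly the
stated Gaussian. Replicate discordance — the failure mode replicate
sorting exists to catch — is a whole-replicate swap: with probability
0.05 per dynamic gene-condition profile, one replicate is drawn from a
different shape. Marginal off fractions are honoured as closely as the
injected A/B shifts allow (genes off in both conditions take up the
remainder of each margin).

What the generator does **not** emulate: RNA-seq count noise (negative
binomial over reads), library-size artifacts, gene-gene correlation,
batch effects, or time-warped/phase-shifted responses. Passing the
synthetic benchmarks therefore demonstrates correctness of the pipeline's
logic and its behaviour under well-separated shapes with i.i.d. noise, not
performance on real sequencing data.

## Problem sizes and desk-scale settings

The library defaults mirror the protocol the workflow was designed around
(k grid 35–90 step 5, 1,000 Gibbs sweeps, 3/3 sorting). The synthetic
benchmarks in the test suite and acceptance script use desk-scale settings
chosen for a single-CPU workstation: 500 genes (≈ 2,100 trajectories after
off-extraction), k grid 4–9 step 1, 5 restarts, 250 Gibbs sweeps; the null
run uses 300 genes and the byte-identity rerun 40. At these sizes the
end-to-end benchmark reaches shift-gene precision 1.0 and recall 0.88–0.98
across generator seeds, with a null false-shift rate of 0.

## Determinism

One run seed fans out to fixed per-stage seeds (coarse clustering, fine
clustering, validation split) through a seeded generator, so stages are
individually reproducible and a rerun with identical config and seed
produces byte-identical output tables. Summary JSON is written with sorted
keys and no timestamps.

## Known limitations

* The fine pass cannot merge sub-clusters across different coarse
  clusters; a coarse split of one true shape is unrecoverable downstream
  (see the k-selection discussion above).
* Quantile normalization distorts trajectories at very small gene counts.
* GP hyperparameters are fixed per coarse cluster, not resampled; the CRP
  concentration, burn-in fraction and least-squares partition choice are
  fixed conventions, each exposed as a config knob.
* The classifier validation measures label learnability, not biological
  truth; a confidently wrong clustering can still score a high F1.
* Only two-condition designs with a shared time grid and equal replicate
  counts are supported.
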