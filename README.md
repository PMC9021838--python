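# geneshift

Replicate-aware detection of **temporal gene-expression pattern shifts**
between two conditions in time-course RNA-seq.

Standard differential-expression tools compare conditions one time point at
a time and average biological replicates, which discards the sequential
structure of a time course and can hide (or invent) responses. `geneshift`
instead treats every replicate's expression trajectory as an independent
series, clusters all trajectories from both conditions into one shared
label space, and calls a gene *shifted* only when its replicates agree on a
temporal pattern within each condition and that pattern differs between
conditions. It was designed around a two-condition plant nodulation time
course (control vs. rhizobia-inoculated roots and shoots, five time points,
three replicates) but applies to any replicated two-condition expression
time course.

## Method

Starting from a genes × samples FPKM matrix whose sample names encode
condition, time and replicate:

1. **Off-profile extraction.** A gene is *unexpressed* (OFF) under a
   condition if at least one replicate is exactly 0.00 FPKM at every time
   point. This runs on raw FPKM, before normalization.
2. **Normalization.** Quantile normalization across samples, then
   log2(x + 1).
3. **Coarse clustering.** Soft-DTW K-means over all per-replicate
   trajectories (both conditions pooled). Soft dynamic time warping
   replaces the hard minimum of DTW with
   softmin_γ(v) = −γ log Σ exp(−v/γ), giving a differentiable alignment
   loss; centroids are soft-DTW barycenters found by gradient descent.
4. **Model selection.** The grid of k values is scored with the
   Davies-Bouldin, Calinski-Harabasz and silhouette indices; the consensus
   (best mean rank, ties to smallest k) is chosen.
5. **Fine clustering.** Each coarse cluster is refined with a Dirichlet
   process mixture of Gaussian processes (squared-exponential kernel,
   collapsed Gibbs sampling over the Chinese-restaurant-process partition),
   yielding composite labels `K{coarse}_D{fine}`.
6. **Replicate sorting & shift calls.** A gene-condition qualifies when
   ≥ `min_agree` of its replicates share one label (3/3 strict or 2/3
   loose). Qualified label pairs are classified:
   **A** off → dynamic, **B** dynamic → off, **C** dynamic → different
   dynamic, plus non-shift, off-in-both and unqualified.
7. **Validation & enrichment.** The final labelling is validated by a
   hold-out sequence classifier (stratified 70/30 split, weighted F1), and
   trajectory sets (genes sharing one control/treated label signature) are
   tested for functional-term enrichment with one-sided Fisher exact tests
   and Benjamini-Hochberg correction (default threshold p_adj < 0.001).

## Worked example

Generate a synthetic 120-gene expression matrix with known injected
shifts, fit the model, and print the run summary:

```python
import geneshift as gs

cfg = gs.SyntheticConfig(n_genes=120, seed=7)
gem, truth = gs.generate_gem(cfg)
gem.to_tsv("example_gem.tsv")

model = gs.GeneShiftModel.from_tsv(
    "example_gem.tsv",
    config=gs.GeneShiftConfig(k_grid=(4, 5, 6, 7, 8), n_init=5,
                              dpgp_max_iterations=250, seed=1))
res = model.fit()
print(res.summary())
```

```
GeneShift pattern-shift summary
===============================================
Genes in matrix                             120
Off in control (all time points)             36
Off in treated (all time points)             34
Off in both conditions                       30
Qualified in both (3/3 sorting)              72
Shift genes (A+B+C)                          10
  A: off -> dynamic                           5
  B: dynamic -> off                           4
  C: dynamic -> dynamic                       1
Non-shift genes                              62
Unqualified genes                            18
Chosen k                                      7
Trajectory sets                              15
Hold-out weighted F1                      0.985
```

Reading the numbers: 36 and 34 genes are silent (all-zero in ≥ 1 replicate
at every time point) under control and treatment respectively, 30 of them
under both. Of the genes qualifying under strict 3/3 replicate sorting, 10
change their temporal pattern between conditions — five switch on
(off → dynamic), four switch off, one changes from one dynamic pattern to
another — while 62 keep the same pattern. `res.shift_frame()` lists the
per-gene consensus labels, e.g.

```
gene_id control_label treated_label         category  n_agree_control  n_agree_treated
 G00007           OFF         K3_D0 A_off_to_dynamic                3                3
```

i.e. gene G00007 is silent in all control replicates and all three treated
replicates share fine cluster `K3_D0`.

The same run is available from the shell:

```bash
geneshift simulate --out gem.tsv --truth truth.tsv --n-genes 120 --seed 7
geneshift run --config run.yaml        # paths + model settings in YAML
geneshift enrich --sets trajectory_sets.tsv --annotations ann.tsv --out enr.tsv
```

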