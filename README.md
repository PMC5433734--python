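# netstrat

Cancer subtype stratification from somatic mutations propagated over
cancer-type-specific co-expression networks.

Somatic mutation profiles are too sparse to compare patients gene by gene:
two tumours of the same subtype rarely mutate the same genes. `netstrat`
addresses this by diffusing each patient's binary mutation profile over a
gene network built from that cancer type's own expression data, so that
mutations hitting different members of the same co-expressed module produce
similar smoothed profiles. The smoothed cohort is then clustered into
molecular subtypes and the subtypes are tested for survival differences and
subtype-specific mutated genes. It is aimed at computational biologists
working with tumour cohorts that have matched expression, mutation and
clinical data (TCGA-style inputs), and at anyone who wants a transparent,
fully scriptable implementation of network-based stratification with a
cancer-specific network.

## Method

1. **Significant co-expression network (SCN).** Spearman rank correlations
   ρ<sub>ij</sub> and two-sided p-values are computed for all gene pairs of
   the expression matrix *E*. The weighted co-expression network (CN) has
   edge weights |ρ<sub>ij</sub>|; the SCN keeps the unweighted edges whose
   Bonferroni-corrected p-value (over the g(g−1)/2 tested pairs) is below
   0.05.
2. **Network smoothing.** With W the SCN adjacency (zero diagonal) and
   W′ = D<sup>−1/2</sup> W D<sup>−1/2</sup>, the binary sample×gene mutation
   matrix F₀ is diffused by
   F<sub>t+1</sub> = α F<sub>t</sub> W′ + (1−α) F₀ (α = 0.7) until
   ‖F<sub>t+1</sub> − F<sub>t</sub>‖<sub>F</sub> < 10⁻⁷. Each patient is
   then quantile-normalised to a common distribution and the matrix is
   transposed to genes×samples.
3. **Graph-regularised NMF (netNMF).** The smoothed matrix F is factorised
   by min<sub>W,H≥0</sub> ‖F − WH‖²<sub>F</sub> + λ·trace(WᵀLW) with
   λ = 200 and L the Laplacian of the p-nearest-neighbour graph (p = 11) of
   the weighted CN, using multiplicative updates. Patients are labelled by
   average-linkage hierarchical clustering of the columns of H
   (**netNMF_HC**), which is more robust than per-sample argmax when a
   patient loads almost equally on two metagenes.
4. **Consensus clustering.** 80% of patients and genes are subsampled 100
   times; each replicate is re-smoothed and re-clustered, and the pairwise
   co-clustering frequencies (normalised by co-sampling frequencies) form a
   patient–patient similarity matrix that is cut into k subtypes by
   average-linkage clustering, for k = 2..8.
5. **Clinical association.** Subtypes are tested against 10-year survival
   (Kaplan–Meier, multi-group log-rank) and against stage/grade (Pearson's
   chi-squared); per-subtype differentially mutated genes are found with a
   Wilcoxon rank-sum statistic and SAM-style permutation q-values
   (1,000 permutations, q < 0.05).

A synthetic-cohort generator with planted expression modules,
subtype-specific mutation patterns and subtype-dependent survival makes the
whole pipeline testable without any data download.

## Worked example

```python
import pandas as pd
import netstrat as ns

# synthetic cohort: 150 patients, 300 genes, 3 planted subtypes
cohort = ns.generate_cohort(ns.SyntheticConfig(seed=7))

corr = ns.spearman_all_pairs(cohort.expression)
scn  = ns.build_scn(corr)                       # propagation graph
F0, scn = ns.align_universes(cohort.mutations, scn)
knn  = ns.knn_graph(ns.build_cn(corr), p=11).subset(scn.genes)

res = ns.consensus_cluster(F0, scn, knn, k=3, n_iter=20, seed=7)
labels = pd.Series(res.labels, index=F0.index)

surv = ns.logrank_test(labels, ns.truncate_followup(cohort.clinical))
smoothed = ns.smooth_profiles(F0, scn)
diff = ns.sam_qvalues(smoothed, labels, 2, n_perm=1000, seed=7)
```

This prints (via the obvious `print` calls):

```
SCN edges: 1305
cluster sizes: [44, 47, 59]
ARI vs planted subtypes: 1.0
log-rank: chi2=39.52 df=2 p=2.62e-09
subtype 2 differential genes at q<0.05: 90
```

The SCN recovers the planted co-expression modules (1,305 significant
edges), the three consensus subtypes match the planted ones exactly
(adjusted Rand index 1.0), the recovered subtypes separate survival
(log-rank p ≈ 3×10⁻⁹), and subtype 2's differential gene set picks up its
mutated module.

The same workflow is available from the shell:

```bash
netstrat simulate --seed 7 --out cohort/
netstrat run --config config.yaml --out-dir results/
```

where `config.yaml` points at the three input TSVs and overrides any of the
defaults (`alpha: 0.7`, `knn_p: 11`, `reg: 200`, `k_min: 2`, `k_max: 8`,
`consensus_iters: 100`, `frac: 0.8`, `scn_alpha: 0.05`,
`min_mutations: 10`, `horizon_years: 10`). Supplying `prior_network:` runs
the pipeline NBS-style over a fixed interaction network instead of the SCN.

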