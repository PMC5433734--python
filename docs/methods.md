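# Methods

This note records the model, the parameter choices, the numerical
conventions and the limits of what the test suite demonstrates.

## Model and workflow

The method assumes that genes with correlated expression in a given cancer
type tend to act in the same regulatory modules, so a mutation anywhere in
a module carries similar information. It therefore (i) learns a
cancer-type-specific gene graph from expression, (ii) diffuses each
patient's sparse binary mutation profile over that graph to a dense
"smoothed" profile, (iii) clusters the smoothed profiles with a
graph-regularised non-negative factorisation under a consensus wrapper, and
(iv) evaluates the clusters against survival and mutation content.

Two different graphs are used deliberately:

* the **SCN** (unweighted; Bonferroni-significant Spearman correlations)
  is the propagation medium, and
* the **p-nearest-neighbour graph of the weighted CN** (|ρ| weights,
  pre-significance) supplies the Laplacian that regularises the
  factorisation.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.7 | diffusion strength in (0,1); larger spreads mutation signal further from its seed gene |
| `tol` (smoothing) | 1e-7 | Frobenius-norm convergence threshold of the diffusion |
| `scn_alpha` | 0.05 | family-wise significance level of SCN edges after Bonferroni correction over g(g−1)/2 pairs |
| `knn_p` | 11 | neighbour count of the CN p-NN graph behind the Laplacian |
| `reg` (λ) | 200 | weight of trace(WᵀLW) in the netNMF objective |
| `k` | 2..8 | number of metagenes = number of subtypes per run |
| `consensus_iters` | 100 | subsampling replicates |
| `frac` | 0.8 | fraction of patients and of genes drawn per replicate, without replacement |
| `min_mutations` | 10 | samples with fewer mutated genes are dropped (strict "fewer than") |
| `horizon_years` | 10 | administrative-censoring horizon for the survival tests (365-day years) |
| `n_perm` | 1000 | label permutations behind the SAM q-values |

All of these are the method's operating point; every one is overridable in
the library, the YAML pipeline config and the CLI.

## Numerical choices

* **Spearman p-values** use the two-sided t approximation
  t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 df; |ρ| = 1 maps to p = 0. Constant
  genes get ρ = 0, p = 1 against all partners (hence never enter the SCN)
  rather than erroring; they still count toward the Bonferroni multiplier,
  which covers all g(g−1)/2 pairs.
* **p-NN ties** at the p-th weight break by ascending gene index, and
  zero-weight pairs are never neighbours, so at p ≥ n−1 the p-NN graph
  equals the weighted graph's support. Neighbour rank is taken on the CN
  weight |ρ|.
* **Convergence of the diffusion** is measured in the Frobenius norm.
  Because the spectral radius of W′ is ≤ 1, the iteration is a contraction
  with factor `alpha`; the fixed point (1−α)F₀(I−αW′)⁻¹ is implemented
  separately as a linear solve and used as an independent oracle in tests.
  Genes isolated in the propagation graph are kept; their smoothed value is
  (1−α)F₀ by construction, and their count is logged.
* **Quantile normalisation** maps each patient onto the mean
  order-statistic distribution; tied values receive the mean of the
  reference values their ranks span. With ties the sorted rows are
  therefore equal only up to tie collapsing (each row's total mass is
  preserved exactly); without ties they are bitwise identical.
  Normalisation happens per patient row, and the single transpose to
  genes×samples follows it.
* **netNMF updates** are the standard multiplicative rules for
  ‖F−WH‖²_F + λ·trace(WᵀLW) with the penalty on the gene-side factor:
  H ← H⊙(WᵀF)⊘(WᵀWH), W ← W⊙(FHᵀ+λAW)⊘(WHHᵀ+λDW), denominators floored at
  1e-12. Initial factors are uniform (0,1] entries scaled by
  sqrt(mean(F)/k), seeded. The stopping rule is relative objective change
  < 1e-6 or 1000 iterations: an absolute residual threshold is not
  attainable in general because the residual of a rank-k fit need not
  approach zero, so a relative-change rule is used instead and
  non-convergence is reported via a flag and the log, never an exception
  (replicates inside the consensus wrapper routinely use the capped
  iterate; the objective trace is still monotone).
* **netNMF_HC** clusters the raw (unnormalised) columns of H with average
  linkage on Euclidean distance — the same linkage the consensus step uses.
  Argmax ties break toward the smallest metagene index.
* **Consensus seeding**: replicate r draws its patient/gene subsample and
  its factorisation init from child seed `master + r`, making runs
  bit-reproducible and replicates independent. Gene subsampling restricts
  both graphs to the sampled genes without re-estimating edges, because the
  SCN is defined once from the full expression matrix. Pairs never
  co-sampled (vanishingly rare at frac 0.8 × 100 replicates) get
  similarity 0 with a warning.
* **Survival**: the 10-year restriction is implemented as administrative
  censoring — events after the horizon become censored observations at the
  horizon (boundary inclusive). The multi-group log-rank test and
  Kaplan–Meier estimator come from `lifelines`; the chi-squared test is
  Pearson's without continuity correction, with a logged warning when any
  expected count is below 5.
* **SAM q-values**: the per-gene statistic is the standardised rank-sum z
  with mid-ranks and tie-corrected variance (ranks are scale-free, so no
  exchangeability fudge factor is added). For each candidate threshold
  (every observed |z|), FDR = median over permutations of the null
  exceedance count divided by the observed exceedance count; a gene's
  q-value is the minimum FDR over thresholds at or below its own |z|,
  capped at 1 — monotone non-increasing in |z| by construction. The
  permutations re-draw the one-vs-rest split across all samples from the
  given seed. Selection at q < 0.05 is strict at the boundary. The module
  accepts smoothed or raw binary input; the pipeline uses smoothed values
  by default and records the choice in its manifest.

## Synthetic cohorts

The generator emulates exactly the structure the method exploits:
block-correlated expression (one latent factor per subtype module, loading
mapped from the target within-module Spearman correlation through
ρ_s = (6/π)·arcsin(r/2), values exponentiated so expression is positive),
independent Bernoulli mutations at a high rate inside a sample's own
subtype module and a low background rate elsewhere, and exponential
survival with per-subtype hazards plus independent exponential censoring
calibrated to the target censoring fraction. Defaults are the
strong-signal regime used throughout the tests: 150 samples, 300 genes,
3 subtypes with 30-gene modules, within-module correlation 0.7, module
mutation rate 0.5 over background 0.02, per-day hazards (5e-3, 2e-3, 1e-3)
— a five-fold hazard ratio between extreme subtypes with median survival
of roughly 139/347/693 days — and 20% censoring.

What the generator does **not** model: mutational signatures and
hypermutators, mutual exclusivity within modules, copy-number or
methylation signal, overlapping modules, batch effects, and non-module
co-expression structure. Passing tests therefore show that the
implementation is correct and that the method recovers planted structure
of the kind it assumes; they do not certify performance on real tumour
cohorts, where module structure is weaker and confounded.

Small test fixtures with few genes raise the background mutation rate
(0.15) so that typical samples clear the 10-mutation burden filter, which
is calibrated to exome-scale panels; the zero-signal null analysis
disables that filter so the null is evaluated on the whole cohort rather
than on the few samples that pass it by chance.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
propagation is validated on 20 random graphs of up to 100 genes at four
values of α against the exact linear solve; optimiser checks use 50×30
instances over 10 seeds; the SCN null uses 50 genes × 100 samples × 20
seeds; end-to-end recovery uses the default 150×300 cohort with 20
consensus replicates (10 for the null); calibration uses 500 chi-squared
simulations and 20 SAM runs at 150 permutations. These sizes give stable
pass/fail behaviour while keeping a full run in the tens of seconds.

## Known limitations

* Gene matching across inputs is exact string equality; no alias
  resolution (unmatched symbols are logged and dropped).
* The SCN is O(g²) in memory for the correlation and adjacency matrices;
  the correlation pass is blocked over columns, but genome-scale runs
  (2×10⁴ genes) need on the order of 10 GB for the dense g×g matrices.
* Consensus replicates are sequential; determinism, not wall-clock, was
  the design priority.
* One seeded initialisation per consensus replicate (no multi-restart
  factorisation); the consensus wrapper is what provides robustness.
* Model-order selection across k = 2..8 is reported, not automated: the
  clinical association tables are the intended basis for choosing k.
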