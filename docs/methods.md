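# Methods

## Model and procedure

The inference treats functional potential as a property carried by taxa:
if a reference cohort provides paired taxonomic (L) and functional (R)
profiles on the same samples, the covariance between the two tables can be
transferred to query samples (Q) profiled only taxonomically. The transfer
is the fourth-corner (RLQ) construction:

* L is decomposed by correspondence analysis. Working with the χ²-residual
  table `L* = P/(rw ⊗ cw) − 1` (not its eigendecomposition) keeps the full
  association structure; sample weights `rw` and taxon weights `cw` are the
  margins of `P = L/total`.
* R is centered per function with weights `rw`; the removed weighted means
  `waR` are the cohort-average functional profile.
* Q is centered per taxon with weights `cw`.
* `inferred = Rc' D_rw L* D_cw Qc + waR` (broadcast per function row).

The estimator is a weighted cross-covariance projection: the inferred
value of function *f* in query sample *s* is a similarity-weighted
combination of the reference samples' functional values, where similarity
is measured between taxonomic residual profiles in the CA metric. It never
inverts the taxa covariance, so it is not a regression: its feature-wise
accuracy is bounded by how much of the functional variation is aligned
with the dominant taxonomic covariance, even with a noiseless reference.
This is the intended behaviour — the procedure degrades gracefully when
taxa outnumber samples, at the cost of smoothing over taxon-specific
detail.

### Assumptions

* R and L describe the same samples; L and Q share taxon identifiers.
* Functional profiles covary with taxonomic profiles in the reference
  habitat. The RV permutation test (`coinertia_rv`, and the automatic
  warning in `ipco infer`) checks this; without significant co-inertia,
  feature-level predictions carry no information (the shuffled-reference
  null demonstrates exactly this).
* Inferred values live on the transformed scale of the chosen transform.
  No inverse transform exists for Hellinger residuals, so none is applied.
  Spearman-based evaluation is unaffected (the transforms are monotone
  within the compared axis).

## Transformations

Six transforms are provided (features × samples orientation; per-sample
ones operate on columns): Hellinger (default), proportion, z-scaling
(per-feature, population-sd convention, constant features map to zeros),
log10 of proportions and of rarefied counts (pseudocount 1e-5 by default,
configurable), and clr (same pseudocount). Hellinger is the default
because it gave the strongest reference co-inertia in practice while
keeping the link table nonnegative, which the CA step requires; clr and
z-scaling produce negative entries in L and are rejected for the link
table with a clear error (they remain available for R in principle and
for co-inertia checks).

Rarefaction is seeded, without replacement (multivariate hypergeometric),
so zero counts never become positive and each column sums exactly to the
requested depth.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `transform` | hellinger | common transform for R, L, Q |
| `scale` | false | also divide centered columns by weighted sd; off because the re-standardisation adds only the weighted mean back |
| `min_shared_taxa_fraction` | 0.5 | minimum fraction of query abundance carried by taxa shared with L; below this the reference is refused |
| `min_reads` | 1000 | samples with fewer total counts are dropped before inference |
| `reference_fraction` | 0.5 | bootstrap split of the paired cohort (reference side) |
| `n_iterations` | 100 | bootstrap iterations; splits are simple random, unstratified |
| pseudocount | 1e-5 | added before log/clr transforms |

Coverage binning grades functions by mean pathway coverage: fixed cuts
0.01/0.1 (the KEGG convention) or quantile cuts at the first quartile and
median of the mean-coverage distribution (the MetaCyc convention), with
half-open bins [0, low) / [low, high) / [high, ∞).

Statistical machinery: Spearman correlation throughout (Pearson on average
ranks; constant vectors yield missing, never 0); two-sided p-values by
exact enumeration over rank pairings for n < 10 and the t-approximation
otherwise; Benjamini–Hochberg adjustment across the full association
family. The metabolite log10(x + pseudocount) transform is monotone and
therefore rank-neutral; it is applied for consistency of exported values
only. Permutation p-values use the (k+1)/(n+1) estimator and can never be
exactly zero.

## The synthetic community generator

`simulate_paired` produces a paired dataset with a known taxon→function
map so that recovery, null and calibration behaviour are all testable
without external data:

* **Genome content** — per-function carrier probabilities are lognormal
  around the mean `genome_density` (0.15), so functions range from
  near-universal to carried by one or two specialist taxa; carriers get
  lognormal copy numbers. This spread is what makes per-function coverage
  (the fraction of samples with at least one carrier present) an
  informative quality grade, as it is for real pathway coverage.
* **Community structure** — per-sample expected taxon proportions are the
  softmax of a lognormal base profile (σ = 2.5, strong gut-like dominance)
  modulated along 3 latent sample gradients (σ = 2.0), with Dirichlet
  overdispersion (total concentration 2·10⁴) and multinomial counts at
  depth 2·10⁴. Concentrating between-sample variation on a few gradients
  reflects the low-dimensional structure (enterotype-like axes) of real
  gut cohorts; it is also the regime in which a few dozen reference
  samples can carry learnable taxon/function covariance at all. With
  exchangeable (gradient-free) Dirichlet variation, no method — including
  a supervised regression oracle — recovers feature profiles from a
  40-sample reference, so that regime would test the dataset, not the
  estimator.
* **Functional truth** — `genome' · relative abundances`, optionally
  perturbed by multiplicative lognormal noise (`noise_sd`), renormalised
  per sample. `weak_covariance=True` routes an independently drawn
  community through the same genome matrix, emulating habitats where
  taxonomy and function do not covary (the known failure mode for this
  family of methods).

What the generator does **not** emulate: 16S copy-number and amplicon
primer bias, taxonomic mis-assignment, pathway-level regrouping effects,
and cross-cohort batch structure. Passing benchmarks therefore show the
machinery is correct and calibrated, not that any particular real habitat
reaches the same accuracy.

### Benchmark sizes and observed behaviour

The standard benchmark (defaults, `noise_sd=0`, 100 bootstrap iterations,
50:50 split, seed 42) was sized to run in seconds: 150 taxa, 60 functions,
80 samples. On it, the bootstrap median per-function Spearman correlation
is ≈ 0.79 overall and ≥ 0.8 for functions at or above the median coverage;
the high-coverage half clearly outperforms the low-coverage half; the
shuffled-reference null drives the median feature correlation to ≈ 0 while
sample-wise correlation stays ≈ 0.9 (functional redundancy — which is why
sample-level agreement should never be quoted as evidence of inference
quality); mean feature correlation rises steeply from a 10 % to a 50 %
reference and plateaus beyond. The ≈ 0.79 overall median is the
estimator's ceiling here, not a noise effect: in-sample inference (Q = L)
reaches ≈ 0.83 on the same data while a ridge-regression oracle reaches
≈ 0.96, the gap being the price of the covariance-projection form noted
above.

## Numerical choices

* Zero-margin taxa/samples are dropped explicitly during alignment (with
  logging), never silently inside the CA, which raises on zero margins.
* `filter_low_inferred` uses linear-interpolation quantiles and retains
  means ≥ threshold, so full ties are never all removed.
* The quantile coverage bins assign ties at a cut to the upper bin;
  the above/below-median coverage comparison counts ties as "below".
* Weighted centering normalises weights internally, so unnormalised
  weights give identical results; `waR` divides by Σrw explicitly.
* TSV output uses full repr precision by default so reruns are
  byte-comparable; `--precision` rounds for human consumption.
* All randomness (rarefaction, bootstrap splits, permutation tests,
  simulation) flows from explicit seeds; unset CLI seeds are drawn once
  and recorded in the run metadata.

## Known limitations

* Feature-wise accuracy is intrinsically bounded (see above); functions
  carried only by rare specialist taxa are recovered poorly even from a
  noiseless reference.
* The inferred scale is not abundance: downstream consumers needing
  abundances must work with ranks or refit on the transformed scale.
* BIOM support is read-only (JSON 1.0 and HDF5 2.x layouts).
* The feature-space RV variant reported alongside sample-space RV in some
  co-inertia work is not implemented; `coinertia_rv` is sample-space.
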