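# ipco

Inference of functional profiles for 16S amplicon samples by double
co-inertia (RLQ / fourth-corner analysis) against a paired
taxonomic–functional reference.

## The problem

16S rRNA amplicon sequencing yields taxonomic composition but no direct
functional (gene/pathway) information, while shotgun metagenomics (mWGS)
yields both at much higher cost. Genome-catalogue tools (PICRUSt, Tax4Fun,
Piphillin) predict function from taxonomy via annotated reference genomes;
this package takes a different route: it exploits the *covariance* between
a paired taxonomic table and functional table measured on the same
reference samples, and transfers that covariance structure to new samples
for which only 16S data exist.

## The method

Three feature tables are involved (all features × samples):

* **R** — reference functional table (functions × reference samples),
* **L** — reference taxonomic table (taxa × reference samples, paired with
  R sample-by-sample),
* **Q** — query taxonomic table (taxa × query samples, sharing taxon
  identifiers with L).

After a common transformation (Hellinger, √ of per-sample relative
abundance, by default), the pipeline is the classic RLQ construction:

1. Correspondence analysis of L gives sample weights `rw` (row weights),
   taxon weights `cw`, and the χ²-residual table
   `L* = P/(rw ⊗ cw) − 1`, with `P = L / grand total`.
2. R is column-centered with weights `rw` ("PCA of R weighted by samples
   from L"); the removed weighted means are
   `waR_f = Σ_i rw_i R_if / Σ_i rw_i`.
3. Q is row-centered (per taxon) with weights `cw`.
4. The fourth-corner cross table is
   `product = Rc' · D_rw · L* · D_cw · Qc`  (functions × query samples).
5. Inferred profiles: `inferred[f, s] = product[f, s] + waR_f`, i.e. the
   weighted mean functional abundance plus the query sample's
   covariance-driven deviation. Values are reported on the transformed
   scale.

Everything around the core — the six normalising transforms, sample-depth
filtering, seeded rarefaction, bootstrap hold-out validation with Spearman
summaries, a shuffled-reference negative control, the RV-coefficient
permutation test for reference suitability, coverage-based quality
binning, and metabolite association with Benjamini–Hochberg adjustment —
is included, along with a synthetic community generator with known
taxon→function structure so the whole pipeline is testable without any
external dataset.

## Worked example

```python
from ipco import simulate_paired, split_reference_query, ipco_infer
from ipco import feature_correlations, sample_correlations

# a paired community with known taxon->function structure
data = simulate_paired(n_samples=80, seed=42, noise_sd=0.0)
R, L, Q, truth = split_reference_query(data, fraction=0.5, seed=0)

inferred = ipco_infer(R, L, Q)          # Hellinger transform, centering only
print("inferred shape:", inferred.values.shape)

f_rho = feature_correlations(inferred, truth)
s_rho = sample_correlations(inferred, truth)
print(f"median feature correlation: {f_rho.median():.2f}")
print(f"median sample  correlation: {s_rho.median():.2f}")
```

prints

```
inferred shape: (60, 40)
median feature correlation: 0.84
median sample  correlation: 0.91
```

The 60 functions of the held-out 40 query samples are inferred purely from
their taxa; the feature correlation says how well each function's
across-sample variation is recovered (the stringent check), the sample
correlation how well each sample's functional ranking is recovered (always
optimistic because abundant functions are shared across samples —
functional redundancy).

The same run from the shell:

```bash
ipco simulate --seed 42 --noise-sd 0 --split-fraction 0.5 --out-dir sim
ipco infer --reference-function sim/R.tsv --reference-taxa sim/L.tsv \
           --query sim/Q.tsv --min-reads 0 --seed 1 --out inferred.tsv
# INFO ipco: reference co-inertia: RV=0.967 p=0.0050
# wrote inferred.tsv (60 functions x 40 query samples)
```

Each CLI run writes a side-car `.meta.json` with the resolved parameters
and seed, and warns when the supplied reference shows no significant
taxon/function co-inertia (in which case feature-level predictions are
unreliable). Further subcommands: `ipco validate` (bootstrap hold-out
validation, optionally with `--shuffle-reference` as a negative control),
`ipco coinertia`, `ipco bin-coverage`, `ipco associate`.

## Scope notes

Inferred values live on the transformed (default Hellinger) scale; no
inverse transform is attempted. The cross-product assigns every function a
small non-zero score, so low-abundance noise can be removed with
`filter_low_inferred` / `--filter-quantile`. KO→pathway regrouping and raw
read processing are out of scope. See `docs/methods.md` for the model
details, parameter choices and limitations.
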