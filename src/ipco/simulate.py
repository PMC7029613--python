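"""Synthetic paired taxonomic/functional communities with known structure.

The generator encodes the premise the inference rests on: functions are
carried by genomes, so a sample's functional profile is (up to noise) a
linear mixture of its taxa — ``functional = genome_content' @ taxon relative
abundances``.  Taxon abundances follow a lognormal-base Dirichlet (strong
dominance structure, sample-to-sample heterogeneity, and realistic per-sample
absences of rare taxa), counts are multinomial at a fixed sequencing depth,
and functional noise is multiplicative lognormal so profiles stay
nonnegative.

Two structural choices make the benchmark informative rather than
degenerate.  First, carrier probabilities vary per function (lognormal
around the mean genome density): some functions are near-universal
housekeeping-like pathways, others are carried by one or two specialist
taxa.  That spread is what makes the per-function "coverage" (the fraction
of samples in which at least one carrier taxon is present) informative,
mirroring how pathway coverage grades inference quality on real data; a
flat carrier probability would make every function's coverage saturate
at 1.  Second, sample-to-sample variation is concentrated along a few
latent gradients (the enterotype-like axes real gut communities show)
rather than being exchangeable noise: a low-dimensional community is what
lets a few dozen reference samples carry learnable taxon/function
covariance, the regime where this style of inference is applicable at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .tables import FeatureTable, TableRole, write_feature_table


@dataclass(frozen=True)
class SyntheticParams:
    n_taxa: int = 150
    n_functions: int = 60
    n_samples: int = 80
    genome_density: float = 0.15
    abundance_model: str = "lognormal_dirichlet"
    depth: int = 20000
    noise_sd: float = 0.1
    seed: int = 0
    # spread of per-function carrier probabilities (lognormal sigma); 0 gives
    # a flat Bernoulli(genome_density) genome matrix
    density_sigma: float = 1.5
    # lognormal sigma of the per-taxon base abundances (gut-like dominance)
    abundance_sigma: float = 2.5
    # number and strength of latent community gradients (enterotype-like
    # axes along which the lognormal base profile is modulated per sample)
    n_gradients: int = 3
    gradient_sigma: float = 2.0
    # total Dirichlet concentration: residual (non-gradient) compositional
    # overdispersion around the gradient-driven expected profile
    concentration: float = 20000.0
    # lognormal sigma of gene copy numbers
    copy_number_sigma: float = 0.5
    # when true, functional profiles are generated from an independent
    # community passed through the same genome matrix: emulates habitats
    # where taxonomy and function do not covary (the regime where the
    # inference legitimately fails)
    weak_covariance: bool = False


@dataclass
class SyntheticDataset:
    """A paired community with known taxon-to-function structure."""

    genome_content: np.ndarray            # taxa x functions copy numbers
    taxa_counts: FeatureTable             # taxa x samples integer counts
    taxa_relative: FeatureTable           # taxa x samples true proportions
    functional_true: FeatureTable         # functions x samples
    coverage_true: FeatureTable           # functions x samples in {0,1}; mean = coverage
    params: SyntheticParams

    @property
    def seed(self) -> int:
        return self.params.seed

    def mean_coverage(self) -> np.ndarray:
        return self.coverage_true.values.mean(axis=1)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def simulate_paired(n_taxa: int = 150, n_functions: int = 60,
                    n_samples: int = 80, genome_density: float = 0.15,
                    abundance_model: str = "lognormal_dirichlet",
                    depth: int = 20000, noise_sd: float = 0.1,
                    seed: int = 0, density_sigma: float = 1.5,
                    abundance_sigma: float = 2.5,
                    n_gradients: int = 3,
                    gradient_sigma: float = 2.0,
                    concentration: float = 20000.0,
                    copy_number_sigma: float = 0.5,
                    weak_covariance: bool = False) -> SyntheticDataset:
    """Simulate a paired taxa/function dataset with known genome content.

    Per-sample expected taxon proportions are the softmax of a lognormal
    base profile modulated along ``n_gradients`` latent sample gradients;
    realised proportions add Dirichlet overdispersion at the given
    ``concentration`` and counts are multinomial at ``depth``.  Returns the
    taxa counts, the true per-sample functional profiles (columns
    renormalised to sum 1 after multiplicative exp(Normal(0, noise_sd))
    noise), and a per-function/per-sample support indicator whose row means
    are the true coverage.
    """
    if min(n_taxa, n_functions, n_samples) < 2:
        raise ValueError("all sizes must be >= 2")
    if not 0.0 < genome_density <= 1.0:
        raise ValueError("genome_density must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if abundance_model != "lognormal_dirichlet":
        raise ValueError(f"unknown abundance model {abundance_model!r}")
    params = SyntheticParams(n_taxa, n_functions, n_samples, genome_density,
                             abundance_model, depth, noise_sd, seed,
                             density_sigma, abundance_sigma, n_gradients,
                             gradient_sigma, concentration,
                             copy_number_sigma, weak_covariance)
    rng = np.random.default_rng(seed)

    # genome content: per-function carrier probability, then Bernoulli x
    # lognormal copy number; every function keeps at least one carrier
    dens = genome_density * rng.lognormal(-density_sigma**2 / 2, density_sigma,
                                          size=n_functions)
    dens = np.clip(dens, 1.0 / n_taxa, 1.0)
    present = rng.random((n_taxa, n_functions)) < dens[None, :]
    for f in np.nonzero(~present.any(axis=0))[0]:
        present[rng.integers(n_taxa), f] = True
    copies = rng.lognormal(0.0, copy_number_sigma, size=(n_taxa, n_functions))
    genome = np.where(present, copies, 0.0)

    # expected taxon proportions: lognormal base modulated along latent
    # gradients, then Dirichlet overdispersion and multinomial counts
    log_base = rng.normal(0.0, abundance_sigma, size=n_taxa)
    loadings = rng.normal(0.0, gradient_sigma / np.sqrt(n_gradients),
                          size=(n_taxa, n_gradients))
    scores = rng.normal(0.0, 1.0, size=(n_gradients, n_samples))
    eta = log_base[:, None] + loadings @ scores
    expected = np.exp(eta - eta.max(axis=0))
    expected /= expected.sum(axis=0)
    rel = np.stack([rng.dirichlet(concentration * expected[:, j])
                    for j in range(n_samples)], axis=1)
    counts = np.stack([rng.multinomial(depth, rel[:, j])
                       for j in range(n_samples)], axis=1).astype(float)

    func = genome.T @ rel                               # functions x samples
    if weak_covariance:
        # functional profiles decoupled from the taxa actually observed:
        # an independent community (fresh gradient scores) mixed through the
        # same genome matrix
        scores_ind = rng.normal(0.0, 1.0, size=(n_gradients, n_samples))
        eta_ind = log_base[:, None] + loadings @ scores_ind
        exp_ind = np.exp(eta_ind - eta_ind.max(axis=0))
        exp_ind /= exp_ind.sum(axis=0)
        rel_ind = np.stack(
            [rng.dirichlet(concentration * exp_ind[:, j]) for j in range(n_samples)],
            axis=1)
        func = genome.T @ rel_ind
    if noise_sd > 0:
        func = func * np.exp(rng.normal(0.0, noise_sd, size=func.shape))
    colsum = func.sum(axis=0)
    func = np.divide(func, colsum, out=np.zeros_like(func), where=colsum > 0)

    support = ((genome > 0).T.astype(float) @ (counts > 0).astype(float)) > 0

    taxa_ids = _ids("taxon_", n_taxa)
    func_ids = _ids("fn_", n_functions)
    sample_ids = _ids("sample_", n_samples)
    return SyntheticDataset(
        genome_content=genome,
        taxa_counts=FeatureTable(counts, taxa_ids, sample_ids, TableRole.TAXONOMIC),
        taxa_relative=FeatureTable(rel, taxa_ids, sample_ids, TableRole.TAXONOMIC),
        functional_true=FeatureTable(func, func_ids, sample_ids, TableRole.FUNCTIONAL),
        coverage_true=FeatureTable(support.astype(float), func_ids, sample_ids,
                                   TableRole.COVERAGE),
        params=params,
    )


def split_reference_query(d: SyntheticDataset, fraction: float = 0.5,
                          seed: int = 0) -> tuple[FeatureTable, FeatureTable,
                                                  FeatureTable, FeatureTable]:
    """Partition samples into a reference side and a query side.

    Returns ``(R, L, Q_taxa, F_truth)``: the reference side's functional and
    taxonomic tables and the query side's taxonomic and true functional
    tables.  The two sides are disjoint and exhaustive.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(d.taxa_counts.sample_ids)
    n = len(ids)
    n_ref = int(round(fraction * n))
    if n_ref < 3 or n - n_ref < 3:
        raise ValueError("each side of the split needs >= 3 samples")
    order = np.random.default_rng(seed).permutation(n)
    ref = [ids[i] for i in sorted(order[:n_ref])]
    qry = [ids[i] for i in sorted(order[n_ref:])]
    R = d.functional_true.select_samples(ref)
    L = d.taxa_counts.select_samples(ref)
    Q = d.taxa_counts.select_samples(qry)
    F = d.functional_true.select_samples(qry)
    return R, L, Q, F


def write_dataset(d: SyntheticDataset, out_dir) -> None:
    """Write R-style TSVs plus params.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_feature_table(d.functional_true, out / "functions.tsv")
    write_feature_table(d.taxa_counts, out / "taxa.tsv")
    write_feature_table(d.coverage_true, out / "coverage.tsv")
    with open(out / "params.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(d.params), fh, indent=2, sort_keys=True)
        fh.write("\n")
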