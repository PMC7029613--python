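"""Validation machinery: bootstrap splits, Spearman summaries, the
shuffled-reference null, coverage binning, and metadata association.

The validation design holds out samples: each iteration randomly splits the
paired dataset into a reference side (used as R and L) and a query side
(whose taxonomic table becomes Q), infers functional profiles for the query
samples, and compares them with the query side's observed functional table
by Spearman correlation in both directions — per sample across functions,
and per function across samples.  Shuffling the sample correspondence
between R and L before inference gives the negative control: feature-wise
signal must vanish, while sample-wise correlation can survive through
functional redundancy (abundant functions shared by many taxa) and is not a
useful null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import InferredTable, ipco_infer
from .tables import DEFAULT_PSEUDOCOUNT, FeatureTable, Transform

__all__ = [
    "ValidationConfig", "ValidationResult", "CoverageBins", "spearman",
    "spearman_with_pvalue", "sample_correlations", "feature_correlations",
    "bootstrap_validate", "bin_by_coverage", "associate_with_metadata",
]


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Pairs with missing values are removed first; at least 3 complete pairs
    are required.  Returns NaN (missing) when either vector is constant,
    never an arbitrary 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {x.size}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


_EXACT_N_MAX = 9
_perm_cache: dict[int, np.ndarray] = {}


def _exact_null_ge(rx: np.ndarray, ry: np.ndarray, observed: float) -> float:
    """Exact two-sided p-value by full enumeration of rank pairings.

    Conditions on the observed (tie-containing) rank vectors; feasible for
    n <= 9 (<= 362 880 pairings), vectorised as one matrix product.
    """
    n = rx.size
    if n not in _perm_cache:
        _perm_cache[n] = np.array(list(itertools.permutations(range(n))))
    perms = _perm_cache[n]
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    null = (rxc[perms] @ ryc) / denom
    return float(np.mean(np.abs(null) >= abs(observed) - 1e-12))


def spearman_with_pvalue(x, y) -> tuple[float, float]:
    """Spearman rho and a two-sided p-value.

    Exact permutation null for n < 10, the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    rho = spearman(x, y)
    n = x.size
    if np.isnan(rho):
        return rho, float("nan")
    if n <= _EXACT_N_MAX:
        p = _exact_null_ge(stats.rankdata(x), stats.rankdata(y), rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _paired_matrices(inferred, observed: FeatureTable
                     ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Restrict an inferred table and an observed table to shared IDs."""
    inf_tab = inferred.to_feature_table() if isinstance(inferred, InferredTable) else inferred
    shared_f = [f for f in inf_tab.feature_ids if f in set(observed.feature_ids)]
    shared_s = [s for s in inf_tab.sample_ids if s in set(observed.sample_ids)]
    if len(shared_f) < 3:
        raise ValueError(f"only {len(shared_f)} shared functions; need >= 3")
    if not shared_s:
        raise ValueError("no shared samples between inferred and observed tables")
    A = inf_tab.select_features(shared_f).select_samples(shared_s).values
    B = observed.select_features(shared_f).select_samples(shared_s).values
    return A, B, shared_f, shared_s


def sample_correlations(inferred, observed: FeatureTable) -> pd.Series:
    """Per-sample Spearman correlation across shared functions."""
    A, B, _, shared_s = _paired_matrices(inferred, observed)
    rhos = [spearman(A[:, j], B[:, j]) for j in range(len(shared_s))]
    return pd.Series(rhos, index=shared_s, name="sample_rho")


def feature_correlations(inferred, observed: FeatureTable) -> pd.Series:
    """Per-function Spearman correlation across shared samples."""
    A, B, shared_f, shared_s = _paired_matrices(inferred, observed)
    if len(shared_s) < 3:
        raise ValueError(f"only {len(shared_s)} shared samples; need >= 3")
    rhos = [spearman(A[i, :], B[i, :]) for i in range(len(shared_f))]
    return pd.Series(rhos, index=shared_f, name="feature_rho")


# ---------------------------------------------------------------------------
# bootstrap validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationConfig:
    """Settings for the bootstrap hold-out validation."""

    reference_fraction: float = 0.5
    n_iterations: int = 100
    transform: Transform = Transform.HELLINGER
    scale: bool = False
    seed: int = 0
    shuffle_reference: bool = False
    min_shared_taxa_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.reference_fraction < 1.0:
            raise ValueError("reference_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        self.transform = Transform(self.transform)


@dataclass
class ValidationResult:
    """Per-iteration and averaged Spearman correlations from the bootstrap.

    ``per_iteration_sample_rho`` is iterations x all samples with NaN where a
    sample was not on the query side of that iteration (the matrix is ragged
    by design); ``per_iteration_feature_rho`` is iterations x functions.
    Averages ignore missing entries.
    """

    per_iteration_sample_rho: pd.DataFrame
    per_iteration_feature_rho: pd.DataFrame
    config: ValidationConfig

    @property
    def mean_sample_rho(self) -> pd.Series:
        return self.per_iteration_sample_rho.mean(axis=0, skipna=True)

    @property
    def mean_feature_rho(self) -> pd.Series:
        return self.per_iteration_feature_rho.mean(axis=0, skipna=True)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, s in (("sample", self.mean_sample_rho),
                        ("feature", self.mean_feature_rho)):
            q = s.quantile([0.25, 0.5, 0.75])
            rows[name] = {"mean": s.mean(), "q1": q[0.25], "median": q[0.5],
                          "q3": q[0.75], "n": int(s.notna().sum())}
        return pd.DataFrame(rows).T


def bootstrap_validate(R: FeatureTable, L: FeatureTable,
                       Q_taxa_full: FeatureTable,
                       F_observed_full: FeatureTable,
                       cfg: ValidationConfig) -> ValidationResult:
    """Hold-out bootstrap validation of the inference.

    Each iteration draws ``reference_fraction`` of the paired samples
    without replacement as the reference side (R, L restricted), uses the
    remainder as query (taxa from ``Q_taxa_full``), infers, and correlates
    against the held-out ``F_observed_full`` columns.  With
    ``shuffle_reference`` the sample labels linking R to L are permuted
    before inference, destroying the taxon/function pairing while keeping
    both marginal tables intact — the negative control.
    """
    shared = [s for s in L.sample_ids if s in set(Q_taxa_full.sample_ids)]
    n = len(shared)
    n_ref = int(round(cfg.reference_fraction * n))
    if n_ref < 3 or n - n_ref < 3:
        raise ValueError(
            f"split of {n} samples at fraction {cfg.reference_fraction} leaves "
            f"a side with < 3 samples"
        )
    rng = np.random.default_rng(cfg.seed)
    sample_rows, feature_rows = [], []
    for _ in range(cfg.n_iterations):
        order = rng.permutation(n)
        ref_ids = [shared[i] for i in order[:n_ref]]
        qry_ids = [shared[i] for i in order[n_ref:]]
        r_it = R.select_samples(ref_ids)
        l_it = L.select_samples(ref_ids)
        if cfg.shuffle_reference:
            # break the R<->L pairing: R keeps its data but under permuted labels
            shuffled = [ref_ids[i] for i in rng.permutation(n_ref)]
            r_it = r_it.relabel_samples(shuffled)
        q_it = Q_taxa_full.select_samples(qry_ids)
        inferred = ipco_infer(r_it, l_it, q_it, transform=cfg.transform,
                              scale=cfg.scale,
                              min_shared_taxa_fraction=cfg.min_shared_taxa_fraction)
        obs = F_observed_full.select_samples(qry_ids)
        sample_rows.append(sample_correlations(inferred, obs))
        feature_rows.append(feature_correlations(inferred, obs))
    sample_df = pd.DataFrame(sample_rows).reindex(columns=shared)
    sample_df.index = range(cfg.n_iterations)
    feature_df = pd.DataFrame(feature_rows)
    feature_df.index = range(cfg.n_iterations)
    return ValidationResult(per_iteration_sample_rho=sample_df,
                            per_iteration_feature_rho=feature_df, config=cfg)


# ---------------------------------------------------------------------------
# coverage binning
# ---------------------------------------------------------------------------

@dataclass
class CoverageBins:
    """Low/medium/high quality bins from per-feature mean pathway coverage."""

    thresholds: tuple[float, float]
    scheme: str
    assignment: dict[str, str]
    counts: dict[str, int]
    mean_coverage: pd.Series


def bin_by_coverage(coverage: FeatureTable, scheme: str = "fixed",
                    low_cut: float = 0.01, high_cut: float = 0.1,
                    q_low: float = 0.25, q_high: float = 0.5) -> CoverageBins:
    """Bin features by mean pathway coverage into low/medium/high.

    Coverage is the per-sample fraction (0-1) of a pathway's reactions that
    were detected; its per-feature mean grades how trustworthy the inference
    of that pathway is.  ``fixed`` uses absolute cuts (the KEGG convention:
    mean < 0.01 low, > 0.1 high); ``quantile`` places the cuts at the q_low
    and q_high quantiles of the mean-coverage distribution (the MetaCyc
    convention: 1st quartile and median).  Quantile bins use the half-open
    convention [0, low) / [low, high) / [high, inf).
    """
    if coverage.shape[0] == 0 or coverage.shape[1] == 0:
        raise ValueError("coverage table is empty")
    means = pd.Series(coverage.values.mean(axis=1), index=coverage.feature_ids)
    if scheme == "fixed":
        if not low_cut < high_cut:
            raise ValueError("low_cut must be < high_cut")
        lo, hi = float(low_cut), float(high_cut)
        def assign(m: float) -> str:
            if m < lo:
                return "low"
            if m > hi:
                return "high"
            return "medium"
    elif scheme == "quantile":
        if not 0 <= q_low < q_high <= 1:
            raise ValueError("need 0 <= q_low < q_high <= 1")
        lo = float(means.quantile(q_low))
        hi = float(means.quantile(q_high))
        def assign(m: float) -> str:
            if m < lo:
                return "low"
            if m >= hi:
                return "high"
            return "medium"
    else:
        raise ValueError(f"unknown scheme {scheme!r} (expected 'fixed' or 'quantile')")
    assignment = {f: assign(m) for f, m in means.items()}
    counts = {b: 0 for b in ("low", "medium", "high")}
    for b in assignment.values():
        counts[b] += 1
    return CoverageBins(thresholds=(lo, hi), scheme=scheme,
                        assignment=assignment, counts=counts,
                        mean_coverage=means)


# ---------------------------------------------------------------------------
# metadata / metabolite association
# ---------------------------------------------------------------------------

def associate_with_metadata(func, metabolites: FeatureTable,
                            pseudocount: float = DEFAULT_PSEUDOCOUNT,
                            alpha: float = 0.05,
                            log_metabolites: bool = True) -> pd.DataFrame:
    """Correlate every function with every metabolite/metadata variable.

    Metabolite levels are log10(x + pseudocount) transformed when
    nonnegative (a monotone map, so ranks — and hence rho — are unchanged;
    it is applied for consistency of any exported values).  All pairwise
    Spearman correlations are computed with two-sided p-values and
    Benjamini-Hochberg adjusted across the full function x metabolite
    family.  Returns a tidy frame with one row per pair.
    """
    f_tab = func.to_feature_table() if isinstance(func, InferredTable) else func
    shared = [s for s in f_tab.sample_ids if s in set(metabolites.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    F = f_tab.select_samples(shared).values
    M = metabolites.select_samples(shared).values
    if log_metabolites:
        if (M < 0).any():
            raise ValueError(
                "metabolite table has negative values; pass log_metabolites=False"
            )
        M = np.log10(M + pseudocount)
    rows = []
    for i, fid in enumerate(f_tab.feature_ids):
        for j, mid in enumerate(metabolites.feature_ids):
            rho, p = spearman_with_pvalue(F[i, :], M[j, :])
            rows.append((fid, mid, rho, p))
    df = pd.DataFrame(rows, columns=["function_id", "metabolite_id", "rho", "p_value"])
    ok = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["p_adjusted"] = adj
    df["direction"] = np.sign(df["rho"]).astype("Int64")
    df["significant"] = df["p_adjusted"] <= alpha
    return df
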