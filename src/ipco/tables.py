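"""Abundance tables, file IO, normalising transformations and depth filtering.

The canonical in-memory and on-disk orientation is features x samples, the
convention used by HUMAnN-style functional profilers and most OTU-table
exporters.  Downstream ordination code transposes internally where it needs
samples in rows.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


class TableRole(str, enum.Enum):
    """What a feature table measures."""

    TAXONOMIC = "taxonomic"
    FUNCTIONAL = "functional"
    COVERAGE = "coverage"
    METABOLITE = "metabolite"


class Transform(str, enum.Enum):
    """Per-table normalisation methods.

    ``hellinger``        square root of per-sample relative abundance
    ``proportion``       per-sample relative abundance
    ``zscale``           per-feature standardisation across samples
    ``log10_proportion`` log10(relative abundance + pseudocount)
    ``log10_rarefied``   log10(rarefied count + pseudocount)
    ``clr``              centred log-ratio within each sample
    ``none``             identity
    """

    HELLINGER = "hellinger"
    PROPORTION = "proportion"
    ZSCALE = "zscale"
    LOG10_PROPORTION = "log10_proportion"
    LOG10_RAREFIED = "log10_rarefied"
    CLR = "clr"
    NONE = "none"


#: default pseudocount for log-ratio style transforms (configurable everywhere)
DEFAULT_PSEUDOCOUNT = 1e-5

_NONNEGATIVE_ROLES = frozenset(
    {TableRole.TAXONOMIC, TableRole.FUNCTIONAL, TableRole.COVERAGE}
)


def _check_unique(ids: list[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {what} IDs: {', '.join(dups)}")


@dataclass
class FeatureTable:
    """A nonnegative features x samples abundance matrix with string IDs.

    Parameters
    ----------
    values
        2-D float array, one row per feature, one column per sample.
    feature_ids, sample_ids
        Unique string identifiers matching the matrix dimensions.
    role
        What the table measures; nonnegativity is enforced for taxonomic,
        functional and coverage tables (metabolite tables may carry
        already-transformed, possibly negative, measurements).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    role: TableRole = TableRole.TAXONOMIC

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(i) for i in self.feature_ids]
        self.sample_ids = [str(i) for i in self.sample_ids]
        self.role = TableRole(self.role)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} feature IDs x {len(self.sample_ids)} sample IDs"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            r, c = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.role in _NONNEGATIVE_ROLES and (self.values < 0).any():
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    # -- constructors / converters ------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, role: TableRole | str = TableRole.TAXONOMIC
                   ) -> "FeatureTable":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)),
                   list(df.columns.astype(str)), TableRole(role))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.feature_ids),
                            columns=list(self.sample_ids))

    # -- basic queries ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def feature_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def select_samples(self, ids: list[str]) -> "FeatureTable":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample IDs: {', '.join(missing)}")
        cols = [pos[s] for s in ids]
        return replace(self, values=self.values[:, cols], sample_ids=list(ids))

    def select_features(self, ids: list[str]) -> "FeatureTable":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"unknown feature IDs: {', '.join(missing)}")
        rows = [pos[f] for f in ids]
        return replace(self, values=self.values[rows, :], feature_ids=list(ids))

    def relabel_samples(self, ids: list[str]) -> "FeatureTable":
        return replace(self, sample_ids=list(ids))


@dataclass
class TransformedTable(FeatureTable):
    """A feature table after one of the normalising transforms.

    Values may be negative (clr, zscale, log variants); the transform tag and
    the pseudocount used are recorded so downstream output can state its scale.
    """

    transform: Transform = Transform.NONE
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.transform = Transform(self.transform)
        # transformed values live on an arbitrary real scale: skip the
        # role-based nonnegativity check but keep the structural ones
        role = TableRole(self.role)
        self.role = TableRole.METABOLITE  # placeholder to bypass sign check
        super().__post_init__()
        self.role = role


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "tsv",
                       role: TableRole | str = TableRole.TAXONOMIC) -> FeatureTable:
    """Read a features x samples table from TSV or BIOM.

    The TSV dialect is tab-separated UTF-8 with a header row of sample IDs
    (first header cell ignored) and the first column holding feature IDs.
    BIOM (1.0 JSON or 2.x HDF5) is supported read-only.
    """
    if format == "biom":
        from ._biom import read_biom
        df = read_biom(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                         float_precision="round_trip",
                         dtype_backend="numpy_nullable")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        bad = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
        if len(bad):
            col = bad[0]
            nonnum = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            where = nonnum.index[0] if len(nonnum) else "?"
            raise ValueError(
                f"non-numeric cell at feature {where!r}, sample {col!r} in {path}"
            )
        df = df.astype(float)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom')")
    _check_unique(list(df.index), "feature")
    _check_unique(list(df.columns), "sample")
    if df.isna().any().any():
        raise ValueError(f"missing value in {path}")
    return FeatureTable.from_frame(df, role)


def write_feature_table(t: FeatureTable, path, precision: int | None = None) -> None:
    """Write a table as TSV; full repr precision unless ``precision`` given."""
    df = t.to_frame()
    fmt = None if precision is None else f"%.{precision}g"
    df.to_csv(path, sep="\t", index_label="#ID", float_format=fmt)


# ---------------------------------------------------------------------------
# filtering / rarefaction
# ---------------------------------------------------------------------------

def filter_low_depth(t: FeatureTable, min_reads: int = 1000) -> FeatureTable:
    """Drop samples with fewer than ``min_reads`` total counts.

    Mirrors the usual amplicon QC step of discarding shallowly sequenced
    samples before any normalisation.
    """
    sums = t.sample_sums()
    keep = [s for s, tot in zip(t.sample_ids, sums) if tot >= min_reads]
    if not keep:
        raise ValueError(
            f"all {len(t.sample_ids)} samples have depth < {min_reads}"
        )
    return t.select_samples(keep)


def rarefy(t: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each column is drawn from the multivariate hypergeometric distribution on
    its counts, so a zero count can never become positive and each rarefied
    column sums exactly to ``depth``.
    """
    counts = np.rint(t.values).astype(np.int64)
    if not np.allclose(t.values, counts):
        raise ValueError("rarefy requires integer counts")
    sums = counts.sum(axis=0)
    shallow = [s for s, tot in zip(t.sample_ids, sums) if tot < depth]
    if shallow:
        raise ValueError(
            f"depth {depth} exceeds total counts of samples: {', '.join(shallow)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return replace(t, values=out.astype(float))


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def _column_proportions(t: FeatureTable) -> np.ndarray:
    sums = t.values.sum(axis=0)
    zero = [s for s, tot in zip(t.sample_ids, sums) if tot <= 0]
    if zero:
        raise ValueError(f"zero-sum sample columns: {', '.join(zero)}")
    return t.values / sums


def transform(t: FeatureTable, method: Transform | str,
              pseudocount: float = DEFAULT_PSEUDOCOUNT,
              rarefaction_depth: int | None = None,
              seed: int | None = None) -> TransformedTable:
    """Apply one of the normalising transforms to a features x samples table.

    hellinger and proportion are per-sample (column-local); zscale is
    per-feature across samples; the log variants add ``pseudocount`` before
    taking log10; clr divides by the per-sample geometric mean of the
    pseudocounted abundances.
    """
    method = Transform(method)
    if method is Transform.HELLINGER:
        vals = np.sqrt(_column_proportions(t))
    elif method is Transform.PROPORTION:
        vals = _column_proportions(t)
    elif method is Transform.ZSCALE:
        mu = t.values.mean(axis=1, keepdims=True)
        sd = t.values.std(axis=1, keepdims=True)  # population (n) convention
        centered = t.values - mu
        vals = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    elif method is Transform.LOG10_PROPORTION:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for log10_proportion")
        vals = np.log10(_column_proportions(t) + pseudocount)
    elif method is Transform.LOG10_RAREFIED:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for log10_rarefied")
        if rarefaction_depth is None:
            raise ValueError("log10_rarefied requires rarefaction_depth")
        if seed is None:
            raise ValueError("log10_rarefied requires a seed")
        vals = np.log10(rarefy(t, rarefaction_depth, seed).values + pseudocount)
    elif method is Transform.CLR:
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 for clr")
        logx = np.log(t.values + pseudocount)
        vals = logx - logx.mean(axis=0, keepdims=True)
    elif method is Transform.NONE:
        vals = t.values.copy()
    else:  # pragma: no cover - Transform() above rejects unknown names
        raise ValueError(f"unknown transform {method!r}")
    return TransformedTable(vals, list(t.feature_ids), list(t.sample_ids),
                            t.role, transform=method,
                            pseudocount=float(pseudocount))
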