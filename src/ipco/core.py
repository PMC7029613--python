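"""The fourth-corner functional inference itself.

The method relates three tables: a reference functional table R (functions x
reference samples), a reference taxonomic table L (taxa x reference samples,
paired with R sample-by-sample), and a query taxonomic table Q (taxa x query
samples, sharing taxon identifiers with L).  After a common transformation,
L is decomposed by correspondence analysis; R is centered by the CA sample
weights and Q by the CA taxa weights; their weighted cross-product through
the CA residual table is the fourth-corner association matrix, and adding
the weighted mean functional profile (waR) back to each function's row turns
the association scores into inferred functional profiles for the query
samples, on the transformed scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ordination import CADecomposition, CenteredTable, correspondence_analysis, weighted_center
from .tables import (
    DEFAULT_PSEUDOCOUNT,
    FeatureTable,
    TableRole,
    Transform,
    transform as apply_transform,
)

logger = logging.getLogger(__name__)


@dataclass
class AlignedTriplet:
    """R, L, Q restricted to a common sample and taxon universe.

    ``r`` and ``l`` share identical sample order; ``l`` and ``q`` share
    identical taxon order; no all-zero row or column remains in ``l``.
    Tables are still on the raw (untransformed) scale.
    """

    r: FeatureTable
    l: FeatureTable
    q: FeatureTable
    dropped_taxa_query: list[str]
    dropped_taxa_reference: list[str]
    dropped_samples_reference: list[str]
    taxa_ids: list[str]
    query_abundance_retained: float


@dataclass
class InferredTable:
    """Inferred functional profiles for the query samples.

    ``raw_product`` is the fourth-corner cross table (functions x query
    samples); ``values`` adds the weighted-mean functional abundance ``waR``
    back to each function's row.  Both live on the transformed scale of the
    chosen transform.
    """

    raw_product: np.ndarray
    values: np.ndarray
    waR: np.ndarray
    function_ids: list[str]
    query_sample_ids: list[str]
    transform: Transform
    scale_flag: bool

    def to_feature_table(self) -> FeatureTable:
        from .tables import TransformedTable

        return TransformedTable(self.values, list(self.function_ids),
                                list(self.query_sample_ids),
                                TableRole.FUNCTIONAL, transform=self.transform)

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)


def align_triplet(R: FeatureTable, L: FeatureTable, Q: FeatureTable,
                  min_shared_taxa_fraction: float = 0.5) -> AlignedTriplet:
    """Align the reference pair (R, L) and the query table Q.

    R and L must describe an identical sample set (paired reference); L and
    Q are restricted to their shared taxa.  Taxa or reference samples whose
    L margin becomes all-zero after the intersection would break the
    chi-square residuals and are dropped from every table they appear in.
    The fraction of Q's total abundance carried by the shared taxa is
    reported, and an unsuitable reference (fraction below
    ``min_shared_taxa_fraction``) is an error.
    """
    r_samples, l_samples = set(R.sample_ids), set(L.sample_ids)
    if r_samples != l_samples:
        only_r = sorted(r_samples - l_samples)
        only_l = sorted(l_samples - r_samples)
        raise ValueError(
            "R and L must be paired on the same samples; "
            f"only in R: {only_r or '-'}, only in L: {only_l or '-'}"
        )
    l_taxa = set(L.feature_ids)
    shared_taxa = [t for t in L.feature_ids if t in set(Q.feature_ids)]
    dropped_q = [t for t in Q.feature_ids if t not in l_taxa]
    if len(shared_taxa) < 2:
        raise ValueError(
            f"L and Q share only {len(shared_taxa)} taxa; need >= 2"
        )
    q_total = Q.values.sum()
    retained = (
        float(Q.select_features(shared_taxa).values.sum() / q_total)
        if q_total > 0 else 0.0
    )
    if retained < min_shared_taxa_fraction:
        raise ValueError(
            f"shared taxa carry only {retained:.1%} of the query abundance "
            f"(< {min_shared_taxa_fraction:.0%}); the reference does not cover "
            "this community - use a reference with better taxonomic overlap"
        )
    logger.info("query abundance retained by shared taxa: %.1f%%", 100 * retained)

    l_sub = L.select_features(shared_taxa)
    # taxa with all-zero L rows after intersection break the CA margins
    zero_taxa = [t for t, s in zip(l_sub.feature_ids, l_sub.feature_sums()) if s <= 0]
    taxa_ids = [t for t in shared_taxa if t not in set(zero_taxa)]
    if len(taxa_ids) < 2:
        raise ValueError("fewer than 2 taxa with nonzero reference abundance remain")
    l_sub = l_sub.select_features(taxa_ids)
    # reference samples that lost all their abundance with the dropped taxa
    zero_samples = [s for s, tot in zip(l_sub.sample_ids, l_sub.sample_sums()) if tot <= 0]
    samples = [s for s in L.sample_ids if s not in set(zero_samples)]
    if len(samples) < 3:
        raise ValueError("fewer than 3 reference samples with shared-taxon abundance remain")
    l_sub = l_sub.select_samples(samples)
    r_sub = R.select_samples(samples)
    q_sub = Q.select_features(taxa_ids)
    if zero_taxa:
        logger.info("dropped %d taxa with zero reference margin: %s",
                    len(zero_taxa), ", ".join(zero_taxa))
    if zero_samples:
        logger.info("dropped %d reference samples with zero shared-taxon abundance: %s",
                    len(zero_samples), ", ".join(zero_samples))
    return AlignedTriplet(r=r_sub, l=l_sub, q=q_sub,
                          dropped_taxa_query=dropped_q,
                          dropped_taxa_reference=zero_taxa,
                          dropped_samples_reference=zero_samples,
                          taxa_ids=taxa_ids,
                          query_abundance_retained=retained)


def rlq_product(rc: CenteredTable, ca: CADecomposition,
                qc: CenteredTable) -> np.ndarray:
    """The fourth-corner cross table: functions x query samples.

    ``rc`` holds the centered reference functional table (reference samples x
    functions), ``qc`` the centered query taxonomic table (taxa x query
    samples).  Entry [f, s] is the double sum over reference samples i and
    taxa t of ``rc.xstar[i, f] * lw[i] * lstar[i, t] * cw[t] * qc.xstar[t, s]``,
    computed as chained matrix products.
    """
    n_ref, n_taxa = ca.lstar.shape
    if rc.xstar.shape[0] != n_ref:
        raise ValueError(
            f"centered R has {rc.xstar.shape[0]} rows, CA has {n_ref} samples"
        )
    if qc.xstar.shape[0] != n_taxa:
        raise ValueError(
            f"centered Q has {qc.xstar.shape[0]} rows, CA has {n_taxa} taxa"
        )
    middle = (ca.lw[:, None] * ca.lstar) * ca.cw[None, :]
    return rc.xstar.T @ middle @ qc.xstar


def ipco_infer(R: FeatureTable, L: FeatureTable, Q: FeatureTable,
               transform: Transform | str = Transform.HELLINGER,
               scale: bool = False,
               min_shared_taxa_fraction: float = 0.5,
               pseudocount: float = DEFAULT_PSEUDOCOUNT,
               rarefaction_depth: int | None = None,
               seed: int | None = None) -> InferredTable:
    """Infer functional profiles for the query samples.

    Pipeline: align the triplet, transform all three tables, decompose the
    transformed L by correspondence analysis, center transformed R by the CA
    sample weights (recording the weighted means, waR) and transformed Q by
    the CA taxa weights, form the fourth-corner product, and add waR back to
    each function row.  ``scale`` additionally divides centered columns by
    their weighted standard deviation (off by default: the re-standardisation
    step adds only the weighted mean back, implying centering-only).

    Output values are on the transformed scale; negative entries are
    possible and reported as-is.
    """
    trip = align_triplet(R, L, Q, min_shared_taxa_fraction)
    kw = dict(pseudocount=pseudocount, rarefaction_depth=rarefaction_depth)
    if Transform(transform) is Transform.LOG10_RAREFIED:
        kw["seed"] = seed if seed is not None else 0
    rt = apply_transform(trip.r, transform, **kw)
    lt = apply_transform(trip.l, transform, **kw)
    qt = apply_transform(trip.q, transform, **kw)
    if (lt.values < 0).any():
        raise ValueError(
            f"transform {Transform(transform).value!r} produces negative values "
            "in L, which correspondence analysis cannot accept"
        )
    ca = correspondence_analysis(lt)  # samples x taxa internally
    rc = weighted_center(rt.values.T, ca.lw, scale=scale)   # ref samples x functions
    qc = weighted_center(qt.values, ca.cw, scale=scale)     # taxa x query samples
    product = rlq_product(rc, ca, qc)
    waR = rc.weighted_means
    values = product + waR[:, None]
    return InferredTable(raw_product=product, values=values, waR=waR,
                         function_ids=list(trip.r.feature_ids),
                         query_sample_ids=list(trip.q.sample_ids),
                         transform=Transform(transform), scale_flag=bool(scale))


def filter_low_inferred(t: InferredTable, quantile: float) -> InferredTable:
    """Drop functions whose mean inferred abundance sits below a quantile.

    The cross-product assigns every function a small nonzero score, so the
    low tail is mostly noise; this removes functions whose across-sample
    mean falls below the given (linear-interpolation) quantile of all
    function means.  Retention is mean >= threshold.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    means = t.row_means()
    cut = float(np.quantile(means, quantile))
    keep = np.nonzero(means >= cut)[0]
    if keep.size == 0:
        raise ValueError("quantile filter would remove every function")
    return InferredTable(raw_product=t.raw_product[keep, :],
                         values=t.values[keep, :], waR=t.waR[keep],
                         function_ids=[t.function_ids[i] for i in keep],
                         query_sample_ids=list(t.query_sample_ids),
                         transform=t.transform, scale_flag=t.scale_flag)
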