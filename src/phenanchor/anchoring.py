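"""Phenotypic anchoring, fold-change profile clustering and gene-set
over-representation.

The anchoring stage asks whether the transcriptomic point of departure (a
module's median expression BMC) coincides with the apical phenotype's
benchmark concentration.  Supporting views: Ward clustering of mean log2
fold-change profiles across concentrations, and a generic hypergeometric
over-representation test of gene sets supplied as GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .dge import bh_adjust
from .phenotype import PhenotypeFit

__all__ = [
    "ward_cluster",
    "hypergeometric_enrichment",
    "AnchorReport",
    "anchor_report",
]


def ward_cluster(fc_profiles: pd.DataFrame, k_clusters: int = 6) -> pd.Series:
    """Ward-linkage agglomerative clustering of per-gene mean log2FC
    profiles (gene x concentration), cut at ``k_clusters``.

    Labels are re-assigned deterministically: clusters are numbered 1..k in
    decreasing order of their mean profile's grand mean (strongest
    responders first, ties by smallest member gene id).
    """
    n = fc_profiles.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes to cluster")
    if k_clusters > n:
        raise ValueError("k_clusters exceeds the number of genes")
    z = linkage(fc_profiles.to_numpy(float), method="ward")
    raw = fcluster(z, t=k_clusters, criterion="maxclust")
    labels = pd.Series(raw, index=fc_profiles.index, name="cluster")
    order = sorted(
        np.unique(raw),
        key=lambda c: (
            -float(fc_profiles.loc[labels == c].to_numpy().mean()),
            min(labels.index[labels == c]),
        ),
    )
    remap = {c: i + 1 for i, c in enumerate(order)}
    return labels.map(remap)


def hypergeometric_enrichment(
    query: set[str],
    terms: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    p = P(X >= k) with X ~ Hypergeom(N = |background|, K = |term inter
    background|, n = |query|); BH adjustment across terms.
    """
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not query:
        import warnings

        warnings.warn("empty query gene set", stacklevel=2)
        return pd.DataFrame(
            columns=["term_id", "k_overlap", "K_term", "n_query", "N_background", "p", "padj"]
        )
    n_bg, n_q = len(background), len(query)
    rows = []
    for term_id, members in terms.items():
        in_bg = members & background
        k = len(query & in_bg)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(in_bg), n_q))
        rows.append(
            {
                "term_id": term_id,
                "k_overlap": k,
                "K_term": len(in_bg),
                "n_query": n_q,
                "N_background": n_bg,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


@dataclass
class AnchorReport:
    """Transcriptomic module BMC vs phenotype BMC, side by side."""

    module_id: int
    median_bmc: Optional[float]
    median_bmdl: Optional[float]
    median_bmdu: Optional[float]
    mean_bmc: Optional[float]
    n_modeled: int
    phenotype_bmc: Optional[float]
    phenotype_bmdl: Optional[float]
    bmc_ratio: Optional[float]  # module median / phenotype BMC
    interval_overlaps_phenotype: Optional[bool]
    complete: bool

    def to_dict(self) -> dict:
        return asdict(self)


def anchor_report(
    module_summary: dict,
    phenotype_fit: PhenotypeFit,
    module_id: int = 1,
) -> AnchorReport:
    """Compare a module's median expression BMC with the phenotype BMC.

    ``module_summary`` is the output of :func:`phenanchor.bmc.geneset_bmc`.
    The ratio is module-median / phenotype BMC; the overlap flag says
    whether the phenotype BMC falls inside the module's [BMDL, BMDU]
    interval.  Undefined inputs yield a flagged partial report.
    """
    med = module_summary.get("median_bmc")
    p_bmc = phenotype_fit.bmc if not phenotype_fit.bmc_undefined else None
    ratio = None
    overlap = None
    if med is not None and p_bmc is not None:
        ratio = float(med / p_bmc)
        lo = module_summary.get("median_bmdl")
        hi = module_summary.get("median_bmdu")
        if lo is not None and hi is not None:
            overlap = bool(lo <= p_bmc <= hi)
    return AnchorReport(
        module_id=module_id,
        median_bmc=med,
        median_bmdl=module_summary.get("median_bmdl"),
        median_bmdu=module_summary.get("median_bmdu"),
        mean_bmc=module_summary.get("mean_bmc"),
        n_modeled=int(module_summary.get("n_modeled", 0)),
        phenotype_bmc=p_bmc,
        phenotype_bmdl=phenotype_fit.bmdl,
        bmc_ratio=ratio,
        interval_overlaps_phenotype=overlap,
        complete=med is not None and p_bmc is not None,
    )
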