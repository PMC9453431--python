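"""Leave-one-concentration-out (LOCO) edge-weight perturbation analysis.

For a module of interest, the network is re-inferred once per non-control
concentration with that concentration's replicate columns removed (same seed
and gene set as the full inference, so ratio variation reflects the data
removal and not ensemble randomness).  The ratio of full to reduced weight
for every ordered within-module pair, across the seven leave-outs, classifies
edges as *consistently higher* (ratio > 1 for every left-out concentration:
the edge depends on every concentration's data) and *progressively lost*
(additionally, ratios strictly increase with the left-out concentration —
the edge is driven ever more strongly by the higher concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExperimentDesign
from .network import NetworkConfig, infer_network

__all__ = [
    "loco_networks",
    "edge_weight_ratios",
    "classify_edges",
    "module_weight_matrix",
    "loco_summary",
    "EdgeClassification",
]


def module_weight_matrix(edges: pd.DataFrame, module_genes: set[str]) -> pd.Series:
    """All ordered-pair weights among ``module_genes`` (above and below any
    cutoff), indexed by (source, target)."""
    sub = edges[
        edges["source"].isin(module_genes) & edges["target"].isin(module_genes)
    ]
    return sub.set_index(["source", "target"])["weight"].sort_index()


def loco_networks(
    fc: pd.DataFrame,
    design: ExperimentDesign,
    module_genes: set[str],
    cfg: NetworkConfig | None = None,
) -> dict[float, pd.Series]:
    """Re-infer the network once per left-out non-control concentration.

    Returns {left-out concentration -> Series of all ordered within-module
    pair weights}.  The control is never removed: it is the fold-change
    reference.
    """
    cfg = cfg or NetworkConfig()
    missing = module_genes - set(fc.index)
    if missing:
        raise ValueError(f"module genes absent from the matrix: {sorted(missing)[:5]}")
    conc_of = design.concentration_of().loc[fc.columns]
    out: dict[float, pd.Series] = {}
    for c in sorted(conc_of.unique()):
        if c == 0:
            continue
        keep = conc_of.index[~np.isclose(conc_of, c)].tolist()
        if len(keep) < 3:
            raise ValueError("fewer than 3 samples remain after removal")
        reduced_edges = infer_network(fc[keep], cfg)
        out[float(c)] = module_weight_matrix(reduced_edges, module_genes)
    return out


def edge_weight_ratios(
    full_weights: pd.Series, reduced_by_conc: dict[float, pd.Series]
) -> pd.DataFrame:
    """Full/reduced weight ratio per ordered pair per left-out concentration.

    Cells are +inf where the reduced weight is 0 but the full weight is
    positive (the pair only co-expresses when that concentration is
    present) and 1 where both are 0.
    """
    cols = {}
    for c in sorted(reduced_by_conc):
        red = reduced_by_conc[c].reindex(full_weights.index)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = full_weights / red
        ratio = ratio.where(~((red == 0) & (full_weights == 0)), 1.0)
        ratio = ratio.where(~((red == 0) & (full_weights > 0)), np.inf)
        cols[c] = ratio
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class EdgeClassification:
    pair: tuple[str, str]
    consistently_higher: bool
    progressive_loss: bool
    has_undefined: bool


def classify_edges(
    table: pd.DataFrame, conc_order: list[float] | None = None, tau_threshold: float = 1.0
) -> pd.DataFrame:
    """Classify each ordered pair from its ratio profile.

    ``consistently_higher``: ratio > 1 in every column (pairs with +inf
    cells qualify on their defined cells but are flagged); this marks edges
    whose weight drops whenever any concentration is removed.
    ``progressive_loss``: consistently higher AND ratios strictly
    increasing with the rank of the left-out concentration (Kendall tau
    over the ordered columns >= ``tau_threshold``; the default 1 demands a
    strict monotone increase).  Pairs with undefined cells are excluded
    from progressive loss.
    """
    concs = sorted(table.columns) if conc_order is None else list(conc_order)
    vals = table[concs].to_numpy(float)
    finite = np.isfinite(vals)
    has_undef = ~finite.all(axis=1)
    above_one = np.where(finite, vals > 1.0, True).all(axis=1) & (
        np.where(finite, True, False).any(axis=1)
    )
    consistently = above_one

    progressive = np.zeros(len(table), dtype=bool)
    ranks = np.arange(len(concs))
    for i in np.nonzero(consistently & ~has_undef)[0]:
        tau = stats.kendalltau(ranks, vals[i]).statistic
        progressive[i] = bool(tau >= tau_threshold - 1e-12)
    out = pd.DataFrame(
        {
            "consistently_higher": consistently,
            "progressive_loss": progressive,
            "has_undefined": has_undef,
        },
        index=table.index,
    )
    return out


def loco_summary(classification: pd.DataFrame) -> dict:
    return {
        "n_edges": int(len(classification)),
        "n_consistently_higher": int(classification["consistently_higher"].sum()),
        "n_progressive_loss": int(classification["progressive_loss"].sum()),
        "n_with_undefined": int(classification["has_undefined"].sum()),
    }
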