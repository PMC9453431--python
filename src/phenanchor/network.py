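"""Tree-ensemble co-expression network inference and module detection.

Per-replicate log2 fold changes against the control mean feed a GENIE3-style
procedure: each gene in turn is regressed on all other genes with a random
forest, and the forest's variance-reduction importances become directed edge
weights (normalized to sum to 1 per target).  Edges above a weight cutoff
form the network; modules come from Clauset-Newman-Moore greedy modularity
maximization on the undirected projection, and hub structure is summarized
by degree and betweenness centralities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import greedy_modularity_communities
from sklearn.ensemble import RandomForestRegressor

from .datatypes import ExperimentDesign
from .simulate import round_sig

__all__ = [
    "NetworkConfig",
    "CoexpressionNetwork",
    "fold_change_matrix",
    "select_top_cv",
    "infer_network",
    "threshold_network",
    "detect_modules",
    "centralities",
    "possible_edge_count",
    "retained_fraction",
]


@dataclass(frozen=True)
class NetworkConfig:
    n_top_cv: int = 8000
    edge_cutoff: float = 0.0086
    n_trees: int = 500
    candidate_features: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_cutoff <= 0:
            raise ValueError("edge_cutoff must be positive")


@dataclass
class CoexpressionNetwork:
    """Thresholded directed network with modules and centralities."""

    edges: pd.DataFrame  # columns: source, target, weight
    isolated: list[str]
    module_of: dict[str, int] | None = None
    degree_of: dict[str, int] | None = None
    betweenness_of: dict[str, float] | None = None

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["source"]) | set(self.edges["target"]))

    def undirected(self, weighted: bool = True) -> nx.Graph:
        """Undirected projection; reciprocal edge weights are summed."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for s, t, w in self.edges.itertuples(index=False):
            if g.has_edge(s, t):
                g[s][t]["weight"] += w
            else:
                g.add_edge(s, t, weight=w if weighted else 1.0)
        return g


def fold_change_matrix(
    norm_expr: pd.DataFrame,
    design: ExperimentDesign,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-replicate log2 fold changes vs the control-replicate mean.

    Control replicates are retained as columns (their fold changes scatter
    around zero), matching the all-32-sample input the network stage uses.
    """
    ctrl = design.control_samples
    if len(ctrl) < 2:
        raise ValueError("need >=2 control replicates")
    ctrl_mean = norm_expr[ctrl].mean(axis=1)
    return np.log2(norm_expr.add(pseudocount)).sub(
        np.log2(ctrl_mean + pseudocount), axis=0
    )


def select_top_cv(fc: pd.DataFrame, n_top_cv: int) -> pd.DataFrame:
    """Keep the ``n_top_cv`` genes with the highest coefficient of variation.

    CV is computed on linear-scale ratios (2**log2fc): on the log scale the
    per-gene mean sits near zero and the CV blows up.  Ties break by
    gene_id so selection is deterministic.
    """
    if n_top_cv > fc.shape[0]:
        raise ValueError("n_top_cv exceeds the number of genes")
    ratios = np.exp2(fc)
    cv = ratios.std(axis=1, ddof=1) / ratios.mean(axis=1).abs()
    # stable sort after an index sort -> ties break lexicographically
    ranked = cv.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    return fc.loc[ranked.index[:n_top_cv]]


def infer_network(fc: pd.DataFrame, cfg: NetworkConfig | None = None) -> pd.DataFrame:
    """GENIE3-style directed edge weights for all ordered gene pairs.

    For each target gene a random forest (``n_trees`` trees, sqrt(p)
    candidate features per split) regresses the target's fold-change row on
    all other genes; the forest's normalized importances are the incoming
    edge weights, summing to 1 per target (0 for zero-variance targets).
    Deterministic under a fixed config seed.
    """
    cfg = cfg or NetworkConfig()
    if fc.shape[0] < 2 or fc.shape[1] < 3:
        raise ValueError("need >=2 genes and >=3 samples")
    genes = fc.index.tolist()
    x = fc.to_numpy(float)
    n = len(genes)
    weights = np.zeros((n, n))  # weights[i, j] = importance of gene i for target j
    ss = np.random.SeedSequence(cfg.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
    for j in range(n):
        y = x[j]
        if np.allclose(y, y[0]):
            continue
        others = np.delete(np.arange(n), j)
        # full-sample trees (no bagging): randomness comes only from the
        # per-split candidate-feature draw, so jointly permuting the sample
        # columns leaves the weights unchanged
        rf = RandomForestRegressor(
            n_estimators=cfg.n_trees,
            max_features=cfg.candidate_features,
            bootstrap=False,
            random_state=child_seeds[j],
            n_jobs=1,
        )
        rf.fit(x[others].T, y)
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        weights[others, j] = imp
    src, tgt = np.nonzero(~np.eye(n, dtype=bool))
    return pd.DataFrame(
        {
            "source": [genes[i] for i in src],
            "target": [genes[j] for j in tgt],
            "weight": weights[src, tgt],
        }
    )


def threshold_network(
    edges: pd.DataFrame, cfg: NetworkConfig | None = None
) -> CoexpressionNetwork:
    """Retain edges with weight strictly above the cutoff.

    Nodes left with no edge are dropped from the graph but reported in
    ``isolated``.
    """
    cfg = cfg or NetworkConfig()
    kept = edges[edges["weight"] > cfg.edge_cutoff].reset_index(drop=True)
    all_nodes = set(edges["source"]) | set(edges["target"])
    connected = set(kept["source"]) | set(kept["target"])
    return CoexpressionNetwork(edges=kept, isolated=sorted(all_nodes - connected))


def detect_modules(net: CoexpressionNetwork) -> dict[str, int]:
    """Greedy-modularity (CNM) modules on the weighted undirected projection.

    Module ids are assigned 1..m in decreasing module size, ties broken by
    the lexicographically smallest member, so labelling is deterministic.
    """
    if len(net.edges) == 0:
        raise ValueError("cannot detect modules in an edgeless network")
    g = net.undirected(weighted=True)
    communities = greedy_modularity_communities(g, weight="weight")
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    module_of = {gene: i + 1 for i, comm in enumerate(ordered) for gene in comm}
    net.module_of = module_of
    return module_of


def centralities(net: CoexpressionNetwork) -> pd.DataFrame:
    """Degree (distinct neighbours, direction-blind) and normalized
    betweenness on the unweighted undirected projection."""
    g = net.undirected(weighted=False)
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=True)
    net.degree_of = deg
    net.betweenness_of = btw
    return pd.DataFrame(
        {"gene_id": list(deg), "degree": list(deg.values()), "betweenness": [btw[k] for k in deg]}
    ).set_index("gene_id", drop=False)


def possible_edge_count(n_genes: int) -> int:
    """Ordered gene pairs: n(n-1).  A 178-gene module has 31,506."""
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    return n_genes * (n_genes - 1)


def retained_fraction(n_edges: int, n_genes: int, sig_figs: int = 1) -> float:
    """Percentage of possible ordered pairs retained, to ``sig_figs``
    significant figures (4,678 of 8,000 genes' pairs -> 0.007%)."""
    possible = possible_edge_count(n_genes)
    if n_edges > possible:
        raise ValueError("n_edges exceeds the number of possible edges")
    if n_edges == 0:
        return 0.0
    return round_sig(100.0 * n_edges / possible, sig_figs)
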