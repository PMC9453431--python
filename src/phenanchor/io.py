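"""Readers and writers for the pipeline's plain-text formats.

Tabular outputs are TSV with optional ``#``-prefixed metadata header lines
(``# key=value``); gene sets are GMT; networks export as edge-list TSV,
GraphML and SIF (for Cytoscape).  Readers validate and report the offending
line number on malformed input; write -> read round-trips are identities.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import networkx as nx

from .datatypes import CountMatrix, ExperimentDesign, PhenotypeTable

__all__ = [
    "write_counts",
    "read_counts",
    "write_design",
    "read_design",
    "write_phenotype",
    "read_phenotype",
    "read_gmt",
    "write_gmt",
    "write_edges",
    "read_edges",
    "write_graphml",
    "write_sif",
    "write_json",
    "read_json",
]


def _write_header(fh, metadata: Optional[Mapping] = None) -> None:
    for key, value in (metadata or {}).items():
        fh.write(f"# {key}={value}\n")


def _read_metadata(path: Path) -> tuple[dict, int]:
    meta, n_skip = {}, 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta, n_skip


def write_counts(counts: CountMatrix, path, metadata: Optional[Mapping] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        counts.values.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_counts(path) -> CountMatrix:
    path = Path(path)
    _, n_skip = _read_metadata(path)
    df = pd.read_csv(path, sep="\t", skiprows=n_skip, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    values = np.empty(df.shape, dtype=np.int64)
    for i, (gid, row) in enumerate(df.iterrows()):
        arr = pd.to_numeric(row, errors="coerce")
        bad = arr.isna() | (arr != arr.round())
        if bad.any():
            line_no = n_skip + 2 + i  # 1-based, after header line
            raise ValueError(f"non-integer count at line {line_no} (gene {gid})")
        values[i] = arr.to_numpy()
    return CountMatrix(pd.DataFrame(values, index=df.index, columns=df.columns))


def write_design(design: ExperimentDesign, path, metadata: Optional[Mapping] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        design.table.to_csv(fh, sep="\t", index=False)


def read_design(path) -> ExperimentDesign:
    _, n_skip = _read_metadata(Path(path))
    df = pd.read_csv(path, sep="\t", skiprows=n_skip)
    df["is_control"] = df["is_control"].astype(bool)
    return ExperimentDesign(df)


def write_phenotype(pheno: PhenotypeTable, path, metadata: Optional[Mapping] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        pheno.table.to_csv(fh, sep="\t", index=False)


def read_phenotype(path) -> PhenotypeTable:
    _, n_skip = _read_metadata(Path(path))
    df = pd.read_csv(path, sep="\t", skiprows=n_skip)
    return PhenotypeTable(df)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: term, description, members.  Duplicate terms keep the
    last definition with a warning."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {i}: expected >=3 tab-separated fields")
            term = parts[0]
            if term in terms:
                warnings.warn(f"duplicate GMT term {term!r}; keeping the last", stacklevel=2)
            terms[term] = {g for g in parts[2:] if g}
    return terms


def write_gmt(terms: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for term, members in terms.items():
            fh.write("\t".join([term, term] + sorted(members)) + "\n")


def write_edges(edges: pd.DataFrame, path, metadata: Optional[Mapping] = None) -> None:
    with open(path, "w") as fh:
        _write_header(fh, metadata)
        edges.to_csv(fh, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    _, n_skip = _read_metadata(Path(path))
    return pd.read_csv(path, sep="\t", skiprows=n_skip)


def write_graphml(edges: pd.DataFrame, path) -> None:
    g = nx.DiGraph()
    for s, t, w in edges[["source", "target", "weight"]].itertuples(index=False):
        g.add_edge(s, t, weight=float(w))
    nx.write_graphml(g, path)


def write_sif(edges: pd.DataFrame, path, interaction: str = "coexp") -> None:
    with open(path, "w") as fh:
        for s, t in edges[["source", "target"]].itertuples(index=False):
            fh.write(f"{s}\t{interaction}\t{t}\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
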