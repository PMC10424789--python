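"""Readers and writers for every external format the pipeline touches.

All tables are tab-delimited text; networks go out as edge-list TSV or
GraphML; result objects as JSON.  Writers sort rows deterministically so
re-runs produce byte-identical, diffable files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceTable, CoNetwork, FunctionTable
from .errors import NegativeValueError


def read_abundance_table(path, metadata_path) -> AbundanceTable:
    """Read a taxon x sample TSV plus a sample-metadata TSV.

    The abundance file has taxon ids in the first column and sample ids in
    the header row; the metadata file is indexed by sample id.  Validation
    (duplicate ids, negative values, metadata coverage) happens in the
    :class:`AbundanceTable` constructor and raises named errors.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        raise NegativeValueError(f"non-numeric abundance values in {path}")
    return AbundanceTable(values, metadata)


def write_abundance_table(table: AbundanceTable, path, metadata_path) -> None:
    table.values.to_csv(path, sep="\t", index_label="taxon_id")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> dict:
    """Read a two-column taxon -> phylum TSV into a plain dict."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.iloc[:, 0].to_dict()


def write_taxonomy(taxonomy: Mapping, path) -> None:
    frame = pd.DataFrame(
        {"phylum": [taxonomy[t] for t in sorted(taxonomy)]},
        index=pd.Index(sorted(taxonomy), name="taxon_id"),
    )
    frame.to_csv(path, sep="\t")


def read_function_table(path) -> FunctionTable:
    return FunctionTable(pd.read_csv(path, sep="\t", index_col=0))


def write_function_table(table: FunctionTable, path) -> None:
    table.values.to_csv(path, sep="\t", index_label="category")


def write_network(net: CoNetwork, path, format: str = "edge_tsv") -> None:
    """Write a network as ``edge_tsv`` (source, target, r) or ``graphml``.

    The edge TSV keeps the signed correlation at six decimals and sorts
    rows lexicographically; GraphML round-trips node attributes (phylum,
    module, Zi, Pi, role) for import into standard network tools.
    """
    path = Path(path)
    if format == "edge_tsv":
        rows = []
        for a, b, data in net.graph.edges(data=True):
            a, b = sorted((str(a), str(b)))
            rows.append((a, b, data["r"]))
        rows.sort()
        with open(path, "w") as handle:
            handle.write("source\ttarget\tr\n")
            for a, b, r in rows:
                handle.write(f"{a}\t{b}\t{r:.6f}\n")
    elif format == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, format: str = "edge_tsv", provenance: dict | None = None) -> CoNetwork:
    path = Path(path)
    if format == "edge_tsv":
        graph = nx.Graph()
        frame = pd.read_csv(path, sep="\t")
        for row in frame.itertuples(index=False):
            graph.add_edge(row.source, row.target, r=float(row.r))
    elif format == "graphml":
        graph = nx.read_graphml(path)
    else:
        raise ValueError(f"unknown network format: {format!r}")
    return CoNetwork(graph, provenance or {})


def write_json(obj, path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True, default=_jsonable)
        handle.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
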