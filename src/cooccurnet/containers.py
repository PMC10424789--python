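"""Core data containers shared by every pipeline stage.

The pipeline moves three kinds of observations around: a taxon-by-sample
abundance table with per-sample metadata, a taxonomy map (taxon -> phylum),
and an undirected co-occurrence network whose edges carry signed Pearson
correlations.  All tabular data are pandas objects; networks wrap a
:class:`networkx.Graph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import (
    DuplicateIdError,
    MissingMetadataError,
    NegativeValueError,
    UnknownCategoryError,
)

#: Treatment levels: control plus three increasing herbicide doses.
TREATMENT_LEVELS = ("CK", "L", "M", "H")

#: The eight predominant phyla tracked individually; everything else is "Others".
PREDOMINANT_PHYLA = (
    "Acidobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Chloroflexi",
    "Gemmatimonadetes",
    "Planctomycetes",
    "Proteobacteria",
    "Verrucomicrobia",
)

OTHERS = "Others"

#: The 15 predicted function categories (one cellular process, three genetic
#: information processing, eleven metabolism), keyed by their abbreviations.
FUNCTION_CATEGORIES = (
    "CGD",          # cell growth and death
    "FSD",          # folding, sorting and degradation
    "RR",           # replication and repair
    "Translation",  # translation
    "CM",           # carbohydrate metabolism
    "LM",           # lipid metabolism
    "AAM",          # amino acid metabolism
    "MCV",          # metabolism of cofactors and vitamins
    "XBM",          # xenobiotic biodegradation and metabolism
    "BOSM",         # biosynthesis of other secondary metabolites
    "EM",           # energy metabolism
    "MTP",          # metabolism of terpenoids and polyketides
    "MOAA",         # metabolism of other amino acids
    "NM",           # nucleotide metabolism
    "GBM",          # glycan biosynthesis and metabolism
)


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with taxon ids on the index and sample ids on the columns.
        Counts and relative abundances are both accepted; values are used
        as-is by the Pearson correlation step (no rank transform), so the
        scale the caller supplies is the scale that is correlated.
    metadata
        DataFrame indexed by sample id.  Conventional columns are ``soil``,
        ``treatment`` (one of :data:`TREATMENT_LEVELS`), ``day`` and
        ``replicate``, but extra columns pass through untouched.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate taxon ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dupes}")
        if (self.values.to_numpy() < 0).any():
            raise NegativeValueError("abundance table contains negative values")
        missing = self.values.columns.difference(self.metadata.index)
        if len(missing):
            raise MissingMetadataError(
                f"samples missing metadata: {sorted(missing)}"
            )
        # keep metadata aligned to the sample order of the table
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def taxon_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable) -> "AbundanceTable":
        ids = list(sample_ids)
        return AbundanceTable(self.values[ids], self.metadata.loc[ids])

    def subset_taxa(self, taxon_ids: Iterable) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(taxon_ids)], self.metadata)


@dataclass
class FunctionTable:
    """Predicted function-category x sample relative abundances."""

    values: pd.DataFrame  # category x sample

    def __post_init__(self) -> None:
        unknown = [c for c in self.values.index if c not in FUNCTION_CATEGORIES]
        if unknown:
            raise UnknownCategoryError(f"unknown function categories: {unknown}")
        if (self.values.to_numpy() < 0).any():
            raise NegativeValueError("function table contains negative values")

    @property
    def categories(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class CoNetwork:
    """Undirected co-occurrence network with signed correlation weights.

    Nodes are taxon ids; every edge carries the signed Pearson ``r`` that
    passed the threshold.  Isolated taxa are never part of the node set, so
    ``n_nodes`` counts connected taxa only.  ``provenance`` records how the
    network was built (soil, treatment, threshold, mode, filters).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def links(self) -> set:
        """Edges as unordered taxon-id pairs (sign/weight ignored)."""
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def edge_weight(self, a, b) -> float:
        return self.graph.edges[a, b]["r"]

    def degree(self, node) -> int:
        return self.graph.degree[node]


def phylum_of(taxonomy: Mapping, taxon) -> str:
    """Phylum for a taxon, binning unrecognised phyla into ``Others``."""
    phylum = taxonomy.get(taxon, OTHERS)
    return phylum if phylum in PREDOMINANT_PHYLA else OTHERS
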