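"""Co-occurrence network inference from abundance tables.

One network per soil x treatment group: pairwise Pearson correlations
between taxa across that group's samples, thresholded at |r| >= 0.9 by
default.  The sign of the correlation is kept on the edge; taxa left
without a single retained edge are dropped from the node set, so node
counts measure *connected* taxa.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceTable, CoNetwork
from .errors import EmptyFilterError, ThresholdError, ZeroVarianceWarning


def filter_taxa(
    table: AbundanceTable,
    min_prevalence: float = 0.0,
    min_mean_abundance: float = 0.0,
) -> AbundanceTable:
    """Keep taxa present (value > 0) in at least ``min_prevalence`` of
    samples and with mean abundance at least ``min_mean_abundance``.

    Row order is preserved.  Raises :class:`EmptyFilterError` if nothing
    survives — an empty table is never a valid network input.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in [0, 1]")
    values = table.values
    prevalence = (values > 0).mean(axis=1)
    mean_abundance = values.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_abundance >= min_mean_abundance)
    if not keep.any():
        raise EmptyFilterError(
            f"filter (prevalence >= {min_prevalence}, mean >= {min_mean_abundance}) "
            "removed all taxa"
        )
    return AbundanceTable(values.loc[keep], table.metadata)


def pairwise_pearson(table: AbundanceTable) -> pd.DataFrame:
    """All-pairs Pearson correlation between taxa across samples.

    Zero-variance taxa have undefined correlations; they are excluded
    from the result and reported through a :class:`ZeroVarianceWarning`
    rather than silently propagating NaN.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to correlate taxa")
    values = table.values.to_numpy(dtype=float)
    variances = values.var(axis=1)
    flat = variances == 0
    if flat.any():
        dropped = [t for t, bad in zip(table.taxon_ids, flat) if bad]
        warnings.warn(
            f"excluded {len(dropped)} zero-variance taxa: {dropped}",
            ZeroVarianceWarning,
            stacklevel=2,
        )
        values = values[~flat]
    taxa = [t for t, bad in zip(table.taxon_ids, flat) if not bad]
    corr = np.atleast_2d(np.corrcoef(values))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=taxa, columns=taxa)


def build_network(
    corr: pd.DataFrame,
    threshold: float = 0.9,
    mode: str = "absolute",
    provenance: dict | None = None,
) -> CoNetwork:
    """Threshold a correlation matrix into a co-occurrence network.

    ``mode="absolute"`` keeps pairs with |r| >= threshold (sign retained
    on the edge); ``mode="positive_only"`` keeps r >= threshold.  Taxa
    incident to no retained edge are excluded from the node set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ThresholdError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("absolute", "positive_only"):
        raise ValueError(f"unknown mode: {mode!r}")
    matrix = corr.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1] or not np.allclose(matrix, matrix.T):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(matrix), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")

    taxa = list(corr.index)
    graph = nx.Graph()
    iu, ju = np.triu_indices(len(taxa), k=1)
    r = matrix[iu, ju]
    passed = np.abs(r) >= threshold if mode == "absolute" else r >= threshold
    for i, j, value in zip(iu[passed], ju[passed], r[passed]):
        graph.add_edge(taxa[i], taxa[j], r=float(value))

    info = dict(provenance or {})
    info.update(threshold=threshold, mode=mode)
    return CoNetwork(graph, info)


def infer_network(
    table: AbundanceTable,
    threshold: float = 0.9,
    mode: str = "absolute",
    min_prevalence: float = 0.0,
    min_mean_abundance: float = 0.0,
    provenance: dict | None = None,
) -> CoNetwork:
    """Convenience composition: filter -> correlate -> threshold."""
    filtered = filter_taxa(table, min_prevalence, min_mean_abundance)
    corr = pairwise_pearson(filtered)
    info = dict(provenance or {})
    info.update(
        min_prevalence=min_prevalence, min_mean_abundance=min_mean_abundance
    )
    return build_network(corr, threshold, mode, info)
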