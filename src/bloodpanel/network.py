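"""Pearson co-expression networks over the top dysregulated genes.

Edges connect gene pairs whose Pearson correlation across samples exceeds a
cutoff (signed, strict; default 0.50 to retain only strong positive
co-expression).  Missing values are handled pairwise-complete.  Connected
components are reported descriptively — in practice the panel genes fall
into a virus-response block and a bacteria-response block.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import GenePanel

__all__ = ["pearson_matrix", "build_network", "connected_components"]


def pearson_matrix(
    expr: pd.DataFrame, gene_subset: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric gene x gene Pearson correlation matrix (pairwise-complete).

    Zero-variance genes produce NaN rows/columns (undefined correlation).
    """
    if gene_subset is not None:
        wanted = [g.upper() for g in gene_subset]
        missing = sorted(set(wanted) - set(expr.index))
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        expr = expr.loc[wanted]
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    pcc = expr.T.corr(min_periods=3)
    return pcc


def build_network(
    pcc: pd.DataFrame,
    cutoff: float = 0.50,
    panel: GenePanel | None = None,
) -> nx.Graph:
    """Graph with an edge wherever pcc > cutoff (strict, signed).

    Every gene becomes a node (isolated genes stay as singletons); nodes
    carry a ``panel`` attribute (vrg/brg/other) when a panel is given.
    """
    g = nx.Graph()
    genes = list(pcc.index)
    vrg = set(panel.vrg) if panel else set()
    brg = set(panel.brg) if panel else set()
    for gene in genes:
        tag = "vrg" if gene in vrg else "brg" if gene in brg else "other"
        g.add_node(gene, panel=tag)
    vals = pcc.to_numpy()
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            w = vals[i, j]
            if np.isfinite(w) and w > cutoff:
                g.add_edge(genes[i], genes[j], pcc=float(w))
    return g


def connected_components(network: nx.Graph) -> list[set[str]]:
    """Components sorted by size descending (then by smallest member)."""
    comps = [set(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
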