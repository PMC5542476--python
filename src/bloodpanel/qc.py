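"""Probe-level quality control and probe-to-gene aggregation.

The QC recipe for microarray intensity matrices, applied in order:

1. log2-transform (done at read time, see :mod:`bloodpanel.io`);
2. remove probes whose fraction of bad entries (missing OR below the
   intensity floor) exceeds ``max_missing_fraction``;
3. floor the surviving values at ``floor`` (default ``log2(100)``);
4. average probes per gene on the log2 scale (mean over non-missing).

A gene-level entry is missing only when every probe of that gene is missing
in that sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["QCParams", "filter_probes", "floor_values", "aggregate_probes", "run_qc"]


@dataclass(frozen=True)
class QCParams:
    """Filtering/flooring parameters.

    floor
        log2 intensity floor; values below it are unreliable background.
    max_missing_fraction
        a probe is dropped when its bad-entry fraction strictly exceeds this.
    """

    floor: float = math.log2(100.0)
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.floor <= 0:
            raise ValueError("floor must be positive (log2 intensity)")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def filter_probes(probes: pd.DataFrame, params: QCParams = QCParams()) -> pd.DataFrame:
    """Drop probes with > ``max_missing_fraction`` bad (missing or sub-floor) entries.

    Probe order is preserved.  Raises if nothing survives.
    """
    bad = probes.isna() | (probes < params.floor)
    keep = bad.mean(axis=1) <= params.max_missing_fraction
    out = probes.loc[keep]
    if out.empty:
        raise ValueError(
            "all probes removed by QC filter; review floor/max_missing_fraction"
        )
    return out


def floor_values(probes: pd.DataFrame, params: QCParams = QCParams()) -> pd.DataFrame:
    """Replace non-missing values below the floor by the floor (idempotent)."""
    return probes.clip(lower=params.floor)


def aggregate_probes(probes: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene x sample by per-gene log2 mean.

    ``probe_map`` has columns probe_id, gene_symbol; probes mapping to several
    genes contribute to each.  Unmapped probes are excluded (count logged).
    Gene symbols are uppercased; output genes are sorted alphabetically.
    """
    pm = probe_map.copy()
    pm["gene_symbol"] = pm["gene_symbol"].str.upper()
    mapped = pm[pm["probe_id"].isin(probes.index)]
    n_unmapped = probes.index.difference(pd.Index(mapped["probe_id"])).size
    if n_unmapped:
        logger.info("aggregate_probes: %d probes without gene mapping excluded", n_unmapped)
    if mapped.empty:
        raise ValueError("no retained probe has a gene mapping")
    expanded = probes.loc[mapped["probe_id"]]
    expanded.index = pd.Index(mapped["gene_symbol"], name="gene")
    # groupby mean skips NaN: gene entry missing only if all probes missing
    genes = expanded.groupby(level=0).mean()
    genes.columns = probes.columns
    return genes


def run_qc(
    probes: pd.DataFrame,
    probe_map: pd.DataFrame,
    params: QCParams = QCParams(),
) -> pd.DataFrame:
    """Full QC pipeline: filter -> floor -> aggregate to gene level."""
    kept = filter_probes(probes, params)
    floored = floor_values(kept, params)
    return aggregate_probes(floored, probe_map)
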