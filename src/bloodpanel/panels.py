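"""Cross-dataset frequency ranking and VRG/BRG panel selection.

Genes are ranked by how often they pass the stringent fold-change cutoff
(FC > 2.0 or FC < 0.5) across a collection of case/control datasets.
Candidates dysregulated in at least ``min_datasets`` datasets feed two
selection procedures:

* virus-response genes (VRGs): the top ``n_viral_top`` candidates by mean
  FC over the designated viral datasets;
* bacteria-response genes (BRGs): the union of (a) candidates with mean FC
  over the bacterial datasets above ``bacterial_high_fc``, (b) candidates
  significant in at least ``rescue_min_datasets`` datasets, and (c)
  candidates with mid-range bacterial mean FC significant in at least
  ``mid_fc_min_datasets`` datasets, with explicit include/exclude overrides
  applied last and the list truncated/padded to size by bacterial mean FC.

Down-regulated genes are counted in the frequency table but never enter
panels; the viral list takes precedence when a gene qualifies for both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DEGThresholds
from .io import GenePanel

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyTable",
    "SelectionRules",
    "frequency_table",
    "select_candidates",
    "select_vrgs",
    "select_brgs",
    "build_panel",
    "find_specific_genes",
]


@dataclass
class FrequencyTable:
    """Per-gene dysregulation counts over datasets plus the FC matrix behind them.

    ``fc`` is genes x datasets (NaN where a gene is absent from a dataset);
    each dataset contributes at most one direction per gene, so
    ``n_up + n_down == n_significant``.
    """

    fc: pd.DataFrame
    n_significant: pd.Series
    n_up: pd.Series
    n_down: pd.Series
    thresholds: DEGThresholds

    @property
    def datasets(self) -> list[str]:
        return list(self.fc.columns)

    def mean_fc(self, dataset_ids: Sequence[str]) -> pd.Series:
        """Arithmetic mean of linear FC over the given datasets."""
        missing = [d for d in dataset_ids if d not in self.fc.columns]
        if missing:
            raise KeyError(f"unknown dataset ids: {missing}")
        return self.fc[list(dataset_ids)].mean(axis=1)


@dataclass
class SelectionRules:
    min_datasets: int = 8
    n_viral_top: int = 10
    n_bacterial: int = 10
    bacterial_high_fc: float = 8.0
    bacterial_mid_fc_range: tuple[float, float] = (5.0, 8.0)
    mid_fc_min_datasets: int = 10
    rescue_min_datasets: int = 13
    include: tuple[str, ...] = ()
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_viral_top < 1 or self.n_bacterial < 1:
            raise ValueError("panel sizes must be >= 1")
        lo, hi = self.bacterial_mid_fc_range
        if not (0 < lo <= hi <= self.bacterial_high_fc):
            raise ValueError("mid FC range must be positive and below the high-FC cutoff")
        self.include = tuple(g.upper() for g in self.include)
        self.exclude = tuple(g.upper() for g in self.exclude)


def frequency_table(
    fc_by_dataset: Mapping[str, pd.Series],
    thresholds: DEGThresholds = DEGThresholds.stringent(),
) -> FrequencyTable:
    """Count, per gene, how many datasets pass the FC cutoff in each direction.

    The gene universe is the union over datasets; a gene absent from a
    dataset contributes no count there.
    """
    if not fc_by_dataset:
        raise ValueError("need at least one dataset")
    fc = pd.DataFrame(
        {ds: s for ds, s in fc_by_dataset.items()}
    )
    fc.index = fc.index.str.upper()
    if fc.index.duplicated().any():
        raise ValueError("duplicate gene symbols after uppercasing")
    up = (fc > thresholds.up).sum(axis=1)
    down = (fc < thresholds.down).sum(axis=1)
    return FrequencyTable(
        fc=fc,
        n_significant=up + down,
        n_up=up,
        n_down=down,
        thresholds=thresholds,
    )


def select_candidates(freq: FrequencyTable, rules: SelectionRules = SelectionRules()) -> list[str]:
    """Genes significant in at least ``min_datasets`` datasets.

    Ordered by count descending, then alphabetically.
    """
    keep = freq.n_significant[freq.n_significant >= rules.min_datasets]
    if keep.empty:
        warnings.warn("no candidate genes pass the frequency cutoff", stacklevel=2)
        return []
    order = sorted(keep.index, key=lambda g: (-keep[g], g))
    return order


def _ranked(
    freq: FrequencyTable, genes: Sequence[str], dataset_ids: Sequence[str]
) -> list[str]:
    """Sort genes by mean FC desc, ties by n_significant desc then name."""
    mean_fc = freq.mean_fc(dataset_ids)
    return sorted(
        genes, key=lambda g: (-mean_fc.get(g, -np.inf), -freq.n_significant.get(g, 0), g)
    )


def select_vrgs(
    freq: FrequencyTable,
    candidates: Sequence[str],
    viral_dataset_ids: Sequence[str],
    rules: SelectionRules = SelectionRules(),
) -> list[str]:
    """Top candidates by mean FC across the viral datasets (up-regulated only)."""
    mean_fc = freq.mean_fc(viral_dataset_ids)
    pool = [g for g in candidates if mean_fc.get(g, 0.0) > 1.0]
    ranked = _ranked(freq, pool, viral_dataset_ids)
    if len(ranked) < rules.n_viral_top:
        warnings.warn(
            f"only {len(ranked)} viral candidates available "
            f"(requested {rules.n_viral_top})",
            stacklevel=2,
        )
    return ranked[: rules.n_viral_top]


def select_brgs(
    freq: FrequencyTable,
    candidates: Sequence[str],
    bacterial_dataset_ids: Sequence[str],
    rules: SelectionRules = SelectionRules(),
    already_selected: Sequence[str] = (),
) -> list[str]:
    """Bacteria-response genes via high-FC, frequency-rescue and mid-FC rules.

    ``already_selected`` (normally the VRG list) is excluded up front so the
    two panels stay disjoint.
    """
    mean_fc = freq.mean_fc(bacterial_dataset_ids)
    taken = {g.upper() for g in already_selected}
    pool = [
        g for g in candidates if g not in taken and mean_fc.get(g, 0.0) > 1.0
    ]
    lo, hi = rules.bacterial_mid_fc_range

    chosen: dict[str, str] = {}  # gene -> qualifying rule
    for g in pool:
        if mean_fc[g] > rules.bacterial_high_fc:
            chosen[g] = "high_fc"
    for g in pool:
        if g not in chosen and freq.n_significant[g] >= rules.rescue_min_datasets:
            chosen[g] = "frequency_rescue"
    for g in pool:
        if (
            g not in chosen
            and lo <= mean_fc[g] <= hi
            and freq.n_significant[g] >= rules.mid_fc_min_datasets
        ):
            chosen[g] = "mid_fc"

    for g in rules.exclude:
        chosen.pop(g, None)
    for g in rules.include:
        if g in pool and g not in chosen:
            chosen[g] = "override_include"

    ranked = _ranked(freq, list(chosen), bacterial_dataset_ids)
    if len(ranked) > rules.n_bacterial:
        ranked = ranked[: rules.n_bacterial]
    elif len(ranked) < rules.n_bacterial:
        # pad from the remaining pool by bacterial mean FC
        filler = [g for g in _ranked(freq, pool, bacterial_dataset_ids)
                  if g not in chosen and g not in rules.exclude]
        need = rules.n_bacterial - len(ranked)
        if filler[:need]:
            logger.info("select_brgs: padding with %d genes below the rule cutoffs", need)
        ranked = ranked + filler[:need]
        if len(ranked) < rules.n_bacterial:
            warnings.warn(
                f"only {len(ranked)} bacterial genes available "
                f"(requested {rules.n_bacterial})",
                stacklevel=2,
            )
    return ranked


def build_panel(
    freq: FrequencyTable,
    viral_dataset_ids: Sequence[str],
    bacterial_dataset_ids: Sequence[str],
    rules: SelectionRules = SelectionRules(),
) -> GenePanel:
    """Run the full candidate -> VRG -> BRG procedure and record provenance."""
    candidates = select_candidates(freq, rules)
    vrg = select_vrgs(freq, candidates, viral_dataset_ids, rules)
    brg = select_brgs(freq, candidates, bacterial_dataset_ids, rules, already_selected=vrg)
    viral_mean = freq.mean_fc(viral_dataset_ids)
    bact_mean = freq.mean_fc(bacterial_dataset_ids)
    provenance = {
        g: {
            "panel": "vrg" if g in vrg else "brg",
            "mean_fc_viral": float(viral_mean.get(g, np.nan)),
            "mean_fc_bacterial": float(bact_mean.get(g, np.nan)),
            "n_significant": int(freq.n_significant.get(g, 0)),
        }
        for g in [*vrg, *brg]
    }
    return GenePanel(vrg=vrg, brg=brg, provenance=provenance)


def find_specific_genes(
    freq: FrequencyTable,
    target_dataset_ids: Sequence[str],
    max_background_count: int = 0,
) -> list[str]:
    """Genes significant in every target dataset but rare in the background.

    Background = all datasets of the table not listed as targets.  Used for
    the disease-specific-marker screen (e.g., sepsis-only genes).
    """
    targets = list(target_dataset_ids)
    missing = [d for d in targets if d not in freq.fc.columns]
    if missing:
        raise KeyError(f"unknown target datasets: {missing}")
    background = [d for d in freq.fc.columns if d not in targets]
    thr = freq.thresholds
    sig = (freq.fc > thr.up) | (freq.fc < thr.down)
    in_all_targets = sig[targets].all(axis=1)
    bg_count = sig[background].sum(axis=1)
    hits = freq.fc.index[in_all_targets & (bg_count <= max_background_count)]
    return sorted(hits)
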