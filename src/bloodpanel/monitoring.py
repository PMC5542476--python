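"""Longitudinal panel tracking for a single subject.

Given a normalized expression time series for the 20 panel genes, a per-gene
baseline is the median over user-designated healthy timepoints, each
timepoint's values become fold changes against that baseline, and a
timepoint is flagged as a candidate immune event when enough genes of either
panel exceed a fold threshold.  This is an explicit operational stand-in for
by-eye event reading of longitudinal expression plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenePanel

__all__ = ["LongitudinalProfile", "build_profile", "flag_events"]


@dataclass
class LongitudinalProfile:
    subject_id: str
    expression: pd.DataFrame  # genes x timepoints, log2
    fold: pd.DataFrame  # genes x timepoints, linear fold vs baseline
    baseline: pd.Series  # per-gene log2 baseline
    panel: GenePanel
    healthy_timepoints: list[int]

    @property
    def timepoints(self) -> list[int]:
        return list(self.expression.columns)


def build_profile(
    expr_series: pd.DataFrame,
    panel: GenePanel,
    healthy_timepoints: Sequence[int],
    subject_id: str = "subject",
) -> LongitudinalProfile:
    """Fold-vs-baseline series for the panel genes of one subject.

    ``expr_series`` is gene x timepoint (columns = day indices, strictly
    increasing).  Baseline = per-gene median over the designated healthy
    timepoints; fold = 2^(x_t - baseline).
    """
    days = list(expr_series.columns)
    if len(days) < 2:
        raise ValueError("need at least 2 timepoints")
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("timepoints must be strictly increasing")
    healthy = [d for d in healthy_timepoints if d in expr_series.columns]
    if not healthy:
        raise ValueError("no designated healthy timepoints present in series")
    genes = [g for g in panel.genes if g in expr_series.index]
    if not genes:
        raise ValueError("no panel genes in series")
    sub = expr_series.loc[genes]
    baseline = sub[healthy].median(axis=1)
    fold = np.exp2(sub.sub(baseline, axis=0))
    return LongitudinalProfile(
        subject_id=subject_id,
        expression=sub,
        fold=fold,
        baseline=baseline,
        panel=panel,
        healthy_timepoints=list(healthy),
    )


def flag_events(
    profile: LongitudinalProfile,
    fold_threshold: float = 2.0,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-timepoint elevation counts and event flags.

    A timepoint is flagged when at least ``min_genes`` genes of either panel
    (VRG or BRG, counted separately) have fold strictly above
    ``fold_threshold``.
    """
    vrg = [g for g in profile.panel.vrg if g in profile.fold.index]
    brg = [g for g in profile.panel.brg if g in profile.fold.index]
    elevated = profile.fold > fold_threshold
    n_v = elevated.loc[vrg].sum(axis=0) if vrg else pd.Series(0, index=profile.fold.columns)
    n_b = elevated.loc[brg].sum(axis=0) if brg else pd.Series(0, index=profile.fold.columns)
    out = pd.DataFrame(
        {
            "n_vrg_elevated": n_v.astype(int),
            "n_brg_elevated": n_b.astype(int),
        }
    )
    out["flagged"] = (out["n_vrg_elevated"] >= min_genes) | (
        out["n_brg_elevated"] >= min_genes
    )
    out.index.name = "timepoint"
    return out
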