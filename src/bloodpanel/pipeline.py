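"""End-to-end convenience wrappers tying the pipeline stages together."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import diffexpr, panels, qc, scoring
from .classify import KMeansFit, confusion_metrics, kmeans_discriminate
from .io import GenePanel
from .simulate import SimulatedCohort


def cohort_fold_changes(
    cohort: SimulatedCohort,
    qc_params: qc.QCParams = qc.QCParams(),
    from_probes: bool = True,
) -> pd.Series:
    """QC a simulated cohort and return its per-gene median fold changes.

    ``from_probes=False`` skips the probe-level QC and uses the noise-free
    gene view directly (faster; QC is exercised elsewhere).
    """
    if from_probes:
        genes = qc.run_qc(cohort.probes, cohort.probe_map, qc_params)
    else:
        genes = cohort.genes
    meta = cohort.metadata
    return diffexpr.median_fold_change(
        genes,
        list(meta.index[meta["group"] == "case"]),
        list(meta.index[meta["group"] == "control"]),
    )


def panel_from_cohorts(
    cohorts: Mapping[str, SimulatedCohort],
    viral_ids: Sequence[str],
    bacterial_ids: Sequence[str],
    rules: panels.SelectionRules = panels.SelectionRules(),
    from_probes: bool = True,
) -> GenePanel:
    """Full discovery procedure: per-cohort FC -> frequency table -> panel."""
    fc_by_dataset = {
        name: cohort_fold_changes(c, from_probes=from_probes)
        for name, c in cohorts.items()
    }
    freq = panels.frequency_table(fc_by_dataset)
    return panels.build_panel(freq, list(viral_ids), list(bacterial_ids), rules)


def discriminate_cohort(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    panel: GenePanel,
    threshold: float = 2.0,
    seed: int | None = 0,
) -> tuple[KMeansFit, pd.DataFrame]:
    """Score cases of a mixed cohort and cluster them into viral/bacterial.

    Returns the K-means fit (labels accessible via ``fit.labels``) and the
    per-sample score table for the clustered (case) samples.
    """
    fc = scoring.build_fc_matrix(expr, metadata, gene_subset=panel.genes)
    scores = scoring.count_dysregulated(fc, panel, threshold=threshold)
    cases = metadata.index[metadata["group"] == "case"]
    case_scores = scores.loc[[s for s in scores.index if s in set(cases)]]
    fit = kmeans_discriminate(case_scores, seed=seed)
    return fit, case_scores
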