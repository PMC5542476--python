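"""Per-sample fold-change matrices and NG_V/NG_B dysregulation counts.

The FC matrix expresses every sample (cases, and controls when wanted)
relative to the median of the control group: ``fc = 2^(x - median_ctrl)``
per gene.  The panel scores NG_V and NG_B count how many virus-response and
bacteria-response genes exceed a fold threshold (strictly) in each sample;
the pair (NG_V, NG_B) is the feature vector for discrimination.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenePanel

__all__ = [
    "build_fc_matrix",
    "count_dysregulated",
    "relative_expression",
]


def control_ids(metadata: pd.DataFrame) -> list[str]:
    return list(metadata.index[metadata["group"] == "control"])


def case_ids(metadata: pd.DataFrame) -> list[str]:
    return list(metadata.index[metadata["group"] == "case"])


def build_fc_matrix(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    gene_subset: Sequence[str] | None = None,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Linear fold change of each sample against the control-group median.

    ``expr`` is gene x sample log2 values (post-QC); ``metadata`` must label
    every scored sample case/control.  Genes requested but absent from the
    matrix are dropped with a warning (platforms differ in coverage).
    Controls themselves are scored too unless ``include_controls=False``
    (their per-gene FC median is 1 by construction).
    """
    ctrls = [s for s in control_ids(metadata) if s in expr.columns]
    if not ctrls:
        raise ValueError("no control samples available as FC reference")
    if gene_subset is not None:
        wanted = [g.upper() for g in gene_subset]
        present = [g for g in wanted if g in expr.index]
        absent = sorted(set(wanted) - set(present))
        if absent:
            warnings.warn(f"genes absent from matrix dropped: {absent}", stacklevel=2)
        expr = expr.loc[present]
    ref = expr[ctrls].median(axis=1)
    samples = [s for s in expr.columns if s in metadata.index]
    if not include_controls:
        samples = [s for s in samples if s not in set(ctrls)]
    fc = np.exp2(expr[samples].sub(ref, axis=0))
    return fc


def count_dysregulated(
    fc_matrix: pd.DataFrame,
    panel: GenePanel,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """NG_V / NG_B per sample: panel genes with FC strictly above ``threshold``.

    Returns a DataFrame indexed by sample with columns ``ng_v``, ``ng_b``
    and the effective panel sizes ``n_vrg``/``n_brg`` actually present in
    the matrix (missing panel genes cap the attainable counts, so
    classifiers can normalize if needed).
    """
    vrg = [g for g in panel.vrg if g in fc_matrix.index]
    brg = [g for g in panel.brg if g in fc_matrix.index]
    if not vrg and not brg:
        raise ValueError("no panel genes present in FC matrix")
    ng_v = (fc_matrix.loc[vrg] > threshold).sum(axis=0)
    ng_b = (fc_matrix.loc[brg] > threshold).sum(axis=0)
    return pd.DataFrame(
        {
            "ng_v": ng_v.astype(int),
            "ng_b": ng_b.astype(int),
            "n_vrg": len(vrg),
            "n_brg": len(brg),
        }
    ).rename_axis("sample_id")


def relative_expression(
    expr: pd.DataFrame, target_gene: str, reference_gene: str
) -> pd.Series:
    """Per-sample linear ratio of target to a housekeeping reference gene.

    ``2^(x_target - x_reference)``; usable as a classifier input when a
    dataset has no healthy-control group to anchor fold changes.
    """
    target_gene = target_gene.upper()
    reference_gene = reference_gene.upper()
    if reference_gene not in expr.index:
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    if target_gene not in expr.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    ratio = np.exp2(expr.loc[target_gene] - expr.loc[reference_gene])
    ratio.name = f"{target_gene}/{reference_gene}"
    return ratio
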