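"""Sex- and age-effect checks on panel fold changes.

Sex: the median fold change is computed per stratum (male cases vs male
controls; female cases vs female controls) alongside the pooled estimate;
genes whose stratum FCs disagree by more than a flag ratio (default 1.4)
are marked as sex-sensitive.

Age: per-gene Pearson correlation of log2 expression with age; the panel
genes are expected to show at most weak age correlation.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import median_fold_change

__all__ = ["sex_stratified_fc", "age_correlation"]

FLAG_RATIO = 1.4


def _group_ids(metadata: pd.DataFrame, group: str, sex: str | None = None) -> list[str]:
    mask = metadata["group"] == group
    if sex is not None:
        mask &= metadata.get("sex") == sex
    return list(metadata.index[mask])


def sex_stratified_fc(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: Sequence[str],
    flag_ratio: float = FLAG_RATIO,
) -> pd.DataFrame:
    """Median FC overall and within each sex, with the between-sex ratio.

    Returns a DataFrame indexed by gene with columns ``fc_all``, ``fc_male``,
    ``fc_female``, ``sex_ratio`` (max/min of the stratum FCs) and ``flagged``
    (ratio strictly above ``flag_ratio``).  An empty stratum yields NaN for
    that stratum and no flag.
    """
    genes = [g.upper() for g in genes]
    present = [g for g in genes if g in expr.index]
    sub = expr.loc[present]
    out = pd.DataFrame(index=pd.Index(present, name="gene"))
    out["fc_all"] = median_fold_change(
        sub, _group_ids(metadata, "case"), _group_ids(metadata, "control")
    )
    for sex in ("male", "female"):
        cases = _group_ids(metadata, "case", sex)
        ctrls = _group_ids(metadata, "control", sex)
        if not cases or not ctrls:
            warnings.warn(f"empty {sex} stratum; FC undefined", stacklevel=2)
            out[f"fc_{sex}"] = np.nan
        else:
            out[f"fc_{sex}"] = median_fold_change(sub, cases, ctrls)
    pair = out[["fc_male", "fc_female"]]
    out["sex_ratio"] = pair.max(axis=1) / pair.min(axis=1)
    out["flagged"] = out["sex_ratio"] > flag_ratio
    out.loc[out["sex_ratio"].isna(), "flagged"] = False
    return out


def age_correlation(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    genes: Sequence[str],
) -> pd.Series:
    """Pearson correlation of per-gene log2 expression with age.

    Only samples with a recorded age are used; requires >= 3 of them and a
    non-constant age vector.
    """
    if "age" not in metadata.columns:
        raise ValueError("metadata has no age column")
    aged = metadata["age"].dropna()
    samples = [s for s in expr.columns if s in aged.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with age")
    age = aged.loc[samples].astype(float)
    if age.nunique() < 2:
        raise ValueError("age is constant; correlation undefined")
    genes = [g.upper() for g in genes]
    present = [g for g in genes if g in expr.index]
    pcc = expr.loc[present, samples].T.corrwith(age)
    pcc.name = "age_pcc"
    return pcc
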