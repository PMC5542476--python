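"""Median fold changes and rank-product differential expression.

Fold changes are median-based: ``FC = 2^(median(case) - median(control))``
on the log2 scale.  The median (rather than the mean) damps the influence
of samples far from the group centre.

The rank product is the two-sample pairwise variant: every case sample is
compared with every control sample; within each comparison genes are ranked
by log-ratio (rank 1 = most up-regulated); a gene's RP_up is the geometric
mean of its ranks over comparisons, and RP_down the analogue for ascending
ranks.  Significance is expressed as the pfp (proportion of false
predictions), estimated by permuting gene labels within each comparison:
pfp(g) = E[# null RP values <= RP(g)] / rank-position of g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEGThresholds",
    "median_fold_change",
    "rank_product",
    "select_degs",
]


@dataclass(frozen=True)
class DEGThresholds:
    """Linear fold-change cutoffs for calling a gene differentially expressed."""

    up: float = 2.0
    down: float = 0.5

    def __post_init__(self) -> None:
        if not self.up > 1.0 > self.down > 0.0:
            raise ValueError("require up > 1 > down > 0")

    @classmethod
    def stringent(cls) -> "DEGThresholds":
        return cls(up=2.0, down=0.5)

    @classmethod
    def lenient(cls) -> "DEGThresholds":
        return cls(up=1.5, down=0.7)


def _check_groups(expr: pd.DataFrame, case_ids: Sequence[str], control_ids: Sequence[str]) -> None:
    for name, ids in (("case", case_ids), ("control", control_ids)):
        if len(ids) == 0:
            raise ValueError(f"{name} group is empty")
        missing = [s for s in ids if s not in expr.columns]
        if missing:
            raise ValueError(f"{name} samples not in expression matrix: {missing}")


def median_fold_change(
    expr: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
) -> pd.Series:
    """Per-gene linear FC = 2^(case log2 median - control log2 median).

    Medians ignore missing entries.  Genes entirely missing in either group
    get ``NaN`` (callers must exclude them downstream).
    """
    _check_groups(expr, case_ids, control_ids)
    med_case = expr[list(case_ids)].median(axis=1)
    med_ctrl = expr[list(control_ids)].median(axis=1)
    fc = np.exp2(med_case - med_ctrl)
    fc.name = "fc"
    return fc


def _geometric_mean_ranks(ranks: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean ignoring NaN; NaN rows stay NaN."""
    with np.errstate(invalid="ignore"):
        return np.exp(np.nanmean(np.log(ranks), axis=1))


def _rank_columns(mat: np.ndarray, ascending: bool) -> np.ndarray:
    df = pd.DataFrame(mat)
    return df.rank(axis=0, ascending=ascending, method="average").to_numpy()


def rank_product(
    expr: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    n_perm: int = 100,
    max_pairs: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-sample rank product with permutation-based pfp estimates.

    Parameters
    ----------
    n_perm
        permutations of gene labels within each comparison for the null RP
        distribution (must be >= 1).
    max_pairs
        when |case| * |control| exceeds this, a uniform subsample of pairs is
        used (seeded) to bound cost.

    Returns a DataFrame indexed by gene with columns
    ``rp_up, rp_down, pfp_up, pfp_down``.
    """
    _check_groups(expr, case_ids, control_ids)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if expr.shape[0] < 2:
        raise ValueError("rank product needs at least 2 genes")
    rng = np.random.default_rng(seed)

    pairs = [(c, k) for c in case_ids for k in control_ids]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]

    case_mat = expr[[c for c, _ in pairs]].to_numpy()
    ctrl_mat = expr[[k for _, k in pairs]].to_numpy()
    ratios = case_mat - ctrl_mat  # genes x pairs, log2 ratios

    ranks_up = _rank_columns(ratios, ascending=False)
    ranks_down = _rank_columns(ratios, ascending=True)
    rp_up = _geometric_mean_ranks(ranks_up)
    rp_down = _geometric_mean_ranks(ranks_down)

    out = pd.DataFrame(
        {
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": _permutation_pfp(ranks_up, rp_up, n_perm, rng),
            "pfp_down": _permutation_pfp(ranks_down, rp_down, n_perm, rng),
        },
        index=expr.index,
    )
    return out


def _permutation_pfp(
    ranks: np.ndarray, rp_obs: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """pfp(g) = (mean count of null RPs <= RP(g) per permutation) / position(g).

    Null RP values are obtained by shuffling each comparison's rank column
    independently (gene labels permuted, sample labels preserved).
    """
    n_genes = ranks.shape[0]
    null_rps = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        shuffled = rng.permuted(ranks, axis=0)
        null_rps[b] = _geometric_mean_ranks(shuffled)
    null_flat = np.sort(null_rps[~np.isnan(null_rps)])
    # expected number of false positives at each gene's RP level
    exp_fp = np.searchsorted(null_flat, rp_obs, side="right") / n_perm
    order = pd.Series(rp_obs).rank(method="average").to_numpy()  # 1 = smallest RP
    with np.errstate(invalid="ignore", divide="ignore"):
        pfp = exp_fp / order
    return np.clip(pfp, 0.0, 1.0)


def select_degs(
    fc: pd.Series,
    thresholds: DEGThresholds = DEGThresholds.stringent(),
    rp: pd.DataFrame | None = None,
) -> tuple[list[str], list[str]]:
    """Split genes into up-/down-regulated sets at strict FC cutoffs.

    ``fc > up`` and ``fc < down`` are strict; ties at the cutoff are excluded.
    When ``rp`` is given, each set is ordered by its rank-product statistic
    (most significant first); otherwise by |log FC| descending.
    """
    fc = fc.dropna()
    up = fc[fc > thresholds.up]
    down = fc[fc < thresholds.down]
    if rp is not None:
        up_order = rp["rp_up"].reindex(up.index)
        down_order = rp["rp_down"].reindex(down.index)
        return (
            list(up_order.sort_values().index),
            list(down_order.sort_values().index),
        )
    return (
        list(up.sort_values(ascending=False).index),
        list(down.sort_values(ascending=True).index),
    )
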