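"""Independent reference implementations used to cross-check the package.

Everything here is deliberately brute-force / textbook-style and shares no
code with the implementation it checks.
"""

from itertools import permutations

import numpy as np
from scipy.stats import rankdata


def exhaustive_two_partition_ss(points: np.ndarray) -> float:
    """Minimum within-cluster sum of squares over all 2-partitions."""
    n = len(points)
    best = np.inf
    for mask in range(1, 2**n - 1):
        a = [i for i in range(n) if mask & (1 << i)]
        b = [i for i in range(n) if not mask & (1 << i)]
        ss = 0.0
        for grp in (a, b):
            pts = points[grp]
            ss += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, ss)
    return best


def irls_logistic(x: np.ndarray, y: np.ndarray, ridge: float = 1e-4,
                  n_iter: int = 200) -> tuple[float, float]:
    """Newton/IRLS fit of P(y=1|x) = sigmoid(a0 + a1 x).

    Maximizes sum log-likelihood - 0.5 * ridge * a1^2 (intercept
    unpenalized).  Returns (a0, a1).
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    pen = np.diag([0.0, ridge])
    for _ in range(n_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p) - pen @ beta
        hess = X.T @ (X * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(beta[0]), float(beta[1])


def rank_product_bruteforce(expr: np.ndarray, n_case: int, n_control: int):
    """RP_up/RP_down by explicit loops over every case x control comparison.

    ``expr`` is genes x (case samples then control samples), log2 scale.
    """
    n_genes = expr.shape[0]
    case = expr[:, :n_case]
    ctrl = expr[:, n_case:n_case + n_control]
    ranks_up, ranks_down = [], []
    for i in range(n_case):
        for j in range(n_control):
            ratio = case[:, i] - ctrl[:, j]
            ranks_up.append(rankdata(-ratio))
            ranks_down.append(rankdata(ratio))
    ru = np.array(ranks_up).T  # genes x comparisons
    rd = np.array(ranks_down).T
    rp_up = np.exp(np.mean(np.log(ru), axis=1))
    rp_down = np.exp(np.mean(np.log(rd), axis=1))
    return rp_up, rp_down


def exhaustive_null_pfp(rp_obs: np.ndarray, n_genes: int, n_comparisons: int):
    """Exact pfp for small problems by enumerating all rank assignments.

    The null places an independent uniform permutation of ranks 1..n_genes in
    each comparison; pfp(g) = E[# null RP <= RP(g)] / rank position of g.
    Feasible for n_genes=4, n_comparisons=4 ((4!)^4 = 331,776 outcomes).
    """
    perms = np.array(list(permutations(range(1, n_genes + 1))), dtype=float)
    logp = np.log(perms)  # (n_perms, n_genes)

    # accumulate sum of log-ranks over comparisons by repeated broadcasting
    totals = logp
    for _ in range(n_comparisons - 1):
        totals = (totals[:, None, :] + logp[None, :, :]).reshape(-1, n_genes)
    null_rp = np.exp(totals / n_comparisons)  # (n_perms^k, n_genes) per-gene null
    # under the null every gene is exchangeable: pool all values
    pooled = np.sort(null_rp.ravel())
    n_experiments = null_rp.shape[0]
    exp_fp = np.searchsorted(pooled, rp_obs, side="right") / n_experiments
    position = rankdata(rp_obs)
    return np.clip(exp_fp / position, 0.0, 1.0)
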