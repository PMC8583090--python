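"""Independent brute-force oracles used by the test suite.

Each oracle takes the slowest, most literal route (threshold scans, direct
combinatorial sums, grid searches) and stays independent of the package
implementation it checks.
"""

from math import comb

import numpy as np
from scipy import special


def ks_running_sum(hit_positions, n: int) -> float:
    """Exhaustive threshold scan of the two-sided KS running sum.

    hit_positions: 1-based ranks of the gene set in the profile.
    Scans every threshold t, tracking the greatest positive deviation of the
    hit CDF above the uniform CDF (counting hits at t) and the greatest
    negative deviation (counting hits strictly before t).
    """
    hits = set(int(h) for h in hit_positions)
    s = len(hits)
    best_a = -np.inf
    best_b = -np.inf
    for t in range(1, n + 1):
        at_or_before = sum(1 for h in hits if h <= t)
        strictly_before = sum(1 for h in hits if h < t)
        best_a = max(best_a, at_or_before / s - t / n)
        best_b = max(best_b, t / n - strictly_before / s)
    return best_a if best_a >= best_b else -best_b


def bh_step_up(p, alpha: float):
    """Direct BH step-up rejection set at level alpha (indices rejected)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= alpha * k / n:
            k_max = k
    return set(order[:k_max].tolist())


def hypergeom_upper_tail(k: int, universe: int, set_size: int, query: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric pmf."""
    total = comb(universe, query)
    acc = 0
    for i in range(k, min(set_size, query) + 1):
        acc += comb(set_size, i) * comb(universe - set_size, query - i)
    return acc / total


def fit_prior_grid(sample_variances, df_resid: int):
    """Grid-search moment fit of (d0, s0_sq) on log sample variances."""
    s2 = np.asarray(sample_variances, dtype=float)
    e = np.log(s2) - special.digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    target_var = e.var(ddof=1) - special.polygamma(1, df_resid / 2.0)
    if target_var <= 0:
        return np.inf, float(np.exp(e.mean()))
    grid = np.exp(np.linspace(np.log(0.01), np.log(500.0), 20000))
    err = np.abs(special.polygamma(1, grid / 2.0) - target_var)
    d0 = float(grid[np.argmin(err)])
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def pearson_direct(x, y) -> float:
    """Pearson r straight from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def fisher_z_interval(rho: float, n: int, level: float = 0.95):
    """Closed-form Fisher-z interval around a true correlation rho at size n."""
    from scipy.stats import norm

    z = np.arctanh(rho)
    half = norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def auroc_pairwise(scores, labels) -> float:
    """AUROC by exhaustive pairwise comparison (higher score = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)
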