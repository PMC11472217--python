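"""Rank-based block-design tests: Friedman, Skillings-Mack, and Holm post hocs.

Blocks are subjects (or subject x lamina cells) and treatments are sequences,
gas conditions or laminae. Friedman requires complete rows; the Skillings-Mack
statistic generalizes it to tables with missing cells (every treatment must be
observed at least once, blocks with fewer than two observations are dropped)
and reduces exactly to Friedman on complete tie-free tables. With few blocks
the chi-square asymptotics are replaced by a seeded within-block permutation
null. Pairwise post hocs are Wilcoxon signed-rank tests with a normal
approximation, Holm-adjusted over the declared comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["RankTestResult", "friedman", "skillings_mack", "mack_skillings", "posthoc_pairwise"]

#: blocks below this count trigger the permutation null instead of chi-square
PERMUTATION_THRESHOLD = 8


@dataclass
class RankTestResult:
    statistic: float
    df: int
    pvalue: float
    method: str
    n_blocks: int

    def summary(self) -> str:
        return (
            f"{self.method}: chi2({self.df}) = {self.statistic:.4g}, "
            f"p = {self.pvalue:.4g} (n_blocks = {self.n_blocks})"
        )


def _friedman_statistic(x: np.ndarray) -> float:
    """Friedman chi-square with average ranks and tie correction."""
    n, k = x.shape
    ranks = np.vstack([stats.rankdata(row) for row in x])
    R = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum((R - n * (k + 1) / 2.0) ** 2)
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0
    return float(stat / correction)


def friedman(
    table: np.ndarray,
    n_permutations: int = 2000,
    seed: int | None = 0,
    force_asymptotic: bool = False,
) -> RankTestResult:
    """Friedman test on a complete blocks-by-treatments table.

    Rows with missing cells are an error (use :func:`skillings_mack`). For
    fewer than 8 blocks the p-value comes from a seeded within-block
    permutation null unless ``force_asymptotic``.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    if not np.all(np.isfinite(x)):
        raise ValueError("table has missing cells; use skillings_mack")
    n, k = x.shape
    stat = _friedman_statistic(x)
    if n < PERMUTATION_THRESHOLD and not force_asymptotic:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = np.vstack([rng.permutation(row) for row in x])
            if _friedman_statistic(perm) >= stat - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = "Friedman (permutation)"
    else:
        p = float(stats.chi2.sf(stat, k - 1))
        method = "Friedman"
    return RankTestResult(stat, k - 1, p, method, n)


def _skillings_mack_statistic(x: np.ndarray) -> tuple[float, int]:
    """Skillings-Mack statistic and the rank of its null covariance."""
    n, k = x.shape
    obs = np.isfinite(x)
    A = np.zeros(k)
    Sigma = np.zeros((k, k))
    for i in range(n):
        cols = np.where(obs[i])[0]
        ki = len(cols)
        if ki < 2:
            continue
        r = stats.rankdata(x[i, cols])
        w = np.sqrt(12.0 / (ki + 1.0))
        A[cols] += w * (r - (ki + 1) / 2.0)
        # null covariance contribution of block i
        for a_idx, ja in enumerate(cols):
            for jb in cols[a_idx + 1 :]:
                Sigma[ja, jb] -= 1.0
                Sigma[jb, ja] -= 1.0
            Sigma[ja, ja] += ki - 1.0
    Sinv = np.linalg.pinv(Sigma, rcond=1e-10)
    stat = float(A @ Sinv @ A)
    rank = int(np.linalg.matrix_rank(Sigma, tol=1e-10))
    return stat, rank


def skillings_mack(
    table: np.ndarray,
    n_permutations: int = 2000,
    seed: int | None = 0,
    force_asymptotic: bool = False,
) -> RankTestResult:
    """Skillings-Mack test for two-way layouts with missing cells.

    Within each block the observed cells are ranked and centered, scaled by
    sqrt(12 / (k_i + 1)); the statistic is the quadratic form of the treatment
    score vector against the pseudo-inverse of its null covariance, chi-square
    with (treatments - 1) df asymptotically. Reduces to Friedman on complete
    tie-free tables.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 treatments")
    obs = np.isfinite(x)
    usable = obs.sum(axis=1) >= 2
    x = x[usable]
    obs = obs[usable]
    if x.shape[0] < 2:
        raise ValueError("fewer than 2 usable blocks")
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("every treatment must be observed in at least one block")
    n, k = x.shape
    stat, cov_rank = _skillings_mack_statistic(x)
    if cov_rank == 0:
        raise ValueError("degenerate null covariance (no within-block comparisons)")
    df = k - 1
    if n < PERMUTATION_THRESHOLD and not force_asymptotic:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = x.copy()
            for i in range(n):
                cols = np.where(obs[i])[0]
                perm[i, cols] = x[i, cols][rng.permutation(len(cols))]
            if _skillings_mack_statistic(perm)[0] >= stat - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        method = "Skillings-Mack (permutation)"
    else:
        p = float(stats.chi2.sf(stat, df))
        method = "Skillings-Mack"
    return RankTestResult(stat, df, p, method, n)


#: alias matching the common naming of the missing-cell rank test
mack_skillings = skillings_mack


def posthoc_pairwise(
    comparisons: list[tuple[str, np.ndarray, np.ndarray]],
    method: str = "holm",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Wilcoxon signed-rank post hocs with step-down Holm adjustment.

    ``comparisons`` is an explicit family of (label, x, y) paired samples
    (e.g. one lamina between sequences, or neighbouring laminae within one
    sequence). Pairs with missing values are dropped per comparison;
    comparisons with fewer than ``min_pairs`` usable pairs are flagged
    underpowered and their p-values reported unadjusted.

    Returns a tidy frame: comparison, n_pairs, z, p, p_adjusted, underpowered.
    """
    if not comparisons:
        raise ValueError("empty comparison family")
    rows = []
    for label, x, y in comparisons:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        d = x[ok] - y[ok]
        n = len(d)
        if n == 0 or np.all(d == 0):
            rows.append((label, n, 0.0, 1.0, True))
            continue
        under = n < min_pairs
        res = stats.wilcoxon(d, method="approx", correction=False)
        z = float(getattr(res, "zstatistic", stats.norm.isf(res.pvalue / 2.0)))
        rows.append((label, n, z, float(res.pvalue), under))
    df = pd.DataFrame(rows, columns=["comparison", "n_pairs", "z", "p", "underpowered"])
    adj = np.full(len(df), np.nan)
    powered = ~df["underpowered"].to_numpy()
    if powered.any():
        adj[powered] = multipletests(df.loc[powered, "p"], method=method)[1]
    df["p_adjusted"] = np.where(powered, adj, df["p"])
    return df
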