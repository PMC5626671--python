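"""Nonparametric and classical tests used by the phantom/clinical analyses.

Wilcoxon signed-rank (exact enumeration for small samples, normal
approximation otherwise), Friedman's rank test, Steel-Dwass all-pairs
comparisons with family-wise control via the studentized-range
distribution, the paired t test, and Pearson correlation with linear
regression.  Mid-ranks are used for ties throughout; the signed-rank test
drops zero differences (Wilcoxon's convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "StatResult",
    "wilcoxon_signed_rank",
    "friedman",
    "steel_dwass",
    "paired_t",
    "pearson_regression",
]

EXACT_LIMIT = 15  # enumerate all 2^m sign patterns up to this many nonzero diffs


@dataclass(frozen=True)
class StatResult:
    method: str
    statistic: float
    p_value: float
    exact: bool
    n: int
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic by dynamic
    programming over all 2^m sign assignments.

    Mid-ranks can be half-integral, so ranks are doubled to integers and
    the distribution of 2*W+ is built by convolution.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    x, y=None, mode: str = "auto"
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped; ties take mid-ranks.  ``mode="exact"``
    (or "auto" with <= 15 nonzero differences) enumerates the full null
    distribution of W+; otherwise a tie-corrected normal approximation is
    used.  All-zero differences give the degenerate result p = 1.
    """
    if mode not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    m = d.size
    if m == 0:
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, True, 0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    use_exact = mode == "exact" or (mode == "auto" and m <= EXACT_LIMIT)
    if use_exact:
        p = _signed_rank_exact_p(ranks, w_plus)
        return StatResult("wilcoxon_signed_rank", w_plus, p, True, m)
    # tie-corrected normal approximation with continuity correction
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - _tie_correction_signed(ranks)
    z = max(abs(w_plus - mean) - 0.5, 0.0) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return StatResult("wilcoxon_signed_rank", w_plus, p, False, m)


def _tie_correction_signed(ranks: np.ndarray) -> float:
    """Variance reduction for tied absolute differences: sum(t^3 - t)/48."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(((counts**3 - counts).sum()) / 48.0)


def friedman(matrix) -> StatResult:
    """Friedman's rank test on a blocks x treatments matrix.

    Within-block mid-ranks; statistic
    ``chi2_F = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)`` referred to a
    chi-square with k - 1 degrees of freedom.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 treatments")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 blocks")
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rj = ranks.sum(axis=0)
    statistic = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0
    return StatResult("friedman", statistic, p, False, n, {"rank_sums": rj.tolist()})


def _pair_studentized(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected standardized rank-sum statistic for one pair."""
    joint = np.concatenate([a, b])
    ranks = stats.rankdata(joint)
    n1, n2 = a.size, b.size
    n = n1 + n2
    w = ranks[:n1].sum()
    e = n1 * (n + 1) / 2.0
    var = n1 * n2 / (n * (n - 1.0)) * float((ranks**2).sum() - n * (n + 1) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((w - e) / np.sqrt(var))


def steel_dwass(
    groups, method: str = "studentized_range", n_permutations: int = 10_000,
    seed: int | None = 0,
) -> list[StatResult]:
    """Steel-Dwass all-pairs comparisons among k >= 3 groups.

    Each pair is re-ranked jointly; the standardized rank-sum statistic t
    is referred to the studentized-range distribution
    (``p = P(Q_{k, inf} >= |t| * sqrt(2))``), controlling the family-wise
    error over all k(k-1)/2 comparisons.  ``method="permutation"`` instead
    estimates the family-wise p from the permutation distribution of the
    maximum |t| over all pairs under group-label shuffling.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError(
            "Steel-Dwass needs >= 3 groups; use a two-sample rank-sum test instead"
        )
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    pairs = list(combinations(range(k), 2))
    t_obs = {
        (i, j): _pair_studentized(groups[i], groups[j]) for i, j in pairs
    }
    results: list[StatResult] = []
    if method == "studentized_range":
        for (i, j), t in t_obs.items():
            if t == 0.0:
                p = 1.0
            else:
                p = float(
                    min(1.0, stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, np.inf))
                )
            results.append(
                StatResult(
                    "steel_dwass", t, p, False,
                    groups[i].size + groups[j].size,
                    {"pair": (i, j)},
                )
            )
        return results
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    edges = np.cumsum([0] + sizes)
    max_t = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(pooled)
        shuffled = [perm[edges[i]:edges[i + 1]] for i in range(k)]
        max_t[b] = max(
            abs(_pair_studentized(shuffled[i], shuffled[j])) for i, j in pairs
        )
    for (i, j), t in t_obs.items():
        p = float((np.sum(max_t >= abs(t)) + 1) / (n_permutations + 1))
        results.append(
            StatResult(
                "steel_dwass_permutation", t, min(p, 1.0), False,
                groups[i].size + groups[j].size,
                {"pair": (i, j)},
            )
        )
    return results


def paired_t(x, y=None) -> StatResult:
    """Classical two-sided paired t test (n - 1 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size < 2:
        raise ValueError("need >= 2 pairs")
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of differences; t undefined")
    t = float(d.mean() / (d.std(ddof=1) / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), d.size - 1))
    return StatResult("paired_t", t, min(p, 1.0), False, d.size)


def pearson_regression(x, y) -> StatResult:
    """Least-squares line plus Pearson r; the p-value is for r via the
    t transform.  Returns slope/intercept in ``extra``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(x, x[0]):
        raise ValueError("constant x; regression degenerate")
    fit = stats.linregress(x, y)
    return StatResult(
        "pearson_regression",
        float(fit.rvalue),
        float(fit.pvalue),
        False,
        x.size,
        {"slope": float(fit.slope), "intercept": float(fit.intercept)},
    )
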