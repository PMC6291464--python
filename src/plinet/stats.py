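"""Nonparametric statistics battery.

Rank-based partial correlation with covariate control, the Friedman test
across repeated conditions with studentized-range (Nemenyi-type) post-hoc
pairwise comparisons, Wilcoxon signed-rank and Mann-Whitney U tests, and
Benjamini-Hochberg FDR control for node-level test families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "partial_correlation",
    "friedman_test",
    "posthoc_pairwise",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bh_fdr",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    adjust_method: str | None = None
    direction: int = 0           # sign of the effect (+1, -1, 0)
    family: str | None = None
    extra: dict = field(default_factory=dict)


def _as_matrix(covariates, n: int) -> np.ndarray:
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != n:
        raise ValueError(f"covariates have {z.shape[0]} rows, expected {n}")
    return z


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates, method: str = "rank") -> StatResult:
    """Correlation of x and y after removing covariate effects from both.

    ``method="rank"`` (default) rank-transforms x, y and each covariate
    first (Spearman-type partial correlation); ``"linear"`` works on the raw
    values.  p comes from the t approximation with df = n - 2 - n_covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    z = _as_matrix(covariates, len(x))
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(z), axis=1)
    x, y, z = x[ok], y[ok], z[ok]
    n, k = len(x), z.shape[1]
    if n < 4 or n - 2 - k < 1:
        raise ValueError(f"too few complete cases (n={n}) for {k} covariate(s)")
    if method == "rank":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
        z = np.column_stack([sps.rankdata(z[:, j]) for j in range(k)])
    elif method != "linear":
        raise ValueError(f"unknown method {method!r}")

    rx = _residualize(x, z)
    ry = _residualize(y, z)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("a variable is collinear with the covariates")
    r = float(np.dot(rx, ry) / (len(rx) * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(test=f"partial_correlation[{method}]", statistic=r, p_raw=p,
                      direction=int(np.sign(r)), extra={"t": float(t), "df": df, "n": n})


def _friedman_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, values)


def friedman_test(values) -> StatResult:
    """Friedman chi-square on within-subject midranks, with tie correction.

    ``values`` is subjects x k (complete blocks; missing cells are an error).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be subjects x conditions")
    if not np.all(np.isfinite(v)):
        raise ValueError("missing cells: Friedman requires complete blocks")
    n, k = v.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    ranks = _friedman_ranks(v)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rj ** 2)) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in v:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts ** 3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k * k - 1))
    if correction <= 0:
        return StatResult(test="friedman", statistic=0.0, p_raw=1.0,
                          extra={"df": k - 1, "n": n, "mean_ranks": ranks.mean(0).tolist()})
    stat = chi2 / correction
    p = float(sps.chi2.sf(stat, k - 1))
    return StatResult(test="friedman", statistic=float(stat), p_raw=p,
                      extra={"df": k - 1, "n": n, "mean_ranks": ranks.mean(0).tolist()})


def wilcoxon_signed_rank(paired_a, paired_b) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; p is exact for small tie-free samples and a
    tie-corrected normal approximation otherwise.  All-zero differences give
    the degenerate p = 1.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return StatResult(test="wilcoxon_signed_rank", statistic=0.0, p_raw=1.0,
                          direction=0, extra={"n": 0})
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="auto")
    direction = int(np.sign(np.sum(np.sign(d))))
    return StatResult(test="wilcoxon_signed_rank", statistic=float(res.statistic),
                      p_raw=float(res.pvalue), direction=direction,
                      extra={"n": int(d.size)})


def mann_whitney_u(a, b) -> StatResult:
    """Two-sided Mann-Whitney U; exact for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(res.statistic)
    direction = int(np.sign(u - a.size * b.size / 2.0))
    return StatResult(test="mann_whitney_u", statistic=u, p_raw=float(res.pvalue),
                      direction=direction, extra={"n1": int(a.size), "n2": int(b.size),
                                                  "method": method})


def posthoc_pairwise(values, method: str = "wsr_adjusted") -> list[StatResult]:
    """Pairwise post-hoc comparisons after a Friedman test.

    For each of the k(k-1)/2 condition pairs, ``p_adjusted`` comes from the
    Nemenyi studentized-range procedure on Friedman mean ranks (the standard
    reading of a Tukey-Kramer-style adjustment for this design), while
    ``p_raw`` is the plain paired Wilcoxon signed-rank p for transparency.
    """
    if method not in ("wsr_adjusted", "nemenyi"):
        raise ValueError(f"unknown method {method!r}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be subjects x conditions")
    n, k = v.shape
    if k < 2:
        raise ValueError("need >= 2 conditions")
    mean_ranks = _friedman_ranks(v).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out: list[StatResult] = []
    for i, j in combinations(range(k), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p_adj = float(sps.studentized_range.sf(z * np.sqrt(2.0), k, np.inf))
        p_adj = min(1.0, p_adj)
        wsr = wilcoxon_signed_rank(v[:, i], v[:, j])
        out.append(StatResult(
            test=f"posthoc[{i}-{j}]", statistic=float(mean_ranks[i] - mean_ranks[j]),
            p_raw=wsr.p_raw, p_adjusted=p_adj, adjust_method="nemenyi",
            direction=int(np.sign(mean_ranks[i] - mean_ranks[j])),
            extra={"pair": (i, j), "wsr_statistic": wsr.statistic, "n": n}))
    return out


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: rejection mask and monotone adjusted p-values.

    Rejects all ordered p_(i) with i <= max{ i : p_(i) <= i*q/m }; adjusted
    p-values are the standard min-cummin transform of p_(i) * m / i.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresholds = q * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return reject, adj
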