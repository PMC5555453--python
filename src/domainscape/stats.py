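"""Rank and enrichment statistics: Kruskal-Wallis with tie correction,
Dunn post hoc z tests under Holm step-down control, upper-tail
hypergeometric gene-set enrichment, Spearman correlation, and LOESS with
a cross-validated span for the Nc-vs-CAI diagnostic.

The rank tests are implemented directly from their formulas (with midrank
tie handling) so that the widely used library routines remain available
as independent cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata, t as t_dist, hypergeom


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def _tie_sum(pooled: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    H = [12/(N(N+1)) * sum n_i * Rbar_i^2 - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N)),
    p from chi-square with (number of groups - 1) df.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if N < 3:
        raise ValueError("need >= 3 observations in total")
    ranks = rankdata(pooled)
    h = 0.0
    off = 0
    for g in groups:
        r = ranks[off : off + len(g)]
        h += r.sum() ** 2 / len(g)
        off += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    correction = 1.0 - _tie_sum(pooled) / (N**3 - N)
    if correction <= 0:  # all values identical
        return 0.0, 1.0
    h /= correction
    return float(h), float(chi2.sf(h, len(groups) - 1))


# ---------------------------------------------------------------------------
# Dunn post hoc with Holm step-down

@dataclass
class GroupComparison:
    labels: list
    kw_h: float
    kw_p: float
    alpha: float
    posthoc_run: bool
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    note: str = ""


def holm_adjust(pvalues) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjusted p-values and rejection flags at alpha=None.

    Returns (adjp, order) where adjp is in the input order; rejection at a
    level should use the step-down rule (prefix of the p-ordered list).
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj, order


def dunn_holm(groups, labels=None, alpha: float = 0.05,
              force_posthoc: bool = False) -> GroupComparison:
    """Kruskal-Wallis gatekeeper followed by pairwise Dunn z tests with
    Holm family-wise error control.

    Dunn z for groups i, j uses pooled midranks:
    z = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with T the tie sum.  The post hoc stage only runs when the KW test
    rejects at alpha (the gatekeeping workflow), unless forced.  Holm
    rejections form a prefix of the p-ordered pairs: the step-down stops
    at the first non-rejection.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    kw_h, kw_p = kruskal_wallis(groups)
    if kw_p >= alpha and not force_posthoc:
        return GroupComparison(labels, kw_h, kw_p, alpha, False,
                               note="KW not significant; post hoc skipped")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = rankdata(pooled)
    means, sizes = [], []
    off = 0
    for g in groups:
        means.append(ranks[off : off + len(g)].mean())
        sizes.append(len(g))
        off += len(g)
    var_base = N * (N + 1) / 12.0 - _tie_sum(pooled) / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (means[i] - means[j]) / se if se > 0 else 0.0
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": z, "p": 2.0 * norm.sf(abs(z))})
    df = pd.DataFrame(rows)
    adjp, order = holm_adjust(df["p"].to_numpy())
    df["adjp"] = adjp
    reject = np.zeros(len(df), dtype=bool)
    for idx in order:  # step-down: stop at first failure
        if df.loc[idx, "adjp"] <= alpha:
            reject[idx] = True
        else:
            break
    df["reject"] = reject
    return GroupComparison(labels, kw_h, kw_p, alpha, True, df)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment

@dataclass
class EnrichmentResult:
    population: int
    successes: int
    sample: int
    observed: int
    p_value: float


def hypergeom_upper(N: int, K: int, n: int, k: int,
                    exact_limit: int = 1000) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment P(X >= k).

    Exact integer combinatorics for N <= exact_limit (sums of binomial
    products over a common denominator), log-gamma via scipy beyond.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid population/sample: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"observed overlap k={k} outside [0, min(K, n)]")
    if N <= exact_limit:
        num = sum(math.comb(K, j) * math.comb(N - K, n - j)
                  for j in range(k, min(K, n) + 1) if n - j <= N - K)
        p = num / math.comb(N, n)
    else:
        p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(N, K, n, k, p)


# ---------------------------------------------------------------------------
# Spearman correlation

def spearman(x, y) -> tuple[float | None, float | None, str]:
    """Spearman rho on midranks and its two-sided t-approximation p-value.

    Returns (rho, p, status); a constant input yields (None, None,
    "undefined: constant input") rather than NaN surprises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must pair up")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None, None, "undefined: constant input"
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / math.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    if abs(rho) >= 1.0:
        return rho, 0.0, "ok"
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return rho, float(2 * t_dist.sf(abs(t), n - 2)), "ok"


# ---------------------------------------------------------------------------
# LOESS with GCV-selected span

@dataclass
class TrendFit:
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    span: float
    degree: int = 1
    robust_iters: int = 4


def _lowess_trace(x: np.ndarray, frac: float) -> float:
    """Trace of the local-linear smoother matrix with tricube weights over
    the frac-nearest neighbours (closed form of the self-influence)."""
    n = len(x)
    r = max(int(np.ceil(frac * n)), 2)
    tr = 0.0
    order = np.argsort(x)
    xs = x[order]
    for i in range(n):
        d = np.abs(xs - xs[i])
        bw = np.partition(d, r - 1)[r - 1]
        if bw == 0:
            tied = d == 0
            tr += 1.0 / np.sum(tied)
            continue
        w = np.clip(1 - (d / bw) ** 3, 0, None) ** 3
        dx = xs - xs[i]
        s0, s1, s2 = np.sum(w), np.sum(w * dx), np.sum(w * dx * dx)
        denom = s0 * s2 - s1 * s1
        tr += w[i] * s2 / denom if denom > 0 else w[i] / s0
    return tr


def loess_trend(x, y, span: float | None = None,
                span_grid=None, robust_iters: int = 4) -> TrendFit:
    """Degree-1 LOESS (tricube weights, bisquare robustness iterations)
    with the span selected by generalized cross-validation.

    GCV(span) = n * RSS / (n - trace(S))^2 evaluated on the initial
    non-robust pass over a grid (default 0.2-0.95 step 0.05); the robust
    iterations then run at the chosen span.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 points")
    order = np.argsort(x)

    def fit(frac: float, it: int) -> np.ndarray:
        out = lowess(y, x, frac=frac, it=it, delta=0.0, return_sorted=False)
        return np.asarray(out, dtype=float)

    if span is None:
        grid = np.arange(0.2, 0.951, 0.05) if span_grid is None else np.asarray(span_grid)
        n = len(x)
        best = (np.inf, grid[-1])
        for frac in grid:
            resid = y - fit(frac, 0)
            tr = _lowess_trace(x, frac)
            denom = n - tr
            if denom <= 0:
                continue
            score = n * float(np.sum(resid**2)) / denom**2
            if score < best[0]:
                best = (score, float(frac))
        span = best[1]
    fitted = fit(span, robust_iters)
    return TrendFit(x, y, fitted, span, 1, robust_iters)


def local_slope_sign(trend: TrendFit) -> np.ndarray:
    """Sign of the fitted curve's local slope at each point (x-sorted
    finite differences mapped back to input order); the mutational-bias
    vs selection classification of the inverted-V diagnostic."""
    order = np.argsort(trend.x)
    xs, fs = trend.x[order], trend.fitted[order]
    slopes = np.gradient(fs, xs, edge_order=1)
    out = np.empty(len(xs))
    out[order] = np.sign(slopes)
    return out
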