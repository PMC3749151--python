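"""Rank statistics and multivariate helpers with explicit tie/continuity conventions.

Small-sample nonparametric results are sensitive to reporting conventions that
software packages do not share: which U is reported, how ties enter the normal
variance, whether a continuity correction is applied, and how zero differences
are handled in the signed-rank test.  This module pins one convention set down
and exposes every switch:

* ``mann_whitney`` — midrank ties, reported statistic is ``min(U1, U2)``,
  tie-corrected normal variance, continuity correction (0.5 toward the mean)
  applied by default.
* ``wilcoxon_signed_rank`` — zero differences dropped before ranking, midrank
  ties on |d|, tie-corrected variance, no continuity correction by default.

These defaults are the conventions under which the blind-test comparisons in
this package's reference analyses reproduce exactly from integer percentage
tables.  Kendall's tau-b, Shapiro-Wilk, one-way ANOVA and the studentized-range
tail are delegated to scipy; PCA is an explicit correlation-matrix
eigendecomposition so that the loading sign convention is deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "PCAResult",
    "midranks",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "kendall_tau",
    "one_way_anova",
    "tukey_hsd",
    "shapiro_wilk",
    "pca",
]


@dataclass
class RankTestResult:
    """Statistic bundle for a rank test (Mann-Whitney U or Wilcoxon W)."""

    name: str                      # "U" or "W"
    statistic: float
    z: float
    p: float
    n1: int
    n2: int                        # for W: number of zero differences dropped
    tie_counts: tuple[int, ...]    # multiplicities of tied groups (t >= 2)
    continuity: bool
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.name == "U" and not (0 <= self.statistic <= self.n1 * self.n2):
                raise ValueError("U out of range")
            if self.name == "W":
                n = self.extra.get("n_effective", self.n1)
                if not (0 <= self.statistic <= n * (n + 1) / 2):
                    raise ValueError("W out of range")


@dataclass
class PCAResult:
    loadings: np.ndarray           # (n_vars, n_components), columns are components
    explained_pct: np.ndarray      # percentages, sum to 100
    scores: np.ndarray             # (n_obs, n_components)
    columns: list[str] | None = None


def _as_finite_1d(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


def midranks(values) -> np.ndarray:
    """Ranks 1..n with tied values receiving the mean of their rank positions."""
    arr = _as_finite_1d(values)
    return sps.rankdata(arr, method="average")


def _tie_counts(values: np.ndarray) -> tuple[int, ...]:
    _, counts = np.unique(values, return_counts=True)
    return tuple(int(c) for c in counts if c >= 2)


def mann_whitney(a, b, continuity: bool = True) -> RankTestResult:
    """Two-sample Mann-Whitney test on midranks.

    Reports ``min(U1, U2)``. The normal deviate z is signed from the first
    sample's U (so a first sample with lower ranks yields negative z), uses
    the tie-corrected variance

        sigma^2 = (n1*n2/12) * [(N+1) - sum(t^3 - t) / (N*(N-1))],

    and, when ``continuity`` is set, shrinks |U1 - mu| by 0.5 before dividing.
    """
    a = _as_finite_1d(a, "a")
    b = _as_finite_1d(b, "b")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    ties = _tie_counts(pooled)
    big_n = n1 + n2
    tie_term = sum(t ** 3 - t for t in ties)
    var = n1 * n2 / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return RankTestResult("U", u, float("nan"), float("nan"), n1, n2,
                              ties, continuity, degenerate=True,
                              extra={"u1": u1, "u2": u2, "reason": "zero variance"})
    mu = n1 * n2 / 2.0
    diff = u1 - mu
    if continuity and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult("U", u, float(z), float(min(p, 1.0)), n1, n2,
                          ties, continuity, extra={"u1": float(u1), "u2": float(u2)})


def mann_whitney_exact_p(a, b) -> float:
    """Exact two-sided p for min-U by full enumeration of group labelings.

    Brute-force reference for small N; O(C(N, n1)) — intended for N <= 14.
    """
    a = _as_finite_1d(a, "a")
    b = _as_finite_1d(b, "b")
    n1 = len(a)
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    obs = _min_u(ranks[:n1], n1, len(b))
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if _min_u(ranks[list(idx)], n1, len(b)) <= obs + 1e-9:
            count += 1
    return count / total


def _min_u(group_ranks: np.ndarray, n1: int, n2: int) -> float:
    u1 = group_ranks.sum() - n1 * (n1 + 1) / 2.0
    return min(u1, n1 * n2 - u1)


def wilcoxon_signed_rank(x, y, continuity: bool = False) -> RankTestResult:
    """Paired Wilcoxon signed-rank test on differences d = y - x.

    Zero differences are dropped (reducing the effective n), |d| are
    midranked, W = sum of ranks of positive differences, and

        z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48).

    No continuity correction is applied unless requested.
    """
    x = _as_finite_1d(x, "x")
    y = _as_finite_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return RankTestResult("W", 0.0, float("nan"), float("nan"), 0, n_zero,
                              (), continuity, degenerate=True,
                              extra={"n_effective": 0, "reason": "all differences zero"})
    ranks = midranks(np.abs(d))
    w = float(ranks[d > 0].sum())
    ties = _tie_counts(np.abs(d))
    tie_term = sum(t ** 3 - t for t in ties)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return RankTestResult("W", w, float("nan"), float("nan"), n, n_zero,
                              ties, continuity, degenerate=True,
                              extra={"n_effective": n, "reason": "zero variance"})
    mu = n * (n + 1) / 4.0
    diff = w - mu
    if continuity and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankTestResult("W", w, float(z), float(min(p, 1.0)), n, n_zero,
                          ties, continuity, extra={"n_effective": n})


def wilcoxon_exact_p(x, y) -> float:
    """Exact two-sided p for W+ by enumerating all 2^n sign assignments."""
    x = _as_finite_1d(x, "x")
    y = _as_finite_1d(y, "y")
    d = (y - x)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences zero")
    if n > 20:
        raise ValueError("enumeration limited to n <= 20")
    ranks = midranks(np.abs(d))
    obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if abs(w - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / 2 ** n


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall's tau-b with tie adjustment; normal-approximation two-sided p."""
    x = _as_finite_1d(x, "x")
    y = _as_finite_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau undefined: zero variance in an input")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def one_way_anova(groups) -> dict:
    """One-way ANOVA. Returns F, df = (between, within), p.

    ``groups`` is a sequence of 1-D samples. An everywhere-zero within-group
    variance is flagged with an infinite F rather than an exception.
    """
    arrs = [_as_finite_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs at least 2 values")
    k = len(arrs)
    n_total = sum(len(g) for g in arrs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrs)
    if ssw == 0:
        return {"F": float("inf"), "df": (k - 1, n_total - k), "p": 0.0,
                "degenerate": True}
    f, p = sps.f_oneway(*arrs)
    return {"F": float(f), "df": (k - 1, n_total - k), "p": float(p),
            "degenerate": False}


def tukey_hsd(groups, labels=None) -> list[dict]:
    """Tukey(-Kramer) HSD after one-way ANOVA.

    Q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)); the p-value is
    the studentized-range tail with k groups and N - k error df.
    """
    arrs = [_as_finite_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrs):
        raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [str(i) for i in range(len(arrs))]
    k = len(arrs)
    n_total = sum(len(g) for g in arrs)
    df_w = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in arrs) / df_w
    out = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = arrs[i], arrs[j]
        se = np.sqrt(msw / 2.0 * (1.0 / len(gi) + 1.0 / len(gj)))
        if se == 0:
            q, p = float("inf"), 0.0
        else:
            q = abs(gi.mean() - gj.mean()) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        out.append({"pair": (labels[i], labels[j]), "Q": float(q), "p": p,
                    "mean_diff": float(gi.mean() - gj.mean())})
    return out


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    arr = _as_finite_1d(values)
    if not 3 <= len(arr) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(arr)
    return float(w), float(p)


def pca(matrix, standardize: bool = True, columns=None) -> PCAResult:
    """Principal component analysis by eigendecomposition.

    With ``standardize`` (default) the correlation matrix is decomposed —
    appropriate when variables are on incommensurate scales. Each component's
    loadings are signed so that the largest-magnitude loading is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 3 observations and >= 2 variables")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite values")
    names = list(columns) if columns is not None else [str(i) for i in range(x.shape[1])]
    sd = x.std(axis=0, ddof=1)
    if standardize:
        bad = np.where(sd == 0)[0]
        if bad.size:
            raise ValueError(f"constant column under standardization: {names[bad[0]]}")
        xc = (x - x.mean(axis=0)) / sd
    else:
        xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    if total == 0:
        raise ValueError("zero total variance")
    explained = 100.0 * eigval / total
    scores = xc @ eigvec
    return PCAResult(loadings=eigvec, explained_pct=explained, scores=scores,
                     columns=names)
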