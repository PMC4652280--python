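"""Statistical primitives shared by the screens and the integration step.

Classical tests (Fisher exact, Student t, one-way ANOVA, chi-square) delegate
to scipy; rank correlation is implemented both pairwise (with an optional
exact small-n permutation p) and vectorised over a gene x strain matrix, which
is what the permutation screens need.  FDR control is available as
Benjamini-Hochberg (via statsmodels) and as Storey q-values with the
lambda-grid pi0 estimate.

Every stochastic procedure takes an explicit seed; there is no module-level
RNG state.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    tail: str  # "one" or "two"
    df: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class PermutationNull:
    """Observed per-item statistics and their permutation null."""

    observed: np.ndarray  # (n_items,)
    null: np.ndarray  # (n_perm, n_items)
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# rank correlation


def _rank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def spearman(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> TestResult:
    """Spearman rank correlation with midrank ties.

    Two-sided p from the t approximation with df = n - 2; for n <= 9 an
    exact p can be requested (``exact=True``), computed by enumerating all
    n! permutations of one ranking.  Pairs with a missing value are dropped
    first (pairwise-complete).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValueError("exact permutation p limited to n <= 9")
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = _pearson_rows(rx[perms], ry)
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = _spearman_p_t(np.array([rho]), n)[0]
    return TestResult(statistic=rho, p_value=p, tail="two", df=n - 2)


def _pearson_rows(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``y``."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    return (rc @ yc) / denom


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for rank correlations via the t approximation."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return np.minimum(p, 1.0)


def spearman_matrix(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided p of a matrix against one response.

    ``X`` is items x observations (e.g. genes x strains); rows with zero rank
    variance get ``rho = NaN, p = NaN`` (constant expression carries no rank
    signal).  Midranks handle ties; p uses the t approximation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[1] != n:
        raise ValueError("X columns must match response length")
    if n < 3:
        raise ValueError("need >= 3 observations")
    rX = _rank(X, axis=1)
    ry = _rank(y)
    const = np.ptp(rX, axis=1) == 0
    rho = np.full(X.shape[0], np.nan)
    if np.ptp(ry) == 0:
        raise ValueError("constant response vector")
    ok = ~const
    rho[ok] = _pearson_rows(rX[ok], ry)
    p = np.full(X.shape[0], np.nan)
    p[ok] = _spearman_p_t(rho[ok], n)
    return rho, p


# ---------------------------------------------------------------------------
# classical tests


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, tail: str = "two"
) -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    ``tail="one_greater"`` tests enrichment of the top-left cell (upper
    hypergeometric tail); ``tail="two"`` sums all tables at least as extreme.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("every margin of the 2x2 table must be positive")
    alternative = {"one_greater": "greater", "two": "two-sided"}.get(tail)
    if alternative is None:
        raise ValueError(f"unknown tail {tail!r}")
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return TestResult(
        statistic=float(odds),
        p_value=float(p),
        tail="one" if tail == "one_greater" else "two",
        extra={"table": table.tolist()},
    )


def student_t_two_sample(
    a: Sequence[float], b: Sequence[float], tails: int = 2, welch: bool = False
) -> TestResult:
    """Two-sample Student's t-test, pooled variance by default (Welch by flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not welch and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if tails == 1:
        p = p / 2 if res.statistic > 0 else 1 - p / 2
    elif tails != 2:
        raise ValueError("tails must be 1 or 2")
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        tail="two" if tails == 2 else "one",
        df=float(res.df),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA F test across >= 2 groups."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(g.size < 2 for g in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.var(g, ddof=1) == 0 for g in arrs):
        raise ValueError("zero within-group variance in every group")
    f, p = stats.f_oneway(*arrs)
    k = len(arrs)
    n = sum(g.size for g in arrs)
    return TestResult(statistic=float(f), p_value=float(p), tail="one", df=(k - 1, n - k))


# ---------------------------------------------------------------------------
# multiple testing


def _check_pvals(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = _check_pvals(np.asarray(pvals))
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(
    pvals: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with smoothed pi0 from a lambda grid.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the grid
    (default 0.05..0.95 step 0.05), smoothed with a cubic polynomial and read
    off at the largest lambda, then clipped to (0, 1].  ``pi0=1`` reproduces
    Benjamini-Hochberg exactly.
    """
    p = _check_pvals(np.asarray(pvals))
    m = p.size
    if m == 0:
        return p
    if pi0 is None:
        grid = (
            np.arange(0.05, 0.96, 0.05)
            if lambda_grid is None
            else np.asarray(lambda_grid, dtype=float)
        )
        pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in grid])
        if grid.size >= 4:
            coef = np.polyfit(grid, pi0_l, 3)
            pi0 = float(np.polyval(coef, grid.max()))
        else:
            pi0 = float(pi0_l[-1])
        pi0 = min(1.0, max(pi0, 1.0 / m))  # guard degenerate estimates
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotonicity
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return out


# ---------------------------------------------------------------------------
# permutation machinery


def permutation_null(
    stat_fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    response: np.ndarray,
    data: np.ndarray,
    n_perm: int,
    seed: int,
) -> PermutationNull:
    """Null distribution of per-item statistics under response permutation.

    ``stat_fn(data, response)`` must return one statistic per item (row of
    ``data``).  Permutations are drawn uniformly with replacement — the
    identity permutation is not excluded — so the same machinery is valid for
    any n; when ``n_perm`` exceeds n! this simply resamples, which is logged.
    """
    response = np.asarray(response, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = response.size
    if n <= 20 and n_perm > math.factorial(n):
        logger.info(
            "n_perm=%d exceeds %d distinct permutations; sampling with replacement",
            n_perm,
            math.factorial(n),
        )
    rng = np.random.default_rng(seed)
    observed = np.asarray(stat_fn(data, response), dtype=float)
    null = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        null[b] = stat_fn(data, response[rng.permutation(n)])
    return PermutationNull(observed=observed, null=null, n_perm=n_perm, seed=seed)
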