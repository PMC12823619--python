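"""Statistical kernels shared by the imaging and MALDI pipelines.

Two-sided Mann–Whitney U (exact enumeration for small tie-free samples,
normal approximation with midrank tie correction and continuity
correction otherwise), two-sample t-tests (Student and Welch), and the
up/down-regulated gene-count arithmetic used to summarise differential
expression.

The exact U null distribution is computed with the classical counting
recurrence (the coefficient of q^u in the Gaussian binomial), so exact
p-values agree with brute-force enumeration of all C(n_x+n_y, n_x) rank
arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps


@dataclass
class GroupComparison:
    """Result of a two-group comparison.

    ``method`` records which kernel produced the p-value:
    ``exact`` | ``normal-approx`` | ``t-student`` | ``t-welch``.
    """

    metric: str
    group_a: str
    group_b: str
    statistic: float
    p_two_sided: float
    method: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p outside [0,1]: {self.p_two_sided}")


@dataclass
class DegCounts:
    """Up/down differential-gene counts with integer percentages."""

    comparison: str
    n_up: int
    n_down: int
    total: int
    pct_up: int
    pct_down: int


@lru_cache(maxsize=None)
def _u_null_counts(n_x: int, n_y: int) -> Tuple[int, ...]:
    """Counts of rank arrangements per U value for tie-free samples.

    Recurrence: c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u) — an
    arrangement either ends in an x (which then exceeds all n y's,
    adding n to U) or in a y (adding nothing).
    """
    if n_x == 0 or n_y == 0:
        return (1,)
    shifted = _u_null_counts(n_x - 1, n_y)  # ends in x
    tail = _u_null_counts(n_x, n_y - 1)  # ends in y
    out = [0] * (n_x * n_y + 1)
    for u, c in enumerate(shifted):
        out[u + n_y] += c
    for u, c in enumerate(tail):
        out[u] += c
    return tuple(out)


def exact_mwu_p(u: float, n_x: int, n_y: int) -> float:
    """Two-sided exact p: lower tail of min(U, n_x·n_y − U), doubled, capped."""
    counts = _u_null_counts(n_x, n_y)
    total = sum(counts)
    u_low = min(u, n_x * n_y - u)
    tail = sum(c for uu, c in enumerate(counts) if uu <= u_low)
    return min(1.0, 2.0 * tail / total)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks under ties
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approx"] = "auto",
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test; U is reported for ``x``.

    ``auto`` uses exact enumeration when n_x + n_y <= 20 and the pooled
    sample is tie-free, else the normal approximation with midrank tie
    correction and a 0.5 continuity correction. Ties always force the
    approximate path (the exact null assumes distinct values).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    u = _u_statistic(x, y)

    if mode == "exact" and has_ties:
        raise ValueError("exact mode requires tie-free samples")
    use_exact = mode == "exact" or (
        mode == "auto" and not has_ties and n_x + n_y <= 20
    )

    if use_exact:
        p = exact_mwu_p(u, n_x, n_y)
        method = "exact"
    else:
        n = n_x + n_y
        mu = n_x * n_y / 2.0
        # Tie-corrected null variance.
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts)).sum())
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0 or u == mu:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(var)
            z = max(z, 0.0)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        method = "normal-approx"

    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        statistic=u, p_two_sided=p, method=method, n_a=n_x, n_b=n_y,
    )


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["student", "welch"] = "student",
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided two-sample t-test (pooled-variance Student or Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        statistic=float(res.statistic), p_two_sided=float(res.pvalue),
        method=f"t-{variant}", n_a=x.size, n_b=y.size,
    )


def _round_half_up(value: float) -> int:
    return int(np.floor(value + 0.5))


def summarize_deg_counts(n_up: int, n_down: int, name: str = "") -> DegCounts:
    """Totals and half-up-rounded integer percentages of up/down genes."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be nonnegative")
    total = n_up + n_down
    if total == 0:
        raise ValueError("at least one gene required")
    return DegCounts(
        comparison=name,
        n_up=n_up,
        n_down=n_down,
        total=total,
        pct_up=_round_half_up(100.0 * n_up / total),
        pct_down=_round_half_up(100.0 * n_down / total),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default output)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
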