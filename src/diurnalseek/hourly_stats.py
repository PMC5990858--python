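"""Per-hour ANOVA and the directional Tukey-Kramer significance matrix.

Treating each clock hour as a group and days as replicates, a one-way
ANOVA tests whether any hours differ; the Tukey-Kramer procedure then
makes all 276 pairwise hour comparisons while controlling the familywise
error rate via the studentized range distribution.  The output is the
24x24 directional matrix: entry (i, j) is set when hour i's distribution
is significantly greater than hour j's (adjusted p below alpha AND mean_i
above mean_j) -- the adjusted p itself is two-sided and symmetric.

With equal group sizes (complete days give n = n_days for every hour) the
Kramer unequal-n standard error reduces exactly to classic Tukey HSD.

Implementation note: the significance decision compares the studentized
statistic q against the exact critical value (scipy's studentized_range
ppf, cached per (k, df, alpha)); reported adjusted p-values come from a
cached monotone interpolant of the survival function, accurate to better
than 1e-5, because direct sf evaluation is far too slow for Monte-Carlo
calibration at hundreds of evaluations per matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .diurnal import FoldedDays
from .exceptions import ConfigError, DegenerateDataError

__all__ = ["SignificanceMatrix", "hourly_anova", "tukey_kramer"]


@dataclass
class SignificanceMatrix:
    """Directional hour-vs-hour comparison results.

    ``greater[i, j]`` is True when hour i is significantly greater than
    hour j at level ``alpha`` (never both (i,j) and (j,i)); ``p_adjusted``
    is symmetric with unit diagonal; ``n_by_hour`` gives group sizes.
    """

    greater: np.ndarray
    p_adjusted: np.ndarray
    mean_by_hour: np.ndarray
    alpha: float
    n_by_hour: np.ndarray

    @property
    def n_hours(self) -> int:
        return len(self.mean_by_hour)

    def significant_pairs(self) -> list[tuple[int, int]]:
        """(i, j) pairs with hour i significantly greater than hour j."""
        return [tuple(ij) for ij in np.argwhere(self.greater)]


def _matrix(folded: FoldedDays | np.ndarray) -> np.ndarray:
    """Accept FoldedDays or any replicates x groups array (k need not be 24,
    which keeps the machinery reusable for block-level comparisons)."""
    m = folded.matrix if isinstance(folded, FoldedDays) else np.asarray(folded, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DegenerateDataError(
            f"need a replicates x groups matrix with >= 2 of each, got {m.shape}"
        )
    return m


def _groups(folded: FoldedDays | np.ndarray) -> list[np.ndarray]:
    m = _matrix(folded)
    return [m[:, h] for h in range(m.shape[1])]


def hourly_anova(folded: FoldedDays | np.ndarray) -> tuple[float, float]:
    """One-way ANOVA across the 24 hourly groups (days as replicates).

    Returns (F, p).  F is 0 when all group means coincide; all-equal
    groups with zero within-group variance raise DegenerateDataError
    because the F statistic is undefined there.
    """
    groups = _groups(folded)
    means = np.array([g.mean() for g in groups])
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        if np.allclose(means, means[0]):
            raise DegenerateDataError(
                "zero within-group variance with equal means: F undefined"
            )
        return float("inf"), 0.0
    if np.ptp(means) == 0:
        # no between-group variability at all
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@lru_cache(maxsize=32)
def _q_critical(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


@lru_cache(maxsize=32)
def _sf_interpolant(k: int, df: int) -> PchipInterpolator:
    # sf is smooth and monotone in q; a dense PCHIP fit of log-sf keeps
    # interpolation monotone and accurate to <1e-5 absolute in p
    grid = np.concatenate([np.linspace(1e-3, 8.0, 150), np.linspace(8.1, 25.0, 60)])
    sf = stats.studentized_range.sf(grid, k, df)
    sf = np.clip(sf, 1e-300, 1.0)
    return PchipInterpolator(grid, np.log(sf), extrapolate=True)


def studentized_range_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Fast survival function of the studentized range (cached interpolant)."""
    q = np.asarray(q, dtype=float)
    out = np.exp(_sf_interpolant(k, df)(np.clip(q, 1e-3, 25.0)))
    out[q <= 0] = 1.0
    return np.clip(out, 0.0, 1.0)


def tukey_kramer(
    folded: FoldedDays | np.ndarray, alpha: float = 0.05
) -> SignificanceMatrix:
    """All-pairs hour comparison via the Tukey-Kramer procedure.

    For hours i, j with means m_i, m_j, sizes n_i, n_j and pooled
    within-group variance s2 (df = N - k):

        q_ij = |m_i - m_j| / sqrt(s2/2 * (1/n_i + 1/n_j))

    referred to the studentized range distribution with k groups.
    """
    if not 0 < alpha <= 0.5:
        raise ConfigError(f"alpha must be in (0, 0.5], got {alpha}")
    groups = _groups(folded)
    k = len(groups)
    n = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df = int(n.sum() - k)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        if np.allclose(means, means[0]):
            raise DegenerateDataError(
                "zero within-group variance with equal means: q undefined"
            )
        s2 = 0.0
    else:
        s2 = ssw / df

    diff = means[:, None] - means[None, :]
    se = np.sqrt(s2 / 2.0 * (1.0 / n[:, None] + 1.0 / n[None, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diff) / se
    q[~np.isfinite(q)] = np.inf
    np.fill_diagonal(q, 0.0)

    p = studentized_range_sf(q, k, df)
    p[np.isinf(q)] = 0.0
    np.fill_diagonal(p, 1.0)

    q_crit = _q_critical(alpha, k, df)
    greater = (q > q_crit) & (diff > 0)
    np.fill_diagonal(greater, False)
    return SignificanceMatrix(
        greater=greater,
        p_adjusted=p,
        mean_by_hour=means,
        alpha=alpha,
        n_by_hour=n,
    )
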