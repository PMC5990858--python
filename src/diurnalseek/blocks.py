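"""Trichotomized time-block analysis of raw hourly RSV.

The 24-hour day is partitioned into three 8-hour blocks —

* ``night``:   00:00-07:59 (hours 0-7), unstructured nighttime,
* ``work``:    08:00-15:59 (hours 8-15), structured office hours,
* ``evening``: 16:00-23:59 (hours 16-23), unstructured leisure time —

and the raw hourly values falling into each block are compared by one-way
ANOVA followed by pairwise t-tests on the ANOVA-pooled variance with a
Bonferroni correction (x3, capped at 1).  This runs on raw RSV, not the
band-passed reconstruction: the blocks summarize observed search volume.

By default each hourly value is one observation (n = 8 x days per block);
``unit="day"`` aggregates to daily block means first (n = days per block)
for sensitivity analysis, since hourly values within a day are not
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .exceptions import ConfigError, DataError, DegenerateDataError
from .io_trends import HourlyQuerySeries

__all__ = ["BLOCK_ORDER", "BlockSummary", "assign_block", "block_summaries",
           "block_anova_posthoc"]

# report order follows the diurnal sequence night -> work -> evening
BLOCK_ORDER = ("night", "work", "evening")
_BLOCK_OF_HOUR = {h: "night" for h in range(8)}
_BLOCK_OF_HOUR.update({h: "work" for h in range(8, 16)})
_BLOCK_OF_HOUR.update({h: "evening" for h in range(16, 24)})


def assign_block(hour: int) -> str:
    """Map a clock hour 0-23 to its time block (total partition)."""
    h = int(hour)
    if h != hour or not 0 <= h <= 23:
        raise DataError(f"hour must be an integer in 0-23, got {hour!r}")
    return _BLOCK_OF_HOUR[h]


@dataclass
class PairComparison:
    block_a: str
    block_b: str
    mean_diff: float
    p_raw: float
    p_bonferroni: float


@dataclass
class BlockSummary:
    """Per-block descriptives plus (optionally) omnibus and post-hoc tests."""

    term: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    comparisons: list[PairComparison] = field(default_factory=list)
    f_statistic: float | None = None
    p_omnibus: float | None = None
    alpha: float = 0.05
    unit: str = "hour"

    def comparison(self, a: str, b: str) -> PairComparison:
        for c in self.comparisons:
            if {c.block_a, c.block_b} == {a, b}:
                return c
        raise KeyError(f"no comparison between {a!r} and {b!r}")


def _block_values(series: HourlyQuerySeries, unit: str) -> dict[str, np.ndarray]:
    hours = series.hours_of_day()
    out = {
        b: series.values[np.isin(hours, np.arange(8 * i, 8 * i + 8))]
        for i, b in enumerate(BLOCK_ORDER)
    }
    if unit == "day":
        out = {
            b: v[: len(v) - len(v) % 8].reshape(-1, 8).mean(axis=1)
            for b, v in out.items()
        }
    elif unit != "hour":
        raise ConfigError(f"unit must be 'hour' or 'day', got {unit!r}")
    return out


def block_summaries(series: HourlyQuerySeries, unit: str = "hour") -> BlockSummary:
    """Mean and sample SD of RSV per time block (no tests)."""
    vals = _block_values(series, unit)
    return BlockSummary(
        term=series.term,
        n={b: len(v) for b, v in vals.items()},
        mean={b: float(v.mean()) for b, v in vals.items()},
        sd={b: float(v.std(ddof=1)) if len(v) > 1 else 0.0
            for b, v in vals.items()},
        unit=unit,
    )


def block_anova_posthoc(
    series: HourlyQuerySeries,
    alpha: float = 0.05,
    unit: str = "hour",
) -> BlockSummary:
    """Omnibus ANOVA over the 3 blocks plus Bonferroni-corrected post-hocs.

    Pairwise comparisons are two-sided t-tests using the ANOVA-pooled
    variance (MSE on N-3 df, SPSS-style post hoc); each raw p is
    multiplied by 3 and capped at 1.
    """
    if not 0 < alpha <= 0.5:
        raise ConfigError(f"alpha must be in (0, 0.5], got {alpha}")
    summary = block_summaries(series, unit)
    summary.alpha = alpha
    vals = _block_values(series, unit)
    groups = [vals[b] for b in BLOCK_ORDER]
    if any(len(g) < 2 for g in groups):
        raise DataError("each block needs at least 2 observations")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0 and np.ptp([g.mean() for g in groups]) == 0:
        raise DegenerateDataError(
            "zero within-block variance with equal means: F undefined"
        )
    f, p = stats.f_oneway(*groups)
    summary.f_statistic, summary.p_omnibus = float(f), float(p)

    df = sum(len(g) for g in groups) - len(groups)
    mse = ssw / df
    for a, b in combinations(BLOCK_ORDER, 2):
        ga, gb = vals[a], vals[b]
        diff = float(ga.mean() - gb.mean())
        se = np.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
        if se == 0:
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p_raw = float(2 * stats.t.sf(abs(t), df))
        summary.comparisons.append(
            PairComparison(a, b, diff, p_raw, min(1.0, 3 * p_raw))
        )
    return summary
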