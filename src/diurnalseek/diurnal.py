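"""Folding hourly series into 24-hour cycles and mean diurnal profiles.

The effect-size measure throughout is the peak-trough difference of the
24-point mean profile, in percentage points (pp) of the 0-100 normalized
RSV scale.  Hour *h* labels the clock window [h:00, h+1:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .io_trends import HourlyQuerySeries

__all__ = ["FoldedDays", "DiurnalProfile", "fold_days", "mean_profile"]


@dataclass
class FoldedDays:
    """Days x 24 matrix: row d, column h holds the value at day d, hour h."""

    matrix: np.ndarray
    day_labels: list[str] = field(default_factory=list)
    hour_labels: np.ndarray = field(default_factory=lambda: np.arange(24))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 24:
            raise DataError(f"folded matrix must be days x 24, got {self.matrix.shape}")

    @property
    def n_days(self) -> int:
        return self.matrix.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major (day by day) flattening; inverse of fold_days."""
        return self.matrix.ravel()


@dataclass
class DiurnalProfile:
    """24 per-hour means with peak/trough location and pp difference.

    ``pp_difference = mean_by_hour[peak_hour] - mean_by_hour[trough_hour]``;
    ties at flat extrema break to the earliest hour.
    """

    mean_by_hour: np.ndarray
    peak_hour: int
    trough_hour: int
    pp_difference: float

    @classmethod
    def from_means(cls, mean_by_hour: np.ndarray) -> "DiurnalProfile":
        m = np.asarray(mean_by_hour, dtype=float)
        if m.shape != (24,):
            raise DataError(f"profile needs exactly 24 hourly means, got {m.shape}")
        peak = int(np.argmax(m))    # argmax/argmin take the earliest tie
        trough = int(np.argmin(m))
        return cls(m, peak, trough, float(m[peak] - m[trough]))


def fold_days(series: HourlyQuerySeries) -> FoldedDays:
    """Reshape an hourly series into complete 24-hour days.

    Leading/trailing partial days are trimmed (so the first retained sample
    falls on hour 0); at least 2 complete days must remain.  The reshaping
    is lossless on the retained samples: ``fold_days(s).flatten()``
    reproduces them exactly.
    """
    hours = series.hours_of_day()
    start = int(np.argmax(hours == 0)) if (hours == 0).any() else len(hours)
    n_rest = len(hours) - start
    n_days = n_rest // 24
    if n_days < 2:
        raise DataError(
            f"term {series.term!r}: {n_days} complete day(s) after trimming; "
            "need at least 2"
        )
    vals = series.values[start : start + n_days * 24]
    days = [str(series.timestamps[start + 24 * d])[:10] for d in range(n_days)]
    return FoldedDays(vals.reshape(n_days, 24), day_labels=days)


def mean_profile(folded: FoldedDays) -> DiurnalProfile:
    """Arithmetic mean over days for each hour, with peak-trough summary."""
    if folded.n_days < 2:
        raise DataError("mean profile needs at least 2 days")
    return DiurnalProfile.from_means(folded.matrix.mean(axis=0))
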