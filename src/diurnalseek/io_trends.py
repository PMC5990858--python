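"""Reading, validating, stitching and writing hourly RSV time series.

The on-disk dialect mirrors Google Trends hourly CSV exports: a UTF-8 file
with a header row, an ISO-8601-like hourly timestamp column first
(``YYYY-MM-DDTHH`` and full ISO both accepted) and one column per query
term holding integer relative search volume (RSV) in [0, 100], with ``<1``
standing for a suppressed small value.  Reconstructed (band-passed) series
are written in the same dialect with 4 decimal places and a
``#reconstructed=true`` comment line so round-trips preserve the flag.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateTimestampError,
    GapError,
    ParseError,
    SpacingError,
    ValidationError,
)

HOUR = np.timedelta64(1, "h")

__all__ = [
    "HourlyQuerySeries",
    "StitchReport",
    "read_trends_csv",
    "write_trends_csv",
    "stitch_weekly",
    "validate_series",
]


@dataclass
class HourlyQuerySeries:
    """One query term's uniformly hourly RSV time series.

    Parameters
    ----------
    term : str
        Query string label.
    timestamps : numpy.ndarray of datetime64[h]
        Strictly increasing hourly instants (local clock labels).  The grid
        is treated as abstract and uniform; no time-zone or DST arithmetic
        is performed.
    values : numpy.ndarray of float
        RSV per hour.  Raw series hold integers in [0, 100]; reconstructed
        series hold finite reals and may be negative (deviations from the
        series mean unless the mean was restored).
    is_reconstructed : bool
        Distinguishes raw RSV from a band-passed reconstruction.
    """

    term: str
    timestamps: np.ndarray
    values: np.ndarray
    is_reconstructed: bool = False

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[h]")
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape or self.timestamps.ndim != 1:
            raise ValidationError(
                f"term {self.term!r}: timestamps and values must be 1-D and equal "
                f"length, got {self.timestamps.shape} vs {self.values.shape}"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start_hour(self) -> int:
        """Clock hour (0-23) of the first sample."""
        return int(self.timestamps[0].astype("datetime64[h]").astype(int) % 24)

    def hours_of_day(self) -> np.ndarray:
        """Clock hour 0-23 for every sample."""
        return self.timestamps.astype(int) % 24

    def check_uniform(self) -> None:
        """Raise SpacingError unless timestamps form a 1-hour grid."""
        diffs = np.diff(self.timestamps)
        bad = np.nonzero(diffs != HOUR)[0]
        if bad.size:
            locs = ", ".join(str(self.timestamps[i]) for i in bad[:5])
            raise SpacingError(
                f"term {self.term!r}: non-hourly spacing after {bad.size} "
                f"timestamp(s), first at {locs}"
            )

    def check_raw_range(self) -> None:
        if self.is_reconstructed:
            return
        bad = (self.values < 0) | (self.values > 100) | ~np.isfinite(self.values)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValidationError(
                f"term {self.term!r}: RSV value {self.values[i]} at "
                f"{self.timestamps[i]} outside [0, 100]"
            )


@dataclass
class StitchReport:
    """Provenance record for a multi-segment stitch.

    ``rescale_factors`` holds one strictly positive factor per input
    segment; ``overlap_hours`` one entry per junction; ``conflicts`` counts
    overlapping hours whose rescaled values disagree beyond tolerance.
    """

    segments_in: int
    overlap_hours: list[int] = field(default_factory=list)
    rescale_factors: list[float] = field(default_factory=list)
    conflicts: int = 0
    warnings: list[str] = field(default_factory=list)


def _parse_timestamp_column(raw: pd.Series) -> np.ndarray:
    out = np.empty(len(raw), dtype="datetime64[h]")
    for i, cell in enumerate(raw):
        try:
            out[i] = np.datetime64(str(cell).strip(), "h")
        except ValueError as exc:
            raise ParseError(
                f"row {i + 2}: malformed timestamp {cell!r}"
            ) from exc
    return out


def _parse_value(cell, term: str, row: int) -> float:
    s = str(cell).strip()
    if s == "<1":
        # Google Trends suppresses small proportions; convention maps to 0.
        return 0.0
    try:
        v = float(s)
    except ValueError as exc:
        raise ParseError(f"row {row}: unparseable value {cell!r} for {term!r}") from exc
    return v


def read_trends_csv(path) -> list[HourlyQuerySeries]:
    """Read a Google-Trends-style hourly CSV into one series per term column.

    Lines starting with ``#`` are treated as comments; a
    ``#reconstructed=true`` line marks every series in the file as
    reconstructed (real-valued, range-unchecked).
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    reconstructed = any(
        line.strip().lower().replace(" ", "") == "#reconstructed=true"
        for line in text.splitlines()
        if line.startswith("#")
    )
    df = pd.read_csv(io.StringIO(text), comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a timestamp column plus >=1 term column")
    ts = _parse_timestamp_column(df.iloc[:, 0])

    out: list[HourlyQuerySeries] = []
    for col in df.columns[1:]:
        vals = np.array(
            [_parse_value(c, col, i + 2) for i, c in enumerate(df[col])], dtype=float
        )
        s = HourlyQuerySeries(term=col, timestamps=ts.copy(), values=vals,
                              is_reconstructed=reconstructed)
        if not reconstructed:
            s.check_raw_range()
            frac = np.modf(s.values)[0]
            if np.any(frac != 0):
                i = int(np.argmax(frac != 0))
                raise ValidationError(
                    f"term {col!r}: raw RSV must be integer, got "
                    f"{s.values[i]} at row {i + 2}"
                )
        s.check_uniform()
        out.append(s)
    return out


def write_trends_csv(path, series_list: list[HourlyQuerySeries]) -> None:
    """Write series sharing one timestamp grid back to the CSV dialect."""
    first = series_list[0]
    for s in series_list[1:]:
        if not np.array_equal(s.timestamps, first.timestamps):
            raise ValidationError("all series in one file must share timestamps")
    reconstructed = any(s.is_reconstructed for s in series_list)
    df = pd.DataFrame({"time": [str(t) for t in first.timestamps]})
    for s in series_list:
        if reconstructed:
            df[s.term] = [f"{v:.4f}" for v in s.values]
        else:
            df[s.term] = s.values.astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        if reconstructed:
            fh.write("#reconstructed=true\n")
        df.to_csv(fh, index=False)


def validate_series(series: HourlyQuerySeries, max_gap: int = 2) -> HourlyQuerySeries:
    """Return a series on a gap-free hourly grid.

    Gaps of at most ``max_gap`` missing hours are filled by linear
    interpolation (a warning is emitted per repair); anything larger
    raises GapError.  Duplicate timestamps raise DuplicateTimestampError.
    """
    ts, vals = series.timestamps, series.values
    if len(np.unique(ts)) != len(ts):
        dup = ts[np.nonzero(np.diff(np.sort(ts).astype(int)) == 0)[0][0]]
        raise DuplicateTimestampError(
            f"term {series.term!r}: duplicate timestamp {dup}"
        )
    order = np.argsort(ts)
    ts, vals = ts[order], vals[order]
    steps = np.diff(ts) / HOUR
    if np.all(steps == 1):
        return HourlyQuerySeries(series.term, ts, vals, series.is_reconstructed)
    missing = steps - 1
    worst = int(missing.max())
    if worst > max_gap:
        i = int(np.argmax(missing))
        raise GapError(
            f"term {series.term!r}: gap of {worst} missing hour(s) after "
            f"{ts[i]} exceeds max_gap={max_gap}"
        )
    full = np.arange(ts[0], ts[-1] + HOUR, HOUR)
    have = np.isin(full, ts)
    out = np.empty(len(full))
    out[have] = vals
    grid = full.astype(int).astype(float)
    out[~have] = np.interp(grid[~have], grid[have], vals)
    n_filled = int((~have).sum())
    warnings.warn(
        f"term {series.term!r}: interpolated {n_filled} missing hour(s)",
        stacklevel=2,
    )
    return HourlyQuerySeries(series.term, full, out, series.is_reconstructed)


def stitch_weekly(
    segments: list[HourlyQuerySeries],
    tolerance: float = 1.0,
) -> tuple[HourlyQuerySeries, StitchReport]:
    """Merge overlapping (or exactly abutting) downloads of one term.

    Each Google Trends export is internally consistent but carries its own
    0-100 normalization, so consecutive segments are brought onto a common
    relative scale by the ratio of means over their overlap, concatenated
    (the earlier segment wins on overlapping hours), and the result is
    renormalized so its maximum is exactly 100.  RSV being relative, the
    output is invariant to scaling any input segment by a positive constant.

    Abutting segments (gap of 0 hours, no overlap) cannot be cross-scaled;
    they are each max-normalized to 100 before concatenation and a warning
    is recorded in the report.  A gap raises GapError, as does an overlap
    whose mean is zero (no scale information).
    """
    if not segments:
        raise GapError("stitch_weekly needs at least one segment")
    term = segments[0].term
    for s in segments:
        if s.term != term:
            raise ValidationError(f"mixed terms in stitch: {s.term!r} vs {term!r}")
        s.check_uniform()
    segs = sorted(segments, key=lambda s: s.timestamps[0])
    report = StitchReport(segments_in=len(segs))

    any_abut = False
    for a, b in zip(segs, segs[1:]):
        if b.timestamps[0] > a.timestamps[-1] + HOUR:
            gap = int((b.timestamps[0] - a.timestamps[-1]) / HOUR) - 1
            raise GapError(
                f"term {term!r}: {gap} hour gap between segments at "
                f"{a.timestamps[-1]}"
            )
        if b.timestamps[0] == a.timestamps[-1] + HOUR:
            any_abut = True

    if any_abut:
        # No overlap information anywhere consistent; fall back to
        # per-segment max normalization.
        report.warnings.append(
            "abutting segments without overlap: per-segment max normalization"
        )
        scaled = []
        for s in segs:
            m = s.values.max()
            f = 100.0 / m if m > 0 else 1.0
            report.rescale_factors.append(f)
            scaled.append(s.values * f)
            report.overlap_hours.append(0)
        report.overlap_hours.pop()  # one junction fewer than segments
        ts = np.concatenate([s.timestamps for s in segs])
        vals = np.concatenate(scaled)
        keep = np.concatenate(([True], np.diff(ts) > np.timedelta64(0, "h")))
        merged = HourlyQuerySeries(term, ts[keep], vals[keep])
    else:
        # factor for segment k+1 chains through the k-th junction: ratio of
        # (already-rescaled) earlier means to later means on the overlap

        cum = [1.0]
        for a, b in zip(segs, segs[1:]):
            lo = max(a.timestamps[0], b.timestamps[0])
            hi = min(a.timestamps[-1], b.timestamps[-1])
            ov = np.arange(lo, hi + HOUR, HOUR)
            report.overlap_hours.append(len(ov))
            a_ov = a.values[np.isin(a.timestamps, ov)] * cum[-1]
            b_ov = b.values[np.isin(b.timestamps, ov)]
            if b_ov.mean() == 0 or a_ov.mean() == 0:
                raise GapError(
                    f"term {term!r}: overlap mean of zero at junction {lo}; "
                    "cannot rescale"
                )
            cum.append(a_ov.mean() / b_ov.mean())
        report.rescale_factors = cum
        # earlier segment wins on overlapping hours
        seen: dict[int, float] = {}
        for s, f in zip(segs, cum):
            rescaled = s.values * f
            for t, v in zip(s.timestamps.astype(int), rescaled):
                if t in seen:
                    if abs(seen[t] - v) > tolerance:
                        report.conflicts += 1
                else:
                    seen[t] = v
        ts = np.array(sorted(seen), dtype="int64").astype("datetime64[h]")
        vals = np.array([seen[int(t.astype(int))] for t in ts])
        merged = HourlyQuerySeries(term, ts, vals)

    merged.check_uniform()
    peak = merged.values.max()
    if peak <= 0:
        raise GapError(f"term {term!r}: stitched series has no positive values")
    merged.values = merged.values * (100.0 / peak)
    return merged, report
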