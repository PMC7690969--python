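"""Gap-free daily time series, tallies, alignment and variance stabilization.

The analysis works on counts per calendar day. :class:`DailySeries` is the
common container: a start date plus one non-negative value per consecutive
day, with no gaps. Helpers build rumor count series, compute category
shares at display precision, log-transform for variance stabilization, and
trim two series to their common date range before correlation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .labels import EMOTIONS, Emotion, as_emotion


@dataclass(frozen=True)
class DailySeries:
    """A gap-free, date-indexed vector of non-negative daily values.

    Parameters
    ----------
    start_date
        Calendar date of the first value.
    values
        One value per consecutive day; non-negative and finite.
    """

    start_date: dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("a daily series needs at least 2 consecutive days")
        if not np.all(np.isfinite(vals)):
            raise ValueError("daily series values must be finite")
        if np.any(vals < 0):
            raise ValueError("daily series values must be non-negative")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=len(self) - 1)

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(len(self))]

    def to_pandas(self) -> pd.Series:
        idx = pd.date_range(self.start_date, periods=len(self), freq="D")
        return pd.Series(self.values, index=idx)

    @classmethod
    def from_pandas(cls, s: pd.Series) -> "DailySeries":
        idx = pd.DatetimeIndex(s.index)
        if not idx.is_monotonic_increasing:
            s = s.sort_index()
            idx = pd.DatetimeIndex(s.index)
        full = pd.date_range(idx[0], idx[-1], freq="D")
        if len(full) != len(idx) or not (full == idx).all():
            raise AlignmentError("series index has date gaps or duplicates")
        return cls(idx[0].date(), s.to_numpy(dtype=float))

    def slice_window(self, start: dt.date, end: dt.date) -> "DailySeries":
        """Return the sub-series covering ``start..end`` (inclusive)."""
        i0 = (start - self.start_date).days
        i1 = (end - self.start_date).days + 1
        if i0 < 0 or i1 > len(self):
            raise AlignmentError(
                f"window {start}..{end} not covered by series "
                f"{self.start_date}..{self.end_date}"
            )
        return DailySeries(start, self.values[i0:i1])


def align(
    a: DailySeries, b: DailySeries, min_overlap: int = 2
) -> tuple[DailySeries, DailySeries]:
    """Trim two daily series to their common consecutive date range.

    Raises :class:`AlignmentError` when the overlap is shorter than
    ``min_overlap`` days (a lag scan out to lag K needs ``2*K + 3``).
    """
    start = max(a.start_date, b.start_date)
    end = min(a.end_date, b.end_date)
    n = (end - start).days + 1
    if n < max(2, min_overlap):
        raise AlignmentError(
            f"series overlap {max(n, 0)} days ({start}..{end}); "
            f"at least {max(2, min_overlap)} required"
        )
    return a.slice_window(start, end), b.slice_window(start, end)


def log_stabilize(series: DailySeries) -> DailySeries:
    """Natural log of (value + 1), elementwise.

    Daily counts are roughly exponentially distributed over the epidemic
    window; the log transform stabilizes the variance before correlation.
    The +1 offset keeps zero-count days defined and maps them to 0, and
    Pearson correlations downstream are invariant to the log base.
    """
    return DailySeries(series.start_date, np.log1p(series.values))


# ---------------------------------------------------------------------------
# Category tallies


@dataclass(frozen=True)
class CategoryTally:
    """Counts per category with shares at a fixed display precision."""

    counts: dict[str, int]
    total: int
    shares: dict[str, float] = field(default=None)  # type: ignore[assignment]
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("tally total must be positive")
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts must sum to the total")
        if self.shares is None:
            shares = {
                k: round_half_up(100.0 * v / self.total, self.decimals)
                for k, v in self.counts.items()
            }
            object.__setattr__(self, "shares", shares)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up at ``decimals`` places (display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def category_shares(counts: Mapping[object, int], decimals: int = 1) -> CategoryTally:
    """Percentage share of each category: 100 x count / total.

    Shares are rounded half-up at ``decimals`` places — the display
    convention for published proportions (1 dp for rumor categories,
    2 dp for comment emotion categories).
    """
    clean = {str(k): int(v) for k, v in counts.items()}
    if any(v < 0 for v in clean.values()):
        raise ValueError("category counts must be non-negative")
    total = sum(clean.values())
    if total == 0:
        raise ValueError("cannot compute shares of an empty tally")
    return CategoryTally(counts=clean, total=total, decimals=decimals)


# ---------------------------------------------------------------------------
# Rumor series


@dataclass(frozen=True)
class RumorSeries:
    """Daily rumor counts: total plus one series per emotion tag."""

    total: DailySeries
    by_tag: dict[Emotion, DailySeries]
    n_excluded: int  # rumors dated outside the requested window

    def tally(self) -> CategoryTally:
        counts = {tag.value: int(s.values.sum()) for tag, s in self.by_tag.items()}
        return category_shares(counts, decimals=1)


def rumor_series(
    rumors: Iterable[tuple[dt.date, "str | Emotion"]] | pd.DataFrame,
    window: tuple[dt.date, dt.date],
) -> RumorSeries:
    """Count rumors per day, in total and per emotion tag.

    ``rumors`` is an iterable of ``(date, tag)`` pairs or a DataFrame with
    ``date`` and ``emotion_tag`` columns. Days with no rumors count as 0;
    rumors dated outside ``window`` are excluded and tallied in
    ``n_excluded``.
    """
    start, end = window
    n = (end - start).days + 1
    if n < 2:
        raise AlignmentError("window must span at least 2 days")

    if isinstance(rumors, pd.DataFrame):
        pairs = [
            (pd.Timestamp(row.date).date(), row.emotion_tag)
            for row in rumors.itertuples(index=False)
        ]
    else:
        pairs = [(d, t) for d, t in rumors]

    per_tag = {lab: np.zeros(n) for lab in EMOTIONS}
    excluded = 0
    for date, tag in pairs:
        i = (date - start).days
        if 0 <= i < n:
            per_tag[as_emotion(tag)][i] += 1
        else:
            excluded += 1

    by_tag = {lab: DailySeries(start, v) for lab, v in per_tag.items()}
    total = DailySeries(start, np.sum([v.values for v in by_tag.values()], axis=0))
    return RumorSeries(total=total, by_tag=by_tag, n_excluded=excluded)
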