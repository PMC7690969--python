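"""Correction of case counts across a diagnosis-criteria change.

When a region switches from counting only nucleic-acid-confirmed cases to
also counting clinically diagnosed ones, the reported daily series shows a
one-off spike (the accumulated clinical backlog is cleared over about two
days) and the pre-change segment systematically understates incidence.
The correction estimates the clinical-to-nucleic ratio from the first days
after the backlog clears, and scales each pre-change day's nucleic-acid
count by (1 + mean ratio). Days on or after the change date pass through
as reported.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, UndefinedRatioError
from .timeseries import DailySeries


@dataclass(frozen=True)
class DailyCaseRecord:
    """One region-day of reported case counts."""

    date: dt.date
    region: str
    nucleic_count: float
    clinical_count: float
    reported_total: float

    def __post_init__(self) -> None:
        if min(self.nucleic_count, self.clinical_count, self.reported_total) < 0:
            raise ValueError(f"negative case count on {self.date}")


@dataclass(frozen=True)
class CalibrationResult:
    """Clinical/nucleic ratios, the (1 + mean) multiplier, corrected series."""

    ratio_by_day: dict[dt.date, float]
    mean_ratio: float
    multiplier: float
    calibrated_series: DailySeries
    change_date: dt.date


def diagnosis_ratio(clinical_count: float, nucleic_count: float) -> float:
    """Ratio of clinically diagnosed to nucleic-acid-confirmed cases.

    Returned unrounded; rounding to 2 decimals is a display concern.
    """
    if nucleic_count <= 0:
        raise UndefinedRatioError(
            "clinical/nucleic ratio undefined with zero nucleic-acid cases"
        )
    return clinical_count / nucleic_count


def calibration_multiplier(post_change_ratios: Sequence[float]) -> float:
    """1 + arithmetic mean of the post-change clinical/nucleic ratios.

    The mean is taken over the unrounded ratios; rounding each ratio before
    averaging would discard information for no reason.
    """
    ratios = np.asarray(list(post_change_ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("at least one post-change ratio is required")
    if np.any(ratios < 0):
        raise ValueError("ratios must be non-negative")
    return 1.0 + float(ratios.mean())


def _records_from_frame(cases: pd.DataFrame) -> list[DailyCaseRecord]:
    recs = []
    for row in cases.itertuples(index=False):
        recs.append(
            DailyCaseRecord(
                date=pd.Timestamp(row.date).date(),
                region=str(getattr(row, "region", "all")),
                nucleic_count=float(row.nucleic_count),
                clinical_count=float(row.clinical_count),
                reported_total=float(row.reported_total),
            )
        )
    return recs


def calibrate_series(
    cases: "Sequence[DailyCaseRecord] | pd.DataFrame",
    change_date: dt.date,
    ratio_dates: Sequence[dt.date],
    integer_output: bool = False,
) -> CalibrationResult:
    """Correct a daily case series across the diagnosis-criteria change.

    Parameters
    ----------
    cases
        One record per consecutive day for a single region.
    change_date
        First date whose reporting already includes clinical diagnoses at
        the steady ratio (the day after the backlog has cleared). Days
        strictly before it are scaled; days on/after pass through.
    ratio_dates
        Days (on/after ``change_date``) whose clinical/nucleic ratios are
        averaged into the multiplier.
    integer_output
        Round calibrated values half-to-even to integers. Off by default:
        downstream correlation works on reals.
    """
    if isinstance(cases, pd.DataFrame):
        records = _records_from_frame(cases)
    else:
        records = list(cases)
    records.sort(key=lambda r: r.date)
    dates = [r.date for r in records]
    if len(dates) < 2:
        raise AlignmentError("need at least 2 days of case records")
    expected = [dates[0] + dt.timedelta(days=i) for i in range(len(dates))]
    if dates != expected:
        raise AlignmentError("case records must cover consecutive dates without gaps")

    by_date = {r.date: r for r in records}
    ratio_by_day: dict[dt.date, float] = {}
    for d in ratio_dates:
        if d < change_date:
            raise ValueError(f"ratio date {d} precedes the change date {change_date}")
        if d not in by_date:
            raise AlignmentError(f"ratio date {d} missing from the case records")
        ratio_by_day[d] = diagnosis_ratio(
            by_date[d].clinical_count, by_date[d].nucleic_count
        )
    multiplier = calibration_multiplier(list(ratio_by_day.values()))
    mean_ratio = multiplier - 1.0

    calibrated = np.array(
        [
            r.nucleic_count * multiplier if r.date < change_date else r.reported_total
            for r in records
        ]
    )
    if integer_output:
        calibrated = np.round(calibrated)  # numpy rounds half to even
    return CalibrationResult(
        ratio_by_day=ratio_by_day,
        mean_ratio=mean_ratio,
        multiplier=multiplier,
        calibrated_series=DailySeries(dates[0], calibrated),
        change_date=change_date,
    )
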