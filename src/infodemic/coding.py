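"""Consensus emotion coding and interrater reliability.

Every comment is labelled independently by at least three trained coders;
the final category is the strict plurality of their labels. Items with no
strict plurality (ties) get an explicit unresolved marker rather than an
arbitrarily imposed category, and are excluded from the per-day emotion
series but tracked in a residual tally, so category shares are never
biased by an invented tie-breaking order.

Reliability is quantified with Fleiss' kappa over the five categories:

    Po = mean over items of the pairwise rater agreement,
    Pe = sum over categories of the squared marginal proportion,
    kappa = (Po - Pe) / (1 - Pe),

interpreted on the conventional Landis-Koch bands (0.61-0.80 is
"substantial").
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateAgreementError, ProtocolViolationError
from .labels import (
    EMOTIONS,
    LABEL_CODES,
    N_CATEGORIES,
    UNRESOLVED,
    Emotion,
    _UnresolvedType,
    as_emotion,
)
from .timeseries import DailySeries

#: Landis-Koch interpretation bands for chance-corrected agreement.
KAPPA_BANDS: tuple[tuple[float, str], ...] = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)

MIN_CODERS = 3


@dataclass(frozen=True)
class CodedComment:
    """A dated comment with its coder labels and consensus category."""

    comment_id: str
    date: dt.date
    coder_labels: tuple[Emotion, ...]
    consensus: "Emotion | _UnresolvedType"

    def __post_init__(self) -> None:
        if len(self.coder_labels) < MIN_CODERS:
            raise ProtocolViolationError(
                f"comment {self.comment_id}: {len(self.coder_labels)} coder labels; "
                f"protocol requires at least {MIN_CODERS}"
            )


@dataclass(frozen=True)
class KappaResult:
    """Fleiss' kappa with its provenance and interpretation band."""

    kappa: float
    n_items: int
    n_raters: int
    interpretation: str


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value to its conventional interpretation band."""
    if kappa < 0:
        return "poor"
    for upper, name in KAPPA_BANDS[1:]:
        if kappa <= upper:
            return name
    return "almost perfect"


def consensus_label(coder_labels: Sequence["str | Emotion"]) -> "Emotion | _UnresolvedType":
    """Strict-plurality consensus of one comment's coder labels.

    Returns the single most frequent label, or :data:`UNRESOLVED` when two
    or more labels tie for the top count. Order of coders is irrelevant.
    """
    labels = [as_emotion(lab) for lab in coder_labels]
    if len(labels) < MIN_CODERS:
        raise ProtocolViolationError(
            f"{len(labels)} coder labels supplied; protocol requires at least {MIN_CODERS}"
        )
    counts = Counter(labels).most_common()
    if len(counts) > 1 and counts[0][1] == counts[1][1]:
        return UNRESOLVED
    return counts[0][0]


def consensus_codes(label_codes: np.ndarray) -> np.ndarray:
    """Vectorized strict-plurality consensus over an items x raters code matrix.

    ``label_codes`` holds integer category codes (canonical order). Returns
    one code per item, with -1 marking unresolved ties. Agrees with
    :func:`consensus_label` item by item.
    """
    codes = np.asarray(label_codes)
    if codes.ndim != 2 or codes.shape[1] < MIN_CODERS:
        raise ProtocolViolationError(
            f"label matrix must be items x raters with >= {MIN_CODERS} raters"
        )
    n_items = codes.shape[0]
    # per-item category counts via bincount on offset codes
    offsets = np.arange(n_items)[:, None] * N_CATEGORIES
    flat = (codes + offsets).ravel()
    table = np.bincount(flat, minlength=n_items * N_CATEGORIES).reshape(
        n_items, N_CATEGORIES
    )
    top = table.max(axis=1)
    winners = table.argmax(axis=1)
    tied = (table == top[:, None]).sum(axis=1) > 1
    winners[tied] = -1
    return winners


def add_consensus(comments: pd.DataFrame) -> pd.DataFrame:
    """Append a ``consensus`` column to a comments table.

    The table carries one ``coder_*`` column per coder (as produced by the
    synthetic generator or read from ``comments.csv``). Unresolved items get
    the string ``"unresolved"``.
    """
    coder_cols = [c for c in comments.columns if c.startswith("coder_")]
    if len(coder_cols) < MIN_CODERS:
        raise ProtocolViolationError(
            f"comments table has {len(coder_cols)} coder columns; need >= {MIN_CODERS}"
        )
    code_of = {lab.value: code for lab, code in LABEL_CODES.items()}
    codes = np.column_stack(
        [comments[c].map(code_of).to_numpy(dtype=np.int64) for c in coder_cols]
    )
    winners = consensus_codes(codes)
    names = np.array([lab.value for lab in EMOTIONS] + ["unresolved"])
    out = comments.copy()
    out["consensus"] = names[winners]  # -1 indexes the trailing "unresolved"
    return out


def interrater_kappa(label_matrix: Sequence[Sequence["str | Emotion"]] | np.ndarray) -> KappaResult:
    """Fleiss' kappa for an items x raters matrix of emotion labels.

    Every item must carry the same number of raters (>= 2); a pipeline with
    per-item rater counts varying should first subsample each item to the
    minimum common count (see :func:`subsample_raters`). When every rating
    in the whole matrix falls in one category, chance agreement Pe is 1 and
    kappa is undefined: a :class:`DegenerateAgreementError` is raised rather
    than letting NaN propagate.
    """
    rows = [[as_emotion(lab) for lab in row] for row in np.asarray(label_matrix, dtype=object)]
    n_items = len(rows)
    if n_items < 2:
        raise ProtocolViolationError("kappa needs at least 2 items")
    n_raters = len(rows[0])
    if n_raters < 2 or any(len(r) != n_raters for r in rows):
        raise ProtocolViolationError("kappa needs a constant rater count >= 2 per item")

    table = np.zeros((n_items, N_CATEGORIES), dtype=np.int64)
    for i, row in enumerate(rows):
        for lab in row:
            table[i, LABEL_CODES[lab]] += 1
    return _fleiss_from_table(table, n_raters)


def _fleiss_from_table(table: np.ndarray, n_raters: int) -> KappaResult:
    n_items = table.shape[0]
    pairs = (table * (table - 1)).sum(axis=1) / (n_raters * (n_raters - 1))
    p_o = pairs.mean()
    marginals = table.sum(axis=0) / (n_items * n_raters)
    p_e = float((marginals**2).sum())
    if p_e >= 1.0:
        raise DegenerateAgreementError(
            "all ratings fall in a single category; chance agreement is 1 "
            "and kappa is undefined"
        )
    kappa = float((p_o - p_e) / (1.0 - p_e))
    return KappaResult(
        kappa=kappa,
        n_items=n_items,
        n_raters=n_raters,
        interpretation=interpret_kappa(kappa),
    )


def kappa_from_codes(codes: np.ndarray) -> KappaResult:
    """Fleiss' kappa from an integer code matrix (fast path for big tables)."""
    codes = np.asarray(codes)
    n_items, n_raters = codes.shape
    if n_items < 2 or n_raters < 2:
        raise ProtocolViolationError("kappa needs >= 2 items and >= 2 raters")
    offsets = np.arange(n_items)[:, None] * N_CATEGORIES
    table = np.bincount(
        (codes + offsets).ravel(), minlength=n_items * N_CATEGORIES
    ).reshape(n_items, N_CATEGORIES)
    return _fleiss_from_table(table, n_raters)


def subsample_raters(rows: Iterable[Sequence["str | Emotion"]]) -> np.ndarray:
    """Trim variable-length rater lists to the minimum common count.

    The protocol guarantees at least three coders but allows more on some
    items; Fleiss' kappa needs a constant count, so each item keeps its
    first k labels in stored order (deterministic, no resampling).
    """
    rows = [list(r) for r in rows]
    if not rows:
        raise ProtocolViolationError("no items supplied")
    k = min(len(r) for r in rows)
    if k < 2:
        raise ProtocolViolationError("minimum common rater count must be >= 2")
    return np.asarray([r[:k] for r in rows], dtype=object)


@dataclass(frozen=True)
class EmotionDailyCounts:
    """Per-day consensus counts: one series per category plus the residual."""

    by_label: dict[Emotion, DailySeries]
    unresolved: DailySeries

    def total(self) -> DailySeries:
        start = self.unresolved.start_date
        vals = self.unresolved.values.copy()
        for s in self.by_label.values():
            vals = vals + s.values
        return DailySeries(start, vals)


def consensus_counts_by_day(
    comments: pd.DataFrame, window: tuple[dt.date, dt.date]
) -> EmotionDailyCounts:
    """Daily counts of comments per consensus category over a date window.

    Unresolved comments are counted in none of the five emotion series;
    they appear only in the residual series, so that per day:
    sum over the 5 categories + unresolved = total comments.
    """
    start, end = window
    n = (end - start).days + 1
    if n < 2:
        raise AlignmentError("window must span at least 2 days")
    dates = pd.to_datetime(comments["date"]).dt.date
    day_idx = np.array([(d - start).days for d in dates])
    if day_idx.min() < 0 or day_idx.max() >= n:
        raise AlignmentError("comments fall outside the requested window")

    by_label: dict[Emotion, DailySeries] = {}
    for lab in EMOTIONS:
        mask = (comments["consensus"] == lab.value).to_numpy()
        by_label[lab] = DailySeries(start, np.bincount(day_idx[mask], minlength=n))
    unresolved_mask = (comments["consensus"] == "unresolved").to_numpy()
    unresolved = DailySeries(start, np.bincount(day_idx[unresolved_mask], minlength=n))
    return EmotionDailyCounts(by_label=by_label, unresolved=unresolved)
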