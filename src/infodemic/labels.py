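"""The closed five-category emotion coding scheme.

Public comments and rumors are coded into the four basic human emotions
(happiness, sadness, anger, fear) plus "neutral" for items carrying no
emotional content. The set is closed: every coder label, consensus label
and rumor tag is one of these five values.
"""

from __future__ import annotations

import enum


class Emotion(str, enum.Enum):
    """One of the five emotion coding categories."""

    HAPPINESS = "happiness"
    SADNESS = "sadness"
    ANGER = "anger"
    FEAR = "fear"
    NEUTRAL = "neutral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical category order used everywhere (probability vectors, tallies).
EMOTIONS: tuple[Emotion, ...] = (
    Emotion.HAPPINESS,
    Emotion.SADNESS,
    Emotion.ANGER,
    Emotion.FEAR,
    Emotion.NEUTRAL,
)

#: The four basic emotions (everything but neutral).
BASIC_EMOTIONS: tuple[Emotion, ...] = EMOTIONS[:4]

#: Negative emotions that epidemic severity tilts the public toward.
NEGATIVE_EMOTIONS: tuple[Emotion, ...] = (Emotion.ANGER, Emotion.FEAR)

#: Integer code of each category in canonical order.
LABEL_CODES: dict[Emotion, int] = {lab: i for i, lab in enumerate(EMOTIONS)}

N_CATEGORIES = len(EMOTIONS)


class _UnresolvedType:
    """Marker for a comment whose coders produced no strict plurality."""

    _instance: "_UnresolvedType | None" = None

    def __new__(cls) -> "_UnresolvedType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNRESOLVED"

    def __str__(self) -> str:
        return "unresolved"


#: Sentinel returned by consensus coding when no strict plurality exists.
UNRESOLVED = _UnresolvedType()


def as_emotion(value: "str | Emotion") -> Emotion:
    """Coerce a string (or Emotion) to an :class:`Emotion`, validating it."""
    if isinstance(value, Emotion):
        return value
    try:
        return Emotion(value)
    except ValueError as exc:
        valid = ", ".join(e.value for e in EMOTIONS)
        raise ValueError(f"unknown emotion label {value!r}; expected one of: {valid}") from exc
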