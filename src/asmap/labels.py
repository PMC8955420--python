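"""Class-label schemes: 3-class categorical, rating binarization, quadrants.

Two annotation styles are supported: categorical trial codes in {-1, 0, 1}
mapping to negative/neutral/positive, and 1-9 valence/arousal ratings
binarized at a threshold (default 5.5, boundary assigned to the high
class). The quadrant scheme is the cross product of the two binarizations.
Trial labels propagate to every window cut from that trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from asmap.errors import ValidationError

__all__ = [
    "EmotionLabel",
    "SCHEMES",
    "binarize_rating",
    "quadrant_label",
    "seed_label",
    "read_ratings_table",
    "read_code_table",
]

#: Class names per scheme, in stable 0-based index order.
SCHEMES: dict[str, tuple[str, ...]] = {
    "seed3": ("negative", "neutral", "positive"),
    "deap_valence": ("LV", "HV"),
    "deap_arousal": ("LA", "HA"),
    "deap_quadrant": ("HVHA", "HVLA", "LVHA", "LVLA"),
}

DEFAULT_THRESHOLD = 5.5

_SEED_CODES = {-1: "negative", 0: "neutral", 1: "positive"}


@dataclass(frozen=True)
class EmotionLabel:
    scheme: str
    class_name: str
    class_index: int

    def __post_init__(self) -> None:
        classes = SCHEMES.get(self.scheme)
        if classes is None:
            raise ValidationError(f"unknown scheme {self.scheme!r}; known: {sorted(SCHEMES)}")
        if self.class_name not in classes:
            raise ValidationError(
                f"class {self.class_name!r} not valid for scheme {self.scheme!r} ({classes})"
            )
        if classes.index(self.class_name) != self.class_index:
            raise ValidationError(
                f"class_index {self.class_index} inconsistent with {self.class_name!r} "
                f"in scheme {self.scheme!r}"
            )


def _label(scheme: str, class_name: str) -> EmotionLabel:
    return EmotionLabel(scheme, class_name, SCHEMES[scheme].index(class_name))


def _check_rating(rating: float, what: str) -> None:
    if not 1.0 <= rating <= 9.0:
        raise ValidationError(f"{what} rating {rating} outside [1, 9]")


def binarize_rating(
    rating: float, dimension: str, threshold: float = DEFAULT_THRESHOLD
) -> EmotionLabel:
    """Low/high split of a 1-9 rating; rating >= threshold is the high class."""
    if dimension not in ("valence", "arousal"):
        raise ValidationError(f"dimension must be 'valence' or 'arousal', got {dimension!r}")
    _check_rating(rating, dimension)
    scheme = "deap_valence" if dimension == "valence" else "deap_arousal"
    high, low = ("HV", "LV") if dimension == "valence" else ("HA", "LA")
    return _label(scheme, high if rating >= threshold else low)


def quadrant_label(
    valence: float, arousal: float, threshold: float = DEFAULT_THRESHOLD
) -> EmotionLabel:
    """Four-class label from the two independent binarizations."""
    v = binarize_rating(valence, "valence", threshold)
    a = binarize_rating(arousal, "arousal", threshold)
    return _label("deap_quadrant", v.class_name + a.class_name)


def seed_label(code: int) -> EmotionLabel:
    """Map a categorical trial code in {-1, 0, 1} to its 3-class label."""
    if code not in _SEED_CODES:
        raise ValidationError(f"trial code {code} not in {sorted(_SEED_CODES)}")
    return _label("seed3", _SEED_CODES[code])


def read_ratings_table(path: str | Path, scheme: str = "deap_quadrant") -> dict[str, EmotionLabel]:
    """Read a delimited table of trial_id, valence, arousal into labels."""
    df = pd.read_csv(path)
    required = {"trial_id", "valence", "arousal"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: ratings table missing columns {sorted(missing)}")
    out: dict[str, EmotionLabel] = {}
    for row in df.itertuples(index=False):
        if scheme == "deap_quadrant":
            out[str(row.trial_id)] = quadrant_label(row.valence, row.arousal)
        elif scheme == "deap_valence":
            out[str(row.trial_id)] = binarize_rating(row.valence, "valence")
        elif scheme == "deap_arousal":
            out[str(row.trial_id)] = binarize_rating(row.arousal, "arousal")
        else:
            raise ValidationError(f"scheme {scheme!r} is not rating-based")
    return out


def read_code_table(path: str | Path) -> dict[str, EmotionLabel]:
    """Read a delimited table of trial_id, code (in {-1, 0, 1}) into labels."""
    df = pd.read_csv(path)
    required = {"trial_id", "code"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: code table missing columns {sorted(missing)}")
    return {str(r.trial_id): seed_label(int(r.code)) for r in df.itertuples(index=False)}
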