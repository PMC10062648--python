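"""Stimulus naming grammar and participant-group vocabulary.

The stimulus database addressed by this package assigns each short video to
one of six participant groups (gender x age band) and one of three valence
states. File names encode this assignment:

* specific/comparison short videos:
  ``valence_gender_age_number.MP4`` with gender ``1`` = male, ``2`` = female,
  age ``1`` = 20-24, ``2`` = 25-29, ``3`` = 30-34, number in 1..3;
* film clips: ``valence_film_number.MP4``.

Parsing and formatting are exact inverses on every canonical name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

GENDERS = ("male", "female")
AGE_BANDS = ("20-24", "25-29", "30-34")
VALENCES = ("positive", "neutral", "negative")

#: file-name digit codes (bijective with the group vocabulary)
_GENDER_CODE = {"male": 1, "female": 2}
_GENDER_FROM_CODE = {v: k for k, v in _GENDER_CODE.items()}
_AGE_CODE = {"20-24": 1, "25-29": 2, "30-34": 3}
_AGE_FROM_CODE = {v: k for k, v in _AGE_CODE.items()}

SOURCE_KINDS = ("specific_short_video", "comparison_short_video", "film_clip")


class StimulusNameError(ValueError):
    """Raised when a stimulus file name violates the naming grammar."""

    def __init__(self, name: str, field: str, message: str):
        self.name = name
        self.field = field
        super().__init__(f"{name!r}: invalid {field}: {message}")


@dataclass(frozen=True)
class GroupKey:
    """One of the six participant groups (gender x age band)."""

    gender: str
    age_band: str

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")

    @property
    def gender_code(self) -> int:
        return _GENDER_CODE[self.gender]

    @property
    def age_code(self) -> int:
        return _AGE_CODE[self.age_band]

    @classmethod
    def from_codes(cls, gender_code: int, age_code: int) -> "GroupKey":
        return cls(_GENDER_FROM_CODE[gender_code], _AGE_FROM_CODE[age_code])

    def __str__(self) -> str:  # e.g. "male_20-24"
        return f"{self.gender}_{self.age_band}"


def all_groups() -> list[GroupKey]:
    """The six participant groups, males first, youngest first."""
    return [GroupKey(g, a) for g in GENDERS for a in AGE_BANDS]


@dataclass(frozen=True)
class StimulusDescriptor:
    """Identity of one stimulus: valence, source, target group and number.

    ``group`` is ``None`` exactly for film clips. ``stimulus_id`` equals the
    canonical file name without its extension.
    """

    valence: str
    source_kind: str
    number: int
    group: Optional[GroupKey] = None
    duration_s: Optional[float] = None

    def __post_init__(self):
        if self.valence not in VALENCES:
            raise ValueError(f"unknown valence {self.valence!r}")
        if self.source_kind not in SOURCE_KINDS:
            raise ValueError(f"unknown source kind {self.source_kind!r}")
        if not 1 <= self.number <= 3:
            raise ValueError(f"number {self.number} outside 1..3")
        if (self.group is None) != (self.source_kind == "film_clip"):
            raise ValueError("group must be None iff the stimulus is a film clip")

    @property
    def stimulus_id(self) -> str:
        if self.source_kind == "film_clip":
            return f"{self.valence}_film_{self.number}"
        return (
            f"{self.valence}_{self.group.gender_code}_"
            f"{self.group.age_code}_{self.number}"
        )

    @property
    def filename(self) -> str:
        return self.stimulus_id + ".MP4"


def parse_stimulus_filename(name: str) -> StimulusDescriptor:
    """Parse a stimulus file name into a :class:`StimulusDescriptor`.

    The extension ``.MP4`` is accepted case-insensitively; the valence word
    is case-sensitive. Raises :class:`StimulusNameError` naming the
    offending field on any grammar violation.
    """
    stem, dot, ext = name.rpartition(".")
    if not dot or ext.lower() != "mp4":
        raise StimulusNameError(name, "extension", "expected '.MP4'")
    parts = stem.split("_")
    if len(parts) == 3:
        valence, film, number_s = parts
        if film != "film":
            raise StimulusNameError(name, "token", f"expected 'film', got {film!r}")
        group = None
        kind = "film_clip"
    elif len(parts) == 4:
        valence, gender_s, age_s, number_s = parts
        for label, tok, table in (
            ("gender digit", gender_s, _GENDER_FROM_CODE),
            ("age digit", age_s, _AGE_FROM_CODE),
        ):
            if not tok.isdigit() or int(tok) not in table:
                raise StimulusNameError(name, label, f"{tok!r} out of range")
        group = GroupKey.from_codes(int(gender_s), int(age_s))
        kind = "specific_short_video"
    else:
        raise StimulusNameError(
            name, "token count", f"expected 3 or 4 '_'-separated tokens, got {len(parts)}"
        )
    if valence not in VALENCES:
        raise StimulusNameError(name, "valence", f"{valence!r} not in {VALENCES}")
    if not number_s.isdigit() or not 1 <= int(number_s) <= 3:
        raise StimulusNameError(name, "number", f"{number_s!r} outside 1..3")
    return StimulusDescriptor(valence=valence, source_kind=kind, number=int(number_s), group=group)


def format_stimulus_filename(desc: StimulusDescriptor) -> str:
    """Canonical file name for a descriptor (inverse of parsing)."""
    return desc.filename


def source_for_group(desc: StimulusDescriptor, group: GroupKey) -> str:
    """Classify a stimulus relative to a viewing group.

    A short video named for the viewer's own group is *specific*; a short
    video named for another group is a *comparison* stimulus; film clips
    are film clips for everyone.
    """
    if desc.source_kind == "film_clip":
        return "film_clip"
    return (
        "specific_short_video" if desc.group == group else "comparison_short_video"
    )


def full_catalog() -> list[StimulusDescriptor]:
    """All 54 group-specific short-video names plus the 9 film-clip names."""
    out = []
    for group in all_groups():
        for valence in VALENCES:
            for number in (1, 2, 3):
                out.append(
                    StimulusDescriptor(
                        valence=valence,
                        source_kind="specific_short_video",
                        number=number,
                        group=group,
                    )
                )
    for valence in VALENCES:
        for number in (1, 2, 3):
            out.append(
                StimulusDescriptor(valence=valence, source_kind="film_clip", number=number)
            )
    return out
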