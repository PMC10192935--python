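"""Core record types shared across the pipeline.

A :class:`SourceRecord` is one incident as read from one database, after
column mapping but with the original row preserved in ``raw``.  Harmonization
(state normalization, city cleanup) happens in :mod:`masslink.readers` and
yields the same type with normalized fields plus provenance flags; the rest of
the pipeline treats such records as *harmonized records*.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date as Date


class Source(enum.Enum):
    """The five incident databases under comparison."""

    SHR = "SHR"            # FBI Supplementary Homicide Report (mass-killing subset)
    ASR = "ASR"            # FBI Active Shooter Report
    MJ = "MJ"              # Mother Jones mass-shootings database
    EVERYTOWN = "EVERYTOWN"
    GVA = "GVA"            # Gun Violence Archive

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Default ordering of the five sources; also the tie-break priority used when
#: merging disagreeing fields (federal reports first, then curated lists).
SOURCE_ORDER: tuple[Source, ...] = (
    Source.SHR,
    Source.ASR,
    Source.EVERYTOWN,
    Source.MJ,
    Source.GVA,
)


class Motive(enum.Enum):
    GANG = "GANG"
    DRUG = "DRUG"
    FAMILY_IPV = "FAMILY_IPV"   # family / intimate-partner violence
    ROBBERY = "ROBBERY"
    TERROR = "TERROR"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class LocationType(enum.Enum):
    PUBLIC = "PUBLIC"
    RESIDENCE = "RESIDENCE"
    MULTIPLE = "MULTIPLE"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"


class VictimCountBasis(enum.Enum):
    """Whether a source's killed count includes the perpetrator."""

    EXCLUDES_PERP = "EXCLUDES_PERP"
    INCLUDES_PERP = "INCLUDES_PERP"
    UNKNOWN = "UNKNOWN"


# USPS state codes (50 states + DC).  Unmatchable state strings are kept
# verbatim and flagged rather than guessed.
STATE_TO_USPS: dict[str, str] = {
    "ALABAMA": "AL", "ALASKA": "AK", "ARIZONA": "AZ", "ARKANSAS": "AR",
    "CALIFORNIA": "CA", "COLORADO": "CO", "CONNECTICUT": "CT",
    "DELAWARE": "DE", "DISTRICT OF COLUMBIA": "DC", "FLORIDA": "FL",
    "GEORGIA": "GA", "HAWAII": "HI", "IDAHO": "ID", "ILLINOIS": "IL",
    "INDIANA": "IN", "IOWA": "IA", "KANSAS": "KS", "KENTUCKY": "KY",
    "LOUISIANA": "LA", "MAINE": "ME", "MARYLAND": "MD",
    "MASSACHUSETTS": "MA", "MICHIGAN": "MI", "MINNESOTA": "MN",
    "MISSISSIPPI": "MS", "MISSOURI": "MO", "MONTANA": "MT",
    "NEBRASKA": "NE", "NEVADA": "NV", "NEW HAMPSHIRE": "NH",
    "NEW JERSEY": "NJ", "NEW MEXICO": "NM", "NEW YORK": "NY",
    "NORTH CAROLINA": "NC", "NORTH DAKOTA": "ND", "OHIO": "OH",
    "OKLAHOMA": "OK", "OREGON": "OR", "PENNSYLVANIA": "PA",
    "RHODE ISLAND": "RI", "SOUTH CAROLINA": "SC", "SOUTH DAKOTA": "SD",
    "TENNESSEE": "TN", "TEXAS": "TX", "UTAH": "UT", "VERMONT": "VT",
    "VIRGINIA": "VA", "WASHINGTON": "WA", "WEST VIRGINIA": "WV",
    "WISCONSIN": "WI", "WYOMING": "WY",
}
USPS_CODES: frozenset[str] = frozenset(STATE_TO_USPS.values())


def normalize_state(value: str | None) -> tuple[str | None, bool]:
    """Map a state string to its USPS code.

    Returns ``(code_or_verbatim, matched)``.  Full names (any case) and codes
    both normalize; anything else is returned verbatim with ``matched=False``.
    """
    if value is None:
        return None, False
    v = value.strip()
    if not v:
        return None, False
    upper = v.upper()
    if upper in USPS_CODES:
        return upper, True
    if upper in STATE_TO_USPS:
        return STATE_TO_USPS[upper], True
    return v, False


@dataclass
class SourceRecord:
    """One incident row as read from one database."""

    source_id: str
    source: Source
    date: Date | None
    state: str | None
    city: str | None
    shooter_names: list[str] = field(default_factory=list)
    n_shooters: int | None = None
    killed_excl_perp: int | None = None
    injured_excl_perp: int | None = None
    perp_died: bool | None = None
    motive_tags: frozenset[Motive] = frozenset()
    location_type: LocationType = LocationType.UNKNOWN
    raw: dict = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("n_shooters", "killed_excl_perp", "injured_excl_perp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def casualties(self) -> int | None:
        """Killed + injured, excluding the perpetrator; None if both unknown."""
        k, i = self.killed_excl_perp, self.injured_excl_perp
        if k is None and i is None:
            return None
        return (k or 0) + (i or 0)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source.value, self.source_id)

    def sort_key(self) -> tuple:
        """Stable ordering: date, state, source priority, source id."""
        return (
            self.date or Date.min,
            self.state or "",
            SOURCE_ORDER.index(self.source),
            self.source_id,
        )


# Harmonized records share the container; the distinction is a pipeline stage.
HarmonizedRecord = SourceRecord
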