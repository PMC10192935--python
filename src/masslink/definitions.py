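"""Declarative inclusion criteria for each database.

Every database operationalizes "mass shooting" differently: the count basis
(fatalities only vs. fatalities+injuries), the threshold level, limits on the
number of shooters, whether the shooter must be identified, and motive
exclusions.  A :class:`Definition` encodes one such rule set so it can be
evaluated mechanically against any record, and the five bundled presets
reproduce the published criteria of SHR (mass-killing subset), ASR, Mother
Jones, Everytown and GVA.

Unknown-field policy
--------------------
Count and shooter rules *fail closed*: a record whose fatality count is
unknown cannot clear a fatality threshold.  Motive and location exclusions
*fail open*: only a known excluded motive disqualifies a record, mirroring
how motive-restricted databases exclude documented gang/drug/domestic
incidents but do not require a motive to be established.  Both behaviors are
configurable per definition via ``fail_open``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .records import LocationType, Motive, SourceRecord


class CountBasis(enum.Enum):
    FATALITIES = "FATALITIES"
    CASUALTIES = "CASUALTIES"


class LocationRestriction(enum.Enum):
    NONE = "NONE"
    PUBLIC_ONLY = "PUBLIC_ONLY"


# Rule identifiers reported in EligibilityVerdict.failed_rules.
RULE_MIN_FATALITIES = "MIN_FATALITIES"
RULE_MIN_CASUALTIES = "MIN_CASUALTIES"
RULE_SHOOTER_COUNT = "SHOOTER_COUNT"
RULE_SHOOTER_KNOWN = "SHOOTER_KNOWN"
RULE_MOTIVE = "MOTIVE"
RULE_LOCATION = "LOCATION"

#: Rule families whose unknown-field behavior is "fail open" by default.
DEFAULT_FAIL_OPEN = frozenset({RULE_MOTIVE, RULE_LOCATION})


@dataclass(frozen=True)
class Definition:
    """Inclusion criteria for one database."""

    name: str
    count_basis: CountBasis = CountBasis.FATALITIES
    min_count: int = 0
    perp_excluded: bool = True
    min_shooters: int | None = None
    max_shooters: int | None = None
    shooter_must_be_known: bool = False
    excluded_motives: frozenset[Motive] = frozenset()
    location_restriction: LocationRestriction = LocationRestriction.NONE
    fail_open: frozenset[str] = DEFAULT_FAIL_OPEN
    #: Explicit exceptions: record keys (``source_id``) admitted regardless of
    #: failed rules.  Mother Jones documents two such exceptions (two-shooter
    #: school shootings); empty by default.
    allow_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if (
            self.min_shooters is not None
            and self.max_shooters is not None
            and self.min_shooters > self.max_shooters
        ):
            raise ValueError("min_shooters > max_shooters")


@dataclass(frozen=True)
class EligibilityVerdict:
    eligible: bool
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.eligible != (len(self.failed_rules) == 0):
            raise ValueError("eligible must equal failed_rules being empty")


def evaluate(record: SourceRecord, definition: Definition) -> EligibilityVerdict:
    """Evaluate one record against one definition.

    Pure and deterministic; returns the full list of failed rules, not just
    the first.
    """
    failed: list[str] = []

    if record.source_id in definition.allow_list:
        return EligibilityVerdict(True)

    # Victim-count threshold.
    if definition.min_count > 0:
        if definition.count_basis is CountBasis.FATALITIES:
            value, rule = record.killed_excl_perp, RULE_MIN_FATALITIES
        else:
            value, rule = record.casualties, RULE_MIN_CASUALTIES
        if value is None:
            if rule not in definition.fail_open:
                failed.append(rule)
        elif value < definition.min_count:
            failed.append(rule)

    # Shooter-count bounds.
    if definition.min_shooters is not None or definition.max_shooters is not None:
        n = record.n_shooters
        if n is None:
            if RULE_SHOOTER_COUNT not in definition.fail_open:
                failed.append(RULE_SHOOTER_COUNT)
        elif (definition.min_shooters is not None and n < definition.min_shooters) or (
            definition.max_shooters is not None and n > definition.max_shooters
        ):
            failed.append(RULE_SHOOTER_COUNT)

    # Shooter identity requirement.
    if definition.shooter_must_be_known and not record.shooter_names:
        failed.append(RULE_SHOOTER_KNOWN)

    # Motive exclusions (fail open on UNKNOWN/absent motive by default).
    known_motives = record.motive_tags - {Motive.UNKNOWN}
    if definition.excluded_motives:
        if known_motives & definition.excluded_motives:
            failed.append(RULE_MOTIVE)
        elif not known_motives and RULE_MOTIVE not in definition.fail_open:
            failed.append(RULE_MOTIVE)

    # Location restriction.
    if definition.location_restriction is LocationRestriction.PUBLIC_ONLY:
        loc = record.location_type
        if loc is LocationType.UNKNOWN:
            if RULE_LOCATION not in definition.fail_open:
                failed.append(RULE_LOCATION)
        elif loc not in (LocationType.PUBLIC, LocationType.MULTIPLE):
            failed.append(RULE_LOCATION)

    return EligibilityVerdict(not failed, tuple(failed))


def load_definitions(path=None) -> dict[str, Definition]:
    """Load definitions from YAML; defaults to the bundled five presets."""
    if path is None:
        text = (
            resources.files("masslink").joinpath("data/definitions.yaml").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    out: dict[str, Definition] = {}
    for name, cfg in spec.items():
        out[name] = Definition(
            name=name,
            count_basis=CountBasis[cfg.get("count_basis", "FATALITIES")],
            min_count=int(cfg.get("min_count", 0)),
            perp_excluded=bool(cfg.get("perp_excluded", True)),
            min_shooters=cfg.get("min_shooters"),
            max_shooters=cfg.get("max_shooters"),
            shooter_must_be_known=bool(cfg.get("shooter_must_be_known", False)),
            excluded_motives=frozenset(
                Motive[m] for m in cfg.get("excluded_motives", [])
            ),
            location_restriction=LocationRestriction[
                cfg.get("location_restriction", "NONE")
            ],
            fail_open=frozenset(cfg.get("fail_open", DEFAULT_FAIL_OPEN)),
            allow_list=frozenset(cfg.get("allow_list", [])),
        )
    return out


#: The five bundled presets, keyed by source name.
PRESETS: dict[str, Definition] = load_definitions()


def _killed(item) -> int | None:
    """Fatality count of a record or an incident cluster."""
    canonical = getattr(item, "canonical", None)
    if canonical is not None:
        return canonical.killed_excl_perp
    return item.killed_excl_perp


def apply_fatality_threshold(items: list, min_fatalities: int) -> tuple[list, list]:
    """Partition records or clusters at a fatality threshold.

    Retained iff killed (excluding perpetrator) >= ``min_fatalities``; items
    with an unknown fatality count are excluded and flagged.  A threshold of 0
    retains everything.
    """
    if min_fatalities < 0:
        raise ValueError("min_fatalities must be >= 0")
    retained, excluded = [], []
    for item in items:
        k = _killed(item)
        if min_fatalities == 0:
            retained.append(item)
        elif k is None:
            flags = getattr(item, "flags", None)
            if flags is not None:
                flags.add("UNKNOWN_FATALITIES")
            excluded.append(item)
        elif k >= min_fatalities:
            retained.append(item)
        else:
            excluded.append(item)
    return retained, excluded


def filter_ledger(
    per_source_totals: dict, per_source_surviving: dict
) -> dict:
    """Excluded-incident counts per source: total - surviving.

    Raises ``ValueError`` if any source reports more survivors than totals.
    """
    excluded = {}
    for source, total in per_source_totals.items():
        surviving = per_source_surviving.get(source, 0)
        if surviving > total:
            raise ValueError(
                f"{source}: surviving ({surviving}) exceeds total ({total})"
            )
        excluded[source] = total - surviving
    return excluded
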