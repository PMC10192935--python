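"""Reading the five source exports into :class:`SourceRecord` lists.

Each source ships its CSV in its own dialect (column names, date format,
whether the killed count includes the perpetrator, whether rows are
incident-level or victim-level).  A :class:`SourceDialect` captures that
dialect declaratively; :func:`load_source` applies it.  Rows that cannot be
parsed are collected in a structured error report, never silently dropped.

The SHR is special twice over: its export is victim-level (one row per
decedent, grouped here into incidents by agency / incident number / date,
the standard convention), and only a subset of it — single-shooter incidents
with four or more firearm fatalities, the FBI's traditional "mass killing" —
belongs in the comparison.  :func:`subset_shr` applies that subset with a
reason code for every dropped record.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from datetime import date as Date, datetime
from importlib import resources
from pathlib import Path

from .records import (
    LocationType,
    Motive,
    Source,
    SourceRecord,
    VictimCountBasis,
    normalize_state,
)


@dataclass(frozen=True)
class SourceDialect:
    """How one source's CSV maps onto SourceRecord fields."""

    source: Source
    column_map: dict[str, str]  # source column -> record field
    date_format: str = "%m/%d/%Y"
    victim_count_basis: VictimCountBasis = VictimCountBasis.EXCLUDES_PERP
    encoding: str = "utf-8"
    delimiter: str = ","
    victim_level: bool = False
    group_keys: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        fields = set(self.column_map.values())
        if "date" not in fields or not (
            {"state", "city", "city_state"} & fields
        ):
            raise ValueError(
                "dialect column_map must cover date and at least one of "
                "state/city"
            )

    def column_for(self, field_name: str) -> str | None:
        for col, f in self.column_map.items():
            if f == field_name:
                return col
        return None


@dataclass(frozen=True)
class ParseError:
    source: Source
    row: int                # 1-based data-row index in the file
    source_id: str
    field: str
    value: str
    message: str


@dataclass
class LoadResult:
    records: list[SourceRecord]
    errors: list[ParseError] = field(default_factory=list)
    n_data_rows: int = 0


def load_dialect(source_or_path) -> SourceDialect:
    """Load a dialect from YAML; a :class:`Source` loads the bundled one."""
    import yaml

    if isinstance(source_or_path, Source):
        text = (
            resources.files("masslink")
            .joinpath(f"data/dialects/{source_or_path.value.lower()}.yaml")
            .read_text()
        )
    else:
        text = Path(source_or_path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text)
    return SourceDialect(
        source=Source(cfg["source"]),
        column_map=dict(cfg["column_map"]),
        date_format=cfg.get("date_format", "%m/%d/%Y"),
        victim_count_basis=VictimCountBasis(
            cfg.get("victim_count_basis", "UNKNOWN")
        ),
        encoding=cfg.get("encoding", "utf-8"),
        delimiter=cfg.get("delimiter", ","),
        victim_level=bool(cfg.get("victim_level", False)),
        group_keys=tuple(cfg.get("group_keys", ())),
    )


BUILTIN_DIALECTS: dict[Source, SourceDialect] = {}


def builtin_dialect(source: Source) -> SourceDialect:
    if source not in BUILTIN_DIALECTS:
        BUILTIN_DIALECTS[source] = load_dialect(source)
    return BUILTIN_DIALECTS[source]


# --- field parsers ---------------------------------------------------------

_MOTIVE_VOCAB = {
    "gang-related": Motive.GANG,
    "gang": Motive.GANG,
    "drug-related": Motive.DRUG,
    "drug": Motive.DRUG,
    "domestic/family violence": Motive.FAMILY_IPV,
    "domestic violence": Motive.FAMILY_IPV,
    "family/intimate partner violence": Motive.FAMILY_IPV,
    "robbery": Motive.ROBBERY,
    "terrorism": Motive.TERROR,
    "terror": Motive.TERROR,
    "other": Motive.OTHER,
    "unknown": Motive.UNKNOWN,
}

_LOCATION_VOCAB = {
    "public": LocationType.PUBLIC,
    "residence": LocationType.RESIDENCE,
    "home": LocationType.RESIDENCE,
    "multiple": LocationType.MULTIPLE,
    "other": LocationType.OTHER,
    "unknown": LocationType.UNKNOWN,
}

_PERP_DIED_TRUE = {"yes", "dead", "killed", "deceased", "suicide"}
_PERP_DIED_FALSE = {"no", "arrested", "apprehended", "at large", "alive"}


def parse_motives(value: str | None) -> frozenset[Motive]:
    if not value or not value.strip():
        return frozenset({Motive.UNKNOWN})
    out = set()
    for part in re.split(r"[;|]", value):
        key = part.strip().lower()
        if key:
            out.add(_MOTIVE_VOCAB.get(key, Motive.OTHER))
    return frozenset(out) if out else frozenset({Motive.UNKNOWN})


def parse_location(value: str | None) -> LocationType:
    if not value or not value.strip():
        return LocationType.UNKNOWN
    return _LOCATION_VOCAB.get(value.strip().lower(), LocationType.OTHER)


def parse_perp_died(value: str | None) -> bool | None:
    if not value or not value.strip():
        return None
    key = value.strip().lower()
    if key in _PERP_DIED_TRUE:
        return True
    if key in _PERP_DIED_FALSE:
        return False
    return None


def _parse_int(value: str | None) -> int | None:
    if value is None:
        return None
    v = value.strip()
    if not v or v.lower() in ("unknown", "na", "n/a", "-"):
        return None
    return int(v)


def _parse_names(value: str | None) -> list[str]:
    if not value:
        return []
    return [n.strip() for n in re.split(r"[;&]| and ", value) if n.strip()]


def _split_city_state(value: str) -> tuple[str | None, str | None]:
    """Split a combined "City, State" field on its last comma."""
    if "," not in value:
        return (value.strip() or None), None
    city, _, state = value.rpartition(",")
    return (city.strip() or None), (state.strip() or None)


# --- loading ---------------------------------------------------------------

def _read_rows(path, dialect: SourceDialect) -> list[dict]:
    with open(path, encoding=dialect.encoding, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            return []
        missing = [
            col for col in dialect.column_map if col not in reader.fieldnames
        ]
        if missing:
            raise ValueError(
                f"{dialect.source.value} file {path} is missing mandatory "
                f"column(s): {', '.join(missing)}"
            )
        return list(reader)


def _mapped(row: dict, dialect: SourceDialect) -> dict[str, str]:
    return {f: row.get(col, "") for col, f in dialect.column_map.items()}


def _row_to_record(
    row: dict, idx: int, dialect: SourceDialect
) -> tuple[SourceRecord | None, list[ParseError]]:
    m = _mapped(row, dialect)
    source_id = m.get("source_id", "").strip() or f"row{idx}"
    errors: list[ParseError] = []

    try:
        date = datetime.strptime(m["date"].strip(), dialect.date_format).date()
    except ValueError as exc:
        errors.append(
            ParseError(dialect.source, idx, source_id, "date", m["date"], str(exc))
        )
        return None, errors

    if "city_state" in m:
        city, state = _split_city_state(m["city_state"])
    else:
        city = (m.get("city") or "").strip() or None
        state = (m.get("state") or "").strip() or None

    counts: dict[str, int | None] = {}
    flags: set[str] = set()
    for f in ("n_shooters", "killed_excl_perp", "injured_excl_perp"):
        if f not in m:
            counts[f] = None
            continue
        try:
            v = _parse_int(m[f])
            if v is not None and v < 0:
                raise ValueError(f"negative count {v}")
            counts[f] = v
        except ValueError as exc:
            errors.append(
                ParseError(dialect.source, idx, source_id, f, m[f], str(exc))
            )
            counts[f] = None
            flags.add(f"BAD_{f.upper()}")

    perp_died = parse_perp_died(m.get("perp_died"))
    killed = counts["killed_excl_perp"]
    if (
        dialect.victim_count_basis is VictimCountBasis.INCLUDES_PERP
        and killed is not None
    ):
        if perp_died is True:
            killed = max(killed - 1, 0)
        elif perp_died is False:
            pass  # count already excludes a surviving perpetrator
        else:
            killed = None
            flags.add("KILLED_BASIS_UNKNOWN")

    record = SourceRecord(
        source_id=source_id,
        source=dialect.source,
        date=date,
        state=state,
        city=city,
        shooter_names=_parse_names(m.get("shooter_names")),
        n_shooters=counts["n_shooters"],
        killed_excl_perp=killed,
        injured_excl_perp=counts["injured_excl_perp"],
        perp_died=perp_died,
        motive_tags=parse_motives(m.get("motive")),
        location_type=parse_location(m.get("location_type")),
        raw=dict(row),
        flags=flags,
    )
    return record, errors


def _group_victim_rows(
    rows: list[dict], dialect: SourceDialect
) -> LoadResult:
    """Group victim-level rows (one per decedent) into incident records."""
    errors: list[ParseError] = []
    groups: dict[tuple, list[tuple[int, dict]]] = {}
    for idx, row in enumerate(rows, start=1):
        m = _mapped(row, dialect)
        try:
            date = datetime.strptime(
                m["date"].strip(), dialect.date_format
            ).date()
        except ValueError as exc:
            sid = "/".join(m.get(k, "") for k in dialect.group_keys)
            errors.append(
                ParseError(dialect.source, idx, sid, "date", m["date"], str(exc))
            )
            continue
        key = tuple(m.get(k, "").strip() for k in dialect.group_keys) + (date,)
        groups.setdefault(key, []).append((idx, row))

    records: list[SourceRecord] = []
    for key in sorted(groups, key=lambda k: tuple(map(str, k))):
        members = groups[key]
        first_idx, first_row = members[0]
        m = _mapped(first_row, dialect)
        date = datetime.strptime(m["date"].strip(), dialect.date_format).date()
        source_id = "-".join(str(p) for p in key[:-1]) + f"-{date.isoformat()}"
        names: list[str] = []
        weapons: list[str] = []
        motives: set[Motive] = set()
        for _, row in members:
            rm = _mapped(row, dialect)
            for n in _parse_names(rm.get("shooter_names")):
                if n not in names:
                    names.append(n)
            weapons.append((rm.get("weapon") or "").strip())
            motives |= parse_motives(rm.get("motive"))
        if len(motives) > 1:
            motives -= {Motive.UNKNOWN}
        try:
            n_shooters = _parse_int(m.get("n_shooters"))
        except ValueError:
            n_shooters = None
        records.append(
            SourceRecord(
                source_id=source_id,
                source=dialect.source,
                date=date,
                state=(m.get("state") or "").strip() or None,
                city=(m.get("city") or "").strip() or None,
                shooter_names=names,
                n_shooters=n_shooters,
                killed_excl_perp=len(members),  # one row per decedent
                injured_excl_perp=None,         # SHR carries no injury data
                perp_died=None,
                motive_tags=frozenset(motives),
                raw={"rows": [dict(r) for _, r in members], "weapons": weapons},
            )
        )
    return LoadResult(records, errors, n_data_rows=len(rows))


def load_source(path, dialect: SourceDialect) -> LoadResult:
    """Parse one source export.

    Every parseable row yields one record (victim-level dialects group rows
    into incidents first); rows with unparseable dates or counts are reported
    in ``errors``.  For incident-level dialects,
    ``len(records) + len(date errors) == n_data_rows``.
    """
    rows = _read_rows(path, dialect)
    if not rows:
        import warnings

        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return LoadResult([], [], 0)
    if dialect.victim_level:
        return _group_victim_rows(rows, dialect)

    records: list[SourceRecord] = []
    errors: list[ParseError] = []
    seen_ids: set[str] = set()
    for idx, row in enumerate(rows, start=1):
        record, errs = _row_to_record(row, idx, dialect)
        errors.extend(errs)
        if record is not None:
            if record.source_id in seen_ids:
                record.flags.add("DUPLICATE_SOURCE_ID")
            seen_ids.add(record.source_id)
            records.append(record)
    return LoadResult(records, errors, n_data_rows=len(rows))


# --- SHR mass-killing subset ----------------------------------------------

#: Weapon codes treated as firearms (lower-case); configurable.
DEFAULT_FIREARM_CODES = frozenset(
    {
        "handgun",
        "handgun - pistol, revolver etc",
        "rifle",
        "shotgun",
        "firearm, type not stated",
        "other gun",
    }
)

#: Known non-firearm codes; anything outside both sets routes to review.
KNOWN_NONFIREARM_CODES = frozenset(
    {
        "knife or cutting instrument",
        "blunt object",
        "personal weapons",
        "strangulation",
        "fire",
        "asphyxiation",
        "narcotics or drugs",
        "poison",
        "explosives",
        "drowning",
        "other or unknown weapon",
    }
)

REASON_SHOOTER_COUNT = "SHOOTER_COUNT"
REASON_FATALITIES = "FATALITIES"
REASON_WEAPON = "WEAPON"


@dataclass
class ShrSubsetResult:
    retained: list[SourceRecord]
    dropped: list[tuple[SourceRecord, tuple[str, ...]]]
    review: list[tuple[SourceRecord, tuple[str, ...]]]  # unknown weapon codes


def subset_shr(
    records: list[SourceRecord],
    firearm_codes: frozenset[str] = DEFAULT_FIREARM_CODES,
    min_fatalities: int = 4,
) -> ShrSubsetResult:
    """Subset SHR incidents to single-shooter, >=4 firearm-fatality events.

    Firearm fatalities are the victim rows whose weapon code is in
    ``firearm_codes``.  Records carrying a weapon code in neither the firearm
    nor the known non-firearm set go to the review list, not the retained set.
    Idempotent and order-independent.
    """
    result = ShrSubsetResult([], [], [])
    for r in records:
        if r.source is not Source.SHR:
            raise ValueError(f"subset_shr got non-SHR record {r.key}")
        weapons = [w.strip().lower() for w in r.raw.get("weapons", []) if w is not None]
        unknown = tuple(
            sorted(
                {
                    w or "<blank>"
                    for w in weapons
                    if w not in firearm_codes and w not in KNOWN_NONFIREARM_CODES
                }
            )
        )
        if not weapons or unknown:
            result.review.append((r, unknown or ("<no weapon data>",)))
            continue
        firearm_kills = sum(w in firearm_codes for w in weapons)
        reasons = []
        if r.n_shooters != 1:
            reasons.append(REASON_SHOOTER_COUNT)
        if firearm_kills < min_fatalities:
            reasons.append(REASON_FATALITIES)
        if reasons:
            result.dropped.append((r, tuple(reasons)))
        else:
            result.retained.append(r)
    return result


# --- window filtering and harmonization ------------------------------------

def filter_window(
    records: list[SourceRecord], start: Date, end: Date
) -> list[SourceRecord]:
    """Keep records with start <= date <= end (closed interval)."""
    if start > end:
        raise ValueError("start must be <= end")
    return [r for r in records if r.date is not None and start <= r.date <= end]


_WS = re.compile(r"\s+")


def harmonize(records: list[SourceRecord]) -> list[SourceRecord]:
    """Normalize state to USPS code and tidy city text; sort stably.

    Unmatchable state strings are kept verbatim with flag STATE_UNMATCHED.
    Returns new record objects; inputs are not mutated.
    """
    out = []
    for r in records:
        state, matched = normalize_state(r.state)
        flags = set(r.flags)
        if r.state is not None and not matched:
            flags.add("STATE_UNMATCHED")
        city = _WS.sub(" ", r.city).strip() if r.city else None
        out.append(replace(r, state=state, city=city, flags=flags))
    out.sort(key=SourceRecord.sort_key)
    return out


# --- CSV output -------------------------------------------------------------

HARMONIZED_COLUMNS = [
    "source",
    "source_id",
    "date",
    "state",
    "city",
    "shooter_names",
    "n_shooters",
    "killed_excl_perp",
    "injured_excl_perp",
    "perp_died",
    "motive_tags",
    "location_type",
    "flags",
]


def write_harmonized_csv(records: list[SourceRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(HARMONIZED_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.source.value,
                    r.source_id,
                    r.date.isoformat() if r.date else "",
                    r.state or "",
                    r.city or "",
                    "; ".join(r.shooter_names),
                    "" if r.n_shooters is None else r.n_shooters,
                    "" if r.killed_excl_perp is None else r.killed_excl_perp,
                    "" if r.injured_excl_perp is None else r.injured_excl_perp,
                    "" if r.perp_died is None else str(r.perp_died).lower(),
                    "; ".join(sorted(m.value for m in r.motive_tags)),
                    r.location_type.value,
                    "; ".join(sorted(r.flags)),
                ]
            )


def write_errors_csv(errors: list[ParseError], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "row", "source_id", "field", "value", "message"])
        for e in errors:
            w.writerow([e.source.value, e.row, e.source_id, e.field, e.value, e.message])
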