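"""Synthetic five-database testbed with known ground truth.

Real mass-shooting databases cannot be bundled or re-downloaded
deterministically, and — more importantly — carry no ground truth about which
rows in different databases describe the same incident.  This module
generates a universe of incidents with full attributes, then lets each of
the five sources "observe" it: a source lists an incident only if the
incident satisfies that source's inclusion definition, detection is imperfect
(default 95%), and listed fields are independently perturbed at low rates
(date shifted a day, a city-name typo, an off-by-one casualty count, a
missing shooter name) — exactly the imperfect-duplicate structure the
linkage stage must resolve.  The emitted CSVs use each source's own dialect,
so the readers are exercised end to end, and the :class:`GroundTruth` object
supports exact truth-side computation of clusters, membership and overlap
counts for use as oracles.

Casualty counts are drawn from negative binomials (overdispersed: mostly
small incidents, rare large ones), with the all-zero (killed, injured) pair
redrawn so every incident has at least one victim while 0-killed and
0-injured incidents both occur.  Dates are drawn a week inside the study
window so a one-day reporting shift never crosses the window boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from datetime import date as Date, timedelta
from importlib import resources

import numpy as np

from .definitions import Definition, PRESETS, evaluate
from .readers import SourceDialect, builtin_dialect
from .records import (
    STATE_TO_USPS,
    LocationType,
    Motive,
    Source,
    SourceRecord,
)

USPS_TO_STATE = {code: name.title() for name, code in STATE_TO_USPS.items()}
USPS_TO_STATE["DC"] = "District of Columbia"

_FIRST_NAMES = [
    "James", "Robert", "John", "Michael", "David", "William", "Richard",
    "Joseph", "Thomas", "Christopher", "Charles", "Daniel", "Matthew",
    "Anthony", "Mark", "Steven", "Andrew", "Paul", "Joshua", "Kenneth",
    "Kevin", "Brian", "Timothy", "Jason", "Jeffrey", "Ryan", "Jacob",
    "Nicholas", "Eric", "Jonathan", "Larry", "Justin", "Scott", "Brandon",
    "Samuel", "Gregory", "Alexander", "Patrick", "Raymond", "Tyler",
]
_LAST_NAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Torres", "Nguyen", "Hill", "Flores", "Green", "Adams",
    "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell", "Carter",
]

_FIREARM_WEAPONS = ["Handgun", "Rifle", "Shotgun", "Firearm, type not stated"]

MOTIVE_STRINGS = {
    Motive.GANG: "Gang-related",
    Motive.DRUG: "Drug-related",
    Motive.FAMILY_IPV: "Domestic/family violence",
    Motive.ROBBERY: "Robbery",
    Motive.TERROR: "Terrorism",
    Motive.OTHER: "Other",
    Motive.UNKNOWN: "Unknown",
}
LOCATION_STRINGS = {
    LocationType.PUBLIC: "Public",
    LocationType.RESIDENCE: "Residence",
    LocationType.MULTIPLE: "Multiple",
    LocationType.OTHER: "Other",
    LocationType.UNKNOWN: "Unknown",
}
_PERP_OUTCOME = {
    Source.ASR: ("Killed", "Apprehended"),
    Source.MJ: ("dead", "arrested"),
    Source.EVERYTOWN: ("Yes", "No"),
    Source.GVA: ("Dead", "Arrested"),
}


def load_cities() -> list[tuple[str, str]]:
    text = resources.files("masslink").joinpath("data/cities.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    return [(r["city"], r["state"]) for r in rows]


@dataclass(frozen=True)
class UniverseConfig:
    """Parameters of the ground-truth incident universe."""

    n_incidents: int = 2000
    date_start: Date = Date(2013, 1, 1)
    date_end: Date = Date(2020, 12, 31)
    date_margin_days: int = 7   # keep 1-day jitter inside the window
    fatality_mean: float = 2.0
    fatality_dispersion: float = 1.0
    injury_mean: float = 3.0
    injury_dispersion: float = 1.0
    motive_probs: tuple[tuple[str, float], ...] = (
        ("GANG", 0.25),
        ("FAMILY_IPV", 0.25),
        ("DRUG", 0.10),
        ("ROBBERY", 0.05),
        ("TERROR", 0.02),
        ("OTHER", 0.33),
    )
    location_probs: tuple[tuple[str, float], ...] = (
        ("PUBLIC", 0.35),
        ("RESIDENCE", 0.45),
        ("MULTIPLE", 0.05),
        ("OTHER", 0.15),
    )
    p_perp_dies: float = 0.2
    p_two_shooters: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_incidents < 0:
            raise ValueError("n_incidents must be >= 0")
        for name in ("p_perp_dies", "p_two_shooters"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for probs_name in ("motive_probs", "location_probs"):
            total = sum(p for _, p in getattr(self, probs_name))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{probs_name} must sum to 1, got {total}")
        if self.date_start > self.date_end:
            raise ValueError("date_start must be <= date_end")


@dataclass
class Incident:
    """One ground-truth incident."""

    incident_id: str
    date: Date
    state: str            # USPS code
    city: str
    shooter_names: list[str]
    n_shooters: int
    killed_excl_perp: int
    injured_excl_perp: int
    perp_died: bool
    motive: Motive
    location_type: LocationType

    def to_record(self, source: Source = Source.GVA) -> SourceRecord:
        """View the true incident as a fully-known record (for evaluation)."""
        return SourceRecord(
            source_id=self.incident_id,
            source=source,
            date=self.date,
            state=self.state,
            city=self.city,
            shooter_names=list(self.shooter_names),
            n_shooters=self.n_shooters,
            killed_excl_perp=self.killed_excl_perp,
            injured_excl_perp=self.injured_excl_perp,
            perp_died=self.perp_died,
            motive_tags=frozenset({self.motive}),
            location_type=self.location_type,
        )


@dataclass(frozen=True)
class SourceModel:
    """How one source observes the universe."""

    source: Source
    definition: Definition
    detection_prob: float = 0.95
    p_date_shift: float = 0.05
    p_city_typo: float = 0.05
    p_count_off_by_one: float = 0.05
    p_missing_name: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "detection_prob",
            "p_date_shift",
            "p_city_typo",
            "p_count_off_by_one",
            "p_missing_name",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


def default_source_models(
    detection_prob: float = 0.95, perturbation: float = 0.05
) -> dict[Source, SourceModel]:
    """One model per source: its bundled definition + common rates."""
    return {
        s: SourceModel(
            source=s,
            definition=PRESETS[s.value],
            detection_prob=detection_prob,
            p_date_shift=perturbation,
            p_city_typo=perturbation,
            p_count_off_by_one=perturbation,
            p_missing_name=perturbation,
        )
        for s in Source
    }


@dataclass
class Emission:
    """One source's listing of one incident, as emitted (post-perturbation)."""

    incident_id: str
    source: Source
    source_id: str
    expected: SourceRecord       # what the reader should parse from the CSV
    perturbed_fields: tuple[str, ...] = ()


@dataclass
class GroundTruth:
    incidents: dict[str, Incident] = field(default_factory=dict)
    emissions: dict[Source, list[Emission]] = field(default_factory=dict)

    def record_to_incident(self) -> dict[tuple[str, str], str]:
        return {
            (e.source.value, e.source_id): e.incident_id
            for ems in self.emissions.values()
            for e in ems
        }

    def membership(self) -> dict[str, set[Source]]:
        """incident_id -> set of sources that listed it."""
        out: dict[str, set[Source]] = {}
        for source, ems in self.emissions.items():
            for e in ems:
                out.setdefault(e.incident_id, set()).add(source)
        return out

    def true_match_pairs(self) -> set[frozenset]:
        """All co-referent cross-record pairs, keyed by (source, source_id)."""
        by_incident: dict[str, list[tuple[str, str]]] = {}
        for ems in self.emissions.values():
            for e in ems:
                by_incident.setdefault(e.incident_id, []).append(
                    (e.source.value, e.source_id)
                )
        pairs: set[frozenset] = set()
        for keys in by_incident.values():
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    pairs.add(frozenset((keys[i], keys[j])))
        return pairs


# --- universe generation ----------------------------------------------------

def _zt_counts(
    rng: np.random.Generator, cfg: UniverseConfig, size: int
) -> tuple[np.ndarray, np.ndarray]:
    """(killed, injured) with the all-zero pair rejected and redrawn."""

    def draw(mean: float, disp: float, n: int) -> np.ndarray:
        p = disp / (disp + mean)
        return rng.negative_binomial(disp, p, size=n)

    killed = draw(cfg.fatality_mean, cfg.fatality_dispersion, size)
    injured = draw(cfg.injury_mean, cfg.injury_dispersion, size)
    while True:
        both_zero = (killed == 0) & (injured == 0)
        n_bad = int(both_zero.sum())
        if n_bad == 0:
            return killed, injured
        killed[both_zero] = draw(cfg.fatality_mean, cfg.fatality_dispersion, n_bad)
        injured[both_zero] = draw(cfg.injury_mean, cfg.injury_dispersion, n_bad)


def generate_universe(cfg: UniverseConfig) -> tuple[list[Incident], GroundTruth]:
    """Draw the ground-truth universe; identical seed, identical universe."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    cities = load_cities()
    n = cfg.n_incidents
    gt = GroundTruth()
    if n == 0:
        return [], gt

    start = cfg.date_start + timedelta(days=cfg.date_margin_days)
    end = cfg.date_end - timedelta(days=cfg.date_margin_days)
    span = (end - start).days + 1
    offsets = rng.integers(0, span, size=n)
    city_idx = rng.integers(0, len(cities), size=n)
    killed, injured = _zt_counts(rng, cfg, n)
    two_shooters = rng.random(n) < cfg.p_two_shooters
    perp_dies = rng.random(n) < cfg.p_perp_dies
    motive_names = [m for m, _ in cfg.motive_probs]
    motives = rng.choice(
        len(motive_names), size=n, p=[p for _, p in cfg.motive_probs]
    )
    location_names = [l for l, _ in cfg.location_probs]
    locations = rng.choice(
        len(location_names), size=n, p=[p for _, p in cfg.location_probs]
    )

    incidents: list[Incident] = []
    for i in range(n):
        n_shooters = 2 if two_shooters[i] else 1
        names = [
            f"{_FIRST_NAMES[rng.integers(len(_FIRST_NAMES))]} "
            f"{_LAST_NAMES[rng.integers(len(_LAST_NAMES))]}"
            for _ in range(n_shooters)
        ]
        city, state = cities[city_idx[i]]
        inc = Incident(
            incident_id=f"INC{i:05d}",
            date=start + timedelta(days=int(offsets[i])),
            state=state,
            city=city,
            shooter_names=names,
            n_shooters=n_shooters,
            killed_excl_perp=int(killed[i]),
            injured_excl_perp=int(injured[i]),
            perp_died=bool(perp_dies[i]),
            motive=Motive[motive_names[motives[i]]],
            location_type=LocationType[location_names[locations[i]]],
        )
        incidents.append(inc)
        gt.incidents[inc.incident_id] = inc
    return incidents, gt


# --- emission ---------------------------------------------------------------

def _typo(city: str, rng: np.random.Generator) -> str:
    """One-character perturbation: substitute, delete or duplicate."""
    if len(city) < 2:
        return city + "e"
    pos = int(rng.integers(len(city)))
    op = int(rng.integers(3))
    if op == 0:
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        repl = alphabet[int(rng.integers(26))]
        while repl == city[pos].lower():
            repl = alphabet[int(rng.integers(26))]
        return city[:pos] + repl + city[pos + 1 :]
    if op == 1:
        return city[:pos] + city[pos + 1 :]
    return city[:pos] + city[pos] + city[pos:]


def emit_source(
    incidents: list[Incident],
    model: SourceModel,
    seed: int,
) -> list[Emission]:
    """One source's listing of the universe.

    Eligibility is decided on the *true* fields (an incident ineligible under
    the model's definition is never emitted); detection then thins eligible
    incidents; perturbations are applied independently per field per emitted
    record.  A perturbed count may cross the eligibility threshold — that is
    the realistic case of one database's listed count disagreeing with
    another's.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    source = model.source
    dialect = builtin_dialect(source)
    emissions: list[Emission] = []
    counter = 0
    for inc in incidents:
        if not evaluate(inc.to_record(source), model.definition).eligible:
            continue
        if rng.random() >= model.detection_prob:
            continue
        counter += 1
        perturbed: list[str] = []

        date = inc.date
        if rng.random() < model.p_date_shift:
            date = date + timedelta(days=1 if rng.random() < 0.5 else -1)
            perturbed.append("date")
        city = inc.city
        if rng.random() < model.p_city_typo:
            city = _typo(city, rng)
            perturbed.append("city")
        killed, injured = inc.killed_excl_perp, inc.injured_excl_perp
        if rng.random() < model.p_count_off_by_one:
            delta = 1 if rng.random() < 0.5 else -1
            if rng.random() < 0.5:
                killed = max(killed + delta, 0)
                perturbed.append("killed_excl_perp")
            else:
                injured = max(injured + delta, 0)
                perturbed.append("injured_excl_perp")
        names = list(inc.shooter_names)
        has_name_col = dialect.column_for("shooter_names") is not None
        if has_name_col and rng.random() < model.p_missing_name:
            names = []
            perturbed.append("shooter_names")
        if not has_name_col:
            names = []

        emissions.append(
            _build_emission(
                inc, model, counter, date, city, killed, injured, names,
                tuple(perturbed),
            )
        )
    return emissions


def _build_emission(
    inc: Incident,
    model: SourceModel,
    counter: int,
    date: Date,
    city: str,
    killed: int,
    injured: int,
    names: list[str],
    perturbed: tuple[str, ...],
) -> Emission:
    source = model.source
    dialect = builtin_dialect(source)
    state_full = USPS_TO_STATE[inc.state]
    if source is Source.SHR:
        agency = f"{inc.city} Police Department"
        incident_num = f"{counter:05d}"
        source_id = f"{agency}-{incident_num}-{date.isoformat()}"
        injured_out: int | None = None
        perp_died: bool | None = None
        state_out = state_full
        location = LocationType.UNKNOWN
    else:
        source_id = f"{source.value}-{counter:05d}"
        injured_out = injured
        perp_died = inc.perp_died
        state_out = (
            inc.state if source in (Source.EVERYTOWN, Source.MJ) else state_full
        )
        location = (
            inc.location_type
            if dialect.column_for("location_type") is not None
            else LocationType.UNKNOWN
        )

    expected = SourceRecord(
        source_id=source_id,
        source=source,
        date=date,
        state=state_out,
        city=city,
        shooter_names=names,
        n_shooters=inc.n_shooters,
        killed_excl_perp=killed,
        injured_excl_perp=injured_out,
        perp_died=perp_died,
        motive_tags=frozenset({inc.motive}),
        location_type=location,
    )
    return Emission(inc.incident_id, source, source_id, expected, perturbed)


def write_source_csv(emissions: list[Emission], model: SourceModel, path) -> int:
    """Write emissions as the source's dialect CSV; returns data-row count."""
    source = model.source
    dialect = builtin_dialect(source)
    columns = list(dialect.column_map.keys())
    n_rows = 0
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=columns)
        w.writeheader()
        for e in emissions:
            for row in _emission_rows(e, dialect):
                w.writerow(row)
                n_rows += 1
    return n_rows


def _emission_rows(e: Emission, dialect: SourceDialect) -> list[dict]:
    r = e.expected
    date_str = r.date.strftime(dialect.date_format)
    motive = MOTIVE_STRINGS[next(iter(r.motive_tags))]
    if dialect.source is Source.SHR:
        # victim-level: one row per decedent; the id suffix is the ISO date
        agency, num = e.source_id[: -len("-YYYY-MM-DD")].rsplit("-", 1)
        rows = []
        for _ in range(r.killed_excl_perp):
            rows.append(
                {
                    "Agency": agency,
                    "Incident": num,
                    "Date": date_str,
                    "State": r.state,
                    "City": r.city,
                    "Offender Name": "; ".join(r.shooter_names),
                    "Offender Count": r.n_shooters,
                    "Weapon": _FIREARM_WEAPONS[
                        sum(ord(c) for c in e.source_id) % len(_FIREARM_WEAPONS)
                    ],
                    "Circumstance": motive,
                }
            )
        return rows

    outcome = _PERP_OUTCOME[dialect.source]
    perp_str = outcome[0] if r.perp_died else outcome[1]
    location = LOCATION_STRINGS[r.location_type]
    if dialect.source is Source.ASR:
        return [
            {
                "Incident #": r.source_id,
                "Date": date_str,
                "State": r.state,
                "City": r.city,
                "Shooter": "; ".join(r.shooter_names),
                "Number of Shooters": r.n_shooters,
                "Killed": r.killed_excl_perp,
                "Wounded": r.injured_excl_perp,
                "Shooter Outcome": perp_str,
                "Circumstances": motive,
                "Location": location,
            }
        ]
    if dialect.source is Source.MJ:
        return [
            {
                "case": r.source_id,
                "location": f"{r.city}, {r.state}",
                "date": date_str,
                "shooter": "; ".join(r.shooter_names),
                "shooters": r.n_shooters,
                "fatalities": r.killed_excl_perp,
                "injured": r.injured_excl_perp,
                "shooter_outcome": perp_str,
                "motive_category": motive,
                "location_type": location,
            }
        ]
    if dialect.source is Source.EVERYTOWN:
        # export counts the shooter among the dead
        killed_incl = r.killed_excl_perp + (1 if r.perp_died else 0)
        return [
            {
                "Incident ID": r.source_id,
                "Date": date_str,
                "State": r.state,
                "City": r.city,
                "Shooter Names": "; ".join(r.shooter_names),
                "Number of Shooters": r.n_shooters,
                "People Killed": killed_incl,
                "People Wounded": r.injured_excl_perp,
                "Shooter Killed": perp_str,
                "Circumstance": motive,
                "Location Type": location,
            }
        ]
    # GVA
    return [
        {
            "Incident ID": r.source_id,
            "Incident Date": date_str,
            "State": r.state,
            "City Or County": r.city,
            "# Killed": r.killed_excl_perp,
            "# Injured": r.injured_excl_perp,
            "# Subjects-Suspects": r.n_shooters,
            "Suspect Outcome": perp_str,
            "Incident Characteristics": motive,
        }
    ]


# --- bundle + oracles -------------------------------------------------------

def generate_bundle(
    cfg: UniverseConfig,
    out_dir,
    models: dict[Source, SourceModel] | None = None,
) -> GroundTruth:
    """Universe + five dialect CSVs + ground-truth JSONL under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = models or default_source_models()
    incidents, gt = generate_universe(cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(Source) + 1)
    for i, source in enumerate(Source):
        model = models[source]
        emissions = emit_source(
            incidents, model, seed=seeds[i + 1].generate_state(1)[0] % (2**31)
        )
        gt.emissions[source] = emissions
        write_source_csv(emissions, model, out / f"{source.value.lower()}.csv")
    write_ground_truth(gt, out / "ground_truth.jsonl")
    return gt


def write_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inc in gt.incidents.values():
            d = asdict(inc)
            d["date"] = inc.date.isoformat()
            d["motive"] = inc.motive.value
            d["location_type"] = inc.location_type.value
            d["emissions"] = {
                s.value: [
                    e.source_id
                    for e in gt.emissions.get(s, [])
                    if e.incident_id == inc.incident_id
                ]
                for s in gt.emissions
            }
            fh.write(json.dumps(d) + "\n")


def true_overlap(gt: GroundTruth, sources: list[Source] | None = None):
    """Overlap summary computed directly from ground truth, bypassing linkage."""
    from .overlap import OverlapSummary
    from .records import SOURCE_ORDER

    sources = list(sources) if sources is not None else list(SOURCE_ORDER)
    names = tuple(s.value for s in sources)
    counts: dict[tuple[str, ...], int] = {}
    total = 0
    for listed in gt.membership().values():
        subset = tuple(s.value for s in sources if s in listed)
        if subset:
            counts[subset] = counts.get(subset, 0) + 1
            total += 1
    return OverlapSummary(counts, total, names)


def pairwise_precision_recall(
    clusters, gt: GroundTruth
) -> tuple[float, float]:
    """Pairwise precision/recall of predicted clusters vs ground truth.

    Both are restricted to records the clustering actually saw, so records
    dropped upstream do not count against recall.
    """
    seen = {m.key for c in clusters for m in c.members}
    truth = {p for p in gt.true_match_pairs() if p <= seen}
    predicted: set[frozenset] = set()
    for c in clusters:
        keys = [m.key for m in c.members]
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                predicted.add(frozenset((keys[i], keys[j])))
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
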