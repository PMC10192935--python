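"""Shared fixtures: record builders and synthetic bundles on disk."""

from __future__ import annotations

from datetime import date as Date

import pytest

from masslink import (
    PipelineConfig,
    Source,
    SourceRecord,
    UniverseConfig,
    default_source_models,
    generate_bundle,
)
from masslink.records import LocationType, Motive


def make_record(
    source=Source.GVA,
    source_id="r1",
    date=Date(2015, 6, 1),
    state="TX",
    city="Houston",
    shooter_names=("John Smith",),
    n_shooters=1,
    killed=4,
    injured=2,
    perp_died=False,
    motives=(Motive.OTHER,),
    location=LocationType.PUBLIC,
    **kwargs,
) -> SourceRecord:
    return SourceRecord(
        source_id=source_id,
        source=source,
        date=date,
        state=state,
        city=city,
        shooter_names=list(shooter_names),
        n_shooters=n_shooters,
        killed_excl_perp=killed,
        injured_excl_perp=injured,
        perp_died=perp_died,
        motive_tags=frozenset(motives),
        location_type=location,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """300-incident bundle, perfect detection, no perturbations."""
    out = tmp_path_factory.mktemp("clean_bundle")
    gt = generate_bundle(
        UniverseConfig(n_incidents=300, seed=7),
        out,
        default_source_models(detection_prob=1.0, perturbation=0.0),
    )
    return out, gt


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """400-incident bundle with default detection and perturbation rates."""
    out = tmp_path_factory.mktemp("noisy_bundle")
    gt = generate_bundle(UniverseConfig(n_incidents=400, seed=11), out)
    return out, gt


def bundle_config(out, **kwargs) -> PipelineConfig:
    return PipelineConfig(
        source_paths={s: out / f"{s.value.lower()}.csv" for s in Source},
        **kwargs,
    )
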