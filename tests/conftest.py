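"""Shared fixtures: a hand-built toy registry and seeded synthetic cohorts."""

from __future__ import annotations

import pytest
from hypothesis import settings

from ohca_partition import SyntheticConfig, generate_cohort
from ohca_partition.registry_io import Cohort, OHCARecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def _record(**overrides) -> OHCARecord:
    """A fully plausible adult witnessed-arrest record; override per test."""
    base = dict(
        age=70,
        sex="male",
        witnessed=True,
        bystander_cpr="chest_compression_only",
        bystander_category="family",
        aed_by_bystander=False,
        dispatcher_assist=True,
        initial_rhythm="VF",
        dc_by_ems=False,
        defibrillator_kind="none",
        airway_tool="none",
        iv_by_ems=False,
        epinephrine_by_ems=False,
        cardiac_cause=True,
        t_cpr=2,
        t_amb=9,
        t_hosp=30,
        t_rosc=None,
        survival_1mo=False,
        cpc=5,
    )
    base.update(overrides)
    return OHCARecord(**base)


@pytest.fixture
def make_record():
    return _record


@pytest.fixture
def toy_cohort() -> Cohort:
    """12 records: 2 unwitnessed, 1 without CPR, 1 mouth-to-mouth only,
    1 minor, 1 with missing outcome, 6 clean (2 of them with ROSC)."""
    records = [
        _record(witnessed=False),
        _record(witnessed=False),
        _record(bystander_cpr="none"),
        _record(bystander_cpr="mouth_to_mouth_only"),
        _record(age=17),
        _record(cpc=None, survival_1mo=True),
        _record(cpc=1, survival_1mo=True, t_rosc=12),
        _record(cpc=2, survival_1mo=True, t_rosc=20),
        _record(),
        _record(t_cpr=0, t_amb=7, t_hosp=22),
        _record(t_cpr=5, t_amb=11, t_hosp=19, cpc=1, survival_1mo=True),
        _record(t_cpr=10, t_amb=20, t_hosp=60),
    ]
    return Cohort.from_records(records, provenance="toy")


@pytest.fixture(scope="session")
def clean_cohort() -> Cohort:
    """Contamination-free synthetic cohort, moderate size."""
    cohort, _ = generate_cohort(SyntheticConfig(n=5_000, seed=7))
    return cohort


@pytest.fixture(scope="session")
def clean_cohort_truth():
    cohort, truth = generate_cohort(SyntheticConfig(n=5_000, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def registry_cohort() -> Cohort:
    """Raw-registry-like cohort with the full contamination mix."""
    cohort, _ = generate_cohort(SyntheticConfig.registry_like(n=10_000, seed=11))
    return cohort
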