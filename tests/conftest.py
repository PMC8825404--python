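"""Shared fixtures and randomized-record generators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adhocscore.records import AisItem, BODY_REGIONS, PatientRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_record(rng: np.random.Generator, missing_prob: float = 0.25) -> PatientRecord:
    """A random, always-valid patient record with realistic missingness.

    Values deliberately include the exact score thresholds (age 65, GCS 12,
    BE -6, SBP 90, INR 1.4, Hb 7, Horowitz 200) so boundary semantics get
    exercised by every randomized suite.
    """

    def maybe(value):
        return None if rng.random() < missing_prob else value

    def pick(values):
        v = values[rng.integers(len(values))]
        return v

    rec = PatientRecord(
        id=f"r{rng.integers(10**9)}",
        age=maybe(int(rng.integers(16, 101))),
        sex=maybe(pick(["male", "female", "other"])),
        mechanism=maybe(pick(["blunt", "penetrating"])),
        gcs=maybe(int(rng.integers(3, 16))),
        ecs_motor=maybe(pick(["normal", "non_specific", "none"])),
        ecs_pupil_size=maybe(pick(["normal", "not_normal"])),
        ecs_pupil_reactivity=maybe(pick(["normal", "not_normal"])),
        base_excess=maybe(pick([-12.0, -6.0, -5.9, -2.5, 0.0, 3.0])),
        intubated=maybe(bool(rng.random() < 0.4)),
        pao2_fio2=maybe(pick([80.0, 200.0, 200.1, 350.0])),
        hemothorax=maybe(bool(rng.random() < 0.15)),
        sbp=maybe(pick([60.0, 90.0, 91.0, 120.0, 150.0])),
        hb=maybe(pick([5.0, 6.9, 7.0, 11.0, 15.0])),
        inr=maybe(pick([0.9, 1.4, 1.5, 2.5])),
        prbc_transfused=maybe(bool(rng.random() < 0.2)),
        fracture_pelvis=maybe(bool(rng.random() < 0.5)),
        fracture_femur=maybe(bool(rng.random() < 0.4)),
        fracture_tibia=maybe(bool(rng.random() < 0.35)),
        secondary_admission=maybe(bool(rng.random() < 0.05)),
        transferred_out_within_48h=maybe(bool(rng.random() < 0.05)),
        died=maybe(bool(rng.random() < 0.12)),
        mof=maybe(bool(rng.random() < 0.25)),
        icu_los=maybe(round(float(rng.exponential(8.0)), 1)),
        hosp_los=maybe(round(float(rng.exponential(20.0)), 1)),
    )
    if rng.random() < 0.5:
        n_items = int(rng.integers(1, 5))
        rec.ais_items = [
            AisItem(BODY_REGIONS[rng.integers(len(BODY_REGIONS))], int(rng.integers(1, 6)))
            for _ in range(n_items)
        ]
    if rng.random() < 0.3:
        rec.extras = {"hr": str(int(rng.integers(40, 160))), "site": "A"}
    return rec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture
def random_cohort(rng) -> list[PatientRecord]:
    return [random_record(rng) for _ in range(200)]
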