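import math

import pytest
from hypothesis import HealthCheck, settings

from airmorph import (
    AirwayMeasurement,
    CohortDataset,
    LungVolumeRecord,
    MatchedAirway,
    SimulatorConfig,
    generate_cohort,
)
from airmorph.pipeline import analyze_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def circular_measurement(subject="S01", label="RB1", state="MLV", radius=2.0, din=None):
    """A perfectly circular lumen of the given radius (mm)."""
    return AirwayMeasurement(
        subject_id=subject,
        label=label,
        state=state,
        din=din if din is not None else 2 * radius,
        ai=math.pi * radius**2,
        pi=2 * math.pi * radius,
    )


def matched(subject="S01", label="RB1", ai_mlv=10.0, ai_tlc=13.0, radius=2.0):
    """A matched airway with prescribed lumen areas (circle-consistent
    perimeter/diameter scaled accordingly)."""

    def meas(state, ai):
        r = math.sqrt(ai / math.pi)
        return AirwayMeasurement(
            subject_id=subject, label=label, state=state, din=2 * r, ai=ai, pi=2 * math.pi * r
        )

    return MatchedAirway(
        subject_id=subject, label=label, mlv=meas("MLV", ai_mlv), tlc=meas("TLC", ai_tlc)
    )


def assert_measurements_close(left, right, rel=1e-12):
    """Equality of measurement lists up to float serialization (spreadsheet
    writers round at ~16 significant digits)."""
    assert len(left) == len(right)
    for a, b in zip(left, right):
        assert (a.subject_id, a.label, a.state) == (b.subject_id, b.label, b.state)
        for field in ("din", "ai", "pi"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=rel)
        for field in ("wt", "po"):
            va, vb = getattr(a, field), getattr(b, field)
            assert (va is None) == (vb is None)
            if va is not None:
                assert va == pytest.approx(vb, rel=rel)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed fixed) shared across tests."""
    return generate_cohort(SimulatorConfig(), seed=0)


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    dataset, _ = default_cohort
    return analyze_dataset(dataset)


@pytest.fixture()
def tiny_dataset():
    """Two subjects, a handful of airways, both states, plus volumes."""
    measurements = []
    for subject in ("S01", "S02"):
        for label, radius in (("T", 8.0), ("RB1", 2.0), ("LB10", 1.8), ("RU", 4.0)):
            for state, scale in (("MLV", 1.0), ("TLC", 1.15)):
                measurements.append(
                    circular_measurement(subject, label, state, radius * scale)
                )
    volumes = [
        LungVolumeRecord(subject_id=s, side=side, v_mlv=v, v_tlc=v * 1.8)
        for s in ("S01", "S02")
        for side, v in (("right", 1.3), ("left", 1.1))
    ]
    return CohortDataset(measurements=measurements, volumes=volumes, provenance="fixture").validate()
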