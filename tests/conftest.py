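"""Shared fixtures: small seeded study designs and archives."""

import pytest

from ionarchive import (
    CompoundSpec,
    InstrumentModel,
    SampleRecord,
    StudyDesign,
    init_store,
)
from ionarchive.synthetic import (
    default_design,
    default_internal_standards,
    simulate_archive,
)


def make_sample(sid: str, stype: str = "case", batch: str = "batch000",
                acquired: str = "2014-01-06T00:00:00") -> SampleRecord:
    return SampleRecord(
        sample_id=sid,
        run_name="run000",
        uid=f"uid-{sid}",
        file_path=f"/data/{sid}.raw",
        sample_type=stype,
        instrument_id="MS1",
        acquired_at=acquired,
        batch_id=batch,
    )


@pytest.fixture
def store():
    return init_store(":memory:")


@pytest.fixture
def quiet_instrument():
    """Noise-free instrument: measured values equal theory exactly."""
    return InstrumentModel(
        mass_sd=0.0, rt_sd=0.0, intensity_cv=0.0, fragment_yield_sd=0.0,
        detection_floor=1.0,
    )


@pytest.fixture
def small_design():
    return default_design(seed=7, n_batches=2, cases_per_batch=8)


@pytest.fixture
def small_archive(small_design):
    return simulate_archive(small_design)


@pytest.fixture
def zero_noise_design(quiet_instrument):
    return StudyDesign(
        n_batches=2,
        cases_per_batch=5,
        internal_standards=default_internal_standards(),
        qc_mix=tuple(
            CompoundSpec(name=f"qc_{i}", neutral_mass=200.0 + 10.0 * i,
                         rt=2.0 + i, carbon_count=10,
                         fragments=((100.0 + 5.0 * i, 0.5),))
            for i in range(5)
        ),
        instruments=(quiet_instrument,),
        contaminant_rate=0.0,
        seed=11,
    )
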