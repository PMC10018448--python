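"""Seeded generator of componentized LC-HRMS(E) runs with ground truth.

The generator emulates the statistical structure of data-independent MSE
acquisition after upstream componentization: for every compound present in an
injection it emits one component holding the low-energy ions (protonated
molecule, M+1 isotope, declared adducts and in-source fragments) and the
high-energy ions (residual precursor and diagnostic fragments), all sharing
one measured retention time. Measured masses carry Gaussian noise, retention
times carry per-batch drift plus Gaussian noise, and intensities carry
lognormal multiplicative noise. A homogeneous Poisson background of
contaminant ions is overlaid. Everything is a pure function of
``(design.seed, batch_index)``.

Simplifications relative to real instrument output (deliberate): only the
M+1 isotope is modeled (abundance 1.07% per carbon); no chromatographic peak
shapes; one shared RT per compound and injection, so within-component
co-elution is exact.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .config import RUN_TIME_MIN, ToleranceConfig
from .ingest import ComponentIon, ComponentRecord, QCReport, ingest_run, qc_gate
from .screening import TargetDefinition
from .store import PeakRecord, SampleRecord, Store, init_store

__all__ = [
    "PROTON_MASS",
    "ISOTOPE_SPACING",
    "ISOTOPE_ABUNDANCE_PER_CARBON",
    "RESIDUAL_PRECURSOR_FRACTION",
    "CompoundSpec",
    "InstrumentModel",
    "StudyDesign",
    "simulate_run",
    "simulate_archive",
    "target_for",
    "case_truth_table",
    "default_internal_standards",
    "default_qc_mix",
    "default_design",
]

PROTON_MASS = 1.007276  # Da, mass of H+ (electron removed)
ISOTOPE_SPACING = 1.003355  # Da, 13C - 12C
ISOTOPE_ABUNDANCE_PER_CARBON = 0.0107  # natural 13C abundance
RESIDUAL_PRECURSOR_FRACTION = 0.3  # intact precursor surviving the high-energy scan

ALL_ROLES = frozenset({"precursor", "adduct", "insource_fragment", "fragment"})


@dataclasses.dataclass(frozen=True)
class CompoundSpec:
    """Chemistry of one simulated analyte.

    ``fragments``/``insource_fragments`` are (m/z, relative intensity) pairs,
    relative to the measured precursor intensity. ``adducts`` are
    (label, mass shift from the neutral molecule, relative intensity), e.g.
    ``("[M+NH4]+", 18.033823, 0.2)``.
    """

    name: str
    neutral_mass: float
    rt: float
    carbon_count: int = 0
    fragments: tuple[tuple[float, float], ...] = ()
    adducts: tuple[tuple[str, float, float], ...] = ()
    insource_fragments: tuple[tuple[float, float], ...] = ()
    base_intensity: float = 1e5

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError("neutral_mass must be > 0")
        if self.carbon_count < 0:
            raise ValueError("carbon_count must be >= 0")
        if self.rt < 0:
            raise ValueError("rt must be >= 0")

    @property
    def precursor_mz(self) -> float:
        """[M+H]+ m/z."""
        return self.neutral_mass + PROTON_MASS

    @classmethod
    def from_formula(cls, name: str, formula: str, rt: float, **kw) -> "CompoundSpec":
        """Build a spec from a molecular formula (monoisotopic mass via
        atomic masses; deuterium written ``H[2]``)."""
        comp = _ptmass.Composition(formula=formula)
        return cls(
            name=name,
            neutral_mass=_ptmass.calculate_mass(composition=comp),
            rt=rt,
            carbon_count=comp.get("C", 0),
            **kw,
        )


DriftSpec = Union[float, Sequence[float], Callable[[int], float]]


@dataclasses.dataclass(frozen=True)
class InstrumentModel:
    """Measurement-noise model of one instrument.

    ``rt_drift_per_batch`` may be a constant slope (minutes per batch index),
    a sequence indexed by batch (a step function emulating maintenance
    events), or a callable batch -> shift.
    """

    instrument_id: str = "MS1"
    mass_sd: float = 0.0005  # Da
    rt_sd: float = 0.05  # minutes
    rt_drift_per_batch: DriftSpec = 0.0
    intensity_cv: float = 0.2
    detection_floor: float = 50.0  # counts
    fragment_yield_sd: float = 0.1

    def __post_init__(self) -> None:
        for f in ("mass_sd", "rt_sd", "intensity_cv", "fragment_yield_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def drift_at(self, batch_index: int) -> float:
        d = self.rt_drift_per_batch
        if callable(d):
            return float(d(batch_index))
        if isinstance(d, (list, tuple)):
            return float(d[min(batch_index, len(d) - 1)]) if d else 0.0
        return float(d) * batch_index


@dataclasses.dataclass(frozen=True)
class DosedCompound:
    """A compound administered to a fraction of the cases, detectable only
    through the declared subset of ion roles."""

    compound: CompoundSpec
    positive_fraction: float
    detectable_as: frozenset[str] = ALL_ROLES

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not frozenset(self.detectable_as) <= ALL_ROLES:
            raise ValueError(f"detectable_as must be a subset of {set(ALL_ROLES)}")
        object.__setattr__(self, "detectable_as", frozenset(self.detectable_as))


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """Layout of a simulated acquisition campaign.

    Every batch contains one blank matrix, one internal-standard blank,
    ``n_qc_injections`` methanolic QC injections (the standards-mix
    injections run within each batch) and ``cases_per_batch`` case samples.
    Instruments rotate across batches.
    """

    n_batches: int
    cases_per_batch: int
    internal_standards: tuple[CompoundSpec, ...]
    qc_mix: tuple[CompoundSpec, ...]
    instruments: tuple[InstrumentModel, ...]
    dosed_compound: Optional[DosedCompound] = None
    contaminant_rate: float = 20.0  # expected background ions per sample
    seed: int = 0
    run_time: float = RUN_TIME_MIN
    n_blanks_per_batch: int = 1
    n_qc_injections: int = 3

    def __post_init__(self) -> None:
        if self.n_batches < 0 or self.cases_per_batch < 0:
            raise ValueError("batch counts must be >= 0")
        if not self.internal_standards:
            raise ValueError("at least one internal standard is required")
        if not self.instruments:
            raise ValueError("at least one instrument is required")
        if self.n_blanks_per_batch < 1 or self.n_qc_injections < 1:
            raise ValueError("every batch needs blanks and a methanolic QC")


_TRUTH_COLS = [
    "sample_id",
    "batch_id",
    "compound",
    "role",
    "channel",
    "mz_true",
    "rt_true",
    "present",
]


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative intensity noise with unit mean and the given CV."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _emit_compound(
    compound: CompoundSpec,
    sample_id: str,
    batch_id: str,
    component_id: int,
    instrument: InstrumentModel,
    drift: float,
    run_time: float,
    rng: np.random.Generator,
    roles: frozenset[str],
    truth_rows: list,
) -> Optional[ComponentRecord]:
    """Emit one component (both channels) for a compound in one injection."""

    def mznoise() -> float:
        return float(rng.normal(0.0, instrument.mass_sd)) if instrument.mass_sd else 0.0

    rt_true = compound.rt
    rt_meas = rt_true + drift
    if instrument.rt_sd:
        rt_meas += float(rng.normal(0.0, instrument.rt_sd))
    rt_meas = float(np.clip(rt_meas, 0.0, run_time))

    prec_int = compound.base_intensity * _lognormal_factor(rng, instrument.intensity_cv)
    floor = instrument.detection_floor

    ions: list[ComponentIon] = []

    def plant(mz_true: float, intensity: float, channel: str, role: str) -> None:
        visible = intensity >= floor
        if visible:
            ions.append(
                ComponentIon(mz_true + mznoise(), rt_meas, intensity, channel, role)
            )
        truth_rows.append(
            (sample_id, batch_id, compound.name, role, channel, mz_true, rt_true, visible)
        )

    if "precursor" in roles:
        plant(compound.precursor_mz, prec_int, "low", "precursor")
        if compound.carbon_count > 0:
            plant(
                compound.precursor_mz + ISOTOPE_SPACING,
                prec_int * ISOTOPE_ABUNDANCE_PER_CARBON * compound.carbon_count,
                "low",
                "isotope",
            )
        plant(
            compound.precursor_mz,
            prec_int * RESIDUAL_PRECURSOR_FRACTION,
            "high",
            "residual_precursor",
        )
    if "adduct" in roles:
        for _label, shift, rel in compound.adducts:
            plant(compound.neutral_mass + shift, prec_int * rel, "low", "adduct")
    if "insource_fragment" in roles:
        for mz, rel in compound.insource_fragments:
            plant(mz, prec_int * rel, "low", "insource_fragment")
    if "fragment" in roles:
        for mz, rel in compound.fragments:
            yld = rel
            if instrument.fragment_yield_sd:
                yld = rel * max(0.0, 1.0 + float(rng.normal(0.0, instrument.fragment_yield_sd)))
            plant(mz, prec_int * yld, "high", "fragment")

    if not ions:
        return None
    return ComponentRecord(component_id, sample_id, ions)


def simulate_run(
    design: StudyDesign, batch_index: int
) -> tuple[list[SampleRecord], list[ComponentRecord], pd.DataFrame]:
    """Simulate one batch (analytical run).

    Returns the sample records, the componentized peak data and a truth table
    with one row per planted ion (columns ``sample_id, batch_id, compound,
    role, channel, mz_true, rt_true, present``); ``present`` is False for
    ions that fell below the detection floor. Reproducible: the output is a
    pure function of ``(design.seed, batch_index)``.
    """
    if not 0 <= batch_index:
        raise ValueError("batch_index must be >= 0")
    rng = np.random.default_rng([design.seed, batch_index])
    instrument = design.instruments[batch_index % len(design.instruments)]
    drift = instrument.drift_at(batch_index)
    batch_id = f"batch{batch_index:03d}"
    run_name = f"run{batch_index:03d}"
    t0 = datetime.datetime(2014, 1, 6) + datetime.timedelta(days=batch_index)

    # injection plan: blanks, IS blank, methanolic QCs, then cases
    plan: list[tuple[str, str]] = []
    for i in range(design.n_blanks_per_batch):
        plan.append((f"blank{i}", "blank_matrix"))
    plan.append(("isblank", "internal_standard_blank"))
    for i in range(design.n_qc_injections):
        plan.append((f"qc{i}", "methanolic_qc"))
    for i in range(design.cases_per_batch):
        plan.append((f"case{i:03d}", "case"))

    samples: list[SampleRecord] = []
    components: list[ComponentRecord] = []
    truth_rows: list = []

    for pos, (tag, stype) in enumerate(plan):
        sid = f"{batch_id}.{tag}"
        samples.append(
            SampleRecord(
                sample_id=sid,
                run_name=run_name,
                uid=f"uid-{design.seed}-{batch_index}-{pos}",
                file_path=f"/data/{run_name}/{sid}.raw",
                sample_type=stype,
                instrument_id=instrument.instrument_id,
                acquired_at=(t0 + datetime.timedelta(minutes=15 * pos)).isoformat(),
                batch_id=batch_id,
            )
        )
        cid = 0
        # internal standards are spiked into every sample
        for compound in design.internal_standards:
            comp = _emit_compound(
                compound, sid, batch_id, cid, instrument, drift,
                design.run_time, rng, ALL_ROLES, truth_rows,
            )
            if comp is not None:
                components.append(comp)
                cid += 1
        if stype == "methanolic_qc":
            for compound in design.qc_mix:
                comp = _emit_compound(
                    compound, sid, batch_id, cid, instrument, drift,
                    design.run_time, rng, ALL_ROLES, truth_rows,
                )
                if comp is not None:
                    components.append(comp)
                    cid += 1
        if stype == "case" and design.dosed_compound is not None:
            dosed = design.dosed_compound
            if rng.random() < dosed.positive_fraction:
                comp = _emit_compound(
                    dosed.compound, sid, batch_id, cid, instrument, drift,
                    design.run_time, rng, dosed.detectable_as, truth_rows,
                )
                if comp is not None:
                    components.append(comp)
                    cid += 1
        # homogeneous Poisson contaminant background, one single-ion
        # component per contaminant
        n_cont = int(rng.poisson(design.contaminant_rate))
        if n_cont:
            mzs = rng.uniform(100.0, 1000.0, size=n_cont)
            rts = rng.uniform(0.0, design.run_time, size=n_cont)
            ints = 5e3 * rng.lognormal(0.0, 0.5, size=n_cont)
            for mz, rt, inten in zip(mzs, rts, ints):
                components.append(
                    ComponentRecord(
                        cid,
                        sid,
                        [ComponentIon(float(mz), float(rt), float(inten), "low", "unknown")],
                    )
                )
                cid += 1

    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLS)
    return samples, components, truth


@dataclasses.dataclass
class ArchiveResult:
    store: Store
    truth: pd.DataFrame
    gates: list[QCReport]
    emitted_ions: int  # ions emitted across all batches, refused ones included
    emitted_accepted: int  # ions emitted by batches that passed the gate
    ingested_ions: int


def simulate_archive(
    design: StudyDesign,
    store_path: str = ":memory:",
    config: ToleranceConfig | None = None,
    qc_gate_active: bool = True,
) -> ArchiveResult:
    """Run every batch of the design through the QC gate into a fresh store.

    The returned :class:`ArchiveResult` carries the store, the concatenated
    truth table (only for batches that entered the archive), the per-batch QC
    reports and the generator's own ion bookkeeping.
    """
    config = config or ToleranceConfig()
    store = init_store(store_path)
    standards = [target_for(c, with_fragment=False) for c in design.internal_standards]
    qc_targets = [target_for(c, with_fragment=False) for c in design.qc_mix]
    truths = []
    gates = []
    emitted = emitted_accepted = ingested = 0
    for b in range(design.n_batches):
        samples, components, truth = simulate_run(design, b)
        n_ions = sum(len(c.ions) for c in components)
        emitted += n_ions
        run_peaks = [
            PeakRecord(
                sample_id=c.sample_id,
                mz=i.mz,
                rt=i.rt,
                intensity=i.intensity,
                channel=i.channel,
                component_id=c.component_id,
                ion_role=i.ion_role,
            )
            for c in components
            for i in c.ions
        ]
        if qc_gate_active:
            gate = qc_gate(samples, run_peaks, standards, config, qc_mix=qc_targets)
        else:
            gate = QCReport(samples[0].run_name if samples else "", True, [])
        gates.append(gate)
        stats = ingest_run(store, samples, components, gate)
        if stats.accepted:
            ingested += stats.peaks_inserted
            emitted_accepted += n_ions
            truths.append(truth)
    truth_all = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(columns=_TRUTH_COLS)
    )
    return ArchiveResult(store, truth_all, gates, emitted, emitted_accepted, ingested)


def target_for(
    compound: CompoundSpec, with_fragment: bool = True
) -> TargetDefinition:
    """Screening target for a compound: [M+H]+, library RT, first fragment."""
    frag = compound.fragments[0][0] if (with_fragment and compound.fragments) else None
    return TargetDefinition(
        name=compound.name,
        precursor_mz=compound.precursor_mz,
        library_rt=compound.rt,
        fragment_mz=frag,
    )


def case_truth_table(
    samples: list[SampleRecord] | Store,
    truth: pd.DataFrame,
    compound_name: str,
) -> pd.DataFrame:
    """Per-case truth for one compound: columns sample_id, compound, positive.

    A case is positive when the generator planted the compound in it
    (irrespective of the detection floor — truth is what was dosed, as a
    complementary quantitative method would report it).
    """
    if isinstance(samples, Store):
        case_ids = samples.sample_ids("case")
    else:
        case_ids = [s.sample_id for s in samples if s.sample_type == "case"]
    planted = set(truth.loc[truth["compound"] == compound_name, "sample_id"])
    return pd.DataFrame(
        {
            "sample_id": case_ids,
            "compound": compound_name,
            "positive": [sid in planted for sid in case_ids],
        }
    )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def default_internal_standards() -> tuple[CompoundSpec, ...]:
    """Five deuterated internal standards spanning the RT range."""
    return (
        CompoundSpec.from_formula(
            "amphetamine-d5", "C9H8H[2]5N", rt=3.10,
            fragments=((119.1, 0.6), (91.05, 0.4)),
        ),
        CompoundSpec.from_formula(
            "MDMA-d5", "C11H10H[2]5NO2", rt=3.60,
            fragments=((163.1, 0.7), (105.07, 0.3)),
        ),
        CompoundSpec.from_formula(
            "morphine-d3", "C17H16H[2]3NO3", rt=1.90,
            fragments=((201.09, 0.5), (165.07, 0.3)),
        ),
        CompoundSpec.from_formula(
            "cocaine-d3", "C17H18H[2]3NO4", rt=5.25,
            fragments=((185.12, 0.8), (105.03, 0.2)),
        ),
        CompoundSpec.from_formula(
            "diazepam-d5", "C16H8H[2]5ClN2O", rt=8.40,
            fragments=((198.09, 0.4), (154.04, 0.3)),
        ),
    )


def default_qc_mix(n_compounds: int = 100) -> tuple[CompoundSpec, ...]:
    """A deterministic methanolic QC mix of ~100 compounds.

    The mix is fixed chemistry, not a random draw per study: it is generated
    once from a frozen seed, with masses on [150, 550] Da, retention times on
    [1, 14] min and one diagnostic fragment each.
    """
    rng = np.random.default_rng(20140106)
    specs = []
    masses = np.sort(rng.uniform(150.0, 550.0, size=n_compounds))
    rts = rng.uniform(1.0, 14.0, size=n_compounds)
    for i, (m, rt) in enumerate(zip(masses, rts)):
        frag = m * rng.uniform(0.35, 0.75)
        specs.append(
            CompoundSpec(
                name=f"qc_{i:03d}",
                neutral_mass=round(float(m), 4),
                rt=round(float(rt), 3),
                carbon_count=max(1, int(m / 19.0)),
                fragments=((round(float(frag), 4), 0.5),),
                base_intensity=1e5,
            )
        )
    return tuple(specs)


def default_design(
    seed: int = 0,
    n_batches: int = 3,
    cases_per_batch: int = 20,
    n_instruments: int = 3,
    **overrides,
) -> StudyDesign:
    """The standard desk-scale study: rotating instruments, 100-compound QC
    mix, internal standards in every injection."""
    instruments = tuple(
        InstrumentModel(instrument_id=f"MS{i+1}") for i in range(n_instruments)
    )
    kw = dict(
        n_batches=n_batches,
        cases_per_batch=cases_per_batch,
        internal_standards=default_internal_standards(),
        qc_mix=default_qc_mix(),
        instruments=instruments,
        seed=seed,
    )
    kw.update(overrides)
    return StudyDesign(**kw)
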