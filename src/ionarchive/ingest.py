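"""Parse componentized peak files, flatten them to ion rows, and gate runs.

Upstream vendor processing groups co-eluting ions across the low- and
high-energy channels into *components*. This module reads those components
from an open CSV/JSON dialect, *decomponentizes* them (every ion becomes an
independent archive row, keeping its component id only as provenance), and
admits whole runs to the store only when the run passes a QC gate built from
the quantities routinely monitored in a forensic screening laboratory:
internal standards in every sample, methanolic QC-mix detection rates, and
clean blanks.

Component file dialect (version 1)
----------------------------------
CSV with header ``sample_id,component_id,mz,rt,intensity,channel,ion_role``;
one row per ion, rows of one component contiguous or not. ``channel`` is
``low`` or ``high``; ``ion_role`` may be empty (stored as ``unknown``).
The JSON equivalent is a list of objects
``{"sample_id": ..., "component_id": ..., "ions": [{"mz": ..., "rt": ...,
"intensity": ..., "channel": ..., "ion_role": ...}, ...]}``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import pathlib
from typing import Callable, Optional

from .config import ToleranceConfig
from .screening import TargetDefinition
from .store import CHANNELS, ION_ROLES, PeakRecord, SampleRecord, Store

__all__ = [
    "ComponentIon",
    "ComponentRecord",
    "QCCheck",
    "QCReport",
    "IngestStats",
    "ParseError",
    "parse_component_file",
    "write_component_csv",
    "decomponentize",
    "qc_gate",
    "ingest_run",
]


class ParseError(ValueError):
    """Malformed component file; the message names the offending location."""


@dataclasses.dataclass(frozen=True)
class ComponentIon:
    mz: float
    rt: float
    intensity: float
    channel: str
    ion_role: str = "unknown"


@dataclasses.dataclass
class ComponentRecord:
    """One upstream component: a group of co-eluting ions from both channels."""

    component_id: int
    sample_id: str
    ions: list[ComponentIon]

    def validate(self, coelution_width: float) -> None:
        """Check the component invariants: co-elution and >= 1 low-energy ion."""
        if not self.ions:
            raise ValueError(f"component {self.component_id}: no ions")
        rts = [i.rt for i in self.ions]
        if max(rts) - min(rts) > coelution_width:
            raise ValueError(
                f"component {self.component_id} in {self.sample_id}: "
                f"RT spread {max(rts) - min(rts):.4f} min exceeds "
                f"co-elution width {coelution_width} min"
            )
        if not any(i.channel == "low" for i in self.ions):
            raise ValueError(
                f"component {self.component_id} in {self.sample_id}: "
                "no low-energy ion"
            )


@dataclasses.dataclass(frozen=True)
class QCCheck:
    name: str
    passed: bool
    detail: str


@dataclasses.dataclass(frozen=True)
class QCReport:
    run_name: str
    passed: bool
    checks: list[QCCheck]


@dataclasses.dataclass(frozen=True)
class IngestStats:
    run_name: str
    accepted: bool
    samples_inserted: int
    peaks_inserted: int
    reason: str = ""


_CSV_HEADER = ["sample_id", "component_id", "mz", "rt", "intensity", "channel", "ion_role"]


def _check_ion_fields(mz: float, rt: float, intensity: float, channel: str,
                      ion_role: str, where: str) -> None:
    if channel not in CHANNELS:
        raise ParseError(f"{where}: unknown channel {channel!r}")
    if ion_role not in ION_ROLES:
        raise ParseError(f"{where}: unknown ion_role {ion_role!r}")
    if not mz > 0:
        raise ParseError(f"{where}: mz must be > 0, got {mz}")
    if rt < 0:
        raise ParseError(f"{where}: rt must be >= 0, got {rt}")
    if intensity < 0:
        raise ParseError(f"{where}: intensity must be >= 0, got {intensity}")


def parse_component_file(
    path: str | pathlib.Path,
    coelution_width: Optional[float] = None,
) -> list[ComponentRecord]:
    """Parse a component CSV or JSON file into :class:`ComponentRecord` lists.

    Ion count is preserved exactly; malformed rows raise :class:`ParseError`
    naming the line (CSV) or component index (JSON). ``coelution_width``
    (minutes, default: the standard co-elution tolerance) bounds the RT
    spread allowed inside one component.
    """
    path = pathlib.Path(path)
    if coelution_width is None:
        coelution_width = ToleranceConfig().coelution_tol
    if path.suffix.lower() == ".json":
        comps = _parse_json(path)
    else:
        comps = _parse_csv(path)
    for c in comps:
        c.validate(coelution_width)
    return comps


def _parse_csv(path: pathlib.Path) -> list[ComponentRecord]:
    by_key: dict[tuple[str, int], ComponentRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file (missing header)") from None
        if [h.strip() for h in header] != _CSV_HEADER:
            raise ParseError(
                f"{path}:1: bad header {header!r}, expected {_CSV_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            where = f"{path}:{lineno}"
            if len(row) != len(_CSV_HEADER):
                raise ParseError(f"{where}: expected {len(_CSV_HEADER)} fields")
            sid, cid_s, mz_s, rt_s, int_s, channel, role = (c.strip() for c in row)
            try:
                cid = int(cid_s)
                mz, rt, inten = float(mz_s), float(rt_s), float(int_s)
            except ValueError as exc:
                raise ParseError(f"{where}: {exc}") from None
            role = role or "unknown"
            _check_ion_fields(mz, rt, inten, channel, role, where)
            key = (sid, cid)
            if key not in by_key:
                by_key[key] = ComponentRecord(cid, sid, [])
            by_key[key].ions.append(ComponentIon(mz, rt, inten, channel, role))
    return list(by_key.values())


def _parse_json(path: pathlib.Path) -> list[ComponentRecord]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ParseError(f"{path}: top level must be a list of components")
    comps = []
    for i, obj in enumerate(data):
        where = f"{path}: component[{i}]"
        try:
            cid = int(obj["component_id"])
            sid = str(obj["sample_id"])
            ions_raw = obj["ions"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{where}: {exc}") from None
        ions = []
        for j, ion in enumerate(ions_raw):
            iwhere = f"{where}.ions[{j}]"
            try:
                mz, rt = float(ion["mz"]), float(ion["rt"])
                inten = float(ion["intensity"])
                channel = str(ion["channel"])
                role = str(ion.get("ion_role") or "unknown")
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{iwhere}: {exc}") from None
            _check_ion_fields(mz, rt, inten, channel, role, iwhere)
            ions.append(ComponentIon(mz, rt, inten, channel, role))
        comps.append(ComponentRecord(cid, sid, ions))
    return comps


def write_component_csv(
    components: list[ComponentRecord], path: str | pathlib.Path
) -> None:
    """Write components in the version-1 CSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for c in components:
            for ion in c.ions:
                writer.writerow(
                    [
                        c.sample_id,
                        c.component_id,
                        f"{ion.mz:.6f}",
                        f"{ion.rt:.4f}",
                        f"{ion.intensity:.2f}",
                        ion.channel,
                        ion.ion_role,
                    ]
                )


def decomponentize(components: list[ComponentRecord]) -> list[PeakRecord]:
    """Flatten components into independent ion rows.

    Output length equals the total ion count; nothing is merged, dropped or
    averaged. The component id travels along as provenance only.
    """
    peaks = []
    for c in components:
        for ion in c.ions:
            peaks.append(
                PeakRecord(
                    sample_id=c.sample_id,
                    mz=ion.mz,
                    rt=ion.rt,
                    intensity=ion.intensity,
                    channel=ion.channel,
                    component_id=c.component_id,
                    ion_role=ion.ion_role,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# QC gate
# ---------------------------------------------------------------------------

#: sample types that must contain every internal standard (check a)
_IS_CHECKED_TYPES = ("case", "internal_standard_blank", "methanolic_qc")
#: sample types that must be free of QC-mix compounds (check c)
_BLANK_TYPES = ("blank_matrix", "internal_standard_blank")


def _present(
    peaks_by_sample: dict[str, list[PeakRecord]],
    sid: str,
    target: TargetDefinition,
    mass_tol: float,
    rt_tol: float,
    intensity_floor: float = 0.0,
) -> bool:
    for p in peaks_by_sample.get(sid, []):
        if p.channel != "low":
            continue
        if abs(p.mz - target.precursor_mz) > mass_tol:
            continue
        if (
            target.library_rt is not None
            and abs(p.rt - target.library_rt) > rt_tol
        ):
            continue
        if p.intensity < intensity_floor:
            continue
        return True
    return False


def qc_gate(
    run_samples: list[SampleRecord],
    run_peaks: list[PeakRecord],
    standards: list[TargetDefinition],
    config: ToleranceConfig | None = None,
    qc_mix: Optional[list[TargetDefinition]] = None,
    qc_detect_fraction: float = 0.9,
    blank_intensity_floor: float = 0.0,
) -> QCReport:
    """Decide whether an analytical run may enter the archive.

    Three checks, all of which must pass:

    a. every case / internal-standard-blank / methanolic-QC sample contains
       every internal standard's precursor within +/- mass_tol and +/- rt_tol;
    b. every methanolic QC injection detects at least ``qc_detect_fraction``
       of the QC-mix compounds;
    c. blank samples contain no QC-mix precursor above
       ``blank_intensity_floor``.

    Checks (b) and (c) pass vacuously when no ``qc_mix`` is supplied.
    """
    if not standards:
        raise ValueError("qc_gate requires a non-empty internal-standard list")
    if not run_samples:
        raise ValueError("qc_gate requires a run with at least one sample")
    config = config or ToleranceConfig()
    run_name = run_samples[0].run_name

    peaks_by_sample: dict[str, list[PeakRecord]] = {}
    for p in run_peaks:
        peaks_by_sample.setdefault(p.sample_id, []).append(p)

    checks: list[QCCheck] = []

    # (a) internal standards everywhere they are expected
    missing_a = []
    for s in run_samples:
        if s.sample_type not in _IS_CHECKED_TYPES:
            continue
        for std in standards:
            if not _present(
                peaks_by_sample, s.sample_id, std, config.mass_tol, config.rt_tol
            ):
                missing_a.append(f"{std.name} missing in {s.sample_id}")
    checks.append(
        QCCheck(
            "internal_standards_present",
            not missing_a,
            "; ".join(missing_a[:10]) if missing_a else "all internal standards found",
        )
    )

    # (b) methanolic QC detection rate
    fail_b = []
    if qc_mix:
        for s in run_samples:
            if s.sample_type != "methanolic_qc":
                continue
            found = sum(
                _present(
                    peaks_by_sample, s.sample_id, t, config.mass_tol, config.rt_tol
                )
                for t in qc_mix
            )
            frac = found / len(qc_mix)
            if frac < qc_detect_fraction:
                fail_b.append(
                    f"{s.sample_id}: {frac:.2f} < {qc_detect_fraction:.2f}"
                )
    checks.append(
        QCCheck(
            "qc_mix_detection_rate",
            not fail_b,
            "; ".join(fail_b[:10]) if fail_b else "all QC injections above threshold",
        )
    )

    # (c) clean blanks
    fail_c = []
    if qc_mix:
        for s in run_samples:
            if s.sample_type not in _BLANK_TYPES:
                continue
            for t in qc_mix:
                if _present(
                    peaks_by_sample,
                    s.sample_id,
                    t,
                    config.mass_tol,
                    config.rt_tol,
                    intensity_floor=blank_intensity_floor,
                ):
                    fail_c.append(f"{t.name} found in blank {s.sample_id}")
    checks.append(
        QCCheck(
            "blanks_clean",
            not fail_c,
            "; ".join(fail_c[:10]) if fail_c else "no QC-mix signals in blanks",
        )
    )

    return QCReport(run_name, all(c.passed for c in checks), checks)


def ingest_run(
    store: Store,
    run_samples: list[SampleRecord],
    run_components: list[ComponentRecord],
    gate: QCReport,
    fault_hook: Optional[Callable[[], None]] = None,
) -> IngestStats:
    """Admit a run to the archive if and only if its QC gate passed.

    The insert is atomic: either all of the run's samples and ions become
    visible or none do. ``fault_hook`` (tests only) is invoked between the
    sample and peak inserts inside the transaction to exercise crash safety.
    """
    run_name = run_samples[0].run_name if run_samples else gate.run_name
    if not gate.passed:
        failed = [c.name for c in gate.checks if not c.passed]
        return IngestStats(
            run_name, False, 0, 0, reason=f"QC gate failed: {', '.join(failed)}"
        )
    peaks = decomponentize(run_components)
    conn = store._conn
    with conn:  # one transaction: commits on success, rolls back on raise
        conn.executemany(
            "INSERT INTO samples VALUES (?,?,?,?,?,?,?,?)",
            [
                (
                    s.sample_id,
                    s.run_name,
                    s.uid,
                    s.file_path,
                    s.sample_type,
                    s.instrument_id,
                    s.acquired_at,
                    s.batch_id,
                )
                for s in run_samples
            ],
        )
        if fault_hook is not None:
            fault_hook()
        conn.executemany(
            "INSERT INTO peaks (sample_id, mz, rt, intensity, channel,"
            " component_id, ion_role, mz_sd, rt_sd)"
            " VALUES (?,?,?,?,?,?,?,?,?)",
            [
                (
                    p.sample_id,
                    p.mz,
                    p.rt,
                    p.intensity,
                    p.channel,
                    p.component_id,
                    p.ion_role,
                    p.mz_sd,
                    p.rt_sd,
                )
                for p in peaks
            ],
        )
    return IngestStats(run_name, True, len(run_samples), len(peaks))
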