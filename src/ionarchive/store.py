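"""SQL-backed archive of decomponentized LC-HRMS(E) ion signals.

Two tables mirror the archive's architecture: ``samples`` (one row per
analytical injection) and ``peaks`` (one row per measured ion in either energy
channel). Ions are stored *decomponentized*: the component an ion was grouped
into upstream is kept only as provenance (``component_id``) and no query ever
requires it. The universal read primitive is a windowed ion query — a closed
m/z interval crossed with a closed RT interval, optionally restricted by
channel and sample.
"""

from __future__ import annotations

import dataclasses
import sqlite3
from collections.abc import Sequence
from typing import Optional

__all__ = [
    "SAMPLE_TYPES",
    "CHANNELS",
    "ION_ROLES",
    "SampleRecord",
    "PeakRecord",
    "IonWindow",
    "Store",
    "init_store",
]

SAMPLE_TYPES = ("case", "blank_matrix", "internal_standard_blank", "methanolic_qc")
CHANNELS = ("low", "high")
ION_ROLES = (
    "precursor",
    "residual_precursor",
    "isotope",
    "adduct",
    "insource_fragment",
    "fragment",
    "unknown",
)


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One analytical injection.

    ``uid`` is the unique identifier assigned to the raw data file upstream;
    ``sample_id`` is unique within a store.
    """

    sample_id: str
    run_name: str
    uid: str
    file_path: str
    sample_type: str
    instrument_id: str
    acquired_at: str  # ISO-8601 timestamp
    batch_id: str

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample_type {self.sample_type!r} not in {SAMPLE_TYPES}"
            )


@dataclasses.dataclass(frozen=True)
class PeakRecord:
    """One ion signal: accurate mass, retention time, intensity, channel.

    ``mz_sd``/``rt_sd`` carry the upstream diagnostic variance parameters when
    available; they are provenance only and no operation depends on them.
    """

    sample_id: str
    mz: float
    rt: float
    intensity: float
    channel: str
    component_id: Optional[int] = None
    ion_role: str = "unknown"
    mz_sd: Optional[float] = None
    rt_sd: Optional[float] = None
    peak_id: Optional[int] = None  # assigned by the store on insert

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be >= 0, got {self.rt}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel {self.channel!r} not in {CHANNELS}")
        if self.ion_role not in ION_ROLES:
            raise ValueError(f"ion_role {self.ion_role!r} not in {ION_ROLES}")


@dataclasses.dataclass(frozen=True)
class IonWindow:
    """Closed m/z x RT query window, optionally filtered by channel/sample.

    ``sample_filter`` may hold sample_ids and/or sample_types; a peak matches
    if its sample_id or its sample's type is in the set.
    """

    mz_center: float
    mz_tol: float
    rt_lo: float
    rt_hi: float
    channel: Optional[str] = None
    sample_filter: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.mz_tol > 0:
            raise ValueError("mz_tol must be > 0")
        if self.rt_lo > self.rt_hi:
            raise ValueError("rt_lo must be <= rt_hi")
        if self.channel is not None and self.channel not in CHANNELS:
            raise ValueError(f"channel {self.channel!r} not in {CHANNELS}")
        if self.sample_filter is not None and not isinstance(
            self.sample_filter, frozenset
        ):
            object.__setattr__(self, "sample_filter", frozenset(self.sample_filter))


_SCHEMA = """
CREATE TABLE IF NOT EXISTS samples (
    sample_id     TEXT PRIMARY KEY,
    run_name      TEXT NOT NULL,
    uid           TEXT NOT NULL,
    file_path     TEXT NOT NULL,
    sample_type   TEXT NOT NULL CHECK (sample_type IN
        ('case','blank_matrix','internal_standard_blank','methanolic_qc')),
    instrument_id TEXT NOT NULL,
    acquired_at   TEXT NOT NULL,
    batch_id      TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS peaks (
    peak_id      INTEGER PRIMARY KEY,
    sample_id    TEXT NOT NULL REFERENCES samples(sample_id),
    mz           REAL NOT NULL CHECK (mz > 0),
    rt           REAL NOT NULL CHECK (rt >= 0),
    intensity    REAL NOT NULL CHECK (intensity >= 0),
    channel      TEXT NOT NULL CHECK (channel IN ('low','high')),
    component_id INTEGER,
    ion_role     TEXT NOT NULL DEFAULT 'unknown',
    mz_sd        REAL,
    rt_sd        REAL
);
CREATE INDEX IF NOT EXISTS idx_peaks_mz ON peaks (mz);
CREATE INDEX IF NOT EXISTS idx_peaks_rt ON peaks (rt);
CREATE INDEX IF NOT EXISTS idx_peaks_sample ON peaks (sample_id);
"""

_PEAK_COLS = (
    "peak_id",
    "sample_id",
    "mz",
    "rt",
    "intensity",
    "channel",
    "component_id",
    "ion_role",
    "mz_sd",
    "rt_sd",
)


class Store:
    """Handle to an archive database (a file path or ``":memory:"``)."""

    def __init__(self, path: str):
        self.path = str(path)
        try:
            self._conn = sqlite3.connect(self.path)
            self._conn.execute("PRAGMA foreign_keys = ON")
            self._conn.executescript(_SCHEMA)
            self._conn.commit()
        except sqlite3.OperationalError as exc:
            raise IOError(f"cannot open archive at {self.path!r}: {exc}") from exc

    # -- ingest side -----------------------------------------------------

    def add_samples(self, samples: Sequence[SampleRecord]) -> int:
        """Insert sample rows; duplicate sample_ids raise and insert nothing."""
        existing = {
            row[0]
            for row in self._conn.execute("SELECT sample_id FROM samples").fetchall()
        }
        seen: set[str] = set()
        for s in samples:
            if s.sample_id in existing or s.sample_id in seen:
                raise ValueError(f"duplicate sample_id: {s.sample_id!r}")
            seen.add(s.sample_id)
        with self._conn:
            self._conn.executemany(
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
                    for s in samples
                ],
            )
        return len(samples)

    def add_peaks(self, peaks: Sequence[PeakRecord]) -> int:
        """Append ion rows verbatim — no deduplication or merging ever happens.

        Every peak must reference an existing sample.
        """
        known = {
            row[0]
            for row in self._conn.execute("SELECT sample_id FROM samples").fetchall()
        }
        for p in peaks:
            if p.sample_id not in known:
                raise ValueError(
                    f"peak references unknown sample_id: {p.sample_id!r}"
                )
        with self._conn:
            self._conn.executemany(
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
        return len(peaks)

    # -- query side ------------------------------------------------------

    def n_samples(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM samples").fetchone()[0]

    def n_peaks(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM peaks").fetchone()[0]

    def samples(self) -> list[SampleRecord]:
        rows = self._conn.execute(
            "SELECT sample_id, run_name, uid, file_path, sample_type,"
            " instrument_id, acquired_at, batch_id FROM samples ORDER BY sample_id"
        ).fetchall()
        return [SampleRecord(*row) for row in rows]

    def sample_ids(self, sample_type: Optional[str] = None) -> list[str]:
        if sample_type is None:
            rows = self._conn.execute(
                "SELECT sample_id FROM samples ORDER BY sample_id"
            )
        else:
            rows = self._conn.execute(
                "SELECT sample_id FROM samples WHERE sample_type = ?"
                " ORDER BY sample_id",
                (sample_type,),
            )
        return [r[0] for r in rows.fetchall()]

    def query_ions(self, window: IonWindow) -> list[PeakRecord]:
        """All ion rows inside the closed window, ordered by (sample_id, rt, mz).

        Boundary values are included: ``|mz - mz_center| <= mz_tol`` and
        ``rt_lo <= rt <= rt_hi``. No component structure is consulted.
        """
        clauses = ["p.mz >= ? AND p.mz <= ?", "p.rt >= ? AND p.rt <= ?"]
        params: list = [
            window.mz_center - window.mz_tol,
            window.mz_center + window.mz_tol,
            window.rt_lo,
            window.rt_hi,
        ]
        if window.channel is not None:
            clauses.append("p.channel = ?")
            params.append(window.channel)
        if window.sample_filter is not None:
            marks = ",".join("?" * len(window.sample_filter))
            toks = sorted(window.sample_filter)
            clauses.append(
                f"(p.sample_id IN ({marks}) OR s.sample_type IN ({marks}))"
            )
            params.extend(toks)
            params.extend(toks)
        sql = (
            "SELECT p.peak_id, p.sample_id, p.mz, p.rt, p.intensity, p.channel,"
            " p.component_id, p.ion_role, p.mz_sd, p.rt_sd"
            " FROM peaks p JOIN samples s ON p.sample_id = s.sample_id"
            f" WHERE {' AND '.join(clauses)}"
            " ORDER BY p.sample_id, p.rt, p.mz, p.peak_id"
        )
        out = []
        for row in self._conn.execute(sql, params).fetchall():
            d = dict(zip(_PEAK_COLS, row))
            out.append(PeakRecord(**d))
        return out

    def all_peaks(self, channel: Optional[str] = None) -> list[PeakRecord]:
        sql = (
            "SELECT peak_id, sample_id, mz, rt, intensity, channel,"
            " component_id, ion_role, mz_sd, rt_sd FROM peaks"
        )
        params: tuple = ()
        if channel is not None:
            sql += " WHERE channel = ?"
            params = (channel,)
        sql += " ORDER BY sample_id, rt, mz, peak_id"
        return [
            PeakRecord(**dict(zip(_PEAK_COLS, row)))
            for row in self._conn.execute(sql, params).fetchall()
        ]

    # -- transactional helpers (used by ingest for atomicity) ------------

    def begin(self) -> None:
        self._conn.execute("BEGIN")

    def commit(self) -> None:
        self._conn.commit()

    def rollback(self) -> None:
        self._conn.rollback()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def init_store(path: str) -> Store:
    """Create or re-open an archive at ``path`` (``":memory:"`` for ephemeral).

    Idempotent: re-opening an existing archive preserves its contents.
    """
    return Store(path)
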