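"""Tolerance constants shared by every workflow.

All windows in the archive are closed intervals: a value sitting exactly on a
tolerance boundary is inside the window. Mass tolerances are absolute (Da),
never ppm.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import yaml

__all__ = ["ToleranceConfig", "RUN_TIME_MIN"]

#: Default chromatographic run length in minutes; retention times are valid on
#: [0, RUN_TIME_MIN].
RUN_TIME_MIN = 15.0


@dataclasses.dataclass(frozen=True)
class ToleranceConfig:
    """Bundle of the tolerance constants used across the archive.

    Parameters
    ----------
    mass_tol
        Precursor/fragment mass window half-width in Da (3 mDa).
    rt_tol
        Retention-time window half-width in minutes used for target matching
        and for scaling before clustering (0.5 min).
    coelution_tol
        Maximum |RT difference| in minutes for a fragment ion to be grouped
        with its precursor (0.015 min).
    bandwidth
        Mean-shift kernel radius in scaled (dimensionless) units.
    qc_mass_window
        QC evaluation window on mass errors, Da (1 mDa).
    qc_rt_window
        QC evaluation window on RT errors, minutes (0.25 min).
    drift_rt_window
        RT band around the library value beyond which a point is flagged as
        drifted, minutes (0.5 min).
    """

    mass_tol: float = 0.003
    rt_tol: float = 0.5
    coelution_tol: float = 0.015
    bandwidth: float = 1.0
    qc_mass_window: float = 0.001
    qc_rt_window: float = 0.25
    drift_rt_window: float = 0.5

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"ToleranceConfig.{f.name} must be > 0, got {v!r}")

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "ToleranceConfig":
        """Load tolerances from a YAML or JSON mapping; absent keys keep defaults."""
        text = pathlib.Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown tolerance keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)
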