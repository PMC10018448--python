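"""Long-term system-performance analytics over the archive.

Internal standards are spiked into every injection, and the methanolic QC
mixes run within every batch; because their ion signals are archived
alongside the case data, mass and retention-time deviation series, QC-window
statistics, fragmentation reproducibility and RT-drift flags can all be
computed for years of acquisition with plain window queries.

The deviation search window is deliberately wider than the screening RT
window (three times ``rt_tol``) so that a standard that has drifted past the
action limit is still measured — and flagged — rather than lost.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ToleranceConfig
from .screening import TargetDefinition, screen_target
from .store import Store

__all__ = [
    "DeviationPoint",
    "DeviationSeries",
    "DeviationSummary",
    "FragmentationPoint",
    "FragmentationSeries",
    "DriftFlag",
    "deviation_series",
    "deviation_summary",
    "fragmentation_series",
    "drift_flags",
]


@dataclasses.dataclass(frozen=True)
class DeviationPoint:
    """Measured-minus-library error of one standard in one injection."""

    sample_id: str
    acquired_at: str
    compound: str
    mass_error: float  # Da
    rt_error: float  # minutes
    intensity: float


@dataclasses.dataclass
class DeviationSeries:
    """Deviation points plus the injections where the standard was missing.

    A missing standard is never reported as a zero-error point.
    """

    points: list[DeviationPoint]
    missing: list[str]  # sample_ids with no match

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclasses.dataclass(frozen=True)
class DeviationSummary:
    n: int
    mass_mean: float
    mass_sd: float
    rt_mean: float
    rt_sd: float
    frac_mass_within_window: float
    frac_rt_within_window: float


@dataclasses.dataclass(frozen=True)
class FragmentationPoint:
    sample_id: str
    compound: str
    channel: str
    fragment_mz: float
    rel_intensity: float  # fragment / precursor intensity, same channel


@dataclasses.dataclass
class FragmentationSeries:
    points: list[FragmentationPoint]
    missing: list[tuple[str, str]]  # (sample_id, channel) lacking the precursor


@dataclasses.dataclass(frozen=True)
class DriftFlag:
    sample_id: str
    acquired_at: str
    compound: str
    rt_error: float
    event_label: Optional[str] = None


def deviation_series(
    store: Store,
    standard: TargetDefinition,
    config: ToleranceConfig | None = None,
    sample_ids: Optional[list[str]] = None,
) -> DeviationSeries:
    """Mass/RT deviation of one standard across the archive.

    For each in-scope sample the best precursor match under the screening
    rules (smallest |dm/z|, ties by intensity) inside ``+/- mass_tol`` and a
    widened RT search window yields ``mass_error = measured - library`` and
    ``rt_error = measured - library``; samples with no match are listed in
    ``missing``.
    """
    if standard.library_rt is None:
        raise ValueError("deviation_series requires a standard with library_rt")
    config = config or ToleranceConfig()
    acquired = {s.sample_id: s.acquired_at for s in store.samples()}
    search = dataclasses.replace(
        standard, fragment_mz=None, rt_window=3.0 * config.rt_tol
    )
    results = screen_target(store, search, config, sample_ids=sample_ids)
    points, missing = [], []
    for res in results:
        if not res.detected or res.precursor_hit is None:
            missing.append(res.sample_id)
            continue
        hit = res.precursor_hit
        points.append(
            DeviationPoint(
                sample_id=res.sample_id,
                acquired_at=acquired.get(res.sample_id, ""),
                compound=standard.name,
                mass_error=hit.mz - standard.precursor_mz,
                rt_error=hit.rt - standard.library_rt,
                intensity=hit.intensity,
            )
        )
    return DeviationSeries(points, missing)


def deviation_summary(
    points: Sequence[DeviationPoint], config: ToleranceConfig | None = None
) -> DeviationSummary:
    """Mean, SD and the fractions inside the closed QC windows
    (``+/- qc_mass_window``, ``+/- qc_rt_window``)."""
    if not points:
        raise ValueError("deviation_summary requires at least one point")
    config = config or ToleranceConfig()
    me = np.array([p.mass_error for p in points])
    re_ = np.array([p.rt_error for p in points])
    return DeviationSummary(
        n=len(points),
        mass_mean=float(me.mean()),
        mass_sd=float(me.std(ddof=1)) if len(points) > 1 else 0.0,
        rt_mean=float(re_.mean()),
        rt_sd=float(re_.std(ddof=1)) if len(points) > 1 else 0.0,
        frac_mass_within_window=float(
            (np.abs(me) <= config.qc_mass_window).mean()
        ),
        frac_rt_within_window=float((np.abs(re_) <= config.qc_rt_window).mean()),
    )


def fragmentation_series(
    store: Store,
    standard: TargetDefinition,
    fragment_mzs: Optional[Sequence[float]] = None,
    config: ToleranceConfig | None = None,
) -> FragmentationSeries:
    """Fragment-to-precursor intensity ratios in methanolic QC injections.

    Per QC injection and energy channel, each declared fragment's intensity
    relative to the (residual) precursor in the *same* channel; injections
    lacking the channel's precursor are reported missing, never as zeros.
    """
    config = config or ToleranceConfig()
    if fragment_mzs is None:
        if standard.fragment_mz is None:
            raise ValueError("fragmentation_series requires at least one fragment")
        fragment_mzs = [standard.fragment_mz]
    if not fragment_mzs:
        raise ValueError("fragmentation_series requires at least one fragment")

    qc_ids = store.sample_ids("methanolic_qc")
    mass_tol = standard.mass_tol if standard.mass_tol is not None else config.mass_tol
    rt_window = (
        standard.rt_window if standard.rt_window is not None else config.rt_tol
    )

    points: list[FragmentationPoint] = []
    missing: list[tuple[str, str]] = []

    from .store import IonWindow

    for channel in ("low", "high"):
        if standard.library_rt is not None:
            rt_lo = max(0.0, standard.library_rt - rt_window)
            rt_hi = standard.library_rt + rt_window
        else:
            rt_lo, rt_hi = 0.0, float("inf")
        prec_hits = store.query_ions(
            IonWindow(
                mz_center=standard.precursor_mz,
                mz_tol=mass_tol,
                rt_lo=rt_lo,
                rt_hi=rt_hi,
                channel=channel,
            )
        )
        prec_by_sample: dict[str, list] = {}
        for p in prec_hits:
            prec_by_sample.setdefault(p.sample_id, []).append(p)
        frag_hits_by_mz = {
            fmz: store.query_ions(
                IonWindow(
                    mz_center=fmz,
                    mz_tol=mass_tol,
                    rt_lo=max(0.0, rt_lo - config.coelution_tol),
                    rt_hi=rt_hi + config.coelution_tol,
                    channel=channel,
                )
            )
            for fmz in fragment_mzs
        }
        for sid in qc_ids:
            cands = prec_by_sample.get(sid)
            if not cands:
                missing.append((sid, channel))
                continue
            prec = min(
                cands,
                key=lambda p: (
                    abs(p.mz - standard.precursor_mz),
                    -p.intensity,
                    p.peak_id or 0,
                ),
            )
            for fmz in fragment_mzs:
                frags = [
                    f
                    for f in frag_hits_by_mz[fmz]
                    if f.sample_id == sid
                    and abs(f.rt - prec.rt) <= config.coelution_tol
                ]
                if not frags:
                    continue
                frag = min(
                    frags,
                    key=lambda f: (abs(f.mz - fmz), -f.intensity, f.peak_id or 0),
                )
                points.append(
                    FragmentationPoint(
                        sample_id=sid,
                        compound=standard.name,
                        channel=channel,
                        fragment_mz=fmz,
                        rel_intensity=frag.intensity / prec.intensity,
                    )
                )
    return FragmentationSeries(points, missing)


def drift_flags(
    points: Sequence[DeviationPoint],
    config: ToleranceConfig | None = None,
    events: Optional[Sequence[tuple[str, str]]] = None,
) -> list[DriftFlag]:
    """Flag every point whose |rt_error| exceeds the drift band.

    ``events`` is an optional sequence of (timestamp, label) maintenance
    events; each flag is annotated with the most recent event at or before
    its acquisition time.
    """
    config = config or ToleranceConfig()
    ev: list[tuple[pd.Timestamp, str]] = []
    if events:
        ev = sorted(
            (pd.Timestamp(ts), label) for ts, label in events
        )
    flags = []
    for p in sorted(points, key=lambda p: (p.acquired_at, p.sample_id)):
        if abs(p.rt_error) <= config.drift_rt_window:
            continue
        label = None
        if ev and p.acquired_at:
            t = pd.Timestamp(p.acquired_at)
            prior = [lbl for ts, lbl in ev if ts <= t]
            label = prior[-1] if prior else None
        flags.append(
            DriftFlag(p.sample_id, p.acquired_at, p.compound, p.rt_error, label)
        )
    return flags
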