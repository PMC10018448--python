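"""Target matching against the archive and retrospective-screening evaluation.

A screening target is a precursor m/z, optionally a library retention time and
one diagnostic fragment m/z. Detection in a sample requires a low-energy
precursor ion inside the closed +/- mass_tol window (and inside the RT window
when both the target and the library define one); when a fragment is declared,
a high-energy ion within +/- mass_tol of the fragment m/z must co-elute with
the chosen precursor hit within coelution_tol. All windows are closed.

Retrospective screening replays a target list against archived data and
scores detections against a truth table from a complementary analytical
method (e.g. quantitative confirmation results).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import pandas as pd

from .config import ToleranceConfig
from .store import IonWindow, PeakRecord, Store

__all__ = [
    "TargetDefinition",
    "DetectionResult",
    "ConfusionSummary",
    "screen_target",
    "retrospective_screen",
    "load_target_library",
]


@dataclasses.dataclass(frozen=True)
class TargetDefinition:
    """A screening target: precursor m/z, optional library RT and one
    diagnostic fragment m/z.

    ``mass_tol``/``rt_window`` override the config defaults when set.
    """

    name: str
    precursor_mz: float
    library_rt: Optional[float] = None
    fragment_mz: Optional[float] = None
    mass_tol: Optional[float] = None
    rt_window: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.precursor_mz > 0:
            raise ValueError("precursor_mz must be > 0")
        tol = self.mass_tol if self.mass_tol is not None else 0.003
        if self.fragment_mz is not None and not (
            self.fragment_mz < self.precursor_mz + tol
        ):
            raise ValueError(
                "fragment_mz must lie below precursor_mz + mass_tol"
            )


@dataclasses.dataclass(frozen=True)
class DetectionResult:
    """Outcome of screening one target in one sample."""

    sample_id: str
    target: str
    detected: bool
    precursor_hit: Optional[PeakRecord] = None
    fragment_hit: Optional[PeakRecord] = None
    rt_delta: Optional[float] = None


@dataclasses.dataclass
class ConfusionSummary:
    """Detection counts against an external truth condition.

    ``tentative_positives`` are truth-positive detections not already in the
    original case findings; the four counts partition the evaluated samples.
    """

    tentative_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int
    per_sample: pd.DataFrame  # columns: sample_id, target, detected, truth
    #: truth-positive detections already present in the original case
    #: findings; kept separate so that tentative + previously_found + fp + tn
    #: + fn always equals the number of evaluations
    previously_found: int = 0

    @property
    def sensitivity(self) -> float:
        pos = int(self.per_sample["truth"].sum())
        if pos == 0:
            return float("nan")
        hits = int(
            (self.per_sample["detected"] & self.per_sample["truth"]).sum()
        )
        return hits / pos

    @property
    def specificity(self) -> float:
        neg = int((~self.per_sample["truth"]).sum())
        if neg == 0:
            return float("nan")
        return self.true_negatives / neg


def _best_precursor(candidates: list[PeakRecord], mz: float) -> PeakRecord:
    # smallest |dm/z| wins; ties broken by higher intensity, then peak_id
    return min(
        candidates,
        key=lambda p: (abs(p.mz - mz), -p.intensity, p.peak_id or 0),
    )


def screen_target(
    store: Store,
    target: TargetDefinition,
    config: ToleranceConfig | None = None,
    sample_ids: Optional[list[str]] = None,
) -> list[DetectionResult]:
    """Screen one target across every sample in scope.

    Returns one :class:`DetectionResult` per sample (all samples in the store
    unless ``sample_ids`` restricts scope). Among several in-window precursor
    candidates the smallest ``|mz - precursor_mz|`` wins, ties broken by
    higher intensity. The diagnostic fragment, when defined, must be a
    high-energy ion co-eluting with the chosen precursor within
    ``coelution_tol`` (closed interval).
    """
    config = config or ToleranceConfig()
    mass_tol = target.mass_tol if target.mass_tol is not None else config.mass_tol
    rt_window = target.rt_window if target.rt_window is not None else config.rt_tol

    if target.library_rt is not None:
        rt_lo = max(0.0, target.library_rt - rt_window)
        rt_hi = target.library_rt + rt_window
    else:
        rt_lo, rt_hi = 0.0, float("inf")

    prec_hits = store.query_ions(
        IonWindow(
            mz_center=target.precursor_mz,
            mz_tol=mass_tol,
            rt_lo=rt_lo,
            rt_hi=rt_hi,
            channel="low",
        )
    )
    by_sample: dict[str, list[PeakRecord]] = {}
    for p in prec_hits:
        by_sample.setdefault(p.sample_id, []).append(p)

    frag_by_sample: dict[str, list[PeakRecord]] = {}
    if target.fragment_mz is not None:
        frag_hits = store.query_ions(
            IonWindow(
                mz_center=target.fragment_mz,
                mz_tol=mass_tol,
                rt_lo=max(0.0, rt_lo - config.coelution_tol),
                rt_hi=rt_hi + config.coelution_tol,
                channel="high",
            )
        )
        for p in frag_hits:
            frag_by_sample.setdefault(p.sample_id, []).append(p)

    scope = sample_ids if sample_ids is not None else store.sample_ids()
    results = []
    for sid in scope:
        cands = by_sample.get(sid, [])
        if not cands:
            results.append(DetectionResult(sid, target.name, False))
            continue
        prec = _best_precursor(cands, target.precursor_mz)
        if target.fragment_mz is None:
            results.append(
                DetectionResult(sid, target.name, True, precursor_hit=prec)
            )
            continue
        frags = [
            f
            for f in frag_by_sample.get(sid, [])
            if abs(f.rt - prec.rt) <= config.coelution_tol
        ]
        if frags:
            frag = min(
                frags,
                key=lambda f: (
                    abs(f.mz - target.fragment_mz),
                    -f.intensity,
                    f.peak_id or 0,
                ),
            )
            results.append(
                DetectionResult(
                    sid,
                    target.name,
                    True,
                    precursor_hit=prec,
                    fragment_hit=frag,
                    rt_delta=frag.rt - prec.rt,
                )
            )
        else:
            results.append(
                DetectionResult(sid, target.name, False, precursor_hit=prec)
            )
    return results


def retrospective_screen(
    store: Store,
    targets: list[TargetDefinition],
    truth: pd.DataFrame,
    original_findings: Optional[set[tuple[str, str]]] = None,
    config: ToleranceConfig | None = None,
    sample_ids: Optional[list[str]] = None,
) -> ConfusionSummary:
    """Evaluate a target list against a truth table.

    ``truth`` needs columns ``sample_id``, ``compound``, ``positive`` (bool);
    a (sample, target) pair is truth-positive if the table marks that
    compound positive in that sample. ``original_findings`` is a set of
    (sample_id, target_name) pairs already found when the case was open;
    truth-positive detections outside it count as *tentative positives*.
    Truth-negative detections are false positives.
    """
    config = config or ToleranceConfig()
    original_findings = original_findings or set()
    scope = sample_ids if sample_ids is not None else store.sample_ids()

    covered = set(truth["sample_id"])
    missing = [s for s in scope if s not in covered]
    if missing and targets:
        raise ValueError(f"truth table missing sample(s): {missing[:5]}")

    pos_pairs = {
        (r.sample_id, r.compound)
        for r in truth.itertuples()
        if getattr(r, "positive", True)
    }

    rows = []
    tp = fp = tn = fn = known = 0
    for target in targets:
        for res in screen_target(store, target, config, sample_ids=scope):
            truth_pos = (res.sample_id, target.name) in pos_pairs
            if res.detected and truth_pos:
                if (res.sample_id, target.name) not in original_findings:
                    tp += 1
                else:
                    known += 1
            elif res.detected and not truth_pos:
                fp += 1
            elif not res.detected and not truth_pos:
                tn += 1
            else:
                fn += 1
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "target": target.name,
                    "detected": res.detected,
                    "truth": truth_pos,
                }
            )
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "target", "detected", "truth"]
    )
    return ConfusionSummary(tp, fp, tn, fn, per_sample, previously_found=known)


def load_target_library(path: str) -> list[TargetDefinition]:
    """Read a target library CSV: name, precursor_mz[, library_rt, fragment_mz]."""
    df = pd.read_csv(path)
    targets = []
    for r in df.itertuples():
        targets.append(
            TargetDefinition(
                name=str(r.name),
                precursor_mz=float(r.precursor_mz),
                library_rt=(
                    float(r.library_rt)
                    if "library_rt" in df.columns and pd.notna(r.library_rt)
                    else None
                ),
                fragment_mz=(
                    float(r.fragment_mz)
                    if "fragment_mz" in df.columns and pd.notna(r.fragment_mz)
                    else None
                ),
            )
        )
    return targets
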