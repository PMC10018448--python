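"""Differential discovery of alternative screening targets.

Poorly ionized analytes (neutral/acidic drugs under positive electrospray)
may be invisible as protonated molecules yet still leave reproducible traces
— adducts, in-source fragments, metabolites. Given cohorts of known-positive
and known-negative samples, this module clusters low-energy archive ions
across samples in a tolerance-scaled (m/z, RT) plane, ranks clusters purely
by cohort occupancy (intensities are never consulted), and attaches
co-eluting high-energy ions as candidate diagnostic fragments.

Scaling divides m/z by the mass tolerance and RT by the RT tolerance, so two
ions separated by exactly one tolerance in either axis sit at unit Euclidean
distance; a flat-kernel mean shift with bandwidth 1 then groups ions that
recur across samples within tolerance.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import ToleranceConfig
from .store import IonWindow, PeakRecord, Store

__all__ = [
    "ScaledPoint",
    "FeatureCluster",
    "CandidateTarget",
    "scale_points",
    "unscale",
    "mean_shift",
    "build_clusters",
    "cluster_archive",
    "score_clusters",
    "attach_fragments",
    "discover",
]

#: convergence threshold, as a fraction of the bandwidth
_CONVERGENCE_FRAC = 1e-3
#: maximum mean-shift iterations
_MAX_ITER = 300


@dataclasses.dataclass(frozen=True)
class ScaledPoint:
    """One ion in the dimensionless (u, v) = (mz/mass_tol, rt/rt_tol) plane."""

    u: float
    v: float
    peak_ref: PeakRecord


@dataclasses.dataclass
class FeatureCluster:
    """A mean-shift cluster of ions recurring across samples."""

    cluster_id: int
    mode_mz: float
    mode_rt: float
    members: list[PeakRecord]
    samples_present: set[str]
    occupancy_pos: float = float("nan")
    occupancy_neg: float = float("nan")
    score: float = float("nan")


@dataclasses.dataclass
class CandidateTarget:
    """A ranked cluster plus its candidate diagnostic fragments."""

    cluster: FeatureCluster
    attached_fragments: list[tuple[float, float]]  # (mz, rt_delta)
    rank: int = 0


def scale_points(
    peaks: Sequence[PeakRecord], config: ToleranceConfig | None = None
) -> list[ScaledPoint]:
    """Map ions into the tolerance-scaled plane.

    Two ions differing by exactly (mass_tol, 0) or (0, rt_tol) end up at
    Euclidean distance 1. The mapping is invertible given the config.
    """
    config = config or ToleranceConfig()
    return [
        ScaledPoint(p.mz / config.mass_tol, p.rt / config.rt_tol, p)
        for p in peaks
    ]


def unscale(
    u: float, v: float, config: ToleranceConfig | None = None
) -> tuple[float, float]:
    """Invert :func:`scale_points`: (u, v) -> (mz, rt)."""
    config = config or ToleranceConfig()
    return u * config.mass_tol, v * config.rt_tol


def mean_shift(
    points: Sequence[ScaledPoint] | np.ndarray, bandwidth: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-kernel mean shift in the scaled plane.

    Every point iteratively moves to the mean of all *original* points
    within Euclidean distance <= bandwidth of its current position, until
    its displacement falls below ``1e-3 * bandwidth`` (at most 300
    iterations). Converged positions are merged into modes deterministically:
    taken in lexicographic (u, v) order, a position joins the nearest
    existing mode when within ``bandwidth / 2`` of it, else founds a new
    mode. Final modes are sorted by (u, v), so labels are independent of
    input order.

    Returns ``(labels, modes)``: an integer label per point and the
    ``(k, 2)`` array of mode positions.
    """
    if isinstance(points, np.ndarray):
        X = np.asarray(points, dtype=float)
    else:
        X = np.array([[p.u, p.v] for p in points], dtype=float)
    if X.size == 0:
        raise ValueError("mean_shift requires at least one point")
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be > 0")

    tree = cKDTree(X)
    shifted = X.copy()
    tol = _CONVERGENCE_FRAC * bandwidth
    active = np.ones(len(X), dtype=bool)
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        neighbors = tree.query_ball_point(shifted[idx], r=bandwidth)
        new = np.empty((len(idx), 2))
        for j, nbrs in enumerate(neighbors):
            new[j] = X[nbrs].mean(axis=0)
        disp = np.linalg.norm(new - shifted[idx], axis=1)
        shifted[idx] = new
        active[idx] = disp >= tol

    # merge converged positions into modes: process in (u, v) order; a
    # position joins the nearest existing mode when within bandwidth/2
    # (ties to the earliest-created mode), else founds a new mode
    order = np.lexsort((shifted[:, 1], shifted[:, 0]))
    merge_r2 = (bandwidth / 2.0) ** 2
    mode_arr = np.empty((0, 2))
    mode_members: list[list[int]] = []
    for i in order:
        pos = shifted[i]
        if len(mode_members):
            d2 = np.einsum("ij,ij->i", mode_arr - pos, mode_arr - pos)
            m = int(np.argmin(d2))
            if d2[m] <= merge_r2:
                mode_members[m].append(i)
                continue
        mode_arr = np.vstack([mode_arr, pos])
        mode_members.append([int(i)])

    modes = np.array(
        [shifted[members].mean(axis=0) for members in mode_members]
    )
    # final sort of modes by (u, v) and relabel
    final = np.lexsort((modes[:, 1], modes[:, 0]))
    labels = np.empty(len(X), dtype=int)
    for new_label, m in enumerate(final):
        for i in mode_members[m]:
            labels[i] = new_label
    return labels, modes[final]


def build_clusters(
    points: Sequence[ScaledPoint],
    labels: np.ndarray,
    modes: np.ndarray,
    config: ToleranceConfig | None = None,
) -> list[FeatureCluster]:
    """Assemble :class:`FeatureCluster` objects from mean-shift output."""
    config = config or ToleranceConfig()
    clusters = []
    for k in range(len(modes)):
        member_idx = np.flatnonzero(labels == k)
        members = [points[i].peak_ref for i in member_idx]
        mode_mz, mode_rt = unscale(modes[k, 0], modes[k, 1], config)
        clusters.append(
            FeatureCluster(
                cluster_id=k,
                mode_mz=mode_mz,
                mode_rt=mode_rt,
                members=members,
                samples_present={p.sample_id for p in members},
            )
        )
    return clusters


def cluster_archive(
    store: Store,
    config: ToleranceConfig | None = None,
    sample_ids: Optional[Sequence[str]] = None,
    mz_window: Optional[tuple[float, float]] = None,
) -> list[FeatureCluster]:
    """Cluster the archive's low-energy ions across samples.

    Only low-energy ions enter clustering; high-energy ions are attached
    later as candidate fragments. ``sample_ids`` restricts to a cohort;
    ``mz_window`` (lo, hi) optionally pre-windows the ions, for targeted
    runs on a mass region of interest.
    """
    config = config or ToleranceConfig()
    peaks = store.all_peaks(channel="low")
    if sample_ids is not None:
        keep = set(sample_ids)
        peaks = [p for p in peaks if p.sample_id in keep]
    if mz_window is not None:
        lo, hi = mz_window
        peaks = [p for p in peaks if lo <= p.mz <= hi]
    if not peaks:
        return []
    points = scale_points(peaks, config)
    labels, modes = mean_shift(points, config.bandwidth)
    return build_clusters(points, labels, modes, config)


def score_clusters(
    clusters: Sequence[FeatureCluster],
    positives: set[str],
    negatives: set[str],
    max_negative_occupancy: Optional[float] = None,
) -> list[FeatureCluster]:
    """Rank clusters by cohort occupancy difference; intensity-free.

    ``occupancy_pos`` is the fraction of positive samples containing the
    cluster, likewise for negatives; ``score = occupancy_pos -
    occupancy_neg``. Ranking is by descending score, ties by descending
    occupancy_pos then ascending mode m/z. When ``max_negative_occupancy``
    is set, clusters present in more than that fraction of the negatives are
    suppressed as background before ranking.
    """
    positives, negatives = set(positives), set(negatives)
    if not positives or not negatives:
        raise ValueError("both cohorts must be non-empty")
    if positives & negatives:
        raise ValueError(
            f"cohorts overlap: {sorted(positives & negatives)[:5]}"
        )
    scored = []
    for c in clusters:
        c.occupancy_pos = len(c.samples_present & positives) / len(positives)
        c.occupancy_neg = len(c.samples_present & negatives) / len(negatives)
        c.score = c.occupancy_pos - c.occupancy_neg
        if (
            max_negative_occupancy is not None
            and c.occupancy_neg > max_negative_occupancy
        ):
            continue
        scored.append(c)
    scored.sort(key=lambda c: (-c.score, -c.occupancy_pos, c.mode_mz))
    return scored


def attach_fragments(
    candidate: FeatureCluster,
    store: Store,
    config: ToleranceConfig | None = None,
) -> CandidateTarget:
    """Attach co-eluting high-energy ions as candidate diagnostic fragments.

    High-energy ions in the cluster's samples whose RT lies within
    ``coelution_tol`` of the cluster mode RT are collected and deduplicated
    by m/z within ``mass_tol`` (the most intense ion represents each group).
    """
    config = config or ToleranceConfig()
    if not candidate.members:
        raise ValueError("cannot attach fragments to an empty cluster")
    hits = store.query_ions(
        IonWindow(
            mz_center=5e5,
            mz_tol=5e5,  # all masses; selection is by RT, channel, samples
            rt_lo=max(0.0, candidate.mode_rt - config.coelution_tol),
            rt_hi=candidate.mode_rt + config.coelution_tol,
            channel="high",
            sample_filter=frozenset(candidate.samples_present),
        )
    )
    # dedup by mz within mass_tol: most intense first, deterministic ties
    hits.sort(key=lambda p: (-p.intensity, p.mz, p.sample_id))
    attached: list[tuple[float, float]] = []
    for h in hits:
        if any(abs(h.mz - mz) <= config.mass_tol for mz, _ in attached):
            continue
        attached.append((h.mz, h.rt - candidate.mode_rt))
    attached.sort(key=lambda t: t[0])
    return CandidateTarget(cluster=candidate, attached_fragments=attached)


def discover(
    store: Store,
    positives: set[str],
    negatives: set[str],
    config: ToleranceConfig | None = None,
    max_negative_occupancy: float = 0.05,
    top_n: int = 20,
) -> list[CandidateTarget]:
    """End-to-end alternative-target discovery.

    Clusters the low-energy ions of both cohorts, suppresses background
    clusters (present in more than ``max_negative_occupancy`` of the
    negatives), ranks the rest by occupancy difference and attaches
    candidate fragments to the ``top_n`` clusters.
    """
    config = config or ToleranceConfig()
    cohort = sorted(set(positives) | set(negatives))
    clusters = cluster_archive(store, config, sample_ids=cohort)
    ranked = score_clusters(
        clusters, set(positives), set(negatives), max_negative_occupancy
    )
    out = []
    for rank, c in enumerate(ranked[:top_n], start=1):
        cand = attach_fragments(c, store, config)
        cand.rank = rank
        out.append(cand)
    return out
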