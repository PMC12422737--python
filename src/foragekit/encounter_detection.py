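"""Patch-encounter detection from midpoint trajectories.

A patch encounter spans the frames during which the midpoint's signed
distance to the nearest patch edge (positive inside the patch) stays at
or above ``-entry_margin``.  Candidates whose midpoint never comes within
``near_miss_margin`` of the edge are dropped; consecutive candidates on
the same patch are merged when the signed distance during the gap varies
by less than ``exit_std_threshold``.  Three velocity features per
encounter feed the sensing classifier, and (log duration, log mean
on-patch velocity) feed the exploit classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError
from .synthetic_world import ArenaSpec, TrajectoryRecord

__all__ = [
    "DetectionThresholds",
    "DistanceSeries",
    "EncounterRecord",
    "signed_distance",
    "detect_candidates",
    "filter_near_miss",
    "merge_false_exits",
    "instantaneous_velocity",
    "extract_features",
    "detect_encounters",
    "derive_exit_std_threshold",
    "encounters_to_frame",
    "ENCOUNTER_TABLE_COLUMNS",
]

ENCOUNTER_TABLE_COLUMNS = [
    "worm_id", "patch_id", "entry_s", "exit_s", "duration_s", "density",
    "s_k", "t_k", "u_k", "log_dur", "log_vel",
    "start_censored", "end_censored", "midpoint_entered",
]


@dataclass(frozen=True)
class DetectionThresholds:
    """Distance and window thresholds, mm and seconds."""

    entry_margin: float = 0.46024
    near_miss_margin: float = 0.28758
    exit_std_threshold: float = 0.22221
    decel_window: tuple[float, float] = (-1.5, 6.5)
    peak_window: float = 10.0
    smoothing_s: float = 1.0      # 0 disables velocity smoothing

    def __post_init__(self) -> None:
        if not (0 < self.near_miss_margin < self.entry_margin):
            raise ConfigurationError(
                "require 0 < near_miss_margin < entry_margin")
        if self.exit_std_threshold <= 0:
            raise ConfigurationError("exit_std_threshold must be > 0")
        if self.decel_window[0] >= self.decel_window[1]:
            raise ConfigurationError("decel_window must be increasing")


@dataclass
class DistanceSeries:
    """Per-frame signed distance (mm, positive inside) to nearest patch edge."""

    time: np.ndarray
    d: np.ndarray
    nearest_patch_id: np.ndarray
    valid: bool = True


@dataclass
class EncounterRecord:
    worm_id: int
    patch_id: int
    entry_frame: int
    exit_frame: int          # exclusive: first frame outside the encounter
    duration: float          # s
    max_d: float             # mm, max signed distance during the encounter
    start_censored: bool = False
    end_censored: bool = False
    midpoint_entered: bool = False
    relative_density: float = float("nan")
    feature_z: tuple[float, float] | None = None   # (log dur, log mean vel)
    feature_w: tuple[float, float, float] | None = None  # (s_k, t_k, u_k)
    feature_biased: bool = False


def signed_distance(traj: TrajectoryRecord, arena: ArenaSpec) -> DistanceSeries:
    """Signed distance to the nearest patch edge for every frame.

    ``d = radius - ||midpoint - center||`` for the nearest patch, where
    nearest means minimal (center distance - radius).  Equidistant
    patches resolve to the lowest patch id.
    """
    n = len(traj.time)
    if not arena.patches:
        return DistanceSeries(traj.time, np.full(n, np.nan),
                              np.full(n, -1, dtype=int), valid=False)
    centers = np.array([[p.x, p.y] for p in arena.patches])
    radii = np.array([p.radius for p in arena.patches])
    ids = np.array([p.patch_id for p in arena.patches])
    order = np.argsort(ids, kind="stable")
    centers, radii, ids = centers[order], radii[order], ids[order]
    pts = np.column_stack([traj.x, traj.y])
    dist = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    signed = radii[None, :] - dist
    best = np.argmax(signed, axis=1)   # first (lowest id) wins ties
    return DistanceSeries(traj.time, signed[np.arange(n), best], ids[best])


def detect_candidates(distances: DistanceSeries,
                      thresholds: DetectionThresholds,
                      worm_id: int = 0) -> list[EncounterRecord]:
    """Maximal runs with d >= -entry_margin, split on nearest-patch change."""
    if not distances.valid:
        return []
    d = distances.d
    t = distances.time
    fps = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    inside = d >= -thresholds.entry_margin
    out: list[EncounterRecord] = []
    n = len(d)
    i = 0
    while i < n:
        if not inside[i]:
            i += 1
            continue
        j = i
        pid = distances.nearest_patch_id[i]
        while j < n and inside[j] and distances.nearest_patch_id[j] == pid:
            j += 1
        out.append(EncounterRecord(
            worm_id=worm_id, patch_id=int(pid), entry_frame=i, exit_frame=j,
            duration=(j - i) / fps, max_d=float(d[i:j].max()),
            start_censored=(i == 0), end_censored=(j == n),
            midpoint_entered=bool(d[i:j].max() > 0)))
        i = j
    return out


def filter_near_miss(candidates: Sequence[EncounterRecord],
                     thresholds: DetectionThresholds) -> list[EncounterRecord]:
    """Drop candidates that never came within near_miss_margin of the edge."""
    return [c for c in candidates if c.max_d >= -thresholds.near_miss_margin]


def merge_false_exits(candidates: Sequence[EncounterRecord],
                      distances: DistanceSeries,
                      thresholds: DetectionThresholds) -> list[EncounterRecord]:
    """Merge same-patch candidates across low-variability gaps, to fixed point.

    The gap between consecutive candidates on the same patch is treated as
    a false exit when the standard deviation of the signed distance over
    the gap frames is below ``exit_std_threshold``; gap time then counts
    as on-encounter time.
    """
    fps = (1.0 / (distances.time[1] - distances.time[0])
           if len(distances.time) > 1 else 1.0)
    recs = sorted(candidates, key=lambda c: c.entry_frame)
    changed = True
    while changed:
        changed = False
        merged: list[EncounterRecord] = []
        k = 0
        while k < len(recs):
            cur = recs[k]
            if merged and merged[-1].patch_id == cur.patch_id:
                prev = merged[-1]
                gap = distances.d[prev.exit_frame:cur.entry_frame]
                if gap.size and float(np.std(gap)) < thresholds.exit_std_threshold:
                    new = EncounterRecord(
                        worm_id=prev.worm_id, patch_id=prev.patch_id,
                        entry_frame=prev.entry_frame, exit_frame=cur.exit_frame,
                        duration=(cur.exit_frame - prev.entry_frame) / fps,
                        max_d=max(prev.max_d, cur.max_d),
                        start_censored=prev.start_censored,
                        end_censored=cur.end_censored,
                        midpoint_entered=prev.midpoint_entered or cur.midpoint_entered,
                        relative_density=prev.relative_density)
                    merged[-1] = new
                    changed = True
                    k += 1
                    continue
            merged.append(cur)
            k += 1
        recs = merged
    return recs


def instantaneous_velocity(traj: TrajectoryRecord,
                           smoothing_s: float = 1.0) -> np.ndarray:
    """Central-difference midpoint speed in um/s, optionally smoothed.

    Interior frames use the centered two-step difference; endpoints use
    one-sided differences.  ``smoothing_s`` sets the width of a centered
    moving average (rounded to an odd number of frames); 0 disables it.
    """
    t = np.asarray(traj.time, dtype=float)
    if len(t) < 3:
        raise InputDataError("need >= 3 frames for velocity")
    if np.any(np.diff(t) <= 0):
        raise InputDataError("duplicate or non-increasing timestamps")
    pts = np.column_stack([traj.x, traj.y])
    v = np.empty(len(t))
    v[1:-1] = np.linalg.norm(pts[2:] - pts[:-2], axis=1) / (t[2:] - t[:-2])
    v[0] = np.linalg.norm(pts[1] - pts[0]) / (t[1] - t[0])
    v[-1] = np.linalg.norm(pts[-1] - pts[-2]) / (t[-1] - t[-2])
    v *= 1000.0  # mm/s -> um/s
    if smoothing_s > 0:
        fps = 1.0 / (t[1] - t[0])
        w = max(int(round(smoothing_s * fps)), 1)
        if w % 2 == 0:
            w += 1
        if w > 1:
            kernel = np.ones(w) / w
            pad = w // 2
            vp = np.pad(v, pad, mode="edge")
            v = np.convolve(vp, kernel, mode="valid")
    return v


def extract_features(encounter: EncounterRecord, velocity: np.ndarray,
                     fps: float, thresholds: DetectionThresholds
                     ) -> EncounterRecord:
    """Attach feature_z = (ln dur, ln mean vel) and feature_w = (s, t, u).

    s_k: minimum on-encounter velocity (um/s).  t_k: OLS slope of velocity
    on time over [entry + decel_window[0], entry + decel_window[1]]
    (um/s^2).  u_k: peak velocity within ``peak_window`` seconds before
    entry minus s_k, floored at 0.  Start-censored encounters take entry
    at frame 0 and are flagged ``feature_biased``.
    """
    i0, i1 = encounter.entry_frame, encounter.exit_frame
    if i1 - i0 < 1:
        raise InputDataError("encounter shorter than one frame")
    seg = velocity[i0:i1]
    s_k = float(seg.min())

    lo = max(i0 + int(round(thresholds.decel_window[0] * fps)), 0)
    hi = min(i0 + int(round(thresholds.decel_window[1] * fps)) + 1, len(velocity))
    if hi - lo >= 2:
        tt = np.arange(lo, hi) / fps
        t_k = float(np.polyfit(tt, velocity[lo:hi], 1)[0])
    else:
        t_k = 0.0

    p0 = max(i0 - int(round(thresholds.peak_window * fps)), 0)
    peak = float(velocity[p0:i0 + 1].max()) if i0 + 1 > p0 else s_k
    u_k = max(peak - s_k, 0.0)

    mean_vel = max(float(seg.mean()), 1e-3)
    dur = max(encounter.duration, 1.0 / fps)
    encounter.feature_z = (math.log(dur), math.log(mean_vel))
    encounter.feature_w = (s_k, t_k, u_k)
    encounter.feature_biased = encounter.start_censored
    return encounter


def detect_encounters(traj: TrajectoryRecord, arena: ArenaSpec,
                      thresholds: DetectionThresholds | None = None
                      ) -> list[EncounterRecord]:
    """Full detection pipeline for one trajectory: detect, filter, merge,
    annotate densities, and extract features."""
    thr = thresholds or DetectionThresholds()
    dist = signed_distance(traj, arena)
    cands = detect_candidates(dist, thr, worm_id=traj.worm_id)
    cands = filter_near_miss(cands, thr)
    cands = merge_false_exits(cands, dist, thr)
    dens = {p.patch_id: p.relative_density for p in arena.patches}
    vel = instantaneous_velocity(traj, smoothing_s=thr.smoothing_s)
    for c in cands:
        c.relative_density = dens.get(c.patch_id, float("nan"))
        extract_features(c, vel, traj.fps, thr)
    return cands


def derive_exit_std_threshold(gap_sds: np.ndarray, seed: int = 0) -> float:
    """Re-derive the false-exit threshold from off-patch gap variability.

    Fits a two-component Gaussian mixture to the gap standard deviations
    and returns the point between the component means where the two
    posteriors are equal.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(gap_sds, dtype=float).reshape(-1, 1)
    gmm = GaussianMixture(2, random_state=seed, n_init=5).fit(x)
    lo, hi = sorted(gmm.means_.ravel())
    grid = np.linspace(lo, hi, 2048).reshape(-1, 1)
    post = gmm.predict_proba(grid)
    low_comp = int(np.argmin(gmm.means_.ravel()))
    cross = np.argmin(np.abs(post[:, low_comp] - 0.5))
    return float(grid[cross, 0])


def encounters_to_frame(encounters: Sequence[EncounterRecord],
                        fps: float) -> pd.DataFrame:
    """Flatten records into the canonical encounter table."""
    rows = []
    for c in encounters:
        rows.append({
            "worm_id": c.worm_id, "patch_id": c.patch_id,
            "entry_s": c.entry_frame / fps, "exit_s": c.exit_frame / fps,
            "duration_s": c.duration, "density": c.relative_density,
            "s_k": c.feature_w[0] if c.feature_w else np.nan,
            "t_k": c.feature_w[1] if c.feature_w else np.nan,
            "u_k": c.feature_w[2] if c.feature_w else np.nan,
            "log_dur": c.feature_z[0] if c.feature_z else np.nan,
            "log_vel": c.feature_z[1] if c.feature_z else np.nan,
            "start_censored": c.start_censored,
            "end_censored": c.end_censored,
            "midpoint_entered": c.midpoint_entered,
        })
    return pd.DataFrame(rows, columns=ENCOUNTER_TABLE_COLUMNS)
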