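"""Migration behaviour: speed, phase classification, protrusions, turning.

Phases of chemokinesis are classified by windowed centre-of-mass (COM)
displacement: a frame is "mobile" when the COM displaces by at least
2 um over the 20 s window centred on it (clamped to the track ends), and
maximal runs of equal label lasting at least 20 s become migrating or
stalling phase segments; shorter remainders are left unlabeled.  Migration
flags use net displacement over a stated observation period: at least
7.8 um (half the mean body length) over 2 min for micropipette chemotaxis,
or at least one cell diameter (equivalent-circle diameter of the mean mask
area) over 10 min for random migration.

The "front pixel" is the leading-edge anchor of the track (the extremal
contour point along the heading) — a deterministic, noise-robust stand-in
for a manually chosen brightest front pixel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .polarity import CellTrack

__all__ = [
    "PhaseSegment",
    "ProtrusionDetection",
    "front_pixel_velocity",
    "label_phases_by_displacement",
    "classify_phases",
    "classify_migrating",
    "detect_protrusions",
    "turning_latency",
    "movement_plot",
]

#: printed defaults of the phase classifier
PHASE_MIN_DURATION_S = 20.0
PHASE_DISPLACEMENT_UM = 2.0
#: migration criteria
HALF_BODY_LENGTH_UM = 7.8
HALF_BODY_PERIOD_S = 120.0
DIAMETER_PERIOD_S = 600.0


@dataclass
class PhaseSegment:
    start_s: float
    end_s: float
    label: str                   # migrating | stalling
    window_displacement_um: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def front_pixel_velocity(track: CellTrack, window_s: float = 20.0
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Leading-edge anchor speed over consecutive windows.

    Returns (window start times, per-window speeds in um/s, mean speed).
    """
    dt = track.frame_interval
    if window_s < 2 * dt:
        raise ValueError("window must span at least 2 frame intervals")
    if track.span_s < window_s:
        raise ValueError("track shorter than one velocity window")
    k = int(round(window_s / dt))
    fronts = track.fronts
    n = len(fronts)
    starts, speeds = [], []
    for i in range(0, n - k):        # sliding windows, one per start frame
        disp = np.linalg.norm(fronts[i + k] - fronts[i])
        starts.append(track.times[i])
        speeds.append(disp / (k * dt))
    return np.asarray(starts), np.asarray(speeds), float(np.mean(speeds))


def label_phases_by_displacement(centroids_um: np.ndarray,
                                 frame_interval: float,
                                 min_duration_s: float = PHASE_MIN_DURATION_S,
                                 displacement_um: float = PHASE_DISPLACEMENT_UM,
                                 ) -> list[str]:
    """Per-frame migrating/stalling labels from the windowed-COM rule.

    A frame is mobile when the COM displaces by >= ``displacement_um`` over
    the ``min_duration_s`` window centred on it (shifted to stay inside the
    track near the ends); runs of equal label shorter than
    ``min_duration_s`` are 'unlabeled'.  Shared by the classifier and the
    simulator's ground truth so that agreement measures tracking accuracy
    only.
    """
    if min_duration_s <= 0:
        raise ValueError("min_duration_s must be > 0")
    c = np.asarray(centroids_um, dtype=float)
    n = len(c)
    dt = frame_interval
    w = int(round(min_duration_s / dt))
    if n <= w:
        return ["unlabeled"] * n
    mobile = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, min(i - w // 2, n - 1 - w))
        hi = lo + w
        mobile[i] = np.linalg.norm(c[hi] - c[lo]) >= displacement_um - 1e-9
    labels = []
    i = 0
    while i < n:
        j = i
        while j < n and mobile[j] == mobile[i]:
            j += 1
        run_s = (j - i - 1) * dt
        name = "migrating" if mobile[i] else "stalling"
        if run_s + dt >= min_duration_s:     # run spans >= min_duration
            labels.extend([name] * (j - i))
        else:
            labels.extend(["unlabeled"] * (j - i))
        i = j
    return labels


def classify_phases(track: CellTrack,
                    min_duration_s: float = PHASE_MIN_DURATION_S,
                    displacement_um: float = PHASE_DISPLACEMENT_UM,
                    ) -> list[PhaseSegment]:
    """Maximal migrating/stalling segments of >= ``min_duration_s``."""
    if track.span_s < min_duration_s:
        raise ValueError(
            f"track spans {track.span_s} s; need >= {min_duration_s} s")
    labels = label_phases_by_displacement(
        track.centroids, track.frame_interval, min_duration_s, displacement_um)
    times = track.times
    c = track.centroids
    segments: list[PhaseSegment] = []
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in ("migrating", "stalling"):
            disp = float(np.linalg.norm(c[j - 1] - c[i]))
            segments.append(PhaseSegment(
                start_s=float(times[i]), end_s=float(times[j - 1]),
                label=labels[i], window_displacement_um=disp))
        i = j
    return segments


def classify_migrating(track: CellTrack, criterion: str = "half-body-length",
                       threshold_um: float | None = None,
                       period_s: float | None = None) -> bool:
    """Flag a cell as migrating under one of the printed criteria.

    ``half-body-length``: net displacement of at least 7.8 um over a 2 min
    observation period.  ``one-cell-diameter``: at least the equivalent-
    circle diameter of the mean mask area over 10 min.
    """
    if criterion == "half-body-length":
        thr = HALF_BODY_LENGTH_UM if threshold_um is None else threshold_um
        period = HALF_BODY_PERIOD_S if period_s is None else period_s
    elif criterion == "one-cell-diameter":
        thr = (2.0 * np.sqrt(track.mean_area_um2 / np.pi)
               if threshold_um is None else threshold_um)
        period = DIAMETER_PERIOD_S if period_s is None else period_s
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if track.span_s + 1e-9 < period:
        raise ValueError(
            f"track spans {track.span_s} s but the {criterion!r} criterion "
            f"requires {period} s of observation")
    t0 = track.times[0]
    j = int(np.argmin(np.abs(track.times - (t0 + period))))
    net = np.linalg.norm(track.centroids[j] - track.centroids[0])
    return bool(net >= thr - 1e-9)


# ---------------------------------------------------------------------------
# protrusions

@dataclass
class ProtrusionDetection:
    """A detected protrusion: a contour arc advancing outward."""

    onset_s: float
    end_s: float
    direction_rad: float         # mean angle of the arc about the centroid

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


def _advance_map(tf_prev, tf_next, pixel_size: float,
                 n_points: int = 180) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outward normal displacement (um) of the contour between two frames,
    sampled at ``n_points`` angular positions about the previous centroid.

    Uses the radial distance of the mask boundary at each angle — exact for
    star-shaped outlines, which covers the contour family simulated here.
    """
    c = tf_prev.centroid_um
    ang = np.linspace(-np.pi, np.pi, n_points, endpoint=False)

    def radial(tf) -> np.ndarray:
        rad = tf.contour_um - c
        psi = np.arctan2(rad[:, 1], rad[:, 0])
        r = np.hypot(rad[:, 0], rad[:, 1])
        order = np.argsort(psi)
        psi_s, r_s = psi[order], r[order]
        psi_ext = np.concatenate([psi_s - 2 * np.pi, psi_s, psi_s + 2 * np.pi])
        r_ext = np.concatenate([r_s, r_s, r_s])
        return np.interp(ang, psi_ext, r_ext)

    r0 = radial(tf_prev)
    r1 = radial(tf_next)
    return ang, r1 - r0, r0


def detect_protrusions(track: CellTrack,
                       advance_rate_min: float = 0.05,
                       arc_min_um: float = 2.0,
                       sustain_min_s: float = 5.0,
                       n_points: int = 180) -> list[ProtrusionDetection]:
    """Detect protrusion events on a tracked cell.

    A protrusion is a contiguous contour arc of at least ``arc_min_um``
    whose outward advance rate is >= ``advance_rate_min`` (um/s), sustained
    for >= ``sustain_min_s``.  Returns onset times and arc directions.
    """
    dt = track.frame_interval
    events: list[ProtrusionDetection] = []
    active: list[dict] = []
    for a, b in zip(track.frames[:-1], track.frames[1:]):
        if b.index - a.index != 1:
            active = []
            continue
        ang, dr, r0 = _advance_map(a, b, track.pixel_size, n_points)
        qual = dr / dt >= advance_rate_min
        # contiguous angular runs (cyclic), arc length from local radius
        arcs = []
        if qual.any():
            idx = np.nonzero(qual)[0]
            breaks = np.nonzero(np.diff(idx) > 1)[0]
            runs = np.split(idx, breaks + 1)
            if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == len(qual) - 1:
                runs[0] = np.concatenate([runs[-1], runs[0]])
                runs.pop()
            dtheta = 2 * np.pi / n_points
            for run in runs:
                arc_len = float(np.sum(r0[run] * dtheta))
                if arc_len >= arc_min_um:
                    arcs.append(set(run.tolist()))
        t_pair = a.time_s
        still_active = []
        for ev in active:
            match = next((arc for arc in arcs if arc & ev["bins"]), None)
            if match is not None:
                ev["bins"] = match
                ev["end"] = b.time_s
                ev["all_bins"] |= match
                arcs.remove(match)
                still_active.append(ev)
            else:
                _finalize(ev, events, sustain_min_s, n_points)
        for arc in arcs:
            still_active.append({"bins": arc, "all_bins": set(arc),
                                 "start": t_pair, "end": b.time_s})
        active = still_active
    for ev in active:
        _finalize(ev, events, sustain_min_s, n_points)
    events.sort(key=lambda e: e.onset_s)
    return events


def _finalize(ev: dict, events: list, sustain_min_s: float,
              n_points: int) -> None:
    if ev["end"] - ev["start"] >= sustain_min_s:
        angles = (np.array(sorted(ev["all_bins"])) / n_points) * 2 * np.pi - np.pi
        direction = float(np.angle(np.mean(np.exp(1j * angles))))
        events.append(ProtrusionDetection(onset_s=ev["start"],
                                          end_s=ev["end"],
                                          direction_rad=direction))


def turning_latency(track: CellTrack, events: list[ProtrusionDetection],
                    needle_move_time: float, new_direction: np.ndarray,
                    cone_halfangle_deg: float = 45.0) -> float | None:
    """Time from needle move to the first protrusion toward the new source.

    Only protrusions whose arc direction lies within ``cone_halfangle_deg``
    of ``new_direction`` count; returns None (with a warning) when no such
    protrusion occurs before the track ends.
    """
    d = np.asarray(new_direction, dtype=float)
    if np.linalg.norm(d) == 0:
        raise ValueError("new_direction must be a non-zero vector")
    if needle_move_time > track.times[-1]:
        warnings.warn("needle moved at/after the end of the track; "
                      "turning latency missing", stacklevel=2)
        return None
    target = np.arctan2(d[1], d[0])
    half = np.radians(cone_halfangle_deg)
    for ev in events:
        if ev.onset_s < needle_move_time:
            continue
        if abs(np.angle(np.exp(1j * (ev.direction_rad - target)))) <= half:
            return float(ev.onset_s - needle_move_time)
    warnings.warn("no protrusion toward the new needle direction; "
                  "turning latency missing", stacklevel=2)
    return None


def movement_plot(track: CellTrack) -> tuple[np.ndarray, float, float]:
    """Origin-anchored centroid path.

    Returns (path polyline with the first centroid at the origin, net
    displacement in um, path length in um).
    """
    c = track.centroids
    path = c - c[0]
    steps = np.linalg.norm(np.diff(c, axis=0), axis=1)
    return path, float(np.linalg.norm(path[-1])), float(steps.sum())
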