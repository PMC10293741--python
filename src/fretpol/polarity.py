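"""Where activity sits in the cell: axis profiles, kymographs, polar maps,
peak tracking and pole-dwell/oscillation statistics.

The central longitudinal axis is the chord through the centroid along the
(smoothed) heading, clipped to the cell mask.  Ratio values are sampled
along it at sub-pixel spacing, averaged across a 3-px band normal to the
axis, and reduced to 20 equal-length bins (bin 1 at the leading edge).  The
per-frame maximum of the un-binned profile gives the peak trace; pole zones
extend a fixed axial distance (0.8 um by default) from each anchor, and a
switch event is the peak entering one pole zone after last having been in
the opposite one.  The interval between successive switches is one wave, so
a full pole-to-pole-and-back oscillation cycle contains two waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import find_contours

from .io import RatioMovie

__all__ = [
    "TrackFrame",
    "CellTrack",
    "AxisProfile",
    "AxisProfileSeries",
    "PeakTrace",
    "PolarMap",
    "build_track",
    "axis_profile",
    "axis_profile_series",
    "kymograph",
    "edge_band_values",
    "polar_map",
    "combine_polar_maps",
    "peak_trace",
    "front_back_summary",
]


# ---------------------------------------------------------------------------
# tracking

@dataclass
class TrackFrame:
    """One frame of a cell track."""

    index: int
    time_s: float
    mask: np.ndarray
    contour_um: np.ndarray       # (N, 2) closed polyline, x, y in um
    centroid_um: np.ndarray      # (2,)
    heading: np.ndarray          # (2,) unit vector
    front_um: np.ndarray         # leading-edge anchor (on the contour)
    rear_um: np.ndarray          # uropod anchor (on the contour)
    area_um2: float = np.nan


@dataclass
class CellTrack:
    """Per-frame masks, contours, centroids, headings and pole anchors."""

    frames: list[TrackFrame]
    pixel_size: float
    frame_interval: float

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([f.centroid_um for f in self.frames])

    @property
    def headings(self) -> np.ndarray:
        return np.array([f.heading for f in self.frames])

    @property
    def fronts(self) -> np.ndarray:
        return np.array([f.front_um for f in self.frames])

    @property
    def span_s(self) -> float:
        return self.frames[-1].time_s - self.frames[0].time_s

    @property
    def mean_area_um2(self) -> float:
        return float(np.nanmean([f.area_um2 for f in self.frames]))


def _largest_contour(mask: np.ndarray, pixel_size: float,
                     smooth_window: int = 7) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found in mask")
    best = max(contours, key=len)
    rc = best - 1.0                                 # undo padding
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    # circular moving average knocks the half-pixel staircase of a binary
    # contour down to ~0.1 px, which sub-pixel anchor positions rely on
    if smooth_window > 1 and len(rc) > smooth_window:
        rc = ndimage.uniform_filter1d(rc, smooth_window, axis=0, mode="wrap")
    return rc[:, ::-1] * pixel_size                 # (x, y) um


def _principal_axis(mask: np.ndarray, pixel_size: float) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    pts = np.column_stack([cc, rr]).astype(float) * pixel_size
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def _anchor(contour: np.ndarray, s: np.ndarray, s_max: float,
            pixel_size: float) -> np.ndarray:
    """Extremal contour point along an axis, stabilized laterally.

    A flat tip leaves many near-extremal vertices whose lateral spread is
    ~1 px of noise; the anchor is the contour vertex nearest the centroid
    of the near-extremal arc (within 0.75 px of the extreme)."""
    sel = s >= s_max - 0.75 * pixel_size
    target = contour[sel].mean(axis=0)
    d = np.linalg.norm(contour - target, axis=1)
    return contour[np.argmin(d)]


def build_track(masks: list[np.ndarray | None], frame_interval: float,
                pixel_size: float,
                heading_window_s: float = 5.0) -> CellTrack:
    """Build a cell track from per-frame binary masks.

    The heading is the unit direction of centroid displacement smoothed
    over ``heading_window_s``; a stationary cell falls back to its
    long-axis orientation (sign chosen toward the more protrusive end,
    then toward the previous heading, then toward +x).  More than two
    consecutive empty frames split the track (the longest segment is kept,
    with a warning).
    """
    present = [m is not None and np.asarray(m).any() for m in masks]
    if sum(present) < 2:
        raise ValueError("need at least 2 frames with a non-empty mask")

    # split on runs of >2 consecutive missing frames
    segments: list[list[int]] = [[]]
    run_missing = 0
    for i, ok in enumerate(present):
        if ok:
            if run_missing > 2 and segments[-1]:
                segments.append([])
            segments[-1].append(i)
            run_missing = 0
        else:
            run_missing += 1
    segments = [s for s in segments if len(s) >= 2]
    if not segments:
        raise ValueError("no trackable segment of >= 2 frames")
    if len(segments) > 1:
        warnings.warn("cell lost for > 2 consecutive frames; track split, "
                      "keeping the longest segment", stacklevel=2)
    indices = max(segments, key=len)

    centroids = {}
    for i in indices:
        m = np.asarray(masks[i]).astype(bool)
        r, c = ndimage.center_of_mass(m)
        centroids[i] = np.array([c, r]) * pixel_size
    idx_arr = np.array(indices)
    cents = np.array([centroids[i] for i in indices])

    k = max(1, int(round(heading_window_s / (2 * frame_interval))))
    n = len(indices)
    frames: list[TrackFrame] = []
    prev_heading: np.ndarray | None = None
    min_disp = 0.25 * pixel_size
    for j, i in enumerate(indices):
        lo, hi = max(j - k, 0), min(j + k, n - 1)
        disp = cents[hi] - cents[lo]
        if np.linalg.norm(disp) >= min_disp:
            heading = disp / np.linalg.norm(disp)
        else:
            axis = _principal_axis(np.asarray(masks[i]).astype(bool), pixel_size)
            contour = _largest_contour(np.asarray(masks[i]).astype(bool), pixel_size)
            rad = contour - cents[j]
            d_plus = (rad @ axis).max()
            d_minus = (rad @ -axis).max()
            if abs(d_plus - d_minus) > 1e-6:
                heading = axis if d_plus > d_minus else -axis
            elif prev_heading is not None:
                heading = axis if axis @ prev_heading >= 0 else -axis
            elif axis[0] != 0:
                heading = axis if axis[0] > 0 else -axis
            else:
                heading = axis if axis[1] > 0 else -axis
        prev_heading = heading
        mask = np.asarray(masks[i]).astype(bool)
        contour = _largest_contour(mask, pixel_size)
        s = (contour - cents[j]) @ heading
        frames.append(TrackFrame(
            index=i, time_s=i * frame_interval, mask=mask,
            contour_um=contour, centroid_um=cents[j], heading=heading,
            front_um=_anchor(contour, s, s.max(), pixel_size),
            rear_um=_anchor(contour, -s, (-s).max(), pixel_size),
            area_um2=float(mask.sum()) * pixel_size ** 2))
    return CellTrack(frames=frames, pixel_size=pixel_size,
                     frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# axis profiles

@dataclass
class AxisProfile:
    """Longitudinal ratio profile of one frame (leading edge -> uropod)."""

    distances_um: np.ndarray     # from the leading edge, increasing
    values: np.ndarray           # ratio samples (NaN where undefined)
    bin_means: np.ndarray        # (n_bins,), bin 1 at the leading edge
    axis_length_um: float
    frame_index: int
    time_s: float

    @property
    def profile_mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class AxisProfileSeries:
    """Per-frame axis profiles plus their binned reduction."""

    profiles: list[AxisProfile | None]
    times: np.ndarray
    frame_interval: float
    n_bins: int

    @property
    def bin_matrix(self) -> np.ndarray:
        """(T, n_bins) matrix; gap frames are NaN rows."""
        rows = []
        for p in self.profiles:
            rows.append(np.full(self.n_bins, np.nan) if p is None
                        else p.bin_means)
        return np.vstack(rows)


def _nan_bilinear(values: np.ndarray, valid: np.ndarray,
                  coords_rc: np.ndarray) -> np.ndarray:
    """Bilinear sampling that ignores NaN source pixels."""
    num = ndimage.map_coordinates(np.where(valid, values, 0.0), coords_rc,
                                  order=1, mode="constant", cval=0.0)
    den = ndimage.map_coordinates(valid.astype(float), coords_rc,
                                  order=1, mode="constant", cval=0.0)
    out = np.full(num.shape, np.nan)
    good = den > 0.5
    out[good] = num[good] / den[good]
    return out


def _clip_chord(mask: np.ndarray, centroid_um: np.ndarray,
                heading: np.ndarray, pixel_size: float) -> tuple[float, float]:
    """Signed chord extents (u_rear < 0 < u_front) of the mask along the
    heading through the centroid, in um."""
    h_img, w_img = mask.shape
    max_u = (h_img + w_img) * pixel_size
    step = 0.1 * pixel_size
    u = np.arange(0.0, max_u, step)
    maskf = mask.astype(float)

    def extent(sign: float) -> float:
        px = (centroid_um[0] + sign * u * heading[0]) / pixel_size
        py = (centroid_um[1] + sign * u * heading[1]) / pixel_size
        inside = ndimage.map_coordinates(maskf, np.vstack([py, px]),
                                         order=1, mode="constant", cval=0.0) >= 0.5
        bad = np.nonzero(~inside)[0]
        if len(bad) == 0:
            return float(u[-1])
        return float(u[max(bad[0] - 1, 0)])

    return -extent(-1.0), extent(+1.0)


def axis_profile(ratio: RatioMovie, tf: TrackFrame, n_bins: int = 20,
                 band_halfwidth_px: float = 1.0) -> AxisProfile:
    """Sample the ratio along the central longitudinal axis of one frame.

    Samples at <= 0.5 px spacing (midpoint positions, an equal count per
    bin so the mean of bin means equals the profile mean exactly), each
    averaged across a 3-px-wide band normal to the axis.  Raises if the
    axis is shorter than ``n_bins`` pixels.
    """
    ps = ratio.pixel_size
    u_rear, u_front = _clip_chord(tf.mask, tf.centroid_um, tf.heading, ps)
    length = u_front - u_rear
    if length / ps < n_bins:
        raise ValueError(
            f"axis length {length / ps:.1f} px shorter than n_bins={n_bins}")
    per_bin = max(1, int(np.ceil(2.0 * length / ps / n_bins)))
    n_samples = n_bins * per_bin
    dists = (np.arange(n_samples) + 0.5) * length / n_samples
    u = u_front - dists
    h = tf.heading
    perp = np.array([-h[1], h[0]])
    vals_band = []
    frame_vals = ratio.ratio[tf.index]
    frame_valid = ratio.valid[tf.index]
    for off in (-band_halfwidth_px, 0.0, band_halfwidth_px):
        px = (tf.centroid_um[0] + u * h[0] + off * ps * perp[0]) / ps
        py = (tf.centroid_um[1] + u * h[1] + off * ps * perp[1]) / ps
        vals_band.append(_nan_bilinear(frame_vals, frame_valid,
                                       np.vstack([py, px])))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(np.vstack(vals_band), axis=0)
        bin_means = np.nanmean(values.reshape(n_bins, per_bin), axis=1)
    return AxisProfile(distances_um=dists, values=values, bin_means=bin_means,
                       axis_length_um=length, frame_index=tf.index,
                       time_s=tf.time_s)


def axis_profile_series(ratio: RatioMovie, track: CellTrack,
                        n_bins: int = 20) -> AxisProfileSeries:
    """Axis profiles for every track frame (gap frames become None)."""
    profiles: list[AxisProfile | None] = []
    for tf in track.frames:
        try:
            p = axis_profile(ratio, tf, n_bins=n_bins)
            if np.all(~np.isfinite(p.values)):
                p = None
        except ValueError:
            p = None
        profiles.append(p)
    return AxisProfileSeries(profiles=profiles, times=track.times,
                             frame_interval=track.frame_interval,
                             n_bins=n_bins)


def kymograph(series: AxisProfileSeries) -> np.ndarray:
    """Frames x bins matrix of the binned profiles (leading edge = col 0)."""
    if len(series.profiles) < 2:
        raise ValueError("need at least 2 frames for a kymograph")
    return series.bin_matrix


# ---------------------------------------------------------------------------
# edge band and polar maps

def edge_band_values(ratio: RatioMovie, tf: TrackFrame,
                     band_width_um: float = 0.4,
                     n_angular_bins: int = 360) -> np.ndarray:
    """Mean ratio within ``band_width_um`` of the outer edge, by angle.

    Pixels are grouped by their angular position about the centroid
    (mathematical convention: 0 = +x, counter-clockwise); bins with no
    contributing pixel are NaN.
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be > 0")
    ps = ratio.pixel_size
    if band_width_um < ps:
        warnings.warn(
            f"edge band {band_width_um} um narrower than one pixel "
            f"({ps} um); widened to 1 px", stacklevel=2)
        band_width_um = ps
    dist_in = ndimage.distance_transform_edt(tf.mask) * ps
    sel = tf.mask & (dist_in <= band_width_um) & ratio.valid[tf.index]
    out = np.full(n_angular_bins, np.nan)
    if not sel.any():
        return out
    rr, cc = np.nonzero(sel)
    x = cc * ps - tf.centroid_um[0]
    y = rr * ps - tf.centroid_um[1]
    ang = np.mod(np.arctan2(y, x), 2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi) * n_angular_bins).astype(int),
                      n_angular_bins - 1)
    vals = ratio.ratio[tf.index][rr, cc]
    sums = np.bincount(bins, weights=vals, minlength=n_angular_bins)
    counts = np.bincount(bins, minlength=n_angular_bins)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


@dataclass
class PolarMap:
    """Frames x angular-bin matrix of edge-band ratio, needle-aligned.

    Rendered as eccentric circles: first frame at the centre, last at the
    plot edge.  Angular bins cover 360 degrees exactly once, mathematical
    convention (0 = +x / east, counter-clockwise).
    """

    matrix: np.ndarray
    n_angular_bins: int
    meta: dict = dc_field(default_factory=dict)


#: compass angles in the mathematical convention used throughout
WEST = np.pi
SOUTH = -np.pi / 2


def polar_map(edge_profiles: np.ndarray,
              needle_angle_rad: float | np.ndarray | None,
              needle_move_frame: int | None = None,
              target_before: float = WEST,
              target_after: float = SOUTH) -> PolarMap:
    """Rotate per-frame angular edge profiles so the needle sits due west
    (then due south after ``needle_move_frame``), stacked as a polar map.

    ``edge_profiles`` is (T, n_bins).  A missing needle annotation
    (``None``) produces an unrotated map with a warning.
    """
    profiles = np.atleast_2d(np.asarray(edge_profiles, dtype=float))
    T, nb = profiles.shape
    if needle_angle_rad is None:
        warnings.warn("no needle annotation; polar map left unrotated",
                      stacklevel=2)
        return PolarMap(matrix=profiles.copy(), n_angular_bins=nb,
                        meta={"rotated": False})
    needle = np.broadcast_to(np.asarray(needle_angle_rad, dtype=float), (T,))
    binw = 2 * np.pi / nb
    out = np.empty_like(profiles)
    for t in range(T):
        target = (target_after if needle_move_frame is not None
                  and t >= needle_move_frame else target_before)
        shift = int(round((target - needle[t]) / binw))
        out[t] = np.roll(profiles[t], shift)
    return PolarMap(matrix=out, n_angular_bins=nb, meta={"rotated": True})


def combine_polar_maps(maps: list[PolarMap]) -> PolarMap:
    """Angular-bin mean across cells (frame-by-frame)."""
    if not maps:
        raise ValueError("no maps to combine")
    stack = np.stack([m.matrix for m in maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return PolarMap(matrix=mean, n_angular_bins=maps[0].n_angular_bins,
                    meta={"combined_n": len(maps)})


# ---------------------------------------------------------------------------
# peak tracking

@dataclass
class PeakTrace:
    """Per-frame axial peak position with pole-dwell and wave statistics."""

    times: np.ndarray                 # valid frames only
    peak_um_from_front: np.ndarray
    peak_fraction: np.ndarray
    zones: list[str]                  # front | rear | interior
    switch_times: np.ndarray
    wave_durations_s: np.ndarray
    dwell_front_s: float
    dwell_rear_s: float
    dwell_interior_s: float
    frame_interval: float
    pole_zone_um: float
    #: convention note: oscillation count = number of pole-switch events
    oscillation_convention: str = "switch-events"

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    @property
    def mean_wave_s(self) -> float:
        return (float(np.mean(self.wave_durations_s))
                if len(self.wave_durations_s) else np.nan)

    def to_frame(self) -> pd.DataFrame:
        switch_set = set(np.round(self.switch_times, 9))
        return pd.DataFrame({
            "time_s": self.times,
            "peak_um_from_front": self.peak_um_from_front,
            "zone": self.zones,
            "switch_flag": [round(t, 9) in switch_set for t in self.times],
        })


def peak_trace(series: AxisProfileSeries,
               pole_zone_um: float = 0.8) -> PeakTrace:
    """Track the per-frame axial position of the maximum-ratio pixel.

    Ties are broken toward the previous frame's peak, then toward the
    leading edge.  A switch event is the peak entering one pole zone after
    last having been in the opposite zone; no switch is inferred across a
    gap of invalid frames.  Dwell per zone is frame_interval x frames with
    the peak in that zone.
    """
    if not series.profiles:
        raise ValueError("empty profile series")
    dt = series.frame_interval
    times, peaks_d, peak_frac, zones = [], [], [], []
    switch_times = []
    prev_d: float | None = None
    last_pole: str | None = None
    broken = False          # a gap occurred since the last pole observation
    prev_t: float | None = None
    for p, t in zip(series.profiles, series.times):
        if p is None or not np.any(np.isfinite(p.values)):
            broken = True
            continue
        if prev_t is not None and t - prev_t > 1.5 * dt:
            broken = True
        prev_t = t
        vals = p.values
        finite = np.isfinite(vals)
        vmax = np.nanmax(vals)
        cand = np.nonzero(finite & (vals == vmax))[0]
        if len(cand) > 1 and prev_d is not None:
            d = p.distances_um[cand]
            cand = cand[np.abs(d - prev_d) == np.abs(d - prev_d).min()]
        i_peak = cand[np.argmin(p.distances_um[cand])]
        d = float(p.distances_um[i_peak])
        prev_d = d
        if d <= pole_zone_um + 1e-9:
            zone = "front"
        elif p.axis_length_um - d <= pole_zone_um + 1e-9:
            zone = "rear"
        else:
            zone = "interior"
        times.append(t)
        peaks_d.append(d)
        peak_frac.append(d / p.axis_length_um)
        zones.append(zone)
        if zone in ("front", "rear"):
            if last_pole is not None and zone != last_pole and not broken:
                switch_times.append(t)
            last_pole = zone
            broken = False
    switch_times = np.asarray(switch_times, dtype=float)
    waves = np.diff(switch_times) if len(switch_times) >= 2 else np.array([])
    zones_arr = np.asarray(zones)
    return PeakTrace(
        times=np.asarray(times), peak_um_from_front=np.asarray(peaks_d),
        peak_fraction=np.asarray(peak_frac), zones=zones,
        switch_times=switch_times, wave_durations_s=waves,
        dwell_front_s=float((zones_arr == "front").sum()) * dt,
        dwell_rear_s=float((zones_arr == "rear").sum()) * dt,
        dwell_interior_s=float((zones_arr == "interior").sum()) * dt,
        frame_interval=dt, pole_zone_um=pole_zone_um)


# ---------------------------------------------------------------------------
# front/back summaries

@dataclass
class FrontBackSummary:
    """Time-AUCs of leading-edge (bins 2-3), uropod (bins 18-19) and
    whole-cell (bins 1-20) activity."""

    leading_edge_auc: float
    uropod_auc: float
    whole_cell_auc: float
    window_s: tuple[float, float]


def front_back_summary(series: AxisProfileSeries) -> FrontBackSummary:
    """AUC over time of the leading-edge and uropod bin means (1-indexed
    bins 2-3 and 18-19) plus the whole-cell bin mean."""
    mat = series.bin_matrix
    valid_rows = np.any(np.isfinite(mat), axis=1)
    if valid_rows.sum() < 2:
        raise ValueError("need at least 2 frames with a valid profile")
    t = series.times[valid_rows]
    mat = mat[valid_rows]
    nb = series.n_bins
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        le = np.nanmean(mat[:, 1:3], axis=1)
        ur = np.nanmean(mat[:, nb - 3:nb - 1], axis=1)
        whole = np.nanmean(mat, axis=1)
    return FrontBackSummary(
        leading_edge_auc=float(np.trapezoid(le, t)),
        uropod_auc=float(np.trapezoid(ur, t)),
        whole_cell_auc=float(np.trapezoid(whole, t)),
        window_s=(float(t[0]), float(t[-1])))
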