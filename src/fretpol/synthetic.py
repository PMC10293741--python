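"""Synthetic two-channel FRET biosensor movies with known ground truth.

Renders single-plane (TIRF-like, basal surface) donor/acceptor time-lapse
stacks of a polarized migrating cell whose intracellular activity-ratio
field is fully specified: a front-high longitudinal gradient, an optional
activity peak travelling pole-to-pole as a triangle wave, and an optional
peripheral (edge-band) enrichment.  The acceptor channel is constructed as
``ratio x donor`` before noise, so with noise disabled the pixel-wise
acceptor/donor quotient reproduces the true field exactly — the property
every downstream recovery test rests on.

The default cell geometry is a 15.6 um-long, polarized outline (half-length
7.8 um), matching the mean body length used to define migrating cells in
micropipette chemotaxis assays.  Noise is Poisson photon noise followed by
additive Gaussian read noise, the standard EM-CCD approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.transform import AffineTransform, warp

from .io import TwoChannelMovie

__all__ = [
    "AcquisitionConfig",
    "CellModel",
    "ProtrusionEvent",
    "ActivityField",
    "GroundTruth",
    "affine_matrix",
    "apply_affine",
    "render_movie",
    "render_bead_field",
    "render_phagocytosis_scene",
    "stationary_trajectory",
    "linear_trajectory",
    "phased_trajectory",
]


# ---------------------------------------------------------------------------
# geometry helpers

def affine_matrix(translation: tuple[float, float] = (0.0, 0.0),
                  rotation_deg: float = 0.0,
                  scale: float = 1.0,
                  center: tuple[float, float] | None = None) -> np.ndarray:
    """Build a 3x3 planar affine matrix in (x, y) pixel coordinates.

    Rotation/scale are applied about ``center`` (default: origin), then the
    translation is added.
    """
    th = math.radians(rotation_deg)
    lin = scale * np.array([[math.cos(th), -math.sin(th)],
                            [math.sin(th), math.cos(th)]])
    m = np.eye(3)
    m[:2, :2] = lin
    t = np.asarray(translation, dtype=float)
    if center is not None:
        c = np.asarray(center, dtype=float)
        t = t + c - lin @ c
    m[:2, 2] = t
    return m


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 affine to an (N, 2) array of (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ matrix[:2, :2].T + matrix[:2, 2]
    return out if np.asarray(points).ndim == 2 else out[0]


def _is_identity(matrix: np.ndarray | None) -> bool:
    return matrix is None or np.allclose(matrix, np.eye(3), atol=1e-12)


def _warp_by_affine(img: np.ndarray, matrix_xy: np.ndarray) -> np.ndarray:
    """Resample ``img`` so a feature at p moves to ``matrix_xy @ p``."""
    tform = AffineTransform(matrix=np.linalg.inv(matrix_xy))
    return warp(img, tform, order=1, mode="constant", cval=0.0,
                preserve_range=True)


# ---------------------------------------------------------------------------
# configuration types

@dataclass
class AcquisitionConfig:
    """Imaging parameters of a simulated acquisition.

    ``photon_scale`` is the expected donor photon count at unit cell
    brightness; ``misalignment`` is a 3x3 planar affine (x, y pixel
    coordinates) displacing features in the acceptor channel, emulating the
    imperfect registration of a two-camera emission splitter.  With
    ``noise=False`` the expected (clean) images are returned.
    """

    pixel_size: float = 0.27          # um per pixel
    frame_interval: float = 1.0       # s
    frame_count: int = 120
    image_shape: tuple[int, int] = (128, 128)
    photon_scale: float = 200.0       # photons at unit intensity
    read_noise_sd: float = 3.0        # photons
    background: float = 0.0           # photons
    misalignment: np.ndarray | None = None
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.photon_scale < 0:
            raise ValueError("photon_scale must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.misalignment is not None:
            self.misalignment = np.asarray(self.misalignment, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frame_count) * self.frame_interval


@dataclass
class ProtrusionEvent:
    """A programmed leading-edge protrusion: a localized outward bump.

    The bump amplitude ramps linearly from 0 to ``amplitude_um`` over
    ``ramp_s`` seconds starting at ``onset_s``, holds, and retracts over the
    final ``ramp_s`` of ``duration_s``.  The outward advance rate during the
    ramp is therefore ``amplitude_um / ramp_s``.
    """

    onset_s: float
    duration_s: float
    direction_rad: float          # world angle of the bump centre
    amplitude_um: float = 2.5
    half_width_rad: float = 0.6
    ramp_s: float = 8.0

    def amplitude_at(self, t: float) -> float:
        dt = t - self.onset_s
        if dt < 0 or dt > self.duration_s:
            return 0.0
        rise = min(dt / self.ramp_s, 1.0)
        fall = min((self.duration_s - dt) / self.ramp_s, 1.0)
        return self.amplitude_um * max(min(rise, fall), 0.0)


@dataclass
class CellModel:
    """Smooth closed cell outline advected along a centroid trajectory.

    The base outline is an ellipse of half-length ``body_length_um / 2``
    along the heading and half-width ``body_width_um / 2``; programmed
    protrusion events add transient Gaussian bumps in given world
    directions.
    """

    centroids_um: np.ndarray           # (T, 2) x, y in um
    headings: np.ndarray               # (T, 2) unit vectors
    body_length_um: float = 15.6
    body_width_um: float = 9.0
    protrusions: list[ProtrusionEvent] = dc_field(default_factory=list)
    n_contour_points: int = 256

    def __post_init__(self) -> None:
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        norms = np.linalg.norm(self.headings, axis=1, keepdims=True)
        self.headings = self.headings / norms

    @property
    def n_frames(self) -> int:
        return self.centroids_um.shape[0]

    def contour_at(self, index: int, time_s: float) -> np.ndarray:
        """Closed outline at one frame, (N, 2) (x, y) in um (not repeated)."""
        c = self.centroids_um[index]
        h = self.headings[index]
        n = np.array([-h[1], h[0]])
        theta = np.linspace(0, 2 * np.pi, self.n_contour_points, endpoint=False)
        a = self.body_length_um / 2.0
        b = self.body_width_um / 2.0
        pts = (c[None, :]
               + a * np.cos(theta)[:, None] * h[None, :]
               + b * np.sin(theta)[:, None] * n[None, :])
        for ev in self.protrusions:
            amp = ev.amplitude_at(time_s)
            if amp <= 0:
                continue
            radial = pts - c[None, :]
            psi = np.arctan2(radial[:, 1], radial[:, 0])
            d = np.angle(np.exp(1j * (psi - ev.direction_rad)))
            bump = amp * np.exp(-(d ** 2) / (2 * ev.half_width_rad ** 2))
            unit = radial / np.linalg.norm(radial, axis=1, keepdims=True)
            pts = pts + bump[:, None] * unit
        if not Polygon(pts).is_valid:
            raise ValueError(f"self-intersecting contour at frame {index}")
        return pts


@dataclass
class ActivityField:
    """Phenomenological intracellular activity-ratio field.

    ratio(p) = baseline + gradient * (front-ness) + peak Gaussian, then
    multiplied by ``edge_enrichment`` within ``edge_band_um`` of the
    outline.  ``gradient_amplitude`` is the front-minus-back ratio
    difference.  When ``oscillation_cycle_s`` is set, the peak's axial
    position runs front -> back -> front as a triangle wave with that full
    period (so the pole-to-pole transit — one wave — takes half a cycle).
    """

    baseline_ratio: float = 1.0
    gradient_amplitude: float = 0.0
    peak_amplitude: float = 0.0
    peak_sigma_um: float = 1.5
    oscillation_cycle_s: float | None = None
    peak_fractions: np.ndarray | None = None   # explicit per-frame override
    edge_enrichment: float = 1.0
    edge_band_um: float = 0.8

    def peak_fraction(self, index: int, time_s: float) -> float | None:
        """Axial position of the peak, 0 = leading edge, 1 = uropod."""
        if self.peak_fractions is not None:
            return float(self.peak_fractions[index])
        if self.oscillation_cycle_s is None:
            return None
        phase = (time_s % self.oscillation_cycle_s) / self.oscillation_cycle_s
        return 2 * phase if phase <= 0.5 else 2 * (1 - phase)

    def evaluate(self, mask: np.ndarray, contour_um: np.ndarray,
                 centroid_um: np.ndarray, heading: np.ndarray,
                 pixel_size: float, peak_frac: float | None) -> np.ndarray:
        """True ratio image on the pixel grid; NaN outside the mask."""
        h, w = mask.shape
        xs = np.arange(w) * pixel_size
        ys = np.arange(h) * pixel_size
        X, Y = np.meshgrid(xs, ys)
        s = (X - centroid_um[0]) * heading[0] + (Y - centroid_um[1]) * heading[1]
        s_c = (contour_um - centroid_um) @ heading
        s_max, s_min = float(s_c.max()), float(s_c.min())
        frontness = (s - s_min) / (s_max - s_min)     # 1 at leading edge
        ratio = self.baseline_ratio + self.gradient_amplitude * frontness
        if peak_frac is not None and self.peak_amplitude > 0:
            center_s = s_max - peak_frac * (s_max - s_min)
            ratio = ratio + self.peak_amplitude * np.exp(
                -((s - center_s) ** 2) / (2 * self.peak_sigma_um ** 2))
        if self.edge_enrichment != 1.0:
            dist_in = ndimage.distance_transform_edt(mask) * pixel_size
            ratio = np.where(mask & (dist_in <= self.edge_band_um),
                             ratio * self.edge_enrichment, ratio)
        inside = ratio[mask]
        if inside.size and inside.min() <= 0:
            raise ValueError("activity field must be strictly positive inside the cell")
        out = np.full(mask.shape, np.nan)
        out[mask] = ratio[mask]
        return out


@dataclass
class GroundTruth:
    """Simulator truth for recovery tests (same frame count as the movie)."""

    ratio: np.ndarray                  # (T, H, W), NaN outside cell
    mask: np.ndarray                   # (T, H, W) bool
    centroids_um: np.ndarray           # (T, 2)
    headings: np.ndarray               # (T, 2)
    front_um: np.ndarray               # (T, 2) leading-edge extremal point
    rear_um: np.ndarray                # (T, 2) uropod extremal point
    axis_length_um: np.ndarray         # (T,)
    peak_fraction: np.ndarray | None   # (T,) axial fraction from front
    phase_labels: list[str]            # migrating | stalling | unlabeled
    events: dict
    pixel_size: float
    frame_interval: float
    particle_centers_um: np.ndarray | None = None
    particle_radius_um: float | None = None

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[0]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_frames) * self.frame_interval
        df = pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "time_s": t,
            "centroid_x_um": self.centroids_um[:, 0],
            "centroid_y_um": self.centroids_um[:, 1],
            "front_x_um": self.front_um[:, 0],
            "front_y_um": self.front_um[:, 1],
            "peak_axial_fraction": (self.peak_fraction
                                    if self.peak_fraction is not None
                                    else np.nan),
            "phase_label": self.phase_labels,
        })
        for name, value in self.events.items():
            df[f"event_{name}"] = value
        return df


# ---------------------------------------------------------------------------
# trajectories

def stationary_trajectory(center: tuple[float, float],
                          heading: tuple[float, float],
                          n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    c = np.tile(np.asarray(center, dtype=float), (n_frames, 1))
    h = np.tile(np.asarray(heading, dtype=float), (n_frames, 1))
    return c, h


def linear_trajectory(start: tuple[float, float],
                      direction: tuple[float, float],
                      speed_um_s: float, n_frames: int,
                      frame_interval: float) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    t = np.arange(n_frames) * frame_interval
    c = np.asarray(start, dtype=float)[None, :] + speed_um_s * t[:, None] * d[None, :]
    return c, np.tile(d, (n_frames, 1))


def phased_trajectory(start: tuple[float, float],
                      direction: tuple[float, float],
                      segments: list[tuple[float, float]],
                      frame_interval: float) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant-speed trajectory.

    ``segments`` is a list of ``(duration_s, speed_um_s)``; the heading is
    constant (the cell keeps pointing the same way while stalled).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    total = sum(dur for dur, _ in segments)
    n_frames = int(round(total / frame_interval)) + 1
    pos = np.zeros((n_frames, 2))
    p = np.asarray(start, dtype=float).copy()
    seg_iter = iter(segments)
    seg_end, seg_speed = next(seg_iter)
    t_prev = 0.0
    pos[0] = p
    for i in range(1, n_frames):
        t = i * frame_interval
        while t > seg_end + 1e-9:
            nxt = next(seg_iter, None)
            if nxt is None:
                break
            seg_end += nxt[0]
            seg_speed = nxt[1]
        p = p + seg_speed * (t - t_prev) * d
        pos[i] = p
        t_prev = t
    return pos, np.tile(d, (n_frames, 1))


# ---------------------------------------------------------------------------
# renderers

def _check_in_fov(contour_um: np.ndarray, acq: AcquisitionConfig,
                  index: int) -> None:
    h, w = acq.image_shape
    px = contour_um / acq.pixel_size
    if (px[:, 0].min() < 1 or px[:, 1].min() < 1
            or px[:, 0].max() > w - 2 or px[:, 1].max() > h - 2):
        raise ValueError(f"contour exits the field of view at frame {index}")


def _mask_from_contour(contour_um: np.ndarray,
                       acq: AcquisitionConfig) -> np.ndarray:
    poly_rc = contour_um[:, ::-1] / acq.pixel_size   # (row, col)
    return polygon2mask(acq.image_shape, poly_rc)


def _add_noise(clean: np.ndarray, acq: AcquisitionConfig,
               rng: np.random.Generator) -> np.ndarray:
    shot = rng.poisson(np.clip(clean, 0, None)).astype(float)
    return shot + rng.normal(0.0, acq.read_noise_sd, clean.shape)


def render_movie(cell: CellModel, field: ActivityField,
                 acq: AcquisitionConfig) -> tuple[TwoChannelMovie, GroundTruth]:
    """Render a two-channel movie of a cell with a known activity field.

    Donor intensity is uniform inside the cell (``photon_scale``); the clean
    acceptor is ``ratio x donor``.  The acceptor channel is then displaced by
    ``acq.misalignment`` (if any) and both channels receive Poisson + read
    noise when ``acq.noise`` is set.  Returns the movie and the matching
    :class:`GroundTruth`.
    """
    if cell.n_frames != acq.frame_count:
        raise ValueError(
            f"cell trajectory has {cell.n_frames} frames, "
            f"acquisition expects {acq.frame_count}")
    T = acq.frame_count
    H, W = acq.image_shape
    rng = np.random.default_rng(acq.seed)
    donor = np.empty((T, H, W))
    acceptor = np.empty((T, H, W))
    ratio_true = np.empty((T, H, W))
    mask_true = np.empty((T, H, W), dtype=bool)
    front = np.empty((T, 2))
    rear = np.empty((T, 2))
    axis_len = np.empty(T)
    peak_frac = np.empty(T)
    have_peak = False
    for i in range(T):
        t = i * acq.frame_interval
        contour = cell.contour_at(i, t)
        _check_in_fov(contour, acq, i)
        mask = _mask_from_contour(contour, acq)
        pf = field.peak_fraction(i, t)
        if pf is not None:
            have_peak = True
            peak_frac[i] = pf
        else:
            peak_frac[i] = np.nan
        ratio = field.evaluate(mask, contour, cell.centroids_um[i],
                               cell.headings[i], acq.pixel_size, pf)
        ratio_true[i] = ratio
        mask_true[i] = mask
        s = (contour - cell.centroids_um[i]) @ cell.headings[i]
        front[i] = contour[np.argmax(s)]
        rear[i] = contour[np.argmin(s)]
        axis_len[i] = s.max() - s.min()
        donor_clean = acq.background + acq.photon_scale * mask
        acc_clean = acq.background + acq.photon_scale * np.where(mask, ratio, 0.0)
        if not _is_identity(acq.misalignment):
            acc_clean = _warp_by_affine(acc_clean, acq.misalignment)
        if acq.noise:
            donor[i] = _add_noise(donor_clean, acq, rng)
            acceptor[i] = _add_noise(acc_clean, acq, rng)
        else:
            donor[i] = donor_clean
            acceptor[i] = acc_clean

    from .motility import label_phases_by_displacement
    labels = label_phases_by_displacement(cell.centroids_um, acq.frame_interval)
    gt = GroundTruth(
        ratio=ratio_true, mask=mask_true,
        centroids_um=cell.centroids_um.copy(), headings=cell.headings.copy(),
        front_um=front, rear_um=rear, axis_length_um=axis_len,
        peak_fraction=peak_frac if have_peak else None,
        phase_labels=labels, events={},
        pixel_size=acq.pixel_size, frame_interval=acq.frame_interval)
    movie = TwoChannelMovie(donor=donor, acceptor=acceptor,
                            pixel_size=acq.pixel_size,
                            frame_interval=acq.frame_interval,
                            meta={"kind": "cell", "ground_truth": gt,
                                  "misaligned": not _is_identity(acq.misalignment)})
    return movie, gt


def render_bead_field(n_beads: int, acq: AcquisitionConfig,
                      bead_sigma_px: float = 1.3,
                      amplitude: float = 1000.0,
                      min_separation_px: float = 20.0) -> TwoChannelMovie:
    """Render a single-frame calibration image pair of sub-resolution beads.

    Beads fluoresce in both channels; acceptor-channel bead positions are
    displaced by ``acq.misalignment``.  Bead layout is random but seeded.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads to constrain an affine transform")
    H, W = acq.image_shape
    rng = np.random.default_rng(acq.seed)
    margin = 12.0
    positions = []
    attempts = 0
    while len(positions) < n_beads:
        p = rng.uniform([margin, margin], [W - 1 - margin, H - 1 - margin])
        if all(np.hypot(*(p - q)) >= min_separation_px for q in positions):
            positions.append(p)
        attempts += 1
        if attempts > 20000:
            raise ValueError("could not place beads with requested separation")
    positions = np.array(positions)
    mis = acq.misalignment if acq.misalignment is not None else np.eye(3)
    acc_positions = apply_affine(mis, positions)

    X, Y = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))

    def spots(centers: np.ndarray) -> np.ndarray:
        img = np.zeros((H, W))
        for cx, cy in centers:
            img += amplitude * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2)
                                      / (2 * bead_sigma_px ** 2))
        return img

    donor_clean = acq.background + spots(positions)
    acc_clean = acq.background + spots(acc_positions)
    if acq.noise:
        donor_img = _add_noise(donor_clean, acq, rng)
        acc_img = _add_noise(acc_clean, acq, rng)
    else:
        donor_img, acc_img = donor_clean, acc_clean
    return TwoChannelMovie(
        donor=donor_img[None], acceptor=acc_img[None],
        pixel_size=acq.pixel_size, frame_interval=acq.frame_interval,
        meta={"kind": "beads",
              "bead_positions_px": positions.tolist(),
              "bead_positions_acceptor_px": acc_positions.tolist()})


def render_phagocytosis_scene(cell: CellModel, particle_diameter: float,
                              contact_time: float, engulfment_duration: float,
                              acq: AcquisitionConfig,
                              annulus_ratio: float = 2.0,
                              annulus_width_um: float = 0.5,
                              baseline_ratio: float = 1.0,
                              ) -> tuple[TwoChannelMovie, np.ndarray, GroundTruth]:
    """Render a particle-engulfment scene with a parallel brightfield stack.

    A rigid particle approaches the cell front, touches it at
    ``contact_time`` and is wrapped by a growing phagocytic cup over
    ``engulfment_duration``.  The true ratio is ``annulus_ratio`` in an
    annulus around the particle between contact and full engulfment and
    ``baseline_ratio`` elsewhere, emulating biosensor activity concentrated
    at the forming phagosome cup.
    """
    if particle_diameter <= 0:
        raise ValueError("particle_diameter must be > 0")
    movie_span = (acq.frame_count - 1) * acq.frame_interval
    if contact_time + engulfment_duration > movie_span:
        raise ValueError(
            f"contact_time + engulfment_duration ({contact_time + engulfment_duration} s) "
            f"exceeds the movie span ({movie_span} s)")
    if cell.n_frames != acq.frame_count:
        raise ValueError("cell trajectory frame count != acquisition frame count")

    T = acq.frame_count
    H, W = acq.image_shape
    ps = acq.pixel_size
    rng = np.random.default_rng(acq.seed)
    r_p = particle_diameter / 2.0
    margin = 2.5 * ps                      # cup margin so the particle ends inside
    approach_step = 4.0 * ps               # per-frame approach before contact

    contact_frame = int(round(contact_time / acq.frame_interval))
    engulf_frame = int(round((contact_time + engulfment_duration) / acq.frame_interval))

    donor = np.empty((T, H, W))
    acceptor = np.empty((T, H, W))
    bright = np.empty((T, H, W))
    ratio_true = np.empty((T, H, W))
    mask_true = np.empty((T, H, W), dtype=bool)
    centers = np.empty((T, 2))
    front = np.empty((T, 2))
    rear = np.empty((T, 2))
    axis_len = np.empty(T)

    xs = np.arange(W) * ps
    ys = np.arange(H) * ps
    X, Y = np.meshgrid(xs, ys)

    for i in range(T):
        t = i * acq.frame_interval
        contour = cell.contour_at(i, t)
        _check_in_fov(contour, acq, i)
        body = _mask_from_contour(contour, acq)
        c = cell.centroids_um[i]
        h = cell.headings[i]
        s = (contour - c) @ h
        front[i] = contour[np.argmax(s)]
        rear[i] = contour[np.argmin(s)]
        axis_len[i] = s.max() - s.min()
        # particle: boundary touches the cell edge at contact, approaches before
        touch = c + (s.max() + r_p) * h
        frames_to_contact = max(contact_frame - i, 0)
        pc = touch + frames_to_contact * approach_step * h
        centers[i] = pc
        d_pc = np.hypot(X - pc[0], Y - pc[1])
        disk = d_pc <= r_p
        # phagocytic cup: wrap angle grows linearly from contact to engulfment
        if i < contact_frame:
            cup = np.zeros_like(body)
        else:
            q = min((i - contact_frame) / max(engulf_frame - contact_frame, 1), 1.0)
            vx, vy = X - pc[0], Y - pc[1]
            toward_cell = c - pc
            toward_cell = toward_cell / np.linalg.norm(toward_cell)
            cosang = (vx * toward_cell[0] + vy * toward_cell[1]) / np.maximum(d_pc, 1e-9)
            wrap = np.arccos(np.clip(cosang, -1, 1)) <= q * np.pi + 1e-9
            cup = (d_pc <= r_p + margin) & wrap
        mask = body | cup
        mask_true[i] = mask
        ratio = np.full((H, W), np.nan)
        ratio[mask] = baseline_ratio
        if contact_frame <= i <= engulf_frame:
            annulus = mask & (d_pc > r_p) & (d_pc <= r_p + annulus_width_um)
            ratio[annulus] = annulus_ratio
        ratio_true[i] = ratio
        donor_clean = acq.background + acq.photon_scale * mask
        acc_clean = acq.background + acq.photon_scale * np.where(mask, ratio, 0.0)
        if not _is_identity(acq.misalignment):
            acc_clean = _warp_by_affine(acc_clean, acq.misalignment)
        bright_clean = 100.0 + 15.0 * body + 100.0 * disk
        bright_clean = ndimage.gaussian_filter(bright_clean, 1.0)
        if acq.noise:
            donor[i] = _add_noise(donor_clean, acq, rng)
            acceptor[i] = _add_noise(acc_clean, acq, rng)
            bright[i] = bright_clean + rng.normal(0, 2.0, (H, W))
        else:
            donor[i] = donor_clean
            acceptor[i] = acc_clean
            bright[i] = bright_clean

    from .motility import label_phases_by_displacement
    labels = label_phases_by_displacement(cell.centroids_um, acq.frame_interval)
    gt = GroundTruth(
        ratio=ratio_true, mask=mask_true,
        centroids_um=cell.centroids_um.copy(), headings=cell.headings.copy(),
        front_um=front, rear_um=rear, axis_length_um=axis_len,
        peak_fraction=None, phase_labels=labels,
        events={"contact_s": contact_time,
                "engulfment_s": contact_time + engulfment_duration,
                "contact_frame": contact_frame,
                "engulfment_frame": engulf_frame},
        pixel_size=ps, frame_interval=acq.frame_interval,
        particle_centers_um=centers, particle_radius_um=r_p)
    movie = TwoChannelMovie(
        donor=donor, acceptor=acceptor, pixel_size=ps,
        frame_interval=acq.frame_interval,
        meta={"kind": "phagocytosis", "brightfield": bright, "ground_truth": gt})
    return movie, bright, gt
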