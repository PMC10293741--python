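"""Phagosomal FRET and engulfment timing; fixed-scene uptake counts.

Particles (2 um microspheres by default) are detected in the parallel
brightfield stack and linked across frames by nearest neighbour.  Contact
is the first frame in which the particle boundary comes within one pixel
of the cell mask; full engulfment is the first frame in which the whole
particle disk lies inside the mask eroded by one pixel (the erosion guards
against boundary-pixel flicker — the published assays judged this
visually).  The phagosome signal is read from the in-mask annulus around
the particle rather than the particle disk itself, since the biosensor
signal lives in the cup membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log

from .io import RatioMovie
from .polarity import CellTrack

__all__ = [
    "ParticleTrack",
    "PhagosomeTrace",
    "detect_particles",
    "phagosome_trace",
    "count_uptake",
]


@dataclass
class ParticleTrack:
    """A particle linked across frames."""

    frames: list[int]
    centers_um: np.ndarray       # (n, 2) x, y
    radius_um: float
    ambiguous: bool = False      # possibly a merged detection of two particles

    def center_at(self, frame: int) -> np.ndarray | None:
        if frame in self.frames:
            return self.centers_um[self.frames.index(frame)]
        return None


@dataclass
class PhagosomeTrace:
    """Per-frame phagosome-annulus FRET from contact to full engulfment."""

    times: np.ndarray
    mean_ratio: np.ndarray
    contact_s: float | None
    full_engulfment_s: float | None
    complete: bool

    @property
    def engulfment_time_s(self) -> float | None:
        """Full engulfment minus contact; None unless engulfment completed."""
        if not self.complete:
            return None
        return self.full_engulfment_s - self.contact_s


def detect_particles(brightfield: np.ndarray, pixel_size: float,
                     frame_interval: float,
                     particle_diameter_um: float = 2.0,
                     diameter_tolerance: float = 0.3,
                     threshold_rel: float = 0.15) -> list[ParticleTrack]:
    """Detect circular particles of the expected size and link them.

    Blob detection (Laplacian of Gaussian) at the expected radius +/- the
    tolerance; detections are linked frame-to-frame by nearest neighbour
    within one particle diameter.  A detection whose integrated intensity
    is far above the cohort median is flagged ambiguous (likely two
    unresolved particles).  Zero detections is not an error.
    """
    if particle_diameter_um <= 0:
        raise ValueError("particle_diameter_um must be > 0")
    bf = np.asarray(brightfield, dtype=float)
    if bf.ndim == 2:
        bf = bf[None]
    r_px = particle_diameter_um / 2.0 / pixel_size
    sig_lo = (1 - diameter_tolerance) * r_px / np.sqrt(2)
    sig_hi = (1 + diameter_tolerance) * r_px / np.sqrt(2)
    link_px = particle_diameter_um / pixel_size
    tracks: list[ParticleTrack] = []
    active: list[ParticleTrack] = []
    masses_all: list[float] = []
    detections_per_frame = []
    for t in range(bf.shape[0]):
        frame = bf[t]
        norm = frame - np.median(frame)
        scale = np.abs(norm).max()
        if scale <= 0:
            detections_per_frame.append([])
            continue
        blobs = blob_log(norm / scale, min_sigma=sig_lo, max_sigma=sig_hi,
                         num_sigma=5, threshold=threshold_rel)
        dets = []
        for row, col, sig in blobs:
            rr = int(round(row))
            cc = int(round(col))
            win = int(np.ceil(r_px)) + 2
            r0, r1 = max(rr - win, 0), min(rr + win + 1, frame.shape[0])
            c0, c1 = max(cc - win, 0), min(cc + win + 1, frame.shape[1])
            patch = norm[r0:r1, c0:c1]
            mass = float(np.clip(patch, 0, None).sum())
            dets.append({"xy": np.array([col, row]), "mass": mass})
            masses_all.append(mass)
        detections_per_frame.append(dets)
    median_mass = np.median(masses_all) if masses_all else 0.0
    for t, dets in enumerate(detections_per_frame):
        unmatched = list(dets)
        next_active = []
        for tr in active:
            last = tr.centers_um[-1] / pixel_size
            if unmatched:
                dists = [np.linalg.norm(d["xy"] - last) for d in unmatched]
                j = int(np.argmin(dists))
                if dists[j] <= link_px:
                    d = unmatched.pop(j)
                    tr.frames.append(t)
                    tr.centers_um = np.vstack([tr.centers_um,
                                               d["xy"] * pixel_size])
                    if median_mass > 0 and d["mass"] > 1.3 * median_mass:
                        tr.ambiguous = True
                    next_active.append(tr)
                    continue
        for d in unmatched:
            tr = ParticleTrack(frames=[t],
                               centers_um=(d["xy"] * pixel_size)[None, :],
                               radius_um=particle_diameter_um / 2.0,
                               ambiguous=(median_mass > 0
                                          and d["mass"] > 1.3 * median_mass))
            tracks.append(tr)
            next_active.append(tr)
        active = next_active
    return tracks


def phagosome_trace(ratio: RatioMovie, cell_track: CellTrack,
                    particle: ParticleTrack,
                    annulus_width_um: float = 0.5) -> PhagosomeTrace:
    """Phagosome-annulus mean FRET from particle contact to full engulfment.

    Contact: particle boundary within one pixel of the cell mask.  Full
    engulfment: particle disk entirely inside the mask eroded by one pixel.
    The trace covers contact..engulfment frames (or to the end of
    co-occurrence when engulfment is never reached; ``complete`` False).
    """
    ps = ratio.pixel_size
    dt = ratio.frame_interval
    r_px = particle.radius_um / ps
    mask_by_index = {tf.index: tf.mask for tf in cell_track.frames}
    contact_f: int | None = None
    engulf_f: int | None = None
    common = [f for f in particle.frames if f in mask_by_index]
    if not common:
        return PhagosomeTrace(times=np.array([]), mean_ratio=np.array([]),
                              contact_s=None, full_engulfment_s=None,
                              complete=False)
    H, W = ratio.ratio.shape[1:]
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    records = []
    for f in common:
        pc = particle.center_at(f) / ps
        mask = mask_by_index[f]
        d_pc = np.hypot(X - pc[0], Y - pc[1])
        disk = d_pc <= r_px
        if contact_f is None:
            dist_to_mask = ndimage.distance_transform_edt(~mask)
            boundary = disk & (d_pc >= r_px - 1.0)
            if boundary.any() and dist_to_mask[boundary].min() <= 1.0:
                contact_f = f
        if contact_f is not None and engulf_f is None:
            eroded = ndimage.binary_erosion(mask)
            if disk.any() and np.all(eroded[disk]):
                engulf_f = f
        if contact_f is not None:
            annulus = (mask & ratio.valid[f] & (d_pc > r_px)
                       & (d_pc <= r_px + annulus_width_um / ps))
            val = (float(ratio.ratio[f][annulus].mean())
                   if annulus.any() else np.nan)
            records.append((f * dt, val))
        if engulf_f is not None:
            break
    if contact_f is None:
        return PhagosomeTrace(times=np.array([]), mean_ratio=np.array([]),
                              contact_s=None, full_engulfment_s=None,
                              complete=False)
    times, vals = (np.array([r[0] for r in records]),
                   np.array([r[1] for r in records]))
    return PhagosomeTrace(
        times=times, mean_ratio=vals,
        contact_s=contact_f * dt,
        full_engulfment_s=engulf_f * dt if engulf_f is not None else None,
        complete=engulf_f is not None)


# ---------------------------------------------------------------------------
# fixed-cell uptake counts

@dataclass
class FixedCell:
    """A segmented cell in a fixed-scene image."""

    mask: np.ndarray
    centroid_px: np.ndarray


@dataclass
class FixedParticle:
    """A particle with the membrane-signal flag that marks true uptake
    (distinguishing internalized phagosomes from surface-attached beads)."""

    position_px: np.ndarray
    membrane_flag: bool


def count_uptake(cells: list[FixedCell], particles: list[FixedParticle]
                 ) -> tuple[np.ndarray, float]:
    """Particles taken up per cell and the fraction of cells with >= 1.

    A particle counts as taken up iff its position lies inside a cell mask
    AND its membrane flag is positive.  A particle inside two overlapping
    masks is assigned to the nearer centroid, with a warning.
    """
    if not cells:
        raise ValueError("no cells in the scene")
    counts = np.zeros(len(cells), dtype=int)
    for p in particles:
        col, row = int(round(p.position_px[0])), int(round(p.position_px[1]))
        owners = []
        for i, cell in enumerate(cells):
            H, W = cell.mask.shape
            if 0 <= row < H and 0 <= col < W and cell.mask[row, col]:
                owners.append(i)
        if not owners:
            continue
        if len(owners) > 1:
            warnings.warn("particle inside overlapping masks; assigned to "
                          "the nearer centroid", stacklevel=2)
            owners.sort(key=lambda i: np.linalg.norm(
                np.asarray(p.position_px, dtype=float) - cells[i].centroid_px))
        if p.membrane_flag:
            counts[owners[0]] += 1
    fraction = float(np.mean(counts >= 1))
    return counts, fraction
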