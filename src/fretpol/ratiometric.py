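"""Channel registration, smoothing and FRET-ratio computation.

The acceptor channel of a two-camera emission splitter is misaligned with
the donor channel by a small planar transform.  Following common practice,
the transform is estimated once per experiment from an image pair of beads
that fluoresce in both channels, then applied to every frame.  An affine
model (translation + rotation + scale/shear) is fitted to matched bead
centroids by least squares; this is a deliberate simplification of the
elastic registration sometimes used for this purpose — the physical
misalignment of a beam splitter is well described by an affine map, which
is exactly invertible.

After alignment, frames are smoothed with a circular mean filter (radius
2 px by default) and the pixel-wise acceptor/donor ratio is formed wherever
the donor signal clears a floor, which guards the division without biasing
low-signal ratios the way an additive epsilon would.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.morphology import disk
from skimage.transform import AffineTransform, estimate_transform, warp

from .io import RatioMovie, TwoChannelMovie

__all__ = [
    "RegistrationModel",
    "estimate_registration",
    "apply_registration",
    "smooth",
    "compute_ratio",
    "pseudocolor",
]


@dataclass
class RegistrationModel:
    """Planar affine mapping acceptor-channel (x, y) onto donor coordinates."""

    matrix: np.ndarray          # 3x3 homogeneous, acceptor -> donor
    residual_px: float          # mean landmark error after alignment

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValueError("registration transform is not invertible")
        if self.residual_px < 0:
            raise ValueError("residual must be >= 0")

    @property
    def inverse(self) -> np.ndarray:
        """3x3 affine mapping donor coordinates onto acceptor coordinates."""
        return np.linalg.inv(self.matrix)

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    @classmethod
    def identity(cls) -> "RegistrationModel":
        return cls(matrix=np.eye(3), residual_px=0.0)


# ---------------------------------------------------------------------------
# bead localization

def _refine_centroid(img: np.ndarray, peak_rc: np.ndarray,
                     radius: int = 5, iters: int = 6) -> np.ndarray | None:
    """Iterative intensity-weighted centroid around a peak; returns (x, y)."""
    H, W = img.shape
    r, c = float(peak_rc[0]), float(peak_rc[1])
    for _ in range(iters):
        r0, c0 = int(round(r)), int(round(c))
        if (r0 - radius < 0 or c0 - radius < 0
                or r0 + radius >= H or c0 + radius >= W):
            return None
        win = img[r0 - radius:r0 + radius + 1, c0 - radius:c0 + radius + 1]
        win = win - np.median(win[[0, -1], :])     # local background
        win = np.clip(win, 0, None)
        total = win.sum()
        if total <= 0:
            return None
        rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        r_new = r0 + (win * rr).sum() / total
        c_new = c0 + (win * cc).sum() / total
        if abs(r_new - r) < 1e-4 and abs(c_new - c) < 1e-4:
            r, c = r_new, c_new
            break
        r, c = r_new, c_new
    return np.array([c, r])     # (x, y)


def locate_beads(image: np.ndarray, min_distance: int = 8,
                 threshold_rel: float = 0.2) -> np.ndarray:
    """Sub-pixel bead centroids in one frame, as an (N, 2) (x, y) array."""
    peaks = peak_local_max(image, min_distance=min_distance,
                           threshold_rel=threshold_rel)
    out = []
    for p in peaks:
        c = _refine_centroid(image, p)
        if c is not None:
            out.append(c)
    return np.array(out).reshape(-1, 2)


def estimate_registration(bead_pair: TwoChannelMovie,
                          max_displacement_px: float = 8.0) -> RegistrationModel:
    """Fit the acceptor->donor affine from a bead calibration image pair.

    Beads are localized independently in each channel, matched by nearest
    neighbour (within ``max_displacement_px``), and the affine is fitted by
    least squares.  Raises if fewer than 3 matched landmarks remain or if
    the landmarks are collinear.
    """
    donor_pts = locate_beads(bead_pair.donor[0])
    acc_pts = locate_beads(bead_pair.acceptor[0])
    matches_d, matches_a = [], []
    for p in donor_pts:
        if acc_pts.size == 0:
            break
        d = np.linalg.norm(acc_pts - p, axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_displacement_px:
            matches_d.append(p)
            matches_a.append(acc_pts[j])
    if len(matches_d) < 3:
        raise ValueError(
            f"only {len(matches_d)} matched bead landmarks; "
            "at least 3 are required to fit an affine transform")
    src = np.array(matches_a)
    dst = np.array(matches_d)
    centered = dst - dst.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-6 * max(sv[0], 1.0):
        raise ValueError("bead landmarks are collinear; affine fit is degenerate")
    tform = estimate_transform("affine", src, dst)
    residual = float(np.mean(np.linalg.norm(tform(src) - dst, axis=1)))
    return RegistrationModel(matrix=np.asarray(tform.params), residual_px=residual)


def apply_registration(movie: TwoChannelMovie,
                       model: RegistrationModel) -> TwoChannelMovie:
    """Resample every acceptor frame into donor coordinates.

    Donor frames are untouched.  Bilinear interpolation; samples that fall
    outside the source frame become NaN (invalid) rather than extrapolated.
    """
    tform = AffineTransform(matrix=model.matrix)
    # warp's inverse_map maps output (donor) coords to input (acceptor)
    # coords; the model maps acceptor -> donor, so its inverse is wanted.
    aligned = np.empty_like(movie.acceptor)
    for i in range(movie.n_frames):
        aligned[i] = warp(movie.acceptor[i], tform.inverse, order=1,
                          mode="constant", cval=np.nan, preserve_range=True)
    return TwoChannelMovie(donor=movie.donor.copy(), acceptor=aligned,
                           pixel_size=movie.pixel_size,
                           frame_interval=movie.frame_interval,
                           meta=dict(movie.meta))


# ---------------------------------------------------------------------------
# smoothing and ratio

def _disk_mean(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """NaN-aware normalized mean filter (NaN pixels contribute nothing)."""
    valid = np.isfinite(img)
    num = ndimage.correlate(np.where(valid, img, 0.0), footprint,
                            mode="constant", cval=0.0)
    den = ndimage.correlate(valid.astype(float), footprint,
                            mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def smooth(movie: TwoChannelMovie, radius_px: int = 2) -> TwoChannelMovie:
    """Replace each pixel by the mean of its circular neighbourhood.

    ``radius_px=2`` gives the 13-pixel discrete disk; radius 0 is the
    identity.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return TwoChannelMovie(donor=movie.donor.copy(),
                               acceptor=movie.acceptor.copy(),
                               pixel_size=movie.pixel_size,
                               frame_interval=movie.frame_interval,
                               meta=dict(movie.meta))
    footprint = disk(radius_px).astype(float)
    donor = np.stack([_disk_mean(f, footprint) for f in movie.donor])
    acceptor = np.stack([_disk_mean(f, footprint) for f in movie.acceptor])
    return TwoChannelMovie(donor=donor, acceptor=acceptor,
                           pixel_size=movie.pixel_size,
                           frame_interval=movie.frame_interval,
                           meta=dict(movie.meta))


def default_donor_floor(movie: TwoChannelMovie) -> float:
    """Donor floor from metadata if present, else 1% of the dynamic range."""
    meta = movie.meta
    if "background" in meta and "read_noise_sd" in meta:
        return float(meta["background"]) + 3.0 * float(meta["read_noise_sd"])
    finite = movie.donor[np.isfinite(movie.donor)]
    if finite.size == 0:
        return 0.0
    return float(finite.min() + 0.01 * (finite.max() - finite.min()))


def compute_ratio(movie: TwoChannelMovie,
                  donor_floor: float | None = None) -> RatioMovie:
    """Pixel-wise acceptor/donor ratio wherever the donor clears the floor.

    Pixels with donor below ``donor_floor`` (or non-finite, or with
    non-positive acceptor) are invalid — never infinite or NaN-propagating.
    """
    if donor_floor is not None and donor_floor < 0:
        raise ValueError("donor_floor must be >= 0")
    if donor_floor is None:
        donor_floor = default_donor_floor(movie)
    valid = (np.isfinite(movie.donor) & np.isfinite(movie.acceptor)
             & (movie.donor >= donor_floor) & (movie.donor > 0)
             & (movie.acceptor > 0))
    ratio = np.full(movie.donor.shape, np.nan)
    ratio[valid] = movie.acceptor[valid] / movie.donor[valid]
    return RatioMovie(ratio=ratio, valid=valid,
                      pixel_size=movie.pixel_size,
                      frame_interval=movie.frame_interval,
                      meta=dict(movie.meta))


# ---------------------------------------------------------------------------
# pseudocolouring

#: 16-level blue-to-red lookup table in the style of the Fiji "16 colors"
#: map: low ratios cold (blue), high ratios hot (red/white-red).
_LUT16 = np.array([
    (0, 0, 168), (0, 0, 255), (0, 85, 255), (0, 170, 255),
    (0, 255, 255), (0, 255, 170), (0, 255, 85), (0, 255, 0),
    (85, 255, 0), (170, 255, 0), (255, 255, 0), (255, 198, 0),
    (255, 130, 0), (255, 64, 0), (255, 0, 0), (200, 0, 0),
], dtype=np.uint8)


def pseudocolor(ratio: RatioMovie, lut_range: tuple[float, float],
                background_color: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
    """Discrete 16-level pseudocolour rendering of a ratio movie.

    Ratios at/below ``low`` map to the bottom level, at/above ``high`` to
    the top level; invalid pixels get ``background_color``.  Returns a
    (T, H, W, 3) uint8 stack.
    """
    low, high = lut_range
    if low >= high:
        raise ValueError("lut_range must satisfy low < high")
    levels = np.floor((ratio.ratio - low) / (high - low) * 16).astype(float)
    levels = np.clip(np.nan_to_num(levels, nan=0.0), 0, 15).astype(int)
    out = _LUT16[levels]
    out[~ratio.valid] = np.asarray(background_color, dtype=np.uint8)
    return out
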