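"""Containers and file I/O for two-channel FRET movies.

A movie is a pair of single-plane time-lapse stacks (donor and acceptor
emission of the same biosensor) with the acquisition metadata needed to
convert between pixels/frames and physical units.  Stacks are stored as
float arrays of shape (T, H, W); invalid pixels (e.g. resampling borders)
are NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TwoChannelMovie",
    "RatioMovie",
    "write_movie",
    "read_movie",
    "write_ratio_movie",
    "read_ratio_movie",
]


@dataclass
class TwoChannelMovie:
    """Paired donor/acceptor frame stacks plus acquisition metadata.

    Parameters
    ----------
    donor, acceptor : ndarray, shape (T, H, W)
        Emission intensity stacks.  The two stacks must have equal shape.
    pixel_size : float
        Lateral sampling, micrometres per pixel.
    frame_interval : float
        Time between frames, seconds.
    meta : dict
        Free-form sidecar metadata (scene kind, simulator ground-truth
        handles, bead positions, ...).  Never interpreted by the core
        processing functions.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    pixel_size: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape:
            raise ValueError(
                f"channel shape mismatch: donor {self.donor.shape} vs "
                f"acceptor {self.acceptor.shape}"
            )
        if self.donor.ndim != 3:
            raise ValueError("stacks must be (T, H, W)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.donor.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class RatioMovie:
    """Per-frame acceptor/donor ratio images with a validity mask.

    ``ratio`` is NaN wherever ``valid`` is False; every defined pixel is
    finite and strictly positive.
    """

    ratio: np.ndarray
    valid: np.ndarray
    pixel_size: float
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.ratio.shape != self.valid.shape:
            raise ValueError("ratio/valid shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def write_movie(movie: TwoChannelMovie, directory: str | Path,
                ground_truth: pd.DataFrame | None = None) -> Path:
    """Write a movie as per-channel 32-bit TIFF stacks plus a JSON sidecar.

    Creates ``donor.tif``, ``acceptor.tif``, ``acquisition.json`` and, when
    present in ``movie.meta``, ``brightfield.tif`` and ``ground_truth.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "donor.tif", movie.donor.astype(np.float32))
    tifffile.imwrite(directory / "acceptor.tif", movie.acceptor.astype(np.float32))
    meta = {k: v for k, v in movie.meta.items()
            if isinstance(v, (str, int, float, bool, list, dict))}
    sidecar = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "frame_count": movie.n_frames,
        "meta": meta,
    }
    (directory / "acquisition.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    bf = movie.meta.get("brightfield")
    if bf is not None:
        tifffile.imwrite(directory / "brightfield.tif", np.asarray(bf, dtype=np.float32))
    if ground_truth is not None:
        ground_truth.to_csv(directory / "ground_truth.csv", index=False)
    return directory


def read_movie(directory: str | Path) -> TwoChannelMovie:
    """Read a movie written by :func:`write_movie`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "acquisition.json").read_text())
    donor = tifffile.imread(directory / "donor.tif").astype(float)
    acceptor = tifffile.imread(directory / "acceptor.tif").astype(float)
    if donor.ndim == 2:
        donor = donor[None]
        acceptor = acceptor[None]
    meta = dict(sidecar.get("meta", {}))
    bf_path = directory / "brightfield.tif"
    if bf_path.exists():
        bf = tifffile.imread(bf_path).astype(float)
        meta["brightfield"] = bf if bf.ndim == 3 else bf[None]
    return TwoChannelMovie(
        donor=donor,
        acceptor=acceptor,
        pixel_size=float(sidecar["pixel_size_um"]),
        frame_interval=float(sidecar["frame_interval_s"]),
        meta=meta,
    )


def write_ratio_movie(ratio: RatioMovie, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "ratio.tif", ratio.ratio.astype(np.float32))
    tifffile.imwrite(directory / "ratio_valid.tif",
                     ratio.valid.astype(np.uint8))
    sidecar = {
        "pixel_size_um": ratio.pixel_size,
        "frame_interval_s": ratio.frame_interval,
    }
    (directory / "ratio.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return directory


def read_ratio_movie(directory: str | Path) -> RatioMovie:
    directory = Path(directory)
    sidecar = json.loads((directory / "ratio.json").read_text())
    return RatioMovie(
        ratio=tifffile.imread(directory / "ratio.tif").astype(float),
        valid=tifffile.imread(directory / "ratio_valid.tif").astype(bool),
        pixel_size=float(sidecar["pixel_size_um"]),
        frame_interval=float(sidecar["frame_interval_s"]),
    )
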