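"""Preset synthetic scenes covering every quantified imaging scenario.

Each builder returns the rendered movie plus its ground truth, with the
study-condition defaults baked in: a 15.6 um polarized cell, 1 s or 5 s
frame intervals, a 2 min observation window for chemotaxis, a peak that
oscillates pole-to-pole with an 16 s full cycle (~8 s per wave), 20 s /
2 um chemokinesis phases, and a 2 um particle-engulfment scene.
"""

from __future__ import annotations

import numpy as np

from .io import TwoChannelMovie
from .synthetic import (AcquisitionConfig, ActivityField, CellModel,
                        GroundTruth, ProtrusionEvent, affine_matrix,
                        linear_trajectory, phased_trajectory,
                        render_bead_field, render_movie,
                        render_phagocytosis_scene, stationary_trajectory)

__all__ = [
    "oscillating_peak_scene",
    "migration_scene",
    "chemokinesis_scene",
    "chemotaxis_turn_scene",
    "phagocytosis_scene",
    "bead_scene",
    "SCENES",
]


def _shape_for(path_um: float, body_um: float, pixel_size: float,
               margin_um: float = 6.0) -> tuple[int, int]:
    side = int(np.ceil((path_um + body_um + 2 * margin_um) / pixel_size))
    return (max(side, 96), max(side, 96))


def oscillating_peak_scene(full_cycle_s: float = 16.0,
                           frame_interval: float = 1.0,
                           n_frames: int = 120,
                           noise: bool = False,
                           seed: int = 1,
                           pixel_size: float = 0.27,
                           gradient_amplitude: float = 0.0,
                           ) -> tuple[TwoChannelMovie, GroundTruth]:
    """Stationary polarized cell with peak activity running pole-to-pole.

    The peak's axial position is a triangle wave with period
    ``full_cycle_s`` (front -> back -> front), so each pole-to-pole wave
    takes half a cycle.
    """
    acq = AcquisitionConfig(pixel_size=pixel_size,
                            frame_interval=frame_interval,
                            frame_count=n_frames, image_shape=(128, 128),
                            noise=noise, seed=seed)
    center = (64 * pixel_size, 64 * pixel_size)
    c, h = stationary_trajectory(center, (1.0, 0.0), n_frames)
    cell = CellModel(centroids_um=c, headings=h)
    field = ActivityField(baseline_ratio=1.0,
                          gradient_amplitude=gradient_amplitude,
                          peak_amplitude=0.6, peak_sigma_um=1.5,
                          oscillation_cycle_s=full_cycle_s)
    return render_movie(cell, field, acq)


def migration_scene(speed_um_s: float = 0.15, duration_s: float = 120.0,
                    frame_interval: float = 1.0, noise: bool = False,
                    seed: int = 1, pixel_size: float = 0.27,
                    gradient_amplitude: float = 0.4,
                    ) -> tuple[TwoChannelMovie, GroundTruth]:
    """Cell translating east at constant speed with a front-high gradient."""
    n_frames = int(round(duration_s / frame_interval)) + 1
    path = speed_um_s * duration_s
    shape = _shape_for(path, 15.6, pixel_size)
    acq = AcquisitionConfig(pixel_size=pixel_size,
                            frame_interval=frame_interval,
                            frame_count=n_frames, image_shape=shape,
                            noise=noise, seed=seed)
    start = (6.0 + 7.8, shape[0] * pixel_size / 2)
    c, h = linear_trajectory(start, (1.0, 0.0), speed_um_s, n_frames,
                             frame_interval)
    cell = CellModel(centroids_um=c, headings=h)
    field = ActivityField(baseline_ratio=1.0,
                          gradient_amplitude=gradient_amplitude)
    return render_movie(cell, field, acq)


def chemokinesis_scene(segments: list[tuple[float, float]] | None = None,
                       frame_interval: float = 1.0, noise: bool = False,
                       seed: int = 1, pixel_size: float = 0.27,
                       ) -> tuple[TwoChannelMovie, GroundTruth]:
    """Move / stall / move trajectory for phase classification.

    Default: 40 s at 0.15 um/s, 30 s stalled, 40 s at 0.15 um/s — phases
    comfortably longer than the 20 s / 2 um classification criteria.
    """
    if segments is None:
        segments = [(40.0, 0.15), (30.0, 0.0), (40.0, 0.15)]
    path = sum(d * s for d, s in segments)
    shape = _shape_for(path, 15.6, pixel_size)
    c, h = phased_trajectory((6.0 + 7.8, shape[0] * pixel_size / 2),
                             (1.0, 0.0), segments, frame_interval)
    acq = AcquisitionConfig(pixel_size=pixel_size,
                            frame_interval=frame_interval,
                            frame_count=len(c), image_shape=shape,
                            noise=noise, seed=seed)
    cell = CellModel(centroids_um=c, headings=h)
    field = ActivityField(baseline_ratio=1.0, gradient_amplitude=0.4)
    movie, gt = render_movie(cell, field, acq)
    gt.events["segments"] = segments
    return movie, gt


def chemotaxis_turn_scene(needle_move_s: float = 60.0,
                          response_latency_s: float = 30.0,
                          n_frames: int = 121,
                          frame_interval: float = 1.0, noise: bool = False,
                          seed: int = 1, pixel_size: float = 0.27,
                          ) -> tuple[TwoChannelMovie, GroundTruth]:
    """Micropipette turning assay: needle due west, then moved due south.

    The cell initially protrudes toward the needle (west) and forms a new
    protrusion toward the relocated source ``response_latency_s`` after
    the move.
    """
    acq = AcquisitionConfig(pixel_size=pixel_size,
                            frame_interval=frame_interval,
                            frame_count=n_frames, image_shape=(160, 160),
                            noise=noise, seed=seed)
    center = (80 * pixel_size, 80 * pixel_size)
    c, h = stationary_trajectory(center, (-1.0, 0.0), n_frames)
    west = np.pi
    south = -np.pi / 2
    protrusions = [
        ProtrusionEvent(onset_s=5.0, duration_s=needle_move_s - 10.0,
                        direction_rad=west, amplitude_um=2.5, ramp_s=8.0),
        ProtrusionEvent(onset_s=needle_move_s + response_latency_s,
                        duration_s=30.0, direction_rad=south,
                        amplitude_um=2.5, ramp_s=8.0),
    ]
    cell = CellModel(centroids_um=c, headings=h, protrusions=protrusions)
    field = ActivityField(baseline_ratio=1.0, gradient_amplitude=0.3)
    movie, gt = render_movie(cell, field, acq)
    gt.events.update({"needle_move_s": needle_move_s,
                      "needle_angle_before_rad": west,
                      "needle_angle_after_rad": south,
                      "true_turn_latency_s": response_latency_s})
    movie.meta["needle_move_s"] = needle_move_s
    return movie, gt


def phagocytosis_scene(contact_time_s: float = 20.0,
                       engulfment_duration_s: float = 60.0,
                       particle_diameter_um: float = 2.0,
                       frame_interval: float = 5.0, n_frames: int = 40,
                       noise: bool = False, seed: int = 1,
                       pixel_size: float = 0.27,
                       ) -> tuple[TwoChannelMovie, np.ndarray, GroundTruth]:
    """2 um particle engulfed by a stationary cell; brightfield in parallel."""
    acq = AcquisitionConfig(pixel_size=pixel_size,
                            frame_interval=frame_interval,
                            frame_count=n_frames, image_shape=(160, 160),
                            noise=noise, seed=seed)
    center = (60 * pixel_size, 80 * pixel_size)
    c, h = stationary_trajectory(center, (1.0, 0.0), n_frames)
    cell = CellModel(centroids_um=c, headings=h)
    return render_phagocytosis_scene(cell, particle_diameter_um,
                                     contact_time_s, engulfment_duration_s,
                                     acq)


def bead_scene(n_beads: int = 10,
               translation_px: tuple[float, float] = (1.5, -0.5),
               rotation_deg: float = 0.0, noise: bool = False,
               seed: int = 1, pixel_size: float = 0.27,
               shape: tuple[int, int] = (128, 128)) -> TwoChannelMovie:
    """Bead calibration pair with an injected channel misalignment."""
    mis = affine_matrix(translation=translation_px,
                        rotation_deg=rotation_deg,
                        center=(shape[1] / 2, shape[0] / 2))
    acq = AcquisitionConfig(pixel_size=pixel_size, frame_interval=1.0,
                            frame_count=1, image_shape=shape,
                            misalignment=mis, noise=noise, seed=seed)
    return render_bead_field(n_beads, acq)


SCENES = {
    "migration": migration_scene,
    "chemokinesis": chemokinesis_scene,
    "chemotaxis-turn": chemotaxis_turn_scene,
    "oscillation": oscillating_peak_scene,
    "phagocytosis": phagocytosis_scene,
    "beads": bead_scene,
}
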