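"""Shared fixtures: rendered scenes are expensive, so they are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from fretpol.config import RunConfig
from fretpol.pipeline import analyze_movie
from fretpol.polarity import AxisProfile, AxisProfileSeries, CellTrack, TrackFrame
from fretpol.scenes import (chemokinesis_scene, chemotaxis_turn_scene,
                            migration_scene, oscillating_peak_scene,
                            phagocytosis_scene)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def osc16(default_config):
    """Oscillating-peak scene (16 s full cycle, 1 s frames, noiseless)."""
    movie, gt = oscillating_peak_scene(full_cycle_s=16.0, n_frames=120,
                                       noise=False, seed=1)
    bundle = analyze_movie(movie, default_config)
    return movie, gt, bundle


@pytest.fixture(scope="session")
def gradient_scene(default_config):
    """Slowly migrating cell with a front-high gradient (2.0 front -> 1.0
    back); motion makes the leading-edge assignment unambiguous."""
    movie, gt = migration_scene(speed_um_s=0.1, duration_s=30.0, noise=False,
                                seed=1, gradient_amplitude=1.0)
    bundle = analyze_movie(movie, default_config)
    return movie, gt, bundle


@pytest.fixture(scope="session")
def chemokin(default_config):
    """Move / stall / move chemokinesis scene (40 s / 30 s / 40 s)."""
    movie, gt = chemokinesis_scene(noise=False, seed=1)
    bundle = analyze_movie(movie, default_config)
    return movie, gt, bundle


@pytest.fixture(scope="session")
def turn_scene(default_config):
    """Micropipette turning scene: needle moved at 60 s, response at +30 s."""
    movie, gt = chemotaxis_turn_scene(noise=False, seed=1)
    bundle = analyze_movie(movie, default_config)
    return movie, gt, bundle


@pytest.fixture(scope="session")
def phago60(default_config):
    """Phagocytosis scene: contact 20 s, engulfment over 60 s, 5 s frames."""
    movie, bf, gt = phagocytosis_scene(contact_time_s=20.0,
                                       engulfment_duration_s=60.0,
                                       noise=False, seed=1)
    bundle = analyze_movie(movie, default_config)
    return movie, bf, gt, bundle


# ---------------------------------------------------------------------------
# fabricated-object helpers

def make_track(centroids, frame_interval=1.0, fronts=None, areas=None,
               pixel_size=0.27) -> CellTrack:
    """A minimal CellTrack from explicit centroid (and front) positions."""
    centroids = np.asarray(centroids, dtype=float)
    n = len(centroids)
    fronts = (np.asarray(fronts, dtype=float) if fronts is not None
              else centroids + np.array([5.0, 0.0]))
    areas = np.full(n, 115.0) if areas is None else np.asarray(areas, float)
    dummy_mask = np.ones((4, 4), dtype=bool)
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    frames = []
    for i in range(n):
        if i + 1 < n and np.linalg.norm(centroids[i + 1] - centroids[i]) > 0:
            h = centroids[i + 1] - centroids[i]
        elif i > 0 and np.linalg.norm(centroids[i] - centroids[i - 1]) > 0:
            h = centroids[i] - centroids[i - 1]
        else:
            h = np.array([1.0, 0.0])
        h = h / np.linalg.norm(h)
        frames.append(TrackFrame(
            index=i, time_s=i * frame_interval, mask=dummy_mask,
            contour_um=square + centroids[i], centroid_um=centroids[i],
            heading=h, front_um=fronts[i],
            rear_um=centroids[i] - (fronts[i] - centroids[i]),
            area_um2=float(areas[i])))
    return CellTrack(frames=frames, pixel_size=pixel_size,
                     frame_interval=frame_interval)


def make_series(peak_fractions, axis_length_um=15.6, n_samples=120,
                frame_interval=1.0, n_bins=20,
                peak_sigma_um=1.5) -> AxisProfileSeries:
    """Fabricate an axis-profile series with a peak at given axial fractions.

    ``peak_fractions`` entries may be None (gap frames).
    """
    d = (np.arange(n_samples) + 0.5) * axis_length_um / n_samples
    per_bin = n_samples // n_bins
    profiles = []
    for i, pf in enumerate(peak_fractions):
        if pf is None:
            profiles.append(None)
            continue
        vals = 1.0 + 0.6 * np.exp(-((d - pf * axis_length_um) ** 2)
                                  / (2 * peak_sigma_um ** 2))
        profiles.append(AxisProfile(
            distances_um=d, values=vals,
            bin_means=vals.reshape(n_bins, per_bin).mean(axis=1),
            axis_length_um=axis_length_um, frame_index=i,
            time_s=i * frame_interval))
    times = np.arange(len(peak_fractions)) * frame_interval
    return AxisProfileSeries(profiles=profiles, times=times,
                             frame_interval=frame_interval, n_bins=n_bins)
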