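"""End-to-end runs: register -> ratio -> segment -> track -> analyses.

Operates on a scene directory (per-channel TIFF stacks plus a JSON
sidecar, as written by the simulator or any compatible acquisition
export).  Writes per-cell CSVs with unit-bearing header comments, a
summary CSV, and a plain-text run log with ISO timestamps and the fully
resolved configuration.
"""

from __future__ import annotations

import datetime
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import morphometry, motility, phagocytosis, polarity, ratiometric
from .config import RunConfig
from .io import TwoChannelMovie, read_movie

__all__ = ["run_pipeline", "analyze_movie"]


def _write_csv(df: pd.DataFrame, path: Path, units_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units_comment}\n")
        df.to_csv(fh, index=False)


def _largest_masks(ratio_movie, movie, config) -> list[np.ndarray | None]:
    """Per-frame mask of the largest segmented cell."""
    masks: list[np.ndarray | None] = []
    for t in range(movie.n_frames):
        cells = morphometry.segment_frame(movie.donor[t], movie.pixel_size,
                                          frame_index=t)
        if not cells:
            masks.append(None)
        else:
            masks.append(max(cells, key=lambda c: c.area_um2).mask)
    return masks


def analyze_movie(movie: TwoChannelMovie, config: RunConfig,
                  registration: ratiometric.RegistrationModel | None = None,
                  ) -> dict:
    """Run the analysis stages on an in-memory movie; returns a bundle of
    tables and analysis objects keyed by stage name."""
    if registration is None:
        registration = ratiometric.RegistrationModel.identity()
    aligned = ratiometric.apply_registration(movie, registration)
    smoothed = ratiometric.smooth(aligned, config.smooth_radius_px)
    ratio = ratiometric.compute_ratio(smoothed, config.donor_floor)
    masks = _largest_masks(ratio, smoothed, config)
    track = polarity.build_track(masks, movie.frame_interval,
                                 movie.pixel_size)
    bundle: dict = {"ratio": ratio, "track": track,
                    "registration": registration}

    # morphometry per frame
    mean_fret = morphometry.whole_cell_mean_fret(ratio, track)
    morph = pd.DataFrame({
        "frame": [tf.index for tf in track.frames],
        "time_s": [tf.time_s for tf in track.frames],
        "area_um2": [tf.area_um2 for tf in track.frames],
        "mean_fret": mean_fret.values,
    })
    bundle["morphometry"] = morph
    window = (mean_fret.times[0],
              min(mean_fret.times[0] + config.auc_window_s,
                  mean_fret.times[-1]))
    try:
        bundle["mean_fret_auc"] = morphometry.auc(mean_fret, window)
    except ValueError:
        bundle["mean_fret_auc"] = np.nan

    # polarity
    series = polarity.axis_profile_series(ratio, track, config.n_bins)
    bundle["profiles"] = series
    bundle["kymograph"] = polarity.kymograph(series)
    trace = polarity.peak_trace(series, config.pole_zone_um)
    bundle["peak_trace"] = trace
    bundle["front_back"] = polarity.front_back_summary(series)

    # motility
    try:
        _, _, vmean = motility.front_pixel_velocity(
            track, config.velocity_window_s)
    except ValueError:
        vmean = np.nan
    bundle["front_velocity_mean"] = vmean
    try:
        bundle["phases"] = motility.classify_phases(
            track, config.phase_min_duration_s, config.phase_displacement_um)
    except ValueError:
        bundle["phases"] = []
    path, net, length = motility.movement_plot(track)
    bundle["movement"] = {"path": path, "net_um": net, "length_um": length}
    try:
        bundle["migrating_half_body"] = motility.classify_migrating(
            track, "half-body-length",
            threshold_um=config.migration_half_body_um,
            period_s=config.migration_period_s)
    except ValueError:
        bundle["migrating_half_body"] = None

    # phagocytosis (when a brightfield stack is present)
    bf = movie.meta.get("brightfield")
    if bf is not None:
        particles = phagocytosis.detect_particles(
            np.asarray(bf), movie.pixel_size, movie.frame_interval,
            config.particle_diameter_um)
        traces = [phagocytosis.phagosome_trace(ratio, track, p,
                                               config.annulus_width_um)
                  for p in particles]
        bundle["particles"] = particles
        bundle["phagosome_traces"] = traces
    return bundle


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline on ``config.input_dir``; write CSVs + run log."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    log("run started")
    log("resolved configuration:")
    for line in config.to_yaml().splitlines():
        log_lines.append("    " + line)

    movie = read_movie(config.input_dir)
    log(f"loaded movie: {movie.n_frames} frames, "
        f"{movie.frame_shape}, {movie.pixel_size} um/px")

    beads_dir = Path(config.input_dir) / "beads"
    if beads_dir.exists():
        bead_pair = read_movie(beads_dir)
        registration = ratiometric.estimate_registration(bead_pair)
        log(f"registration from beads: residual {registration.residual_px:.3f} px")
    else:
        registration = ratiometric.RegistrationModel.identity()
        if movie.meta.get("misaligned", False):
            warnings.warn("misalignment declared but no bead calibration "
                          "found; using identity registration", stacklevel=2)
            log("WARNING: identity registration despite declared misalignment")
        else:
            log("no bead calibration; identity registration")

    bundle = analyze_movie(movie, config, registration)

    _write_csv(bundle["morphometry"], out / "morphometry.csv",
               "units: time_s [s], area_um2 [um^2], mean_fret [ratio]")
    kymo = pd.DataFrame(bundle["kymograph"],
                        columns=[f"bin_{i + 1}" for i in range(config.n_bins)])
    _write_csv(kymo, out / "kymograph.csv",
               "rows = frames, bin_1 at the leading edge [ratio]")
    _write_csv(bundle["peak_trace"].to_frame(), out / "peak_trace.csv",
               "units: time_s [s], peak_um_from_front [um]; "
               "oscillations counted as pole-switch events")
    trace = bundle["peak_trace"]
    fb = bundle["front_back"]
    summary = pd.DataFrame([{
        "n_switches": trace.n_switches,
        "mean_wave_s": trace.mean_wave_s,
        "dwell_front_s": trace.dwell_front_s,
        "dwell_rear_s": trace.dwell_rear_s,
        "leading_edge_auc": fb.leading_edge_auc,
        "uropod_auc": fb.uropod_auc,
        "whole_cell_auc": fb.whole_cell_auc,
        "mean_fret_auc": bundle["mean_fret_auc"],
        "front_velocity_um_s": bundle["front_velocity_mean"],
        "net_displacement_um": bundle["movement"]["net_um"],
        "path_length_um": bundle["movement"]["length_um"],
        "migrating_half_body": bundle["migrating_half_body"],
    }])
    _write_csv(summary, out / "summary.csv",
               "units: *_s [s], *_um [um], *_auc [ratio x s], velocity [um/s]")
    phases = pd.DataFrame([{
        "start_s": p.start_s, "end_s": p.end_s, "label": p.label,
        "window_displacement_um": p.window_displacement_um,
    } for p in bundle.get("phases", [])])
    _write_csv(phases, out / "phases.csv",
               "units: start_s/end_s [s], window_displacement_um [um]")
    path_df = pd.DataFrame(bundle["movement"]["path"], columns=["x_um", "y_um"])
    _write_csv(path_df, out / "movement_path.csv",
               "origin-anchored centroid path [um]")
    if "phagosome_traces" in bundle:
        rows = []
        for i, tr in enumerate(bundle["phagosome_traces"]):
            rows.append({
                "particle": i,
                "contact_s": tr.contact_s,
                "full_engulfment_s": tr.full_engulfment_s,
                "engulfment_time_s": tr.engulfment_time_s,
                "complete": tr.complete,
            })
        _write_csv(pd.DataFrame(rows), out / "phagosomes.csv",
                   "units: *_s [s]")
    from .plots import plot_kymograph, plot_movement_path
    plot_kymograph(bundle["kymograph"], movie.frame_interval,
                   out / "kymograph.png")
    plot_movement_path(bundle["movement"]["path"], out / "movement_path.png")
    log("run finished")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    bundle["out_dir"] = out
    return bundle
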