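"""Run configuration and descriptive group summaries.

All quantitative defaults of the pipeline live in one block here: the
40 um^2 adhesion-count exclusion, the 20 s / 2 um phase criteria, the
7.8 um / one-cell-diameter migration thresholds, the 0.8 um pole zone,
the 0.4 um edge band, 20 axis bins and the 125 s AUC window.  Group
summaries stop at descriptive statistics (mean, SD, SEM, n) — inferential
testing is left to the surrounding analysis environment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "summarize_groups"]


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run."""

    input_dir: str = ""
    out_dir: str = "results"
    seed: int = 0
    # acquisition fallbacks (overridden by sidecar metadata when present)
    pixel_size_um: float = 0.27
    frame_interval_s: float = 1.0
    # ratiometric stage
    smooth_radius_px: int = 2
    donor_floor: float | None = None
    # morphometry
    min_area_um2: float = 40.0
    auc_window_s: float = 125.0
    # polarity
    n_bins: int = 20
    pole_zone_um: float = 0.8
    edge_band_um: float = 0.4
    n_angular_bins: int = 360
    # motility
    phase_min_duration_s: float = 20.0
    phase_displacement_um: float = 2.0
    migration_half_body_um: float = 7.8
    migration_period_s: float = 120.0
    diameter_period_s: float = 600.0
    velocity_window_s: float = 20.0
    # phagocytosis
    particle_diameter_um: float = 2.0
    annulus_width_um: float = 0.5

    def to_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())


def summarize_groups(table: pd.DataFrame, group_col: str,
                     value_cols: list[str] | None = None,
                     experiment_col: str | None = None) -> pd.DataFrame:
    """Per-group mean, SD, SEM and n for each metric column.

    With ``experiment_col`` set, each experiment is first reduced to its
    mean and the summary is taken across experiments (so each contributing
    unit is one experiment, matching per-experiment dot plots); otherwise
    cells are pooled.  Groups with no finite values are omitted with a
    warning.  A single-value group reports SD/SEM as NaN (undefined).
    """
    if value_cols is None:
        value_cols = [c for c in table.columns
                      if c not in (group_col, experiment_col)
                      and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for group, sub in table.groupby(group_col, sort=True):
        for col in value_cols:
            if experiment_col is not None:
                vals = sub.groupby(experiment_col)[col].mean().to_numpy(float)
            else:
                vals = sub[col].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            n = len(vals)
            if n == 0:
                import warnings
                warnings.warn(f"group {group!r} has no finite values for "
                              f"{col!r}; omitted", stacklevel=2)
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
            sem = sd / np.sqrt(n) if n > 1 else np.nan
            rows.append({"group": group, "metric": col, "mean": mean,
                         "sd": sd, "sem": sem, "n": n})
    return pd.DataFrame(rows, columns=["group", "metric", "mean", "sd",
                                       "sem", "n"])
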