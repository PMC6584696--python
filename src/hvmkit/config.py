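"""Analysis configuration: every tunable parameter of the pipeline.

The defaults target incident/sidestream dark field recordings of the
sublingual microcirculation at roughly 1-1.5 um/px and 25-60 frames/s.
All keys are exposed as a flat mapping so a run can be reproduced from a
single YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # --- stabilization ---
    stab_max_features: int = 400        # corners tracked per frame pair
    stab_min_features: int = 10         # below this the previous transform is inherited
    stab_min_distance: int = 8          # px, minimum corner spacing
    stab_window: int = 21               # px, Lucas-Kanade window side
    stab_pyr_levels: int = 3
    stab_iterations: int = 20
    stab_max_shift: float = 10.0        # px, larger per-pair estimates are rejected
    smoothing_window: int = 15          # frames, trajectory moving average (odd)

    # --- vessel detection ---
    sigma_capillary: float = 2.5        # px, detection scale of the capillary pass
    sigma_venule: float = 4.0           # px, detection scale on the downsampled venule pass
    venule_downsample: int = 4          # integer decimation factor for the venule pass
    steger_high: float = 0.012          # second-derivative response, hysteresis upper
    steger_low: float = 0.008           # hysteresis lower
    steger_high_venule: float = 0.004
    steger_low_venule: float = 0.002
    link_l: float = 2.5                 # px, max link distance between line points
    link_h: float = 0.5                 # rad, max normal-angle difference when linking
    min_centerline_px: float = 10.0     # px, shortest polyline kept
    vessel_merge_dist: float = 15.0      # px, endpoint gap bridged when joining vessel pieces
    vessel_merge_angle: float = 0.35    # rad, max direction mismatch when joining
    clahe_clip: float = 2.0             # relative histogram slope limit (>= 1)
    clahe_tiles: tuple[int, int] = (8, 8)
    capillary_max_diameter_um: float = 20.0
    min_vessel_contrast: float = 10.0   # gray levels, centerline darker than flanks
    min_venule_contrast: float = 12.0   # gray levels; venules are wide and strongly absorbing

    # --- space-time velocimetry ---
    frame_smooth_sigma: float = 1.0     # px, per-frame Gaussian smoothing
    std_sigma: float = 1.5              # px, detection scale inside diagrams
    std_high: float = 0.05
    std_low: float = 0.02
    std_link_l: float = 2.5
    std_link_h: float = 0.7             # rad; RBC streak curvature exceeds vessel curvature
    std_merge_dist: float = 8.0         # px, endpoint gap bridged when joining fragments
    std_merge_angle: float = 0.5        # rad, max direction mismatch when joining
    min_path_length: float = 25.0       # px, shortest accepted RBC path
    min_path_frames: float = 2.0        # frames a traceable cell must span
    curvature_index_cutoff: float = 0.8
    low_flow_cutoff: float = 25.0       # um/s, species-specific critical RBCv
    perfusion_fraction: float = 0.95    # fraction of normal-flow paths required
    perfusion_mode: str = "fraction"    # "fraction" or "normal_fit"

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd integer")
        if self.clahe_clip < 1:
            raise ValueError("clahe_clip must be >= 1")
        if not 0 < self.perfusion_fraction < 1:
            raise ValueError("perfusion_fraction must lie in (0, 1)")
        if self.perfusion_mode not in ("fraction", "normal_fit"):
            raise ValueError("perfusion_mode must be 'fraction' or 'normal_fit'")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["clahe_tiles"] = list(self.clahe_tiles)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "clahe_tiles" in data:
            data["clahe_tiles"] = tuple(data["clahe_tiles"])
        return cls(**data)
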