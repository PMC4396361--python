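"""Pipeline configuration: YAML-backed, with every analysis parameter at its
standard value and overridable.

Defaults: 33 µm map smoothing, 132 µm concentric-map smoothing, 0.1
percentage-point pedestal subtraction and 0.4 percentage-point inclusion for
patch fits, 0.5 percentage-point minimum per-condition response for the map
comparison, 2 Hz evoked-rate inclusion for units, 10,000 shuffles, alpha
0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import MonitorGeometry

__all__ = ["PipelineConfig", "geometry_to_dict", "geometry_from_dict"]


def geometry_to_dict(geom: MonitorGeometry) -> dict:
    return {
        "width_cm": geom.width_cm,
        "height_cm": geom.height_cm,
        "distance_cm": geom.distance_cm,
        "center_offset_cm": list(geom.center_offset_cm),
        "patch_centres_cm": np.asarray(geom.patch_centres_cm).tolist(),
        "head_pitch_deg": geom.head_pitch_deg,
        "head_roll_deg": geom.head_roll_deg,
        "ipsi_azimuth_sign": geom.ipsi_azimuth_sign,
    }


def geometry_from_dict(d: dict) -> MonitorGeometry:
    return MonitorGeometry(
        width_cm=float(d.get("width_cm", 93.0)),
        height_cm=float(d.get("height_cm", 52.3)),
        distance_cm=float(d.get("distance_cm", 29.5)),
        center_offset_cm=tuple(d.get("center_offset_cm", (0.0, 0.0))),
        patch_centres_cm=np.asarray(d.get("patch_centres_cm", np.zeros((0, 2)))),
        head_pitch_deg=float(d.get("head_pitch_deg", 0.0)),
        head_roll_deg=float(d.get("head_roll_deg", 0.0)),
        ipsi_azimuth_sign=int(d.get("ipsi_azimuth_sign", -1)),
    )


@dataclass
class PipelineConfig:
    # input paths
    stack_path: str | None = None
    schedule_path: str | None = None
    ephys_table_path: str | None = None
    # geometry
    geometry: dict = field(default_factory=dict)
    # imaging analysis parameters
    sigma_map_um: float = 33.0
    sigma_concentric_um: float = 132.0
    patch_subtract_dff: float = 0.001  # 0.1 percentage points
    patch_subtract_mode: str = "absolute"  # or "relative" (fraction of map max)
    patch_include_dff: float = 0.004  # 0.4 percentage points
    min_mean_response: float = 0.005  # 0.5 percentage points, per condition
    response_filter_mode: str = "all"  # strict: every condition must pass
    alpha: float = 0.05
    reference_roi_px: list[int] | None = None  # [row0, row1, col0, col1]
    n_map_permutations: int = 1000
    # ephys analysis parameters
    min_evoked_hz: float = 2.0
    n_shuffles: int = 10_000
    pref_method: str = "argmax"
    # shared
    seed: int = 0
    output_dir: str = "tectomap_out"

    def monitor_geometry(self) -> MonitorGeometry:
        return geometry_from_dict(self.geometry)

    def ref_roi_slices(self) -> tuple[slice, slice] | None:
        if self.reference_roi_px is None:
            return None
        r0, r1, c0, c1 = self.reference_roi_px
        return (slice(r0, r1), slice(c0, c1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
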