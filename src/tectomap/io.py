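"""File I/O: TIFF stacks with JSON sidecars, stimulus schedules, and map
serialisation (float TIFF with the mask as an extra page)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import ImagingStack, StimulusEvent, events_from_frame, events_to_frame
from .maps import AxialMap, ScalarMap

__all__ = [
    "write_stack",
    "read_stack",
    "write_schedule",
    "read_schedule",
    "save_scalar_map",
    "load_scalar_map",
    "save_axial_map",
    "load_axial_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImagingStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.frames, dtype=np.float32), photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {
                "frame_rate_hz": stack.frame_rate_hz,
                "pixel_size_um": stack.pixel_size_um,
                "t0_s": stack.t0_s,
            },
            indent=2,
        )
    )


def read_stack(path: str | Path) -> ImagingStack:
    path = Path(path)
    frames = tifffile.imread(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    return ImagingStack(
        frames=np.asarray(frames),
        frame_rate_hz=float(meta.get("frame_rate_hz", 1.8)),
        pixel_size_um=float(meta.get("pixel_size_um", 11.04)),
        t0_s=float(meta.get("t0_s", 0.0)),
    )


def write_schedule(events: list[StimulusEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_schedule(path: str | Path) -> list[StimulusEvent]:
    return events_from_frame(pd.read_csv(path))


def save_scalar_map(m: ScalarMap, path: str | Path) -> None:
    data = np.stack([m.values.astype(np.float32), m.mask.astype(np.float32)])
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def load_scalar_map(path: str | Path, units: str = "") -> ScalarMap:
    data = tifffile.imread(Path(path))
    return ScalarMap(values=data[0].astype(float), mask=data[1] > 0.5, units=units)


def save_axial_map(m: AxialMap, path: str | Path) -> None:
    data = np.stack(
        [m.angle_deg.astype(np.float32), m.amplitude.astype(np.float32), m.mask.astype(np.float32)]
    )
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def load_axial_map(path: str | Path) -> AxialMap:
    data = tifffile.imread(Path(path))
    mask = data[2] > 0.5
    angle = np.where(mask, data[0].astype(float) % 180.0, 0.0)
    return AxialMap(angle_deg=angle, amplitude=np.abs(data[1].astype(float)), mask=mask)
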