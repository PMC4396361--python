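"""HSV renderings of maps: hue encodes angle or patch identity, saturation
scales linearly with response amplitude (full saturation at the stated
maximum), value is fixed at 1.  Masked-out pixels render black."""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .maps import AxialMap, ScalarMap

__all__ = ["axial_to_rgb", "patch_to_rgb"]


def axial_to_rgb(m: AxialMap, max_amplitude: float | None = None) -> np.ndarray:
    """8-bit RGB rendering of an orientation map (hue = angle / 180)."""
    if max_amplitude is None:
        max_amplitude = float(m.amplitude[m.mask].max()) if m.mask.any() else 1.0
    hue = (m.angle_deg % 180.0) / 180.0
    sat = np.clip(m.amplitude / max(max_amplitude, 1e-30), 0.0, 1.0)
    val = m.mask.astype(float)
    rgb = hsv_to_rgb(np.dstack([hue, sat, val]))
    return (rgb * 255).round().astype(np.uint8)


def patch_to_rgb(
    patch: ScalarMap, amplitude: ScalarMap, n_patches: int, max_amplitude: float | None = None
) -> np.ndarray:
    """8-bit RGB rendering of a best-patch map (one hue per patch id)."""
    if max_amplitude is None:
        ok = amplitude.mask
        max_amplitude = float(amplitude.values[ok].max()) if ok.any() else 1.0
    hue = (patch.values % n_patches) / max(n_patches, 1)
    sat = np.clip(amplitude.values / max(max_amplitude, 1e-30), 0.0, 1.0)
    val = patch.mask.astype(float)
    rgb = hsv_to_rgb(np.dstack([hue, sat, val]))
    return (rgb * 255).round().astype(np.uint8)
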