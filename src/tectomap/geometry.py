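"""Visuotopic geometry: monitor to head-centred coordinates, retinotopy
interpolation, and the concentric-orientation prediction.

Head-centred coordinates follow the convention: *z* along the body axis
(positive in front of the nose), *x* to the animal's right, *y* above the
animal.  Spherical angles are ``azimuth = arctan(x/z)`` and
``elevation = arctan(y / sqrt(x^2 + z^2))``.

The concentric angle at visual-field position (x, y) is the orientation of a
grating tangent to the circle centred on the centre of vision through that
position: ``(90 - atan2_deg(y, x)) mod 180`` with 0° = horizontal.  On the
temporal horizontal axis (x > 0, y = 0) this is 90° (vertical); directly
above the nose it is 0° (horizontal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.typing import ArrayLike
from scipy import optimize
from scipy.interpolate import LinearNDInterpolator

from .circstats import circ_corr_axial
from .maps import AxialMap, ScalarMap, smooth_axial

__all__ = [
    "MonitorGeometry",
    "PatchFit",
    "RetinotopyMaps",
    "HeadAngleFit",
    "fit_patch_gaussian",
    "interpolate_retinotopy",
    "monitor_to_head_xyz",
    "xyz_to_spherical",
    "concentric_angle",
    "concentric_from_angles",
    "build_concentric_map",
    "fit_head_angles",
]


@dataclass
class MonitorGeometry:
    """Stimulus monitor placement and the retinotopic patch grid.

    ``patch_centres_cm`` are (x, y) positions of the patch centres on the
    monitor plane, in cm relative to the monitor centre (x rightward,
    y upward as seen by the animal).  ``center_offset_cm`` shifts the monitor
    centre off the nose axis.  ``head_pitch_deg`` pitches the head down
    (positive pitch raises the apparent elevation of the monitor),
    ``head_roll_deg`` rolls it about the body axis.
    """

    width_cm: float = 93.0
    height_cm: float = 52.3
    distance_cm: float = 29.5
    center_offset_cm: tuple[float, float] = (0.0, 0.0)
    patch_centres_cm: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    head_pitch_deg: float = 0.0
    head_roll_deg: float = 0.0
    #: sign of the azimuth of the ipsilateral hemifield (-1: ipsilateral is x < 0)
    ipsi_azimuth_sign: int = -1

    def __post_init__(self) -> None:
        self.patch_centres_cm = np.atleast_2d(np.asarray(self.patch_centres_cm, dtype=float))
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        if self.patch_centres_cm.size:
            px, py = self.patch_centres_cm[:, 0], self.patch_centres_cm[:, 1]
            if np.any(np.abs(px) > self.width_cm / 2) or np.any(np.abs(py) > self.height_cm / 2):
                raise ValueError("patch centres must lie on the monitor")

    @classmethod
    def with_patch_grid(
        cls,
        rows: int,
        cols: int,
        x_extent_cm: tuple[float, float] | None = None,
        y_extent_cm: tuple[float, float] | None = None,
        **kwargs,
    ) -> "MonitorGeometry":
        """Geometry with a regular rows x cols patch grid over the given extent.

        Patch centres sit at cell centres; the default extent is the full
        monitor.  Patch ids run row-major from the top-left patch, matching
        the order patches are indexed in stimulus schedules.
        """
        geom = cls(**kwargs)
        if x_extent_cm is None:
            x_extent_cm = (-geom.width_cm / 2, geom.width_cm / 2)
        if y_extent_cm is None:
            y_extent_cm = (-geom.height_cm / 2, geom.height_cm / 2)
        xs = np.linspace(*x_extent_cm, 2 * cols + 1)[1::2]
        ys = np.linspace(y_extent_cm[1], y_extent_cm[0], 2 * rows + 1)[1::2]
        cx, cy = np.meshgrid(xs, ys)
        geom.patch_centres_cm = np.column_stack([cx.ravel(), cy.ravel()])
        geom.__post_init__()
        return geom

    @property
    def n_patches(self) -> int:
        return self.patch_centres_cm.shape[0]


def _head_rotation(pitch_deg: float, roll_deg: float) -> np.ndarray:
    """World-to-head rotation: pitch about x applied first, then roll about z."""
    tp, tr = np.deg2rad(pitch_deg), np.deg2rad(roll_deg)
    pitch = np.array(
        [[1, 0, 0], [0, np.cos(tp), np.sin(tp)], [0, -np.sin(tp), np.cos(tp)]]
    )
    roll = np.array(
        [[np.cos(tr), np.sin(tr), 0], [-np.sin(tr), np.cos(tr), 0], [0, 0, 1]]
    )
    return roll @ pitch


def monitor_to_head_xyz(
    points_cm: ArrayLike,
    geom: MonitorGeometry,
    pitch_deg: float | None = None,
    roll_deg: float | None = None,
) -> np.ndarray:
    """Map monitor-plane points (cm, relative to monitor centre) to head xyz (cm).

    With zero pitch and roll and the monitor centred on the nose axis, the
    monitor centre maps to ``(0, 0, distance_cm)``.  Positive pitch rotates
    the head nose-down so a point straight ahead gains elevation; at 90°
    pitch it maps to straight above the animal.
    """
    p = np.atleast_2d(np.asarray(points_cm, dtype=float))
    ox, oy = geom.center_offset_cm
    world = np.column_stack(
        [p[:, 0] + ox, p[:, 1] + oy, np.full(p.shape[0], geom.distance_cm)]
    )
    R = _head_rotation(
        geom.head_pitch_deg if pitch_deg is None else pitch_deg,
        geom.head_roll_deg if roll_deg is None else roll_deg,
    )
    out = world @ R.T
    return out[0] if np.asarray(points_cm).ndim == 1 else out


def xyz_to_spherical(x: ArrayLike, y: ArrayLike, z: ArrayLike) -> tuple[np.ndarray, np.ndarray]:
    """Head xyz to (azimuth_deg, elevation_deg); requires z > 0 (in front)."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if np.any(z <= 0):
        raise ValueError("point behind the animal: z must be positive")
    az = np.rad2deg(np.arctan(x / z))
    el = np.rad2deg(np.arctan(y / np.sqrt(x * x + z * z)))
    return az, el


def concentric_angle(x: ArrayLike, y: ArrayLike) -> np.ndarray | float:
    """Orientation tangent to the circle about the centre of vision, degrees in [0, 180).

    Scale invariant (``concentric_angle(l*x, l*y) == concentric_angle(x, y)``
    for ``l > 0``) and point symmetric.  Undefined (NaN) at the origin.
    """
    xx = np.asarray(x, dtype=float)
    yy = np.asarray(y, dtype=float)
    ang = (90.0 - np.rad2deg(np.arctan2(yy, xx))) % 180.0
    ang = np.where((xx == 0) & (yy == 0), np.nan, ang)
    if ang.ndim == 0:
        val = float(ang)
        if np.isnan(val):
            raise ValueError("concentric angle undefined at the centre of vision")
        return val
    return ang


def concentric_from_angles(azimuth_deg: ArrayLike, elevation_deg: ArrayLike) -> np.ndarray:
    """Concentric angle from spherical angles.

    The visual-field direction with azimuth a and elevation e has head
    coordinates proportional to ``(sin a, tan e * 1, ...)`` at unit
    horizontal range; the concentric angle only depends on (x, y) up to a
    positive scale, so ``(sin a, tan e)`` suffices.
    """
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    el = np.deg2rad(np.asarray(elevation_deg, dtype=float))
    return np.asarray(concentric_angle(np.sin(az), np.tan(el)))


@dataclass
class PatchFit:
    """2D Gaussian fit of one patch's response map.

    ``amplitude_dff`` is the fitted peak response on the original ΔF/F scale
    (the 0.1 percentage-point pedestal subtracted before fitting is added
    back); patches with ``amplitude_dff`` below the inclusion threshold
    (default 0.4 percentage points) are excluded from the retinotopic map.
    """

    patch_id: int
    centre_px: tuple[float, float]  # (row, col)
    sigmas_px: tuple[float, float]  # (sigma_row, sigma_col)
    amplitude_dff: float
    included: bool
    message: str = ""


def _gauss2d(coords, amp, r0, c0, sr, sc):
    rr, cc = coords
    return amp * np.exp(-(((rr - r0) / sr) ** 2 + ((cc - c0) / sc) ** 2) / 2.0)


def fit_patch_gaussian(
    resp_map: ScalarMap,
    patch_id: int = 0,
    subtract_dff: float = 0.001,
    include_threshold_dff: float = 0.004,
    subtract_mode: str = "absolute",
) -> PatchFit:
    """Fit an axis-aligned elliptical 2D Gaussian to a patch response map.

    A small pedestal is removed before fitting to suppress the diffuse
    background response: ``subtract_mode="absolute"`` subtracts
    ``subtract_dff`` ΔF/F (default 0.001, i.e. 0.1 percentage points);
    ``"relative"`` subtracts that fraction of the map maximum.  The result is
    floored at 0 and fit with amplitude, centre and per-axis sigmas free and
    zero offset.  Initialisation comes from the centroid of the
    above-half-max pixels.
    """
    vals = np.where(resp_map.mask, resp_map.values, 0.0).astype(float)
    if np.count_nonzero(resp_map.mask) < 25:
        return PatchFit(patch_id, (np.nan, np.nan), (np.nan, np.nan), 0.0, False, "too few pixels")
    pedestal = subtract_dff if subtract_mode == "absolute" else subtract_dff * float(vals.max())
    work = np.clip(vals - pedestal, 0.0, None)
    peak = float(work.max())
    if peak <= 0:
        return PatchFit(patch_id, (np.nan, np.nan), (np.nan, np.nan), pedestal, False, "no signal")

    rr, cc = np.mgrid[0 : work.shape[0], 0 : work.shape[1]]
    top = work >= 0.5 * peak
    w = work[top]
    r0 = float(np.average(rr[top], weights=w))
    c0 = float(np.average(cc[top], weights=w))
    sr = max(float(np.sqrt(np.average((rr[top] - r0) ** 2, weights=w))), 0.8)
    sc = max(float(np.sqrt(np.average((cc[top] - c0) ** 2, weights=w))), 0.8)
    sel = resp_map.mask
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (rr[sel].astype(float), cc[sel].astype(float)),
            work[sel],
            p0=[peak, r0, c0, sr, sc],
            bounds=(
                [0.0, -work.shape[0], -work.shape[1], 0.3, 0.3],
                [np.inf, 2 * work.shape[0], 2 * work.shape[1], 10 * work.shape[0], 10 * work.shape[1]],
            ),
            maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:  # non-convergence
        return PatchFit(patch_id, (r0, c0), (sr, sc), 0.0, False, f"fit failed: {exc}")
    amp_orig = float(popt[0]) + pedestal
    return PatchFit(
        patch_id=patch_id,
        centre_px=(float(popt[1]), float(popt[2])),
        sigmas_px=(float(popt[3]), float(popt[4])),
        amplitude_dff=amp_orig,
        included=amp_orig >= include_threshold_dff,
    )


@dataclass
class RetinotopyMaps:
    """Per-pixel visual-field coordinates, valid inside the patch-centre hull."""

    azimuth_deg: ScalarMap
    elevation_deg: ScalarMap
    hull_mask: np.ndarray
    x_cm: np.ndarray | None = None  # monitor-plane coordinates, for diagnostics
    y_cm: np.ndarray | None = None


def interpolate_retinotopy(
    fits: Sequence[PatchFit],
    geom: MonitorGeometry,
    shape: tuple[int, int],
    pitch_deg: float | None = None,
    roll_deg: float | None = None,
) -> RetinotopyMaps:
    """Scattered interpolation of patch positions into dense retinotopic maps.

    Each included patch contributes one (pixel centre -> monitor centre)
    correspondence; monitor x and y are interpolated piecewise-linearly on
    the Delaunay triangulation of the patch centres in pixel space, which is
    defined only inside their convex hull (folds in the fitted centres are
    flattened by the triangulation).  The interpolated monitor coordinates
    are then carried through the head transform into azimuth and elevation.
    """
    inc = [f for f in fits if f.included]
    if len(inc) < 3:
        raise ValueError("insufficient retinotopy: need >= 3 included patches")
    pts = np.array([f.centre_px for f in inc])  # (row, col)
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("insufficient retinotopy: patch centres are collinear")
    mon = np.array([geom.patch_centres_cm[f.patch_id] for f in inc])
    interp = LinearNDInterpolator(pts, mon)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    xy = interp(np.column_stack([rr.ravel(), cc.ravel()]))
    x_cm = xy[:, 0].reshape(shape)
    y_cm = xy[:, 1].reshape(shape)
    hull = np.isfinite(x_cm)
    pts_cm = np.column_stack([x_cm[hull], y_cm[hull]])
    xyz = monitor_to_head_xyz(pts_cm, geom, pitch_deg=pitch_deg, roll_deg=roll_deg)
    ok = xyz[:, 2] > 0
    az = np.full(shape, np.nan)
    el = np.full(shape, np.nan)
    az_v, el_v = xyz_to_spherical(xyz[ok, 0], xyz[ok, 1], xyz[ok, 2])
    idx = np.flatnonzero(hull.ravel())[ok]
    az.ravel()[idx] = az_v
    el.ravel()[idx] = el_v
    valid = np.isfinite(az)
    return RetinotopyMaps(
        azimuth_deg=ScalarMap(np.nan_to_num(az), valid, "deg"),
        elevation_deg=ScalarMap(np.nan_to_num(el), valid, "deg"),
        hull_mask=valid,
        x_cm=x_cm,
        y_cm=y_cm,
    )


def build_concentric_map(
    retino: RetinotopyMaps,
    sigma_um: float = 132.0,
    pixel_size_um: float = 11.04,
    ipsi_azimuth_sign: int = -1,
) -> AxialMap:
    """Predicted orientation map under the concentric hypothesis.

    Each pixel gets the concentric angle of its visual-field position.
    Pixels representing the nasal ipsilateral hemifield (azimuth with sign
    ``ipsi_azimuth_sign``) are set to 0° (horizontal), the orientation
    observed for near-nasal receptive fields.  The map is smoothed axially
    (complex-field convolution) with ``sigma_um`` (default 132 µm), which
    emulates receptive-field scatter and light scatter in the measured maps;
    pass 0 for the raw pointwise prediction.
    """
    mask = retino.hull_mask.copy()
    az = retino.azimuth_deg.values
    el = retino.elevation_deg.values
    ang = np.zeros_like(az)
    with np.errstate(invalid="ignore"):
        raw = concentric_from_angles(az, el)
    centre = mask & np.isnan(raw)
    mask = mask & ~centre  # exact centre of vision: orientation undefined
    ang[mask] = raw[mask]
    ipsi = mask & (np.sign(az) == np.sign(ipsi_azimuth_sign)) & (az != 0)
    ang[ipsi] = 0.0
    amp = np.ones_like(ang)
    out = AxialMap(angle_deg=ang, amplitude=amp, mask=mask)
    if sigma_um > 0:
        out = smooth_axial(out, sigma_um, pixel_size_um)
    return out


@dataclass
class HeadAngleFit:
    """Grid search of head pitch/roll against the concentric hypothesis.

    ``alignment_profile`` holds the mean axial alignment
    ``<cos 2(measured - predicted)>`` over the grid; ``corr_profile`` the
    circular correlation at each grid point, reported for sensitivity
    inspection but not used for the argmax (the Fisher-Lee coefficient is
    invariant under a constant rotation of one map, which is exactly what a
    head roll produces, so it cannot identify roll).
    """

    pitch_deg: float
    roll_deg: float
    best_alignment: float
    alignment_profile: np.ndarray  # (n_pitch, n_roll)
    corr_profile: np.ndarray
    pitch_grid: np.ndarray
    roll_grid: np.ndarray
    identifiable: bool


def fit_head_angles(
    retino_builder: Callable[[float, float], AxialMap],
    orientation_map: AxialMap,
    pitch_grid: ArrayLike,
    roll_grid: ArrayLike,
    min_alignment: float = 0.2,
) -> HeadAngleFit:
    """Choose the head pitch/roll that best fits the concentric hypothesis.

    ``retino_builder(pitch, roll)`` must return the predicted concentric map
    under those head angles.  Each candidate is scored by the mean axial
    alignment ``<cos 2(measured - predicted)>`` over pixels valid in both
    maps (1 for perfect agreement, 0 for unrelated orientations, -1 for an
    orthogonal map); the argmax is returned together with the full profile
    for sensitivity reporting.  A profile whose maximum stays below
    ``min_alignment`` is flagged unidentifiable.
    """
    pg = np.atleast_1d(np.asarray(pitch_grid, dtype=float))
    rg = np.atleast_1d(np.asarray(roll_grid, dtype=float))
    if pg.size == 0 or rg.size == 0:
        raise ValueError("pitch/roll grids must be non-empty")
    align = np.full((pg.size, rg.size), np.nan)
    corr = np.full((pg.size, rg.size), np.nan)
    for i, p in enumerate(pg):
        for j, r in enumerate(rg):
            pred = retino_builder(float(p), float(r))
            both = orientation_map.mask & pred.mask
            if np.count_nonzero(both) < 10:
                continue
            d = np.deg2rad(orientation_map.angle_deg[both] - pred.angle_deg[both])
            align[i, j] = float(np.mean(np.cos(2.0 * d)))
            try:
                corr[i, j] = circ_corr_axial(
                    orientation_map.angle_deg[both], pred.angle_deg[both]
                )
            except ValueError:
                pass
    if not np.any(np.isfinite(align)):
        raise ValueError("no grid point produced a valid comparison")
    i, j = np.unravel_index(np.nanargmax(align), align.shape)
    best = float(align[i, j])
    return HeadAngleFit(
        pitch_deg=float(pg[i]),
        roll_deg=float(rg[j]),
        best_alignment=best,
        alignment_profile=align,
        corr_profile=corr,
        pitch_grid=pg,
        roll_grid=rg,
        identifiable=best >= min_alignment,
    )
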