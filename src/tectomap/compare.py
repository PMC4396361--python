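"""Quantitative comparison of measured orientation preference with the
concentric prediction, and per-penetration columnar summaries.

The imaging comparison pools pixels that are valid in both maps and pass a
minimum-response filter (default: every stimulus condition's mean ΔF/F at
least 0.5 percentage points), computes the axial circular correlation, and
bins the signed angular differences into 10°-wide bins centred on 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import (
    ShuffleTestResult,
    circ_corr_axial,
    circ_diff_axial,
    circ_mean_axial,
    circ_var_axial,
    rayleigh_test,
    shuffle_columnar_test,
)
from .geometry import concentric_from_angles
from .maps import AxialMap
from .tuning import (
    collapse_directions,
    direction_to_grating_orientation,
    fit_von_mises,
    preferred_orientation_vector,
    trials_to_tuning,
)

__all__ = [
    "MapComparison",
    "PenetrationSummary",
    "compare_orientation_to_concentric",
    "penetration_concentric_test",
    "columnar_summary",
]

HIST_BIN_EDGES = np.arange(-90.0, 91.0, 10.0)  # 18 bins of 10 degrees


@dataclass
class MapComparison:
    n_pixels: int
    circ_corr: float
    diff_histogram: np.ndarray  # counts per 10-degree bin over [-90, 90]
    bin_edges: np.ndarray
    min_response_filter: float
    median_abs_diff_deg: float
    p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_pixels": self.n_pixels,
            "circ_corr": self.circ_corr,
            "median_abs_diff_deg": self.median_abs_diff_deg,
            "min_response_filter": self.min_response_filter,
            "p_value": self.p_value,
            "diff_histogram": self.diff_histogram.tolist(),
            "bin_edges": self.bin_edges.tolist(),
        }


def compare_orientation_to_concentric(
    measured: AxialMap,
    predicted: AxialMap,
    min_mean_response: float = 0.005,
    per_condition: np.ndarray | None = None,
    filter_mode: str = "all",
    n_permutations: int = 0,
    seed: int = 0,
) -> MapComparison:
    """Pixelwise comparison of a measured orientation map with a prediction.

    ``per_condition`` (n_conditions, H, W) holds the per-stimulus mean
    responses; with ``filter_mode="all"`` (strict) a pixel qualifies only if
    every condition's response reaches ``min_mean_response``, with ``"any"``
    one condition suffices.  Without ``per_condition`` the measured map's
    amplitude is filtered instead.  ``n_permutations > 0`` attaches a
    permutation p-value obtained by shuffling the pixel pairing.
    """
    if measured.angle_deg.shape != predicted.angle_deg.shape:
        raise ValueError("maps must share shape")
    ok = measured.mask & predicted.mask
    if per_condition is not None:
        pc = np.asarray(per_condition, dtype=float)
        if filter_mode == "all":
            ok &= pc.min(axis=0) >= min_mean_response
        elif filter_mode == "any":
            ok &= pc.max(axis=0) >= min_mean_response
        else:
            raise ValueError("filter_mode must be 'all' or 'any'")
    else:
        ok &= measured.amplitude >= min_mean_response
    n = int(np.count_nonzero(ok))
    if n < 10:
        raise ValueError(f"insufficient overlap: only {n} qualifying pixels")
    a = measured.angle_deg[ok]
    b = predicted.angle_deg[ok]
    rho = circ_corr_axial(a, b)
    diffs = np.asarray(circ_diff_axial(a, b))
    hist, _ = np.histogram(diffs, bins=HIST_BIN_EDGES)
    p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            if abs(circ_corr_axial(a, rng.permutation(b))) >= abs(rho):
                count += 1
        p = (1 + count) / (1 + n_permutations)
    return MapComparison(
        n_pixels=n,
        circ_corr=float(rho),
        diff_histogram=hist,
        bin_edges=HIST_BIN_EDGES.copy(),
        min_response_filter=float(min_mean_response),
        median_abs_diff_deg=float(np.median(np.abs(diffs))),
        p_value=p,
    )


@dataclass
class PenetrationSummary:
    """Circular summary of one electrode penetration."""

    penetration_id: str
    circ_mean_deg: float
    circ_var: float
    n_units: int
    rf_azimuth_deg: float | None = None
    rf_elevation_deg: float | None = None


def penetration_concentric_test(
    summaries: list[PenetrationSummary],
    ipsi_azimuth_sign: int = -1,
) -> tuple[pd.DataFrame, float | None]:
    """Concentric prediction at each penetration's receptive field vs its
    measured circular-mean orientation.

    Returns a table with one row per penetration (measured and predicted
    angles and their axial difference) and the circular correlation across
    penetrations, or None when the predictor is degenerate (all receptive
    fields on one radial line give a constant prediction, which the circular
    correlation cannot score) — such cases are flagged in the table's attrs.
    Penetrations with a receptive field at the centre of vision are excluded.
    """
    rows = []
    for s in summaries:
        if s.rf_azimuth_deg is None or s.rf_elevation_deg is None:
            raise ValueError(f"penetration {s.penetration_id} lacks a receptive-field position")
        if s.rf_azimuth_deg == 0 and s.rf_elevation_deg == 0:
            continue  # centre of vision: concentric angle undefined
        pred = float(concentric_from_angles(s.rf_azimuth_deg, s.rf_elevation_deg))
        if np.sign(s.rf_azimuth_deg) == np.sign(ipsi_azimuth_sign) and s.rf_azimuth_deg != 0:
            pred = 0.0
        rows.append(
            {
                "penetration_id": s.penetration_id,
                "measured_deg": s.circ_mean_deg,
                "predicted_deg": pred,
                "diff_deg": float(circ_diff_axial(s.circ_mean_deg, pred)),
                "rf_azimuth_deg": s.rf_azimuth_deg,
                "rf_elevation_deg": s.rf_elevation_deg,
                "n_units": s.n_units,
            }
        )
    table = pd.DataFrame(rows)
    corr: float | None = None
    if len(table) >= 3:
        try:
            corr = circ_corr_axial(table["measured_deg"], table["predicted_deg"])
        except ValueError:
            table.attrs["degenerate_predictor"] = True
    return table, corr


def unit_preferred_orientation(
    trial_table: pd.DataFrame, method: str = "argmax"
) -> float:
    """Preferred grating orientation of one unit from its trial table.

    ``method``: "argmax" (orientation with the largest collapsed response,
    the default entering penetration statistics), "vector" (half-argument of
    the orientation vector sum) or "vonmises" (fitted preferred angle).
    Direction labels are converted to grating orientations first.
    """
    tuning, _, _ = trials_to_tuning(trial_table)
    axes, R = collapse_directions(tuning, mode="average")
    oris = direction_to_grating_orientation(axes)
    order = np.argsort(oris)
    oris, R = oris[order], np.clip(R[order], 0.0, None)
    if method == "argmax":
        return float(oris[int(np.argmax(R))])
    if method == "vector":
        return preferred_orientation_vector(oris, R)
    if method == "vonmises":
        return fit_von_mises(oris, R).phi_preferred_deg
    raise ValueError("method must be 'argmax', 'vector' or 'vonmises'")


def columnar_summary(
    trial_table: pd.DataFrame,
    n_shuffles: int = 10_000,
    seed: int = 0,
    min_evoked_hz: float = 2.0,
    pref_method: str = "argmax",
) -> tuple[pd.DataFrame, ShuffleTestResult, object]:
    """Per-penetration orientation statistics plus the columnar shuffle test.

    The trial table holds one row per trial (columns ``penetration_id``,
    ``unit_id``, ``direction_deg``, ``response``, optionally ``baseline``,
    ``depth_um``, ``rf_azimuth_deg``, ``rf_elevation_deg``).  Units failing
    the evoked-rate inclusion filter (default 2 Hz) are dropped; penetrations
    retaining fewer than 2 units are dropped from the shuffle test.  Returns
    ``(penetration_table, shuffle_result, rayleigh_on_circular_means)``.
    """
    if len(trial_table) == 0:
        raise ValueError("empty unit table")
    prefs_by_pen: dict[str, list[float]] = {}
    rf_by_pen: dict[str, tuple[float, float] | None] = {}
    # one grouped pass over the table: per-unit-direction means, then the
    # evoked-rate filter and the preference, all on the aggregated curves
    mean_tbl = (
        trial_table.groupby(["penetration_id", "unit_id", "direction_deg"], sort=True)["response"]
        .mean()
        .unstack("direction_deg")
    )
    if mean_tbl.isna().any().any():
        raise ValueError("incomplete design: some unit misses a direction")
    if "baseline" in trial_table.columns:
        base = trial_table.groupby(["penetration_id", "unit_id"], sort=True)["baseline"].mean()
    else:
        base = pd.Series(0.0, index=mean_tbl.index)
    evoked = np.clip(mean_tbl.max(axis=1) - base, 0.0, None)
    included_units = evoked >= min_evoked_hz
    dirs = mean_tbl.columns.to_numpy(dtype=float)
    oris_axis = np.unique(dirs % 180.0)
    if oris_axis.size * 2 != dirs.size:
        raise ValueError("unpaired directions: every direction needs its opposite")
    # collapse opposing pairs by average, convert to grating orientation
    collapsed = np.stack(
        [mean_tbl.loc[:, np.isclose(dirs % 180.0, ax)].mean(axis=1).to_numpy() for ax in oris_axis],
        axis=1,
    )
    oris = np.sort(direction_to_grating_orientation(oris_axis))
    order = np.argsort(direction_to_grating_orientation(oris_axis))
    collapsed = np.clip(collapsed[:, order], 0.0, None)
    if pref_method == "argmax":
        prefs = oris[np.argmax(collapsed, axis=1)]
    elif pref_method == "vector":
        vec = collapsed @ np.exp(2j * np.deg2rad(oris))
        prefs = np.rad2deg(np.angle(vec)) / 2.0 % 180.0
    elif pref_method == "vonmises":
        prefs = np.array([fit_von_mises(oris, row).phi_preferred_deg for row in collapsed])
    else:
        raise ValueError("pref_method must be 'argmax', 'vector' or 'vonmises'")
    has_rf = "rf_azimuth_deg" in trial_table.columns
    if has_rf:
        rf_tbl = trial_table.groupby("penetration_id", sort=True)[
            ["rf_azimuth_deg", "rf_elevation_deg"]
        ].first()
    for (pen, _unit), inc, pref in zip(mean_tbl.index, included_units, prefs):
        if not inc:
            continue
        prefs_by_pen.setdefault(str(pen), []).append(float(pref))
        if has_rf and str(pen) not in rf_by_pen:
            rf_by_pen[str(pen)] = (
                float(rf_tbl.loc[pen, "rf_azimuth_deg"]),
                float(rf_tbl.loc[pen, "rf_elevation_deg"]),
            )
    prefs_by_pen = {k: v for k, v in prefs_by_pen.items() if len(v) >= 2}
    if len(prefs_by_pen) < 2:
        raise ValueError("fewer than 2 penetrations with >= 2 included units")

    rows = []
    for pen, prefs in sorted(prefs_by_pen.items()):
        try:
            cmean = circ_mean_axial(prefs)
        except ValueError:
            cmean = np.nan  # balanced preferences: mean undefined
        rf = rf_by_pen.get(pen)
        rows.append(
            {
                "penetration_id": pen,
                "circ_mean_deg": cmean,
                "circ_var": circ_var_axial(prefs),
                "n_units": len(prefs),
                "rf_azimuth_deg": rf[0] if rf else np.nan,
                "rf_elevation_deg": rf[1] if rf else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    shuffle = shuffle_columnar_test(
        [np.asarray(v) for _, v in sorted(prefs_by_pen.items())],
        n_shuffles=n_shuffles,
        seed=seed,
    )
    means = table["circ_mean_deg"].dropna().to_numpy()
    rayleigh = rayleigh_test(means, period_deg=180) if means.size >= 5 else None
    return table, shuffle, rayleigh
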