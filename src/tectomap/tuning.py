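"""Per-unit tuning curves and selectivity indices.

Responses are tabulated per stimulus direction (drift direction of motion for
gratings and dot fields, in degrees on [0, 360)).  Orientation quantities are
derived by collapsing opposite directions.  Two angle conventions coexist:

* *axis* labels: an orientation is labelled by its direction modulo 180°
  (the motion axis), the natural label when collapsing a direction table;
* *grating* labels: the spatial orientation of a drifting grating is
  perpendicular to its motion, ``(direction + 90) mod 180``, so an upward-
  drifting grating is horizontal (0°).

``collapse_directions`` uses axis labels; callers that need physical grating
orientation (map building, the concentric comparison) convert with
``direction_to_grating_orientation`` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy import optimize

from .circstats import circ_diff_axial

__all__ = [
    "DirectionTuning",
    "UnitRecord",
    "VonMisesFit",
    "direction_to_grating_orientation",
    "trials_to_tuning",
    "collapse_directions",
    "orientation_index",
    "direction_selectivity_index",
    "preferred_orientation_vector",
    "fit_von_mises",
    "orientation_gradient",
]


def direction_to_grating_orientation(direction_deg: ArrayLike) -> np.ndarray | float:
    """Grating orientation for a drift direction: ``(direction + 90) mod 180``."""
    o = (np.asarray(direction_deg, dtype=float) + 90.0) % 180.0
    return float(o) if o.ndim == 0 else o


@dataclass
class DirectionTuning:
    """Mean response per stimulus direction for one unit or pixel region."""

    directions: np.ndarray  # degrees in [0, 360), sorted, unique, even count
    mean_response: np.ndarray
    sem: np.ndarray
    n_trials: np.ndarray
    trial_matrix: list[np.ndarray] | None = None  # per-direction trial responses

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.mean_response = np.asarray(self.mean_response, dtype=float)
        d = self.directions
        if d.size == 0 or d.size % 2:
            raise ValueError("need an even, positive number of directions")
        if np.unique(d).size != d.size or np.any(np.diff(d) <= 0):
            raise ValueError("directions must be unique and sorted")
        if np.any(d < 0) or np.any(d >= 360):
            raise ValueError("directions must lie in [0, 360)")
        if self.mean_response.shape != d.shape:
            raise ValueError("mean_response must match directions")


@dataclass
class UnitRecord:
    """One recorded unit: identity, depth, tuning and derived preference."""

    penetration_id: str
    unit_id: str
    depth_um: float
    tuning: DirectionTuning
    evoked_rate_hz: float
    included: bool
    preferred_orientation_deg: float | None = None

    def __post_init__(self) -> None:
        if self.evoked_rate_hz < 0:
            raise ValueError("evoked_rate_hz must be >= 0")


def trials_to_tuning(
    trial_table: pd.DataFrame,
    min_evoked_hz: float = 2.0,
    response_col: str = "response",
    baseline_col: str = "baseline",
) -> tuple[DirectionTuning, bool, float]:
    """Aggregate a per-trial table into a direction tuning curve.

    The table must hold one row per trial with columns ``direction_deg``,
    ``response`` and (optionally) ``baseline``.  The evoked rate is
    ``max over directions of (mean response - mean baseline)``, floored at 0,
    and a unit is flagged included when it reaches ``min_evoked_hz``
    (default 2 Hz, the standard inclusion threshold for visually responsive
    collicular units).

    Returns ``(tuning, included, evoked_rate)``.
    """
    if len(trial_table) == 0:
        raise ValueError("empty trial table")
    grouped = trial_table.groupby("direction_deg", sort=True)[response_col]
    directions = np.array(sorted(trial_table["direction_deg"].unique()), dtype=float)
    if directions.size % 2:
        raise ValueError("incomplete design: odd number of directions")
    means = grouped.mean().to_numpy(dtype=float)
    counts = grouped.count().to_numpy()
    if np.any(counts < 1):
        raise ValueError("incomplete design: missing direction")
    sems = grouped.sem(ddof=1).to_numpy(dtype=float)
    sems = np.where(counts > 1, sems, 0.0)
    sems = np.nan_to_num(sems, nan=0.0)
    trial_lists = [
        trial_table.loc[trial_table["direction_deg"] == d, response_col].to_numpy(dtype=float)
        for d in directions
    ]
    if baseline_col in trial_table.columns:
        base = float(trial_table[baseline_col].mean())
    else:
        base = 0.0
    evoked = max(float(np.max(means) - base), 0.0)
    tuning = DirectionTuning(
        directions=directions,
        mean_response=means,
        sem=sems,
        n_trials=counts,
        trial_matrix=trial_lists,
    )
    return tuning, evoked >= min_evoked_hz, evoked


def collapse_directions(
    t: DirectionTuning, mode: str = "average"
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse opposite directions into orientation responses ``R(phi)``.

    Returns ``(orientations_deg, responses)`` with orientations labelled by
    direction modulo 180 (axis convention) on [0, 180), half as many entries
    as directions.  ``mode="average"`` takes the mean of each opposing pair,
    ``mode="max"`` the larger of the pair (the convention used for pixelwise
    orientation maps).
    """
    if mode not in ("average", "max"):
        raise ValueError("mode must be 'average' or 'max'")
    d = t.directions
    axes = np.unique(d % 180.0)
    if axes.size * 2 != d.size:
        raise ValueError("unpaired directions: every direction needs its opposite")
    R = np.empty(axes.size)
    for i, ax in enumerate(axes):
        pair = t.mean_response[np.isclose(d % 180.0, ax)]
        if pair.size != 2:
            raise ValueError("unpaired directions: every direction needs its opposite")
        R[i] = pair.mean() if mode == "average" else pair.max()
    return axes, R


def _clamped(R: ArrayLike) -> np.ndarray:
    return np.clip(np.asarray(R, dtype=float), 0.0, None)


def orientation_index(orientations_deg: ArrayLike, R: ArrayLike) -> float:
    """Orientation index ``(R_pref - R_ortho) / (R_pref + R_ortho)``.

    ``R_pref`` is the largest (clamped-at-zero) response over the tested
    orientations and ``R_ortho`` the response at the orthogonal orientation,
    which must be among the tested set.  Lies in [0, 1].
    """
    phi = np.asarray(orientations_deg, dtype=float)
    r = _clamped(R)
    if phi.size < 2 or phi.size != r.size:
        raise ValueError("need >= 2 orientation/response pairs of equal length")
    i_pref = int(np.argmax(r))
    ortho = (phi[i_pref] + 90.0) % 180.0
    j = np.where(np.isclose(phi % 180.0, ortho))[0]
    if j.size == 0:
        raise ValueError("orthogonal orientation of the preferred was not tested")
    r_pref, r_ortho = float(r[i_pref]), float(r[j[0]])
    if r_pref + r_ortho == 0:
        raise ValueError("unresponsive: R_pref + R_ortho is zero")
    return (r_pref - r_ortho) / (r_pref + r_ortho)


def direction_selectivity_index(t: DirectionTuning) -> tuple[float, bool]:
    """Vector-sum direction selectivity index and the DSI > 0.5 flag.

    ``DSI = |sum R(phi) exp(i phi)| / sum R(phi)`` over directions, with
    negative mean responses clamped to zero first.
    """
    r = _clamped(t.mean_response)
    total = r.sum()
    if total <= 0:
        raise ValueError("unresponsive: all direction responses are zero")
    vec = np.sum(r * np.exp(1j * np.deg2rad(t.directions)))
    dsi = float(abs(vec) / total)
    return dsi, dsi > 0.5


def preferred_orientation_vector(orientations_deg: ArrayLike, R: ArrayLike) -> float:
    """Vector-average preferred orientation: ``0.5 * arg sum R exp(2i phi)``, in [0, 180)."""
    phi = np.asarray(orientations_deg, dtype=float)
    r = _clamped(R)
    if r.sum() <= 0:
        raise ValueError("unresponsive: all responses are zero")
    vec = np.sum(r * np.exp(2j * np.deg2rad(phi)))
    if abs(vec) <= 1e-12 * r.sum():
        raise ValueError("undefined preference: zero resultant")
    return float(np.rad2deg(np.angle(vec)) / 2.0 % 180.0)


@dataclass
class VonMisesFit:
    """Least-squares fit of ``baseline + amplitude * exp(kappa*(cos(2(phi - phi_pref)) - 1))``."""

    phi_preferred_deg: float
    amplitude: float
    baseline: float
    rss: float
    kappa: float = 1.0
    reliable: bool = True


def _vm_shape(phi_deg: np.ndarray, phi0_deg: float, kappa: float) -> np.ndarray:
    return np.exp(kappa * (np.cos(2.0 * np.deg2rad(phi_deg - phi0_deg)) - 1.0))


def fit_von_mises(
    orientations_deg: ArrayLike,
    R: ArrayLike,
    kappa: float | None = None,
) -> VonMisesFit:
    """Fit an orientation tuning curve with a von Mises bump of fixed width.

    The shape is ``exp(cos(2(phi - phi_pref)) - 1)`` (concentration kappa
    fixed at 1) riding on a free baseline with a free nonnegative amplitude.
    For each candidate preferred angle the amplitude/baseline pair is the
    exact linear least-squares solution, so the fit reduces to a 1-D profile
    search over ``phi_pref`` (0.25° grid plus bounded local refinement) and
    cannot miss the global optimum by more than the refinement tolerance.

    Pass ``kappa`` to fit with a different fixed concentration.  A flat curve
    yields ``amplitude == 0`` and ``reliable=False``.
    """
    phi = np.asarray(orientations_deg, dtype=float)
    r = np.asarray(R, dtype=float)
    if phi.size < 4:
        raise ValueError("need at least 4 tested orientations")
    if phi.size != r.size:
        raise ValueError("orientations and responses must have equal length")
    k = 1.0 if kappa is None else float(kappa)

    def solve(phi0: float) -> tuple[float, float, float]:
        """Best (amplitude, baseline, rss) at fixed preferred angle."""
        s = _vm_shape(phi, phi0, k)
        A = np.column_stack([s, np.ones_like(s)])
        coef, *_ = np.linalg.lstsq(A, r, rcond=None)
        amp, base = float(coef[0]), float(coef[1])
        if amp < 0:  # enforce a nonnegative bump; fall back to a flat fit
            amp, base = 0.0, float(r.mean())
        resid = r - (base + amp * s)
        return amp, base, float(resid @ resid)

    grid = np.arange(0.0, 180.0, 0.25)
    rss_grid = np.array([solve(g)[2] for g in grid])
    best = float(grid[int(np.argmin(rss_grid))])
    res = optimize.minimize_scalar(
        lambda g: solve(float(g))[2],
        bounds=(best - 0.25, best + 0.25),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi0 = float(res.x) % 180.0
    amp, base, rss = solve(phi0)
    scale = max(abs(r).max(), 1e-30)
    reliable = amp > 1e-6 * scale
    if not reliable:
        amp, base = 0.0, float(r.mean())
        rss = float(((r - base) ** 2).sum())
    return VonMisesFit(
        phi_preferred_deg=phi0,
        amplitude=amp,
        baseline=base,
        rss=rss,
        kappa=k,
        reliable=reliable,
    )


def orientation_gradient(track: ArrayLike) -> float:
    """Mean rate of change of preferred orientation along a track, °/100 µm.

    ``track`` is an ordered sequence of ``(position_um, angle_deg_axial)``
    pairs with strictly increasing positions.  Consecutive angular steps use
    the minimal axial difference, so a step across the 0/180 wrap (170° to
    10°) counts as 20°.
    """
    t = np.asarray(track, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError("track must be an (n >= 2, 2) array of (position_um, angle_deg)")
    pos, ang = t[:, 0], t[:, 1]
    dp = np.diff(pos)
    if np.any(dp <= 0):
        raise ValueError("invalid track: positions must be strictly increasing")
    steps = np.abs(circ_diff_axial(ang[1:], ang[:-1]))
    return float(np.mean(steps / dp) * 100.0)
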