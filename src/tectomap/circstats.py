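"""Circular statistics for axial (orientation, period 180°) and directional data.

Orientations are represented in degrees on [0, 180).  Axial quantities are
analysed on doubled angles: an orientation ``phi`` is mapped to the unit
vector ``exp(2i*phi)``, statistics are computed on those vectors, and angular
results are halved back into [0, 180).

The module also implements the penetration-shuffle test for columnar
clustering of orientation preference: the observed statistic is the median,
over electrode penetrations, of the circular variance of the unit preferences
on that penetration, and the null distribution is obtained by randomly
redistributing the pooled preferences over the original penetration-size
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

__all__ = [
    "RayleighResult",
    "ShuffleTestResult",
    "circ_mean_axial",
    "circ_var_axial",
    "circ_diff_axial",
    "circ_corr_axial",
    "rayleigh_test",
    "shuffle_columnar_test",
]

#: resultant lengths below this fraction of the total weight are treated as zero
_RESULTANT_TOL = 1e-12


def _check_axial(angles: ArrayLike) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    if np.any(~np.isfinite(a)) or np.any(a < 0) or np.any(a >= 180):
        raise ValueError("axial angles must be finite and in [0, 180) degrees")
    return a


def _axial_resultant(angles_deg: np.ndarray, weights: np.ndarray | None) -> tuple[complex, float]:
    """Weighted resultant of doubled angles and the total weight."""
    z = np.exp(2j * np.deg2rad(angles_deg))
    if weights is None:
        return complex(z.sum()), float(angles_deg.size)
    w = np.asarray(weights, dtype=float)
    if w.shape != angles_deg.shape:
        raise ValueError("weights must match angles in shape")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return complex((w * z).sum()), float(w.sum())


def circ_mean_axial(angles: ArrayLike, weights: ArrayLike | None = None) -> float:
    """Axial circular mean: half the argument of ``sum w*exp(2i*phi)``, in [0, 180).

    Raises
    ------
    ValueError
        If the resultant vector is (numerically) zero, e.g. for two orthogonal
        orientations with equal weight, where the axial mean is undefined.
    """
    a = _check_axial(angles)
    r, wtot = _axial_resultant(a, None if weights is None else np.asarray(weights, float))
    if wtot <= 0 or abs(r) <= _RESULTANT_TOL * max(wtot, 1.0):
        raise ValueError("undefined axial mean: zero resultant")
    return float(np.rad2deg(np.angle(r)) / 2.0 % 180.0)


def circ_var_axial(angles: ArrayLike, weights: ArrayLike | None = None) -> float:
    """Circular variance of orientations: ``1 - |sum w*exp(2i*phi)| / sum w``.

    0 when all angles coincide, 1 when the doubled angles balance exactly
    (e.g. orthogonal orientations with equal weight).
    """
    a = _check_axial(angles)
    r, wtot = _axial_resultant(a, None if weights is None else np.asarray(weights, float))
    if wtot <= 0:
        raise ValueError("total weight must be positive")
    return float(np.clip(1.0 - abs(r) / wtot, 0.0, 1.0))


def circ_diff_axial(a: ArrayLike, b: ArrayLike) -> np.ndarray | float:
    """Signed minimal axial difference ``a - b``, wrapped into (-90, 90].

    The antipodal case (difference of exactly 90°) returns +90 by convention.
    Accepts scalars or broadcastable arrays of angles in [0, 180).
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if np.any(aa < 0) or np.any(aa >= 180) or np.any(bb < 0) or np.any(bb >= 180):
        raise ValueError("axial angles must be in [0, 180)")
    d = (aa - bb) % 180.0
    d = np.where(d > 90.0, d - 180.0, d)
    if d.ndim == 0:
        return float(d)
    return d


def circ_corr_axial(a: ArrayLike, b: ArrayLike) -> float:
    """Fisher–Lee circular–circular correlation of two orientation samples.

    Both samples are doubled (axial -> directional) and the Fisher–Lee
    T-linear association coefficient is evaluated in its O(n) computational
    form.  Returns 1 for identical non-constant samples; symmetric in its
    arguments.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 3 pairs, or a (doubled-angle)
        degenerate sample with zero circular spread.
    """
    aa = 2.0 * np.deg2rad(np.asarray(a, dtype=float).ravel())
    bb = 2.0 * np.deg2rad(np.asarray(b, dtype=float).ravel())
    if aa.size != bb.size:
        raise ValueError("samples must have equal length")
    n = aa.size
    if n < 3:
        raise ValueError("need at least 3 angle pairs")

    sa, ca = np.sin(aa), np.cos(aa)
    sb, cb = np.sin(bb), np.cos(bb)
    A = float(ca @ cb)
    B = float(sa @ sb)
    C = float(ca @ sb)
    D = float(sa @ cb)
    E = float(np.cos(2 * aa).sum())
    F = float(np.sin(2 * aa).sum())
    G = float(np.cos(2 * bb).sum())
    H = float(np.sin(2 * bb).sum())
    denom_a = n * n - E * E - F * F
    denom_b = n * n - G * G - H * H
    if denom_a <= _RESULTANT_TOL * n * n or denom_b <= _RESULTANT_TOL * n * n:
        raise ValueError("degenerate sample (zero circular variance)")
    rho = 4.0 * (A * B - C * D) / np.sqrt(denom_a * denom_b)
    return float(np.clip(rho, -1.0, 1.0))


@dataclass(frozen=True)
class RayleighResult:
    """Rayleigh test outcome: ``z = n * R**2`` and the corrected p-value."""

    p_value: float
    z: float
    n: int


def rayleigh_test(angles: ArrayLike, period_deg: float = 360.0) -> RayleighResult:
    """Rayleigh test for circular non-uniformity.

    ``period_deg=180`` doubles the angles first, testing orientations for a
    common axis.  The p-value uses the standard finite-n correction
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` where ``Rn = n*R``,
    accurate for small samples; the statistic ``z = n R^2`` is reported as
    well.
    """
    a = np.asarray(angles, dtype=float).ravel()
    n = a.size
    if n < 5:
        raise ValueError("Rayleigh test needs at least 5 angles")
    if period_deg not in (180.0, 360.0, 180, 360):
        raise ValueError("period_deg must be 180 or 360")
    mult = 2.0 if period_deg == 180 else 1.0
    z_c = np.exp(1j * mult * np.deg2rad(a)).sum()
    R = abs(z_c) / n
    Rn = abs(z_c)
    z = n * R * R
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)) - (1.0 + 2.0 * n))
    return RayleighResult(p_value=float(min(max(p, 0.0), 1.0)), z=float(z), n=int(n))


@dataclass
class ShuffleTestResult:
    """Result of the penetration-shuffle clustering test.

    ``p_value`` uses the add-one permutation estimator
    ``(1 + #{null <= real}) / (1 + n_shuffles)`` so that p is never 0.
    """

    real_median_cv: float
    null_median_cvs: np.ndarray = field(repr=False)
    p_value: float
    n_shuffles: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "real_median_cv": self.real_median_cv,
            "p_value": self.p_value,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "null_median_cv_mean": float(np.mean(self.null_median_cvs)),
            "null_median_cv_quantiles": {
                q: float(np.quantile(self.null_median_cvs, float(q)))
                for q in ("0.05", "0.5", "0.95")
            },
        }


def _median_cv_rows(z_rows: np.ndarray, offsets: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Median over penetrations of the circular variance, per row of doubled-angle vectors."""
    sums = np.add.reduceat(z_rows, offsets, axis=1)
    cv = 1.0 - np.abs(sums) / sizes
    return np.median(cv, axis=1)


def shuffle_columnar_test(
    penetrations: list[ArrayLike],
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> ShuffleTestResult:
    """Permutation test for vertical (columnar) clustering of orientation preference.

    The observed statistic is the median over penetrations of the axial
    circular variance of the preferences on each penetration.  For each
    shuffle, the pooled preferences of all units are redistributed at random
    over all positions on all penetrations (a Fisher–Yates shuffle of the
    pooled list, re-split into the original penetration sizes) and the median
    circular variance is recomputed.  Low p means the preferences are more
    clustered within penetrations than chance allows.

    A penetration whose doubled-angle resultant is zero simply contributes a
    circular variance of 1; it is not an error.
    """
    if len(penetrations) < 2:
        raise ValueError("need at least 2 penetrations")
    groups = [_check_axial(p) for p in penetrations]
    sizes = np.array([g.size for g in groups])
    if np.any(sizes < 2):
        raise ValueError("each penetration needs at least 2 angles")
    pooled = np.concatenate(groups)
    if pooled.size < 4:
        raise ValueError("need at least 4 angles in total")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")

    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    z = np.exp(2j * np.deg2rad(pooled))
    real = float(_median_cv_rows(z[None, :], offsets, sizes)[0])

    rng = np.random.default_rng(seed)
    n_total = pooled.size
    null = np.empty(n_shuffles)
    # permute in chunks to bound memory at large n_shuffles
    chunk = max(1, min(n_shuffles, int(4e6 // max(n_total, 1)) or 1))
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        idx = rng.permuted(np.tile(np.arange(n_total), (m, 1)), axis=1)
        null[done : done + m] = _median_cv_rows(z[idx], offsets, sizes)
        done += m

    p = (1.0 + np.count_nonzero(null <= real)) / (1.0 + n_shuffles)
    return ShuffleTestResult(
        real_median_cv=real,
        null_median_cvs=null,
        p_value=float(p),
        n_shuffles=int(n_shuffles),
        seed=int(seed),
    )
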