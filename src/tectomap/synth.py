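"""Synthetic wide-field imaging and electrophysiology datasets with known
ground truth.

The imaging generator emulates an anaesthetized, GCaMP6s-labelled superior
colliculus imaged at macroscopic scale: a baseline fluorescence map is
modulated multiplicatively by stimulus-locked responses convolved with a
mono-exponential indicator kernel (default tau = 1.5 s), on top of slow
drift (sinusoid plus linear trend) and per-frame Gaussian shot noise.  Every
pixel carries a ground-truth retinotopic position (an affine map from pixel
coordinates to the monitor plane) and an orientation preference given by the
chosen organisational rule:

* ``concentric`` — preference equals the concentric angle of the pixel's
  visual-field position (nasal ipsilateral positions prefer horizontal);
* ``random_smooth`` — a spatially smooth but retinotopy-independent
  orientation field;
* ``uniform_null`` — responsive but orientation-untuned pixels (all
  directions drive the same mean response).

The electrophysiology generator emulates penetrations through the retino-
recipient lamina: each penetration has a receptive-field position and (under
the columnar rules) a shared preferred orientation about which its units
scatter with axial von Mises concentration ``within_kappa``; trial firing
rates are Poisson counts of a von Mises orientation tuning curve over the
stimulus window.

All stochastic output is a pure function of the parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import MonitorGeometry, concentric_from_angles, monitor_to_head_xyz, xyz_to_spherical
from .imaging import ImagingStack, StimulusEvent
from .tuning import direction_to_grating_orientation

__all__ = [
    "GroundTruth",
    "SyntheticImagingDataset",
    "default_geometry",
    "gen_imaging_dataset",
    "gen_ephys_dataset",
]

ORIENTATION_RULES = ("concentric", "random_smooth", "uniform_null")


def default_geometry(**kwargs) -> MonitorGeometry:
    """Default monitor geometry: 42-inch screen 29.5 cm ahead, 4x4 patch grid
    over the region of the monitor covered by the simulated retinotopy."""
    kwargs.setdefault("x_extent_cm", (4.0, 33.0))
    kwargs.setdefault("y_extent_cm", (-8.0, 21.0))
    return MonitorGeometry.with_patch_grid(4, 4, **kwargs)


@dataclass
class GroundTruth:
    """Ground truth attached to a synthetic imaging dataset."""

    orientation_rule: str
    pref_deg: np.ndarray  # (H, W) preferred grating orientation
    rf_x_cm: np.ndarray  # (H, W) retinotopic position on the monitor plane
    rf_y_cm: np.ndarray
    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    responsive: np.ndarray  # (H, W) bool; False inside the reference region
    seed: int
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticImagingDataset:
    stack: ImagingStack
    events: list[StimulusEvent]
    truth: GroundTruth
    geometry: MonitorGeometry


def _indicator_kernel(t_mid: np.ndarray, onset: float, offset: float, tau: float) -> np.ndarray:
    """Saturating rise during the stimulus, exponential decay after offset."""
    k = np.zeros_like(t_mid)
    during = (t_mid >= onset) & (t_mid < offset)
    after = t_mid >= offset
    k[during] = 1.0 - np.exp(-(t_mid[during] - onset) / tau)
    peak = 1.0 - np.exp(-(offset - onset) / tau)
    k[after] = peak * np.exp(-(t_mid[after] - offset) / tau)
    return k


def _smooth_random_axial(shape: tuple[int, int], sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth random orientation field in [0, 180)."""
    re = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    im = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)
    return np.rad2deg(np.arctan2(im, re)) / 2.0 % 180.0


def _schedule(
    rng: np.random.Generator,
    n_patches: int,
    n_patch_reps: int,
    directions: np.ndarray,
    n_dir_reps: int,
    stim_s: float,
    isi_s: float,
    t_start: float,
    frame_rate_hz: float,
) -> list[StimulusEvent]:
    """Patch session followed by a grating session; condition order is
    shuffled independently within every repetition block.

    Stimulus onsets are locked to the acquisition frame clock (next frame
    boundary after the minimum interstimulus interval), as triggered
    acquisition systems do; this keeps the frame/window alignment identical
    across presentations.
    """

    def align(t: float) -> float:
        return np.ceil(t * frame_rate_hz - 1e-9) / frame_rate_hz

    events: list[StimulusEvent] = []
    t = align(t_start)
    for _ in range(n_patch_reps):
        for pid in rng.permutation(n_patches):
            events.append(StimulusEvent(t, t + stim_s, "patch", patch_id=int(pid)))
            t = align(t + stim_s + isi_s)
    for _ in range(n_dir_reps):
        for d in rng.permutation(directions):
            events.append(
                StimulusEvent(
                    t, t + stim_s, "grating",
                    direction_deg=float(d), sf_cpd=0.05, tf_hz=2.0, contrast=0.9,
                )
            )
            t = align(t + stim_s + isi_s)
    return events


def gen_imaging_dataset(
    orientation_rule: str = "concentric",
    shape: tuple[int, int] = (96, 96),
    geometry: MonitorGeometry | None = None,
    n_patch_reps: int = 5,
    n_dir_reps: int = 20,
    directions: np.ndarray | None = None,
    frame_rate_hz: float = 1.8,
    pixel_size_um: float = 11.04,
    stim_s: float = 3.0,
    isi_s: float = 9.0,
    rf_x_range_cm: tuple[float, float] = (2.0, 35.0),
    rf_y_range_cm: tuple[float, float] = (23.0, -10.0),
    rf_sigma_cm: float = 5.0,
    patch_amp: float = 0.03,
    untuned_amp: float = 0.01,
    tuned_amp: float = 0.025,
    tuning_kappa: float = 1.0,
    tau_s: float = 1.5,
    noise_sigma_frac: float = 0.01,
    drift_amp_frac: float = 0.003,
    drift_period_s: float = 300.0,
    trend_frac: float = 0.005,
    reference_roi_px: tuple[int, int] = (10, 10),
    seed: int = 0,
) -> SyntheticImagingDataset:
    """Generate a synthetic calcium-imaging session with retinotopic patches
    and full-screen drifting gratings (8 directions).

    Defaults mirror the experimental design the analysis was built for:
    1.8 Hz acquisition at 11.04 µm/px, 3 s stimuli with 9 s interstimulus
    interval, at least 5 repetitions per retinotopic patch and 20 per
    drift direction.  The retinotopy is an affine map from pixel coordinates
    to monitor centimetres (``rf_x_range_cm`` across columns,
    ``rf_y_range_cm`` down rows); patch responses are Gaussian in that
    retinotopic space with scatter ``rf_sigma_cm``.  Grating responses are an
    untuned pedestal (``untuned_amp`` ΔF/F) plus a von Mises orientation
    bump (``tuned_amp`` peak, shape ``exp(kappa*(cos(2Δ)-1))``) centred on
    the rule's angle at each pixel.  A corner region of ``reference_roi_px``
    pixels is left visually unresponsive to exercise reference correction.
    """
    if orientation_rule not in ORIENTATION_RULES:
        raise ValueError(f"orientation_rule must be one of {ORIENTATION_RULES}")
    H, W = shape
    if H < 32 or W < 32:
        raise ValueError("image must be at least 32 x 32")
    if n_patch_reps < 1 or n_dir_reps < 1:
        raise ValueError("repetition counts must be >= 1")
    geom = geometry if geometry is not None else default_geometry()
    dirs = np.arange(0.0, 360.0, 45.0) if directions is None else np.asarray(directions, float)
    rng = np.random.default_rng(seed)

    # --- ground truth -----------------------------------------------------
    rows, cols = np.mgrid[0:H, 0:W]
    rf_x = rf_x_range_cm[0] + (rf_x_range_cm[1] - rf_x_range_cm[0]) * cols / (W - 1)
    rf_y = rf_y_range_cm[0] + (rf_y_range_cm[1] - rf_y_range_cm[0]) * rows / (H - 1)
    xyz = monitor_to_head_xyz(np.column_stack([rf_x.ravel(), rf_y.ravel()]), geom)
    az, el = xyz_to_spherical(xyz[:, 0], xyz[:, 1], xyz[:, 2])
    az = az.reshape(shape)
    el = el.reshape(shape)
    if orientation_rule == "concentric":
        pref = concentric_from_angles(az, el)
        ipsi = (np.sign(az) == np.sign(geom.ipsi_azimuth_sign)) & (az != 0)
        pref = np.where(ipsi | np.isnan(pref), 0.0, pref)
    elif orientation_rule == "random_smooth":
        pref = _smooth_random_axial(shape, sigma_px=8.0, rng=rng)
    else:  # uniform_null: preference is undefined; keep a placeholder field
        pref = np.zeros(shape)
    responsive = np.ones(shape, dtype=bool)
    responsive[: reference_roi_px[0], : reference_roi_px[1]] = False

    # --- schedule and stack ----------------------------------------------
    pad_s = 6.0
    events = _schedule(
        rng, geom.n_patches, n_patch_reps, dirs, n_dir_reps, stim_s, isi_s, pad_s, frame_rate_hz
    )
    t_total = events[-1].offset_s + 8.0
    T = int(np.ceil(t_total * frame_rate_hz))
    t_mid = (np.arange(T) + 0.5) / frame_rate_hz

    f0 = 1000.0 * (1.0 + 0.1 * ndimage.gaussian_filter(rng.standard_normal(shape), 6.0))
    f0 = np.clip(f0, 200.0, None).astype(np.float32)

    # per-pixel response amplitude for each stimulus condition
    mean_shape = float(np.mean(np.exp(tuning_kappa * (np.cos(np.linspace(0, 2 * np.pi, 360)) - 1))))
    amp_by_event: dict[tuple, np.ndarray] = {}
    for d in dirs:
        if orientation_rule == "uniform_null":
            a = untuned_amp + tuned_amp * mean_shape
            amp = np.full(shape, a)
        else:
            o = direction_to_grating_orientation(d)
            bump = np.exp(tuning_kappa * (np.cos(2 * np.deg2rad(o - pref)) - 1.0))
            amp = untuned_amp + tuned_amp * bump
        amp_by_event[("grating", float(d))] = np.where(responsive, amp, 0.0).astype(np.float32)
    for pid in range(geom.n_patches):
        cx, cy = geom.patch_centres_cm[pid]
        d2 = (rf_x - cx) ** 2 + (rf_y - cy) ** 2
        amp = patch_amp * np.exp(-d2 / (2.0 * rf_sigma_cm**2))
        amp_by_event[("patch", pid)] = np.where(responsive, amp, 0.0).astype(np.float32)

    signal = np.zeros((T, H, W), dtype=np.float32)
    for ev in events:
        key = ("patch", ev.patch_id) if ev.kind == "patch" else ("grating", float(ev.direction_deg))
        lo = max(int((ev.onset_s) * frame_rate_hz) - 1, 0)
        hi = min(int((ev.offset_s + 8 * tau_s) * frame_rate_hz) + 2, T)
        k = _indicator_kernel(t_mid[lo:hi], ev.onset_s, ev.offset_s, tau_s).astype(np.float32)
        signal[lo:hi] += k[:, None, None] * amp_by_event[key][None]

    drift = drift_amp_frac * np.sin(2 * np.pi * t_mid / drift_period_s) + trend_frac * (
        t_mid / t_mid[-1]
    )
    frames = f0[None] * (1.0 + drift[:, None, None].astype(np.float32)) * (1.0 + signal)
    frames += (noise_sigma_frac * f0)[None] * rng.standard_normal(frames.shape, dtype=np.float32)
    np.clip(frames, 0.0, None, out=frames)

    truth = GroundTruth(
        orientation_rule=orientation_rule,
        pref_deg=pref,
        rf_x_cm=rf_x,
        rf_y_cm=rf_y,
        azimuth_deg=az,
        elevation_deg=el,
        responsive=responsive,
        seed=int(seed),
        params={
            "rf_sigma_cm": rf_sigma_cm,
            "patch_amp": patch_amp,
            "untuned_amp": untuned_amp,
            "tuned_amp": tuned_amp,
            "tuning_kappa": tuning_kappa,
            "tau_s": tau_s,
            "noise_sigma_frac": noise_sigma_frac,
            "drift_amp_frac": drift_amp_frac,
            "trend_frac": trend_frac,
            "n_patch_reps": n_patch_reps,
            "n_dir_reps": n_dir_reps,
        },
    )
    stack = ImagingStack(frames, frame_rate_hz=frame_rate_hz, pixel_size_um=pixel_size_um)
    return SyntheticImagingDataset(stack=stack, events=events, truth=truth, geometry=geom)


EPHYS_RULES = ("columnar_concentric", "columnar_random", "null")


def gen_ephys_dataset(
    n_penetrations: int = 20,
    units_per_pen: int = 8,
    within_kappa: float = 4.0,
    rule: str = "columnar_random",
    n_trials: int = 5,
    directions: np.ndarray | None = None,
    baseline_hz: float = 2.0,
    amp_hz: float = 8.0,
    stim_s: float = 3.0,
    rf_azimuth_range: tuple[float, float] = (5.0, 50.0),
    rf_elevation_range: tuple[float, float] = (-20.0, 30.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a per-trial unit response table for electrode penetrations.

    Each penetration receives a receptive-field position drawn uniformly in
    the given azimuth/elevation box (contralateral field by default) and,
    under the columnar rules, a shared preferred orientation: the concentric
    angle at the receptive field (``columnar_concentric``) or a uniform
    random angle (``columnar_random``).  Unit preferences scatter about the
    penetration's angle with axial von Mises concentration ``within_kappa``;
    under ``rule="null"`` every unit draws an independent uniform preference.
    Trial responses are Poisson spike counts over the stimulus window of a
    von Mises orientation tuning curve (peak ``baseline + amp`` at the
    preferred orientation), expressed in Hz; the ``baseline`` column holds
    matched Poisson samples of the spontaneous rate.

    The default direction set steps by 22.5° (16 directions, 8 orientations),
    the resolution at which penetration preferences are determined in the
    recordings this emulates; coarser sets quantise the argmax preference
    harder and make the shuffle test conservative through ties.

    Returns ``(trial_table, ground_truth_dict)``.
    """
    if rule not in EPHYS_RULES:
        raise ValueError(f"rule must be one of {EPHYS_RULES}")
    if min(n_penetrations, units_per_pen, n_trials) < 1:
        raise ValueError("all counts must be >= 1")
    dirs = np.arange(0.0, 360.0, 22.5) if directions is None else np.asarray(directions, float)
    rng = np.random.default_rng(seed)

    oris = direction_to_grating_orientation(dirs)
    n_units = n_penetrations * units_per_pen
    pen_ids = np.array([f"pen{p:03d}" for p in range(n_penetrations)])
    rf_az = rng.uniform(*rf_azimuth_range, size=n_penetrations)
    rf_el = rng.uniform(*rf_elevation_range, size=n_penetrations)
    if rule == "columnar_concentric":
        centres = np.asarray(concentric_from_angles(rf_az, rf_el), dtype=float)
    elif rule == "columnar_random":
        centres = rng.uniform(0.0, 180.0, size=n_penetrations)
    else:
        centres = np.full(n_penetrations, np.nan)
    if rule == "null":
        prefs = rng.uniform(0.0, 180.0, size=n_units)
    else:
        delta = np.rad2deg(rng.vonmises(0.0, within_kappa, size=n_units)) / 2.0
        prefs = (np.repeat(centres, units_per_pen) + delta) % 180.0

    # rates: (unit, direction); trials are Poisson counts over the stimulus window
    rates = baseline_hz + amp_hz * np.exp(
        np.cos(2 * np.deg2rad(oris[None, :] - prefs[:, None])) - 1.0
    )
    counts = rng.poisson(rates[:, None, :] * stim_s, size=(n_units, n_trials, dirs.size))
    base_counts = rng.poisson(baseline_hz * stim_s, size=(n_units, n_trials, dirs.size))

    unit_idx = np.repeat(np.arange(n_units), n_trials * dirs.size)
    pen_idx = unit_idx // units_per_pen
    table = pd.DataFrame(
        {
            "penetration_id": pen_ids[pen_idx],
            "unit_id": np.array(
                [f"pen{u // units_per_pen:03d}_u{u % units_per_pen:02d}" for u in range(n_units)]
            )[unit_idx],
            "depth_um": 50.0 * (unit_idx % units_per_pen),
            "stimulus_kind": "grating",
            "direction_deg": np.tile(dirs, n_units * n_trials),
            "phase_deg": 0.0,
            "trial_index": np.tile(np.repeat(np.arange(n_trials), dirs.size), n_units),
            "response": counts.ravel() / stim_s,
            "baseline": base_counts.ravel() / stim_s,
            "rf_azimuth_deg": rf_az[pen_idx],
            "rf_elevation_deg": rf_el[pen_idx],
        }
    )
    truth: dict = {
        "rule": rule,
        "seed": int(seed),
        "penetrations": {
            pen_ids[p]: {
                "rf_azimuth_deg": float(rf_az[p]),
                "rf_elevation_deg": float(rf_el[p]),
                "centre_pref_deg": float(centres[p]),
                "unit_prefs_deg": [
                    float(prefs[p * units_per_pen + u]) for u in range(units_per_pen)
                ],
            }
            for p in range(n_penetrations)
        },
    }
    return table, truth
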