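"""Stimulus-triggered ΔF/F and per-pixel map construction from wide-field
calcium imaging stacks.

The response to one stimulus presentation is ``(Rs - R0) / R0`` where ``Rs``
averages the frames from 0.3 s after stimulus onset until 2 s after offset
and ``R0`` averages the 3.3 s ending 0.3 s after onset.  A frame belongs to a
window when its temporal midpoint falls inside ``[start, end)`` — at a 1.8 Hz
frame rate windows are never frame-aligned, and the midpoint rule makes the
assignment unambiguous.  Responses may be divided by ``1 + r_ref`` with
``r_ref`` the same response in a visually non-responsive reference region, to
cancel slow fluorescence changes unrelated to neuronal activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .maps import AxialMap, ScalarMap, smooth_scalar
from .tuning import direction_to_grating_orientation

logger = logging.getLogger(__name__)

__all__ = [
    "ImagingStack",
    "StimulusEvent",
    "event_response",
    "reference_correct",
    "condition_trial_maps",
    "retinotopy_argmax_map",
    "orientation_polar_map",
    "anova_significance_map",
    "single_condition_map",
]

RESPONSE_START_OFFSET_S = 0.3
RESPONSE_END_PAD_S = 2.0
BASELINE_SPAN_S = 3.0


@dataclass
class ImagingStack:
    """Single-channel fluorescence stack with acquisition metadata."""

    frames: np.ndarray  # (T, H, W), nonnegative
    frame_rate_hz: float = 1.8
    pixel_size_um: float = 11.04
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or min(self.frames.shape) < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz

    def frame_midtimes(self) -> np.ndarray:
        return self.t0_s + (np.arange(self.frames.shape[0]) + 0.5) / self.frame_rate_hz


@dataclass
class StimulusEvent:
    """One stimulus presentation: a retinotopic patch, a drifting grating, or dots."""

    onset_s: float
    offset_s: float
    kind: str  # "patch" | "grating" | "dots"
    patch_id: int | None = None
    direction_deg: float | None = None
    sf_cpd: float | None = None
    tf_hz: float | None = None
    contrast: float | None = None
    phase_deg: float | None = None

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")
        if self.kind == "patch":
            if self.patch_id is None or self.direction_deg is not None:
                raise ValueError("patch events carry patch_id only")
        elif self.kind in ("grating", "dots"):
            if self.direction_deg is None or self.patch_id is not None:
                raise ValueError(f"{self.kind} events carry direction_deg only")
        else:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")


def events_to_frame(events: list[StimulusEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "kind": ev.kind,
                "patch_id": ev.patch_id,
                "direction_deg": ev.direction_deg,
                "sf_cpd": ev.sf_cpd,
                "tf_hz": ev.tf_hz,
                "contrast": ev.contrast,
                "phase_deg": ev.phase_deg,
            }
        )
    return pd.DataFrame(rows)


def events_from_frame(df: pd.DataFrame) -> list[StimulusEvent]:
    out = []
    for _, row in df.iterrows():
        out.append(
            StimulusEvent(
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
                kind=str(row["kind"]),
                patch_id=None if pd.isna(row.get("patch_id")) else int(row["patch_id"]),
                direction_deg=(
                    None if pd.isna(row.get("direction_deg")) else float(row["direction_deg"])
                ),
                sf_cpd=None if pd.isna(row.get("sf_cpd")) else float(row["sf_cpd"]),
                tf_hz=None if pd.isna(row.get("tf_hz")) else float(row["tf_hz"]),
                contrast=None if pd.isna(row.get("contrast")) else float(row["contrast"]),
                phase_deg=None if pd.isna(row.get("phase_deg")) else float(row["phase_deg"]),
            )
        )
    return out


def _window_frames(stack: ImagingStack, start_s: float, end_s: float) -> np.ndarray:
    mid = stack.frame_midtimes()
    return np.flatnonzero((mid >= start_s) & (mid < end_s))


def event_response(stack: ImagingStack, ev: StimulusEvent) -> ScalarMap | None:
    """ΔF/F map for one event, or None when its windows fall off the recording.

    Response window: ``[onset + 0.3 s, offset + 2 s)``; baseline window:
    ``[onset - 3 s, onset + 0.3 s)``.  Pixels with non-positive baseline are
    masked out.  Skipped events are logged, not raised: partial schedules at
    the recording edges are routine.
    """
    b_idx = _window_frames(stack, ev.onset_s - BASELINE_SPAN_S, ev.onset_s + RESPONSE_START_OFFSET_S)
    r_idx = _window_frames(stack, ev.onset_s + RESPONSE_START_OFFSET_S, ev.offset_s + RESPONSE_END_PAD_S)
    t_end = stack.t0_s + stack.duration_s
    if (
        b_idx.size == 0
        or r_idx.size == 0
        or ev.onset_s - BASELINE_SPAN_S < stack.t0_s - 0.5 / stack.frame_rate_hz
        or ev.offset_s + RESPONSE_END_PAD_S > t_end + 0.5 / stack.frame_rate_hz
    ):
        logger.warning(
            "skipping event at %.2f s: windows fall outside the recording", ev.onset_s
        )
        return None
    r0 = stack.frames[b_idx].mean(axis=0, dtype=np.float64)
    rs = stack.frames[r_idx].mean(axis=0, dtype=np.float64)
    ok = r0 > 0
    dff = np.zeros_like(r0)
    dff[ok] = rs[ok] / r0[ok] - 1.0
    return ScalarMap(dff, ok, "dF/F")


def reference_correct(resp: ScalarMap | np.ndarray, ref_resp: float):
    """Divide a ΔF/F response by ``1 + ref_resp`` (reference-region response)."""
    if ref_resp <= -1:
        raise ValueError("invalid reference response: must exceed -1")
    if isinstance(resp, ScalarMap):
        return ScalarMap(resp.values / (1.0 + ref_resp), resp.mask.copy(), resp.units)
    return np.asarray(resp, dtype=float) / (1.0 + ref_resp)


def condition_trial_maps(
    stack: ImagingStack,
    events: list[StimulusEvent],
    kind: str,
    ref_roi: tuple[slice, slice] | None = None,
) -> dict[int | float, list[ScalarMap]]:
    """Per-condition lists of single-trial ΔF/F maps (unsmoothed).

    Conditions are patch ids (``kind="patch"``) or drift directions
    (``kind="grating"``/``"dots"``).  Each trial map is reference-corrected
    when ``ref_roi`` is given; otherwise correction is skipped and logged.
    Spatial filtering belongs to map construction, not to the per-trial
    responses: trial statistics (the ANOVA) operate on the raw responses.
    """
    if ref_roi is None:
        logger.info("no reference region configured; skipping reference correction")
    out: dict[int | float, list[ScalarMap]] = {}
    for ev in events:
        if ev.kind != kind:
            continue
        resp = event_response(stack, ev)
        if resp is None:
            continue
        if ref_roi is not None:
            ref = float(np.mean(resp.values[ref_roi]))
            resp = reference_correct(resp, ref)
        key = ev.patch_id if kind == "patch" else ev.direction_deg
        out.setdefault(key, []).append(resp)
    return out


def condition_mean_maps(
    trial_maps: dict,
    sigma_um: float = 33.0,
    pixel_size_um: float = 11.04,
) -> dict[int | float, ScalarMap]:
    """Per-condition trial-mean ΔF/F maps, smoothed with a 2D Gaussian of
    ``sigma_um`` (default 33 µm, 3 px at 11.04 µm/px); the mask is the
    conjunction of the trial masks."""
    means: dict[int | float, ScalarMap] = {}
    for key, maps in trial_maps.items():
        mask = np.logical_and.reduce([m.mask for m in maps])
        mean = ScalarMap(np.mean([m.values for m in maps], axis=0), mask, maps[0].units)
        means[key] = smooth_scalar(mean, sigma_um, pixel_size_um)
    return means


def _unpack_means(mean_maps: dict) -> tuple[dict, np.ndarray]:
    means = {k: m.values for k, m in mean_maps.items()}
    mask = np.logical_and.reduce([m.mask for m in mean_maps.values()])
    return means, mask


def retinotopy_argmax_map(mean_maps: dict[int, ScalarMap]) -> tuple[ScalarMap, ScalarMap]:
    """Best-patch map: per pixel, the patch id with the largest trial-mean ΔF/F.

    Takes per-patch mean maps (see :func:`condition_mean_maps`).  Returns
    ``(best_patch, amplitude)``; ties break to the lowest patch id (logged)
    and pixels whose best response is non-positive are masked out.
    """
    if not mean_maps:
        raise ValueError("no patch responses")
    means, mask = _unpack_means(mean_maps)
    ids = np.array(sorted(means))
    cube = np.stack([means[i] for i in ids])  # (P, H, W)
    best = np.argmax(cube, axis=0)  # argmax takes the first (lowest id) on ties
    amp = np.take_along_axis(cube, best[None], axis=0)[0]
    n_ties = int(np.sum((cube == amp[None]).sum(axis=0) > 1))
    if n_ties:
        logger.info("retinotopy argmax: %d pixels tied; broken to lowest patch id", n_ties)
    ok = mask & (amp > 0)
    patch = ScalarMap(ids[best].astype(float), ok, "patch_id")
    return patch, ScalarMap(amp, ok, "dF/F")


def orientation_polar_map(
    mean_maps: dict[float, ScalarMap],
) -> tuple[AxialMap, np.ndarray]:
    """Per-pixel preferred orientation from drifting-grating responses.

    Takes per-direction mean maps (see :func:`condition_mean_maps`).  For
    each pixel the response to orientation phi is the maximum of the
    trial-mean responses to the two opposite drift directions sharing that
    grating orientation (clamped at 0); the preferred orientation is half the
    argument of ``sum_phi R(phi) exp(2i phi)`` and the amplitude is the mean
    response over all stimuli (used for saturation scaling on export).
    Pixels with zero resultant are masked out.

    Returns ``(axial_map, per_condition)`` where ``per_condition`` stacks the
    clamped per-orientation responses (n_orientations, H, W), the input to
    the per-condition response filter of the map comparison.
    """
    if not mean_maps:
        raise ValueError("no grating responses")
    means, mask = _unpack_means(mean_maps)
    dirs = np.array(sorted(means))
    oris = np.unique(direction_to_grating_orientation(dirs))
    if oris.size * 2 != dirs.size:
        raise ValueError("unpaired directions: every direction needs its opposite")
    per_ori = []
    for o in oris:
        pair = [means[d] for d in dirs if np.isclose(direction_to_grating_orientation(d), o)]
        per_ori.append(np.clip(np.maximum.reduce(pair), 0.0, None))
    per_ori = np.stack(per_ori)  # (O, H, W)
    phase = np.exp(2j * np.deg2rad(oris))[:, None, None]
    vec = (per_ori * phase).sum(axis=0)
    amp_mean = np.mean([means[d] for d in dirs], axis=0)
    resultant_ok = np.abs(vec) > 1e-12 * np.maximum(per_ori.sum(axis=0), 1e-300)
    ok = mask & resultant_ok
    angle = np.where(ok, np.rad2deg(np.angle(vec)) / 2.0 % 180.0, 0.0)
    amp = np.where(ok, np.clip(amp_mean, 0.0, None), 0.0)
    return AxialMap(angle_deg=angle, amplitude=amp, mask=ok), per_ori


def anova_significance_map(
    trial_maps: dict[float, list[ScalarMap]], alpha: float = 0.05
) -> ScalarMap:
    """Per-pixel one-way ANOVA p-value across the four orientations.

    Trials of opposite drift directions are pooled into one orientation
    group.  Degenerate pixels (zero variance both within and between groups)
    get p = 1; zero within-group variance with a real group difference gives
    p = 0.  The returned mask marks pixels valid in every trial; threshold at
    ``alpha`` for the significance mask.
    """
    dirs = sorted(trial_maps)
    groups: dict[float, list[np.ndarray]] = {}
    mask = None
    for d in dirs:
        o = direction_to_grating_orientation(d)
        for m in trial_maps[d]:
            groups.setdefault(o, []).append(m.values)
            mask = m.mask if mask is None else (mask & m.mask)
    arrays = [np.stack(v) for v in groups.values()]
    if any(a.shape[0] < 2 for a in arrays):
        raise ValueError("need >= 2 trials per orientation group")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*arrays, axis=0)
    p = np.where(np.isnan(p), 1.0, p)  # constant everywhere: no evidence
    return ScalarMap(p, mask, f"p (alpha={alpha})")


def single_condition_map(
    mean_maps: dict[float, ScalarMap], selected: list[float]
) -> ScalarMap:
    """Mean ΔF/F over selected directions minus the mean over all directions."""
    if not selected:
        raise ValueError("selected direction set must be non-empty")
    means, mask = _unpack_means(mean_maps)
    missing = [d for d in selected if d not in means]
    if missing:
        raise ValueError(f"selected directions not shown: {missing}")
    sel = np.mean([means[d] for d in selected], axis=0)
    allm = np.mean(list(means.values()), axis=0)
    return ScalarMap(sel - allm, mask, "dF/F")
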