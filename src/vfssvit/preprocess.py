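"""Fully automated VFSS cleaning pipeline.

Stages, in order: (1) crop the static patient-information band found by a
horizontal Prewitt edge scan of the temporal-mean frame; (2) detect the
circular targeting artifact of the early frames with a Hough transform and
inpaint it; (3) unify the spatial resolution to the corpus median by symmetric
zero-padding / center-cropping; (4) zero everything outside the circular
detector field of view; (5) bilateral denoising, CLAHE contrast enhancement,
re-masking and rescaling to [0, 1].

Every stage is deterministic and shape-contracted; the composed pipeline never
produces NaN/Inf and keeps the masked corners an exact zero set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage import exposure, feature, restoration, transform
from skimage.filters import prewitt_h

from .io import FrameStack

__all__ = [
    "PreprocessConfig",
    "PipelineStageError",
    "crop_info_window",
    "find_crop_rows",
    "transform_mask",
    "detect_targeting_artifact",
    "remove_targeting_artifact",
    "unify_resolution",
    "make_fov_mask",
    "apply_fov_mask",
    "denoise_equalize",
    "run_pipeline",
    "fit_target_hw",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Pipeline parameters, tuned once and then fixed for a whole corpus.

    ``target_hw`` is the corpus-median resolution; it is fitted on the
    training manifest (:func:`fit_target_hw`) and persisted, never recomputed
    per clip, so train and test share one geometry.  CLAHE's ``clahe_clip``
    follows scikit-image semantics (fraction of the tile histogram, in
    (0, 1]).  ``bilateral`` is (window diameter px, sigma_intensity as a
    fraction of the [0,1] range, sigma_space px).
    """

    target_hw: Optional[tuple[int, int]] = None
    prewitt_search_frac: float = 0.2
    prewitt_floor: float = 0.05
    hough_radius_frac: tuple[float, float] = (0.05, 0.15)
    hough_search_frames: int = 10
    hough_accum_threshold: float = 0.4
    # the Hough radius sits on the ring's inner edge, so the inpainting disk
    # is dilated enough to swallow the full ring width
    inpaint_dilation: int = 4
    bilateral: tuple[int, float, float] = (5, 0.1, 3.0)
    clahe_clip: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    fov_margin: int = 0
    min_rows: int = 16

    def __post_init__(self) -> None:
        if self.target_hw is not None and min(self.target_hw) <= 0:
            raise ValueError("target_hw must be positive")
        if self.clahe_clip <= 0:
            raise ValueError("clahe_clip must be > 0")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("clahe_tile_grid must be >= 1x1")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"preprocessing stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _require_single_channel(stack: FrameStack) -> np.ndarray:
    if stack.frames.ndim != 3:
        raise ValueError("expected a single-channel (T,H,W) stack; run reduce_channels first")
    return np.asarray(stack.frames, dtype=np.float64)


# ---------------------------------------------------------------------------
# Stage 1: info-window crop


def _band_edge_row(row_response: np.ndarray, floor: float) -> Optional[int]:
    if row_response.size == 0 or row_response.max() < floor:
        return None
    return int(np.argmax(row_response))


def crop_info_window(stack: FrameStack, config: PreprocessConfig) -> FrameStack:
    """Remove the static overlay band(s) at the top/bottom of the frame.

    The overlay is static, so the edge is found on the temporal-mean frame:
    within the top (and bottom) ``prewitt_search_frac`` of rows, the crop
    boundary is the row of maximal mean absolute horizontal-Prewitt response.
    If no response exceeds ``prewitt_floor`` the stack is returned unchanged.
    """
    crop_top, crop_bottom = find_crop_rows(stack, config)
    h = stack.frame_shape[0]
    if crop_top == 0 and crop_bottom == h:
        return stack
    return stack.with_frames(stack.frames[:, crop_top:crop_bottom, :])


def find_crop_rows(stack: FrameStack, config: PreprocessConfig) -> tuple[int, int]:
    """Row range ``[crop_top, crop_bottom)`` retained by the info-window crop."""
    frames = _require_single_channel(stack)
    t, h, w = frames.shape
    mean_frame = frames.mean(axis=0)
    resp = np.abs(prewitt_h(mean_frame)).mean(axis=1)
    band = max(1, int(round(config.prewitt_search_frac * h)))

    top = _band_edge_row(resp[:band], config.prewitt_floor)
    crop_top = 0 if top is None else top + 1
    bot = _band_edge_row(resp[h - band:], config.prewitt_floor)
    crop_bottom = h if bot is None else h - band + bot
    if crop_bottom - crop_top < config.min_rows:
        raise ValueError(
            f"info-window crop would leave {crop_bottom - crop_top} rows "
            f"(< min_rows={config.min_rows})"
        )
    return crop_top, crop_bottom


# ---------------------------------------------------------------------------
# Stage 2: targeting-artifact removal


def detect_targeting_artifact(
    frames: np.ndarray, config: PreprocessConfig
) -> Optional[tuple[int, int, int]]:
    """Hough-detect the circular targeting artifact in the early frames.

    Returns ``(row, col, radius)`` or ``None`` when no sufficiently supported
    circle exists within the configured radius range.
    """
    t, h, w = frames.shape
    n = min(config.hough_search_frames, t)
    probe = frames[:n].max(axis=0)  # artifact is static; max sharpens the ring
    edges = feature.canny(probe, sigma=1.0)
    rmin = max(3, int(round(config.hough_radius_frac[0] * min(h, w))))
    rmax = max(rmin + 1, int(round(config.hough_radius_frac[1] * min(h, w))))
    radii = np.arange(rmin, rmax + 1)
    accum = transform.hough_circle(edges, radii)
    accums, cx, cy, rad = transform.hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(accums) == 0 or accums[0] < config.hough_accum_threshold:
        return None
    return int(cy[0]), int(cx[0]), int(rad[0])


def remove_targeting_artifact(stack: FrameStack, config: PreprocessConfig) -> FrameStack:
    """Inpaint the detected targeting disk in every frame where it persists.

    Absence of the artifact is not an error: undetected input is returned
    unchanged.  Presence per frame is decided from the ring-band intensity
    (the artifact disappears after the first few frames, so frames whose ring
    response stays near the clip-wide baseline are left untouched).
    """
    frames = _require_single_channel(stack)
    hit = detect_targeting_artifact(frames, config)
    if hit is None:
        return stack
    r0, c0, radius = hit
    t, h, w = frames.shape
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - r0, cc - c0)
    ring = np.abs(dist - radius) <= 1.5
    disk = dist <= radius + config.inpaint_dilation

    ring_resp = frames[:, ring].mean(axis=1)
    baseline = np.median(ring_resp)
    spread = ring_resp.max() - baseline
    if spread < 0.05:
        present = np.zeros(t, dtype=bool)  # ring never clearly brighter
    else:
        present = ring_resp > baseline + 0.5 * spread

    out = frames.copy()
    for i in np.nonzero(present)[0]:
        out[i] = restoration.inpaint_biharmonic(frames[i], disk)
    return stack.with_frames(out.astype(stack.frames.dtype))


# ---------------------------------------------------------------------------
# Stage 3: resolution unification


def _pad_crop_axis(size: int, target: int) -> tuple[slice, slice]:
    """Source and destination slices mapping one axis onto ``target`` pixels."""
    if size >= target:  # center crop
        off = (size - target) // 2
        return slice(off, off + target), slice(0, target)
    off = (target - size) // 2  # symmetric zero pad
    return slice(0, size), slice(off, off + size)


def unify_resolution(stack: FrameStack, target_hw: tuple[int, int]) -> FrameStack:
    """Zero-pad (below target) or center-crop (above target), per axis."""
    frames = _require_single_channel(stack)
    t, h, w = frames.shape
    th, tw = target_hw
    if (h, w) == (th, tw):
        return stack
    src_r, dst_r = _pad_crop_axis(h, th)
    src_c, dst_c = _pad_crop_axis(w, tw)
    out = np.zeros((t, th, tw), dtype=stack.frames.dtype)
    out[:, dst_r, dst_c] = stack.frames[:, src_r, src_c]
    return stack.with_frames(out)


# ---------------------------------------------------------------------------
# Stage 4: circular field-of-view mask


def make_fov_mask(hw: tuple[int, int], margin: int = 0) -> np.ndarray:
    """Inscribed-circle mask: True inside the detector field of view."""
    h, w = hw
    rr, cc = np.mgrid[0:h, 0:w]
    radius = min(h, w) / 2.0 - margin
    d2 = (rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2
    return d2 <= radius**2


def apply_fov_mask(stack: FrameStack, mask: np.ndarray) -> FrameStack:
    """Zero everything outside the mask; idempotent."""
    if mask.shape != stack.frame_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frame shape {stack.frame_shape}"
        )
    out = stack.frames.copy()
    out[:, ~mask] = 0
    return stack.with_frames(out)


# ---------------------------------------------------------------------------
# Stage 5: denoise + CLAHE + renormalize


def denoise_equalize(
    stack: FrameStack, config: PreprocessConfig, mask: np.ndarray
) -> FrameStack:
    """Per frame: bilateral filter -> CLAHE -> re-apply mask -> clip to [0,1].

    CLAHE is skipped for (near-)constant frames, whose equalization is
    undefined; the bilateral filter leaves them constant, satisfying the flat
    limit case.
    """
    frames = _require_single_channel(stack)
    frames = np.clip(frames, 0.0, 1.0)
    d, sigma_int, sigma_sp = config.bilateral
    t, h, w = frames.shape
    kernel = (
        max(1, h // config.clahe_tile_grid[0]),
        max(1, w // config.clahe_tile_grid[1]),
    )
    out = np.empty_like(frames)
    for i in range(t):
        f = restoration.denoise_bilateral(
            frames[i], win_size=d, sigma_color=sigma_int, sigma_spatial=sigma_sp
        )
        if np.ptp(f) > 1e-8:
            f = exposure.equalize_adapthist(
                np.clip(f, 0.0, 1.0), kernel_size=kernel, clip_limit=config.clahe_clip
            )
        out[i] = f
    out[:, ~mask] = 0.0
    out = np.clip(out, 0.0, 1.0)
    return stack.with_frames(out.astype(np.float32))


# ---------------------------------------------------------------------------
# Composition


def run_pipeline(stack: FrameStack, config: PreprocessConfig) -> FrameStack:
    """Full cleaning chain on an eligible single-channel clip.

    Output is ``config.target_hw`` (which must be set — fit it first), lies in
    [0, 1], has exact zeros outside the circular field of view, and is
    deterministic: rerunning on identical input is byte-identical.
    """
    if config.target_hw is None:
        raise ValueError("config.target_hw is unset; call fit_target_hw on the training manifest first")
    stages = [
        ("crop_info_window", lambda s: crop_info_window(s, config)),
        ("remove_targeting_artifact", lambda s: remove_targeting_artifact(s, config)),
        ("unify_resolution", lambda s: unify_resolution(s, config.target_hw)),
    ]
    out = stack
    for name, fn in stages:
        try:
            out = fn(out)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(name, exc) from exc
    mask = make_fov_mask(config.target_hw, config.fov_margin)
    try:
        out = apply_fov_mask(out, mask)
        out = denoise_equalize(out, config, mask)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("denoise_equalize", exc) from exc
    return out


def transform_mask(
    mask: np.ndarray, stack: FrameStack, config: PreprocessConfig
) -> np.ndarray:
    """Map a spatial ROI mask through the clip's deterministic geometry.

    Applies the same info-window crop rows and pad/crop unification the
    pipeline applies to ``stack``, so a region defined in acquisition
    coordinates (e.g. a planted ground-truth region) can be compared against
    pipeline outputs and saliency maps.
    """
    if config.target_hw is None:
        raise ValueError("config.target_hw is unset")
    crop_top, crop_bottom = find_crop_rows(stack, config)
    cropped = mask[crop_top:crop_bottom, :]
    th, tw = config.target_hw
    src_r, dst_r = _pad_crop_axis(cropped.shape[0], th)
    src_c, dst_c = _pad_crop_axis(cropped.shape[1], tw)
    out = np.zeros((th, tw), dtype=mask.dtype)
    out[dst_r, dst_c] = cropped[src_r, src_c]
    return out


def fit_target_hw(stacks: Iterable[FrameStack]) -> tuple[int, int]:
    """Median (H, W) over a training corpus; persist the result in the config."""
    hs, ws = [], []
    for s in stacks:
        h, w = s.frame_shape
        hs.append(h)
        ws.append(w)
    if not hs:
        raise ValueError("cannot fit target resolution on an empty corpus")
    return int(np.median(hs)), int(np.median(ws))
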