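"""Attention-rollout saliency for the 3D-patch transformer.

The self-attention matrices of every head at every layer are captured during
a forward pass, head-averaged, mixed with the identity to account for the
residual path, row-normalized and recursively multiplied; the class-token row
of the product, restricted to the patch tokens, is the relevance vector r.
Each temporal segment's (n_h x n_w) slice of r is bilinearly upsampled to the
frame resolution and min-max normalized to give per-frame maps m_t, which are
combined into a cumulative map M = sum_t w_t m_t using per-frame weights
derived from the classifier's per-segment softmax confidence.  M is
thresholded at the 90th percentile (computed over field-of-view pixels only)
to give the mask Omega, rendered over a low-motion "quiescent" frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .model import ModelConfig, Prediction, extract_patches, forward

__all__ = [
    "SaliencyResult",
    "collect_attention",
    "rollout",
    "bilinear_upsample",
    "frame_maps",
    "confidence_weights",
    "cumulative_map",
    "threshold_mask",
    "quiescent_frame",
    "overlay",
    "explain_clip",
]


@dataclass
class SaliencyResult:
    """Full saliency output for one clip."""

    relevance: np.ndarray  # (N,) probability vector over patch tokens
    m: np.ndarray  # (T, H, W) per-frame maps in [0,1]
    omega: np.ndarray  # (T,) per-frame weights, sums to 1
    M: np.ndarray  # (H, W) cumulative map
    mask: np.ndarray  # (H, W) bool, the 90th-percentile mask
    quiescent_idx: Optional[int] = None
    quiescent_fallback: bool = False
    constant_map_flag: bool = False
    segment_probs: Optional[np.ndarray] = None


def collect_attention(
    params: Dict[str, np.ndarray], config: ModelConfig, tokens: np.ndarray
) -> List[np.ndarray]:
    """One (h, N+1, N+1) row-stochastic attention array per encoder layer."""
    _, attentions, _ = forward(params, tokens, config, collect_attention=True)
    for a in attentions:
        rowsum = a.sum(-1)
        if not np.allclose(rowsum, 1.0, atol=1e-5):
            raise AssertionError("attention rows must sum to 1")
    return attentions


def rollout(
    attentions: List[np.ndarray],
    attention_grads: Optional[List[np.ndarray]] = None,
) -> np.ndarray:
    """Attention rollout with residual identity mixing.

    Default: per layer, A_bar = rownorm(0.5 * mean_heads(A) + 0.5 * I); the
    layer matrices are multiplied last-to-first and the class-token row
    restricted to patch tokens is renormalized to a probability vector.

    When per-layer attention gradients are supplied (``attention_grads``,
    from :func:`vfssvit.model.forward_backward` with
    ``collect_attention_grads=True``), the gradient-weighted variant is used
    instead: heads are combined as mean_heads(relu(grad * A)) before the
    residual mixing, so heads whose attention does not influence the logit
    drop out of the relevance.  Note that head-averaged rollout treats all
    heads alike; heads with near-uniform attention dilute the localized ones.
    """
    s = attentions[0].shape[-1]
    rolled = np.eye(s)
    for i, a in enumerate(attentions):
        if attention_grads is not None:
            combined = np.maximum(a * attention_grads[i], 0.0).mean(axis=0)
            rowsum = combined.sum(-1, keepdims=True)
            combined = np.where(rowsum > 0, combined / np.maximum(rowsum, 1e-12), np.eye(s))
        else:
            combined = a.mean(axis=0)
        mixed = 0.5 * combined + 0.5 * np.eye(s)
        mixed = mixed / mixed.sum(-1, keepdims=True)
        rolled = mixed @ rolled
    r = rolled[0, 1:]
    total = r.sum()
    if total <= 0:
        return np.full(s - 1, 1.0 / (s - 1))
    return r / total


def bilinear_upsample(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Half-pixel-aligned bilinear upsampling with edge clamping.

    Output pixel (i, j) samples the input at ((i + 0.5) * h_in / h_out - 0.5,
    (j + 0.5) * w_in / w_out - 0.5), clamped to the valid range, so each
    patch's value sits at the center of its pixel block after upsampling.
    """
    h_in, w_in = img.shape
    h_out, w_out = out_hw

    def axis_coords(n_in, n_out):
        x = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        x = np.clip(x, 0, n_in - 1)
        lo = np.floor(x).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        return lo, hi, x - lo

    r0, r1, fr = axis_coords(h_in, h_out)
    c0, c1, fc = axis_coords(w_in, w_out)
    top = img[np.ix_(r0, c0)] * (1 - fc) + img[np.ix_(r0, c1)] * fc
    bot = img[np.ix_(r1, c0)] * (1 - fc) + img[np.ix_(r1, c1)] * fc
    return top * (1 - fr[:, None]) + bot * fr[:, None]


def frame_maps(
    relevance: np.ndarray,
    grid_shape: tuple[int, int, int],
    frame_hw: tuple[int, int],
    n_frames: int,
    tp: int,
) -> tuple[np.ndarray, bool]:
    """Per-frame saliency maps from the token relevance vector.

    The (n_h, n_w) slice of each temporal segment is upsampled to the frame
    resolution and min-max normalized to [0, 1]; every frame of segment s
    shares the segment's map.  A constant slice normalizes to all-zeros and
    sets the returned flag instead of producing NaN.
    """
    n_t, n_h, n_w = grid_shape
    vol = np.asarray(relevance, dtype=np.float64).reshape(n_t, n_h, n_w)
    seg_maps = np.empty((n_t,) + tuple(frame_hw))
    constant_flag = False
    for s in range(n_t):
        up = bilinear_upsample(vol[s], frame_hw)
        span = up.max() - up.min()
        if span <= 0:
            seg_maps[s] = 0.0
            constant_flag = True
        else:
            seg_maps[s] = (up - up.min()) / span
    t_idx = np.minimum(np.arange(n_frames) // tp, n_t - 1)
    return seg_maps[t_idx], constant_flag


def confidence_weights(
    params: Dict[str, np.ndarray],
    config: ModelConfig,
    frames: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame weights from per-segment classifier confidence.

    The model emits one study-level probability, so sub-study confidence is
    obtained by scoring each Tp-frame temporal segment independently; segment
    logits for the clip-level predicted class pass through a softmax, each
    segment's share is spread uniformly over its frames, and the result sums
    to 1 over frames.  Returns ``(omega, segment_probs)``.
    """
    frames = np.asarray(frames, dtype=np.float64)
    t = frames.shape[0]
    grid = extract_patches(frames, config)
    clip_pred, _, _ = forward(params, grid.tokens, config)
    positive = clip_pred.y_hat >= 0.5

    n_t = grid.grid_shape[0]
    seg_logits = np.empty(n_t)
    seg_probs = np.empty(n_t)
    for s in range(n_t):
        seg = frames[s * config.tp : (s + 1) * config.tp]
        seg_grid = extract_patches(seg, config)
        pred, _, _ = forward(params, seg_grid.tokens, config)
        seg_probs[s] = pred.y_hat
        seg_logits[s] = pred.logit if positive else -pred.logit
    e = np.exp(seg_logits - seg_logits.max())
    seg_w = e / e.sum()

    frame_seg = np.minimum(np.arange(t) // config.tp, n_t - 1)
    counts = np.bincount(frame_seg, minlength=n_t).astype(float)
    omega = seg_w[frame_seg] / counts[frame_seg]
    omega = omega / omega.sum()
    return omega, seg_probs


def cumulative_map(m: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Weighted pixel-wise sum M(x, y) = sum_t omega_t m_t(x, y)."""
    return np.einsum("t,thw->hw", np.asarray(omega, float), np.asarray(m, float))


def threshold_mask(
    M: np.ndarray, fov_mask: np.ndarray, percentile: float = 90.0
) -> tuple[np.ndarray, bool]:
    """Percentile mask over field-of-view pixels only.

    A constant map carries no saliency: the mask is empty and flagged.
    """
    vals = M[fov_mask]
    if vals.size == 0 or np.ptp(vals) <= 0:
        return np.zeros_like(fov_mask, dtype=bool), True
    thr = np.percentile(vals, percentile)
    return (M >= thr) & fov_mask, False


def quiescent_frame(
    frames: np.ndarray,
    flow_threshold: float = 0.5,
    fov_mask: Optional[np.ndarray] = None,
) -> tuple[int, bool]:
    """First frame whose mean dense-flow magnitude to the next is < threshold.

    Dense optical flow (iterative Lucas-Kanade) is computed between
    consecutive frames and averaged over the field of view.  If no frame
    qualifies, the argmin-flow frame is returned with the fallback flag set.
    """
    from skimage.registration import optical_flow_ilk

    frames = np.asarray(frames, dtype=np.float64)
    t = frames.shape[0]
    if t < 2:
        return 0, False
    if fov_mask is None:
        fov_mask = np.ones(frames.shape[1:], dtype=bool)
    mags = np.empty(t - 1)
    for i in range(t - 1):
        if np.array_equal(frames[i], frames[i + 1]):
            mags[i] = 0.0
        else:
            v, u = optical_flow_ilk(frames[i], frames[i + 1])
            mags[i] = float(np.hypot(v, u)[fov_mask].mean())
        if mags[i] < flow_threshold:
            return i, False
    return int(np.argmin(mags)), True


def overlay(
    M: np.ndarray,
    mask: np.ndarray,
    frame: np.ndarray,
    path: Optional[str] = None,
    alpha: float = 0.5,
) -> np.ndarray:
    """Warm-colormap alpha overlay of M plus the mask contour on a frame.

    Returns (and optionally writes as PNG) an (H, W, 3) uint8 image.  An
    empty mask draws no contour.
    """
    import matplotlib

    if M.shape != frame.shape or mask.shape != frame.shape:
        raise ValueError(
            f"shape mismatch: M {M.shape}, mask {mask.shape}, frame {frame.shape}"
        )
    gray = np.clip(np.asarray(frame, float), 0.0, 1.0)
    span = np.ptp(M)
    m_norm = (M - M.min()) / span if span > 0 else np.zeros_like(M)
    heat = matplotlib.colormaps["hot"](m_norm)[..., :3]
    base = np.repeat(gray[..., None], 3, axis=2)
    a = alpha * m_norm[..., None]
    img = (1 - a) * base + a * heat
    if mask.any():
        from skimage.measure import find_contours

        for contour in find_contours(mask.astype(float), 0.5):
            rr = np.clip(np.round(contour[:, 0]).astype(int), 0, mask.shape[0] - 1)
            cc = np.clip(np.round(contour[:, 1]).astype(int), 0, mask.shape[1] - 1)
            img[rr, cc] = (0.0, 1.0, 0.2)
    out = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, out)
    return out


def explain_clip(
    params: Dict[str, np.ndarray],
    config: ModelConfig,
    frames: np.ndarray,
    fov_mask: Optional[np.ndarray] = None,
    percentile: float = 90.0,
    compute_quiescent: bool = True,
    variant: str = "rollout",
) -> SaliencyResult:
    """End-to-end saliency for one preprocessed clip.

    ``variant='rollout'`` (default) is the deterministic head-averaged
    rollout; ``variant='gradient'`` weights heads by the positive part of the
    abnormal-logit gradient with respect to the attention probabilities
    before rolling out.
    """
    frames = np.asarray(frames, dtype=np.float64)
    t, h, w = frames.shape
    if fov_mask is None:
        from .preprocess import make_fov_mask

        fov_mask = make_fov_mask((h, w))
    grid = extract_patches(frames, config)
    if variant == "gradient":
        from .model import forward_backward

        # y=0 makes d(loss)/d(logit) = y_hat > 0: attention gradients are a
        # positive multiple of the abnormal-logit gradients.
        *_, attn, attn_grads = forward_backward(
            params, grid.tokens, 0.0, config, collect_attention_grads=True
        )
        r = rollout(attn, attn_grads)
    elif variant == "rollout":
        attn = collect_attention(params, config, grid.tokens)
        r = rollout(attn)
    else:
        raise ValueError(f"unknown saliency variant {variant!r}")
    m, const_flag = frame_maps(r, grid.grid_shape, (h, w), t, config.tp)
    omega, seg_probs = confidence_weights(params, config, frames)
    M = cumulative_map(m, omega)
    mask, mask_flag = threshold_mask(M, fov_mask, percentile)
    if compute_quiescent:
        q_idx, q_fb = quiescent_frame(frames, fov_mask=fov_mask)
    else:
        q_idx, q_fb = None, False
    return SaliencyResult(
        relevance=r,
        m=m,
        omega=omega,
        M=M,
        mask=mask,
        quiescent_idx=q_idx,
        quiescent_fallback=q_fb,
        constant_map_flag=const_flag or mask_flag,
        segment_probs=seg_probs,
    )
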