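"""3D-patch vision transformer for binary video classification, in NumPy.

A clip of shape (T, H, W) is cut into non-overlapping spatio-temporal patches
("tubelets") of Tp frames by P x P pixels; each is flattened to a vector of
length Tp*P^2 and linearly projected to a D-dimensional token.  A learnable
class token is prepended, learnable positional embeddings are added, and the
sequence passes through L pre-norm transformer encoder layers (multi-head
self-attention with D/h-dimensional heads, then a two-layer ReLU feed-forward
block, both with residual connections and layer normalization).  The final
class-token embedding is mapped through a small MLP head to a single logit,
and a sigmoid yields the probability that the study is abnormal.  Training
uses binary cross-entropy.

Token enumeration is t-major, then row, then column of the patch grid; each
patch is flattened in (t, row, column) order.  Positional-embedding semantics
depend on this order, so it is fixed here and relied on everywhere.

Both the forward pass and the exact reverse-mode gradients are implemented
explicitly on NumPy arrays; there is no autograd framework underneath.  The
gradient code is verified in the test suite against central finite
differences over random parameter directions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .io import FrameStack

__all__ = [
    "ModelConfig",
    "TokenGrid",
    "Prediction",
    "extract_patches",
    "unpatchify",
    "resize_isotropic",
    "init_params",
    "forward",
    "forward_backward",
    "predict_clip",
    "bce_loss",
    "bce_from_logit",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters.

    Defaults are the full-scale configuration: 25-frame x 16 x 16 tubelets,
    64-dimensional embeddings, 8 heads, 8 encoder layers, MLP head widths
    (128, 64), frames isotropically resized to 256 x 256 before patching.
    ``ffn_dim`` defaults to 4*D (standard transformer convention).
    ``head_type='linear'`` replaces the MLP head with a single linear logit.
    ``temporal_stride`` defaults to Tp (non-overlapping temporal windows).
    """

    tp: int = 25
    p: int = 16
    d: int = 64
    n_heads: int = 8
    n_layers: int = 8
    ffn_dim: Optional[int] = None
    head_dims: tuple[int, ...] = (128, 64)
    head_type: str = "mlp"
    input_hw: int = 256
    activation: str = "relu"
    temporal_stride: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.tp, self.p, self.d, self.n_heads, self.n_layers) < 1:
            raise ValueError("tp, p, d, n_heads, n_layers must all be >= 1")
        if self.d % self.n_heads != 0:
            raise ValueError(f"d={self.d} must be divisible by n_heads={self.n_heads}")
        if self.input_hw % self.p != 0:
            raise ValueError(f"input_hw={self.input_hw} must be divisible by p={self.p}")
        if self.head_type not in ("mlp", "linear"):
            raise ValueError("head_type must be 'mlp' or 'linear'")

    @property
    def ffn_width(self) -> int:
        return 4 * self.d if self.ffn_dim is None else self.ffn_dim

    @property
    def token_dim(self) -> int:
        return self.tp * self.p * self.p


@dataclass
class TokenGrid:
    """Flattened 3D-patch decomposition of one clip."""

    tokens: np.ndarray  # (N, Tp*P^2)
    grid_shape: tuple[int, int, int]  # (n_t, n_h, n_w)
    pad_frames: int  # zero frames appended at the end

    @property
    def n_tokens(self) -> int:
        return int(self.tokens.shape[0])


@dataclass(frozen=True)
class Prediction:
    y_hat: float
    logit: float


class CapacityError(ValueError):
    """Token sequence exceeds the positional-embedding table."""


# ---------------------------------------------------------------------------
# Tokenization


def extract_patches(video: np.ndarray, config: ModelConfig) -> TokenGrid:
    """Cut a (T, H, W) clip into flattened Tp x P x P tubelets.

    T is zero-padded *at the end* to the next multiple of Tp so no observed
    frame is discarded; the token count obeys N = T/Tp * H/P * W/P.
    """
    video = np.asarray(video)
    if video.ndim != 3:
        raise ValueError(f"expected (T,H,W) video, got shape {video.shape}")
    t, h, w = video.shape
    p, tp = config.p, config.tp
    if h % p or w % p:
        raise ValueError(f"frame size {h}x{w} not divisible by patch size {p}")
    pad = (-t) % tp
    if pad:
        video = np.concatenate([video, np.zeros((pad, h, w), video.dtype)], axis=0)
    n_t, n_h, n_w = (t + pad) // tp, h // p, w // p
    tokens = (
        video.reshape(n_t, tp, n_h, p, n_w, p)
        .transpose(0, 2, 4, 1, 3, 5)  # (n_t, n_h, n_w, tp, p, p)
        .reshape(n_t * n_h * n_w, tp * p * p)
    )
    return TokenGrid(tokens=np.ascontiguousarray(tokens), grid_shape=(n_t, n_h, n_w), pad_frames=pad)


def unpatchify(grid: TokenGrid, config: ModelConfig) -> np.ndarray:
    """Inverse of :func:`extract_patches`, including the zero padding."""
    n_t, n_h, n_w = grid.grid_shape
    p, tp = config.p, config.tp
    return (
        grid.tokens.reshape(n_t, n_h, n_w, tp, p, p)
        .transpose(0, 3, 1, 4, 2, 5)
        .reshape(n_t * tp, n_h * p, n_w * p)
    )


def resize_isotropic(stack: FrameStack, input_hw: int) -> FrameStack:
    """Bilinearly resize every frame to ``input_hw`` squared, clipped to [0,1]."""
    from skimage.transform import resize

    t, h, w = stack.frames.shape
    if (h, w) == (input_hw, input_hw):
        return stack
    out = resize(
        np.asarray(stack.frames, dtype=np.float64),
        (t, input_hw, input_hw),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    return stack.with_frames(np.clip(out, 0.0, 1.0).astype(np.float32))


# ---------------------------------------------------------------------------
# Parameters


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped at two standard deviations."""
    return np.clip(rng.normal(0.0, std, size=shape), -2 * std, 2 * std)


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    """Glorot-scale truncated normal for projection matrices.

    At the small widths used here a fixed tiny std starves the class token of
    patch signal; Glorot scaling keeps activations and gradients at unit
    order regardless of D.
    """
    fan_in = shape[0]
    fan_out = shape[1] if len(shape) > 1 else 1
    return _trunc_normal(rng, shape, std=float(np.sqrt(2.0 / (fan_in + fan_out))))


def init_params(
    config: ModelConfig, max_tokens: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Initialize all learnable tensors.

    ``max_tokens`` sizes the positional table for the longest training clip
    (N patch tokens + 1 class slot); longer inference clips raise
    :class:`CapacityError` rather than silently truncating.
    """
    d, f = config.d, config.ffn_width
    params: dict[str, np.ndarray] = {
        "embed.E": _glorot(rng, (config.token_dim, d)),
        "cls": np.zeros(d),
        "pos": _trunc_normal(rng, (max_tokens + 1, d)),
    }
    for i in range(config.n_layers):
        pre = f"enc.{i}."
        params[pre + "ln1.g"] = np.ones(d)
        params[pre + "ln1.b"] = np.zeros(d)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            params[pre + "attn." + name] = _glorot(rng, (d, d))
        params[pre + "ln2.g"] = np.ones(d)
        params[pre + "ln2.b"] = np.zeros(d)
        params[pre + "ffn.W1"] = _glorot(rng, (d, f))
        params[pre + "ffn.b1"] = np.zeros(f)
        params[pre + "ffn.W2"] = _glorot(rng, (f, d))
        params[pre + "ffn.b2"] = np.zeros(d)
    params["final_ln.g"] = np.ones(d)
    params["final_ln.b"] = np.zeros(d)
    if config.head_type == "mlp":
        widths = (d,) + tuple(config.head_dims)
        for j in range(len(config.head_dims)):
            params[f"head.{j}.W"] = _glorot(rng, (widths[j], widths[j + 1]))
            params[f"head.{j}.b"] = np.zeros(widths[j + 1])
        params["head.out.w"] = _glorot(rng, (widths[-1],))
    else:
        params["head.out.w"] = _glorot(rng, (d,))
    params["head.out.b"] = np.zeros(())
    return params


def count_parameters(config: ModelConfig, max_tokens: int) -> int:
    """Closed-form count of trainable scalars; matches init_params exactly."""
    d, f = config.d, config.ffn_width
    n = config.token_dim * d  # embedding E
    n += d  # class token
    n += (max_tokens + 1) * d  # positional table
    per_layer = 2 * d + 4 * d * d + 2 * d + d * f + f + f * d + d
    n += config.n_layers * per_layer
    n += 2 * d  # final layer norm
    if config.head_type == "mlp":
        widths = (d,) + tuple(config.head_dims)
        for j in range(len(config.head_dims)):
            n += widths[j] * widths[j + 1] + widths[j + 1]
        n += widths[-1] + 1
    else:
        n += d + 1
    return n


# ---------------------------------------------------------------------------
# Primitive layers (forward + exact backward)

_LN_EPS = 1e-5


def _ln_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(0)
    db = dy.sum(0)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _mhsa_fwd(zn, wq, wk, wv, wo, n_heads):
    s, d = zn.shape
    dh = d // n_heads
    q = zn @ wq
    k = zn @ wk
    v = zn @ wv
    qh = q.reshape(s, n_heads, dh).transpose(1, 0, 2)
    kh = k.reshape(s, n_heads, dh).transpose(1, 0, 2)
    vh = v.reshape(s, n_heads, dh).transpose(1, 0, 2)
    scores = qh @ kh.transpose(0, 2, 1) / np.sqrt(dh)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite attention logits")
    scores = scores - scores.max(-1, keepdims=True)
    e = np.exp(scores)
    attn = e / e.sum(-1, keepdims=True)  # (h, S, S), rows sum to 1
    oh = attn @ vh
    o = oh.transpose(1, 0, 2).reshape(s, d)
    out = o @ wo
    cache = (zn, qh, kh, vh, attn, o, wq, wk, wv, wo, n_heads)
    return out, attn, cache


def _mhsa_bwd(dout, cache, attn_grad_sink=None):
    zn, qh, kh, vh, attn, o, wq, wk, wv, wo, n_heads = cache
    s, d = zn.shape
    dh = d // n_heads
    do = dout @ wo.T
    dwo = o.T @ dout
    doh = do.reshape(s, n_heads, dh).transpose(1, 0, 2)
    dattn = doh @ vh.transpose(0, 2, 1)
    if attn_grad_sink is not None:
        attn_grad_sink.append(dattn.copy())
    dvh = attn.transpose(0, 2, 1) @ doh
    dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
    dscores /= np.sqrt(dh)
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 2, 1) @ qh
    dq = dqh.transpose(1, 0, 2).reshape(s, d)
    dk = dkh.transpose(1, 0, 2).reshape(s, d)
    dv = dvh.transpose(1, 0, 2).reshape(s, d)
    dzn = dq @ wq.T + dk @ wk.T + dv @ wv.T
    return dzn, zn.T @ dq, zn.T @ dk, zn.T @ dv, dwo


def _ffn_fwd(zn, w1, b1, w2, b2):
    a = zn @ w1 + b1
    r = np.maximum(a, 0.0)
    out = r @ w2 + b2
    return out, (zn, a, r, w1, w2)


def _ffn_bwd(dout, cache):
    zn, a, r, w1, w2 = cache
    dw2 = r.T @ dout
    db2 = dout.sum(0)
    dr = dout @ w2.T
    da = dr * (a > 0)
    dw1 = zn.T @ da
    db1 = da.sum(0)
    dzn = da @ w1.T
    return dzn, dw1, db1, dw2, db2


# ---------------------------------------------------------------------------
# Model forward / backward


def embed_and_assemble(
    tokens: np.ndarray, params: dict[str, np.ndarray]
) -> np.ndarray:
    """Project patches, prepend the class token, add positional embeddings."""
    n = tokens.shape[0]
    capacity = params["pos"].shape[0]
    if n + 1 > capacity:
        raise CapacityError(
            f"sequence of N={n} patch tokens exceeds positional capacity "
            f"{capacity - 1}; retrain with a larger table or shorten the clip"
        )
    z = np.vstack([params["cls"][None, :], tokens @ params["embed.E"]])
    return z + params["pos"][: n + 1]


def forward(
    params: dict[str, np.ndarray],
    tokens: np.ndarray,
    config: ModelConfig,
    *,
    collect_attention: bool = False,
    need_cache: bool = False,
):
    """Full forward pass on one token sequence.

    Returns ``(prediction, attentions, caches)``; ``attentions`` is a list of
    (h, N+1, N+1) row-stochastic arrays (one per layer) when requested.
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    z = embed_and_assemble(tokens, params)
    attentions = [] if collect_attention else None
    caches: dict = {"tokens": tokens, "layers": []} if need_cache else None
    for i in range(config.n_layers):
        pre = f"enc.{i}."
        zn1, c_ln1 = _ln_fwd(z, params[pre + "ln1.g"], params[pre + "ln1.b"])
        att_out, attn, c_att = _mhsa_fwd(
            zn1,
            params[pre + "attn.Wq"],
            params[pre + "attn.Wk"],
            params[pre + "attn.Wv"],
            params[pre + "attn.Wo"],
            config.n_heads,
        )
        z1 = z + att_out
        zn2, c_ln2 = _ln_fwd(z1, params[pre + "ln2.g"], params[pre + "ln2.b"])
        ffn_out, c_ffn = _ffn_fwd(
            zn2,
            params[pre + "ffn.W1"],
            params[pre + "ffn.b1"],
            params[pre + "ffn.W2"],
            params[pre + "ffn.b2"],
        )
        z = z1 + ffn_out
        if collect_attention:
            attentions.append(attn)
        if need_cache:
            caches["layers"].append((c_ln1, c_att, c_ln2, c_ffn))
    zf, c_lnf = _ln_fwd(z, params["final_ln.g"], params["final_ln.b"])
    cls_vec = zf[0]

    head_cache = []
    x = cls_vec
    if config.head_type == "mlp":
        for j in range(len(config.head_dims)):
            a = x @ params[f"head.{j}.W"] + params[f"head.{j}.b"]
            r = np.maximum(a, 0.0)
            head_cache.append((x, a))
            x = r
    logit = float(x @ params["head.out.w"] + params["head.out.b"])
    y_hat = float(expit(logit))
    if need_cache:
        caches["final"] = (c_lnf, zf.shape, head_cache, x)
    return Prediction(y_hat=y_hat, logit=logit), attentions, caches


def forward_backward(
    params: dict[str, np.ndarray],
    tokens: np.ndarray,
    y: float,
    config: ModelConfig,
    collect_attention_grads: bool = False,
):
    """BCE loss, prediction and exact gradients for one labeled sequence.

    With ``collect_attention_grads`` the per-layer attention matrices and the
    loss gradients with respect to them are returned as well (used by the
    gradient-weighted saliency variant); layer order is first-to-last.
    """
    collect = collect_attention_grads
    pred, attns, caches = forward(
        params, tokens, config, need_cache=True, collect_attention=collect
    )
    loss = bce_from_logit(pred.logit, y)
    dlogit = pred.y_hat - y  # d(BCE)/d(logit), the stable closed form

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    attn_grad_sink: list | None = [] if collect else None
    c_lnf, zf_shape, head_cache, last_hidden = caches["final"]

    grads["head.out.w"] += dlogit * last_hidden
    grads["head.out.b"] += np.asarray(dlogit)
    dx = dlogit * params["head.out.w"]
    if config.head_type == "mlp":
        for j in reversed(range(len(config.head_dims))):
            x_in, a = head_cache[j]
            da = dx * (a > 0)
            grads[f"head.{j}.W"] += np.outer(x_in, da)
            grads[f"head.{j}.b"] += da
            dx = params[f"head.{j}.W"] @ da
    dzf = np.zeros(zf_shape)
    dzf[0] = dx
    dz, dg, db = _ln_bwd(dzf, c_lnf)
    grads["final_ln.g"] += dg
    grads["final_ln.b"] += db

    for i in reversed(range(config.n_layers)):
        pre = f"enc.{i}."
        c_ln1, c_att, c_ln2, c_ffn = caches["layers"][i]
        dzn2, dw1, db1, dw2, db2 = _ffn_bwd(dz, c_ffn)
        grads[pre + "ffn.W1"] += dw1
        grads[pre + "ffn.b1"] += db1
        grads[pre + "ffn.W2"] += dw2
        grads[pre + "ffn.b2"] += db2
        dz1_from_ln, dg2, db2_ln = _ln_bwd(dzn2, c_ln2)
        grads[pre + "ln2.g"] += dg2
        grads[pre + "ln2.b"] += db2_ln
        dz1 = dz + dz1_from_ln
        dzn1, dwq, dwk, dwv, dwo = _mhsa_bwd(dz1, c_att, attn_grad_sink)
        grads[pre + "attn.Wq"] += dwq
        grads[pre + "attn.Wk"] += dwk
        grads[pre + "attn.Wv"] += dwv
        grads[pre + "attn.Wo"] += dwo
        dz_from_ln, dg1, db1_ln = _ln_bwd(dzn1, c_ln1)
        grads[pre + "ln1.g"] += dg1
        grads[pre + "ln1.b"] += db1_ln
        dz = dz1 + dz_from_ln

    s = dz.shape[0]
    grads["pos"][:s] += dz
    grads["cls"] += dz[0]
    grads["embed.E"] += caches["tokens"].T @ dz[1:]
    if collect:
        return loss, pred, grads, attns, attn_grad_sink[::-1]
    return loss, pred, grads


# ---------------------------------------------------------------------------
# Losses


def bce_from_logit(logit: float, y: float) -> float:
    """Binary cross-entropy in the numerically stable logit form."""
    z = float(logit)
    return float(max(z, 0.0) - z * y + np.log1p(np.exp(-abs(z))))


def bce_loss(y_hat: float, y: float, eps: float = 1e-12) -> float:
    """-[y log(p) + (1-y) log(1-p)] with epsilon clipping against log(0)."""
    p = np.clip(y_hat, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# Inference helpers and checkpointing


def predict_clip(
    params: dict[str, np.ndarray], config: ModelConfig, stack: FrameStack
) -> Prediction:
    """Resize if needed, tokenize and score one preprocessed clip."""
    stack = resize_isotropic(stack, config.input_hw)
    grid = extract_patches(np.asarray(stack.frames, dtype=np.float64), config)
    pred, _, _ = forward(params, grid.tokens, config)
    return pred


CHECKPOINT_SCHEMA = 1


def save_checkpoint(path: str, params: dict[str, np.ndarray], config: ModelConfig, extra: Optional[dict] = None) -> None:
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": dataclasses.asdict(config),
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **params)


def load_checkpoint(path: str):
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        params = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = meta["config"]
    for key in ("head_dims",):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    config = ModelConfig(**cfg)
    return params, config, meta.get("extra", {})
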