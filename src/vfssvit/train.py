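"""Subject-level splitting, cross-validation, training loop and metrics.

All partitioning is done at the *subject* level: every clip of a patient falls
into exactly one of train/validation/test (and, within cross-validation, one
fold), so no patient identity leaks between partitions.  Training runs Adam
on per-clip binary cross-entropy with gradient accumulation (variable-length
clips make cross-clip batching awkward under learned positional embeddings),
applies the augmentation policy to training clips only, and keeps the
parameter state at the epoch of minimum validation loss, stopping early after
a patience of non-improving epochs.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats

from .io import FrameStack
from .model import (
    ModelConfig,
    bce_from_logit,
    extract_patches,
    forward,
    forward_backward,
    init_params,
)

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "AugmentConfig",
    "MetricsReport",
    "TrainResult",
    "split_subjects",
    "make_folds",
    "sample_augment_params",
    "augment",
    "Adam",
    "train_model",
    "confusion_counts",
    "metrics_from_counts",
    "roc_points",
    "evaluate",
    "paired_t_test",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class SplitPlan:
    """Clip-level partition labels plus CV fold indices, all subject-pure."""

    assignment: Dict[str, str]  # clip_id -> {train, val, test}
    folds: Dict[str, int]  # clip_id -> 1..k (train+val clips only)
    subject_map: Dict[str, str]  # clip_id -> subject_id

    def clip_ids(self, partition: str) -> List[str]:
        return [c for c, p in self.assignment.items() if p == partition]

    def subjects(self, partition: str) -> set:
        return {self.subject_map[c] for c in self.clip_ids(partition)}

    def check_leakage(self) -> None:
        """Assert that no subject spans partitions or folds."""
        parts = {}
        for cid, part in self.assignment.items():
            sid = self.subject_map[cid]
            if parts.setdefault(sid, part) != part:
                raise AssertionError(f"subject {sid} spans partitions")
        fold_of = {}
        for cid, f in self.folds.items():
            sid = self.subject_map[cid]
            if fold_of.setdefault(sid, f) != f:
                raise AssertionError(f"subject {sid} spans folds")


def _subject_clip_counts(manifest: pd.DataFrame) -> pd.Series:
    return manifest.groupby("subject_id")["clip_id"].count()


def split_subjects(
    manifest: pd.DataFrame,
    test_frac: float = 0.10,
    val_frac: float = 0.20,
    seed: int = 0,
) -> SplitPlan:
    """Greedy subject-level train/val/test assignment.

    ``test_frac`` of clips is reserved for testing and the remainder is split
    into train and validation at (1 - val_frac) : val_frac, approximated at
    subject granularity.  Deterministic under ``seed``; the leakage invariant
    holds exactly by construction.
    """
    if manifest["subject_id"].isna().any():
        raise ValueError("every clip needs a subject_id")
    counts = _subject_clip_counts(manifest)
    if len(counts) < 3:
        raise ValueError(
            f"need at least 3 subjects to fill train/val/test, got {len(counts)}"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(np.array(sorted(counts.index))))
    total = int(counts.sum())
    target_test = test_frac * total

    test_subj, test_clips = [], 0
    i = 0
    while test_clips < target_test and len(order) - i > 2:
        s = order[i]
        test_subj.append(s)
        test_clips += int(counts[s])
        i += 1
    remaining = order[i:]
    target_val = val_frac * (total - test_clips)
    val_subj, val_clips = [], 0
    j = 0
    while val_clips < target_val and len(remaining) - j > 1:
        s = remaining[j]
        val_subj.append(s)
        val_clips += int(counts[s])
        j += 1
    train_subj = remaining[j:]

    part_of = {s: "test" for s in test_subj}
    part_of.update({s: "val" for s in val_subj})
    part_of.update({s: "train" for s in train_subj})
    assignment = {
        str(row.clip_id): part_of[row.subject_id] for row in manifest.itertuples()
    }
    subject_map = {str(row.clip_id): str(row.subject_id) for row in manifest.itertuples()}
    return SplitPlan(assignment=assignment, folds={}, subject_map=subject_map)


def make_folds(plan: SplitPlan, k: int = 5, seed: int = 0) -> SplitPlan:
    """Partition train+val subjects into k folds of near-equal clip counts."""
    cv_clips = [c for c, p in plan.assignment.items() if p in ("train", "val")]
    subj_clips: Dict[str, List[str]] = {}
    for c in cv_clips:
        subj_clips.setdefault(plan.subject_map[c], []).append(c)
    if len(subj_clips) < k:
        raise ValueError(f"need at least {k} subjects for {k}-fold CV, got {len(subj_clips)}")
    rng = np.random.default_rng(seed)
    subjects = sorted(subj_clips)
    rng.shuffle(subjects)
    # Largest-first greedy balancing of clip counts across folds.
    subjects.sort(key=lambda s: -len(subj_clips[s]))
    fold_sizes = np.zeros(k, dtype=int)
    folds: Dict[str, int] = {}
    for s in subjects:
        f = int(np.argmin(fold_sizes))
        fold_sizes[f] += len(subj_clips[s])
        for c in subj_clips[s]:
            folds[c] = f + 1
    out = SplitPlan(assignment=dict(plan.assignment), folds=folds, subject_map=dict(plan.subject_map))
    out.check_leakage()
    return out


# ---------------------------------------------------------------------------
# Augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Training-set augmentation: small rotations (degrees, within +/-rot_deg),
    zoom-in up to ``zoom_max`` (0.10 = +10%), additive Gaussian noise.  Each
    transform fires independently with probability ``p_apply``."""

    rot_deg: float = 5.0
    zoom_max: float = 0.10
    noise_sigma: float = 0.01
    p_apply: float = 0.5


def sample_augment_params(aug: AugmentConfig, rng: np.random.Generator):
    """Draw one clip's (angle_deg, zoom_factor, add_noise) triple."""
    angle = 0.0
    if aug.rot_deg > 0 and rng.random() < aug.p_apply:
        angle = float(rng.uniform(-aug.rot_deg, aug.rot_deg))
    zoom = 1.0
    if aug.zoom_max > 0 and rng.random() < aug.p_apply:
        zoom = float(rng.uniform(1.0, 1.0 + aug.zoom_max))
    add_noise = aug.noise_sigma > 0 and rng.random() < aug.p_apply
    return angle, zoom, add_noise


def _zoom_frames(frames: np.ndarray, zoom: float) -> np.ndarray:
    """Zoom in about the frame center by ``zoom`` >= 1, keeping the shape."""
    t, h, w = frames.shape
    matrix = np.diag([1.0, 1.0 / zoom, 1.0 / zoom])
    center = np.array([0.0, (h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ center
    return ndi.affine_transform(frames, matrix, offset=offset, order=1, mode="constant")


def augment(clip: np.ndarray, aug: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply one sampled rotation/zoom to every frame identically, add noise.

    An all-zero configuration returns the input exactly.  Output is clipped
    to [0, 1] and keeps the input shape.
    """
    frames = np.asarray(clip, dtype=np.float64)
    angle, zoom, add_noise = sample_augment_params(aug, rng)
    if angle != 0.0:
        frames = ndi.rotate(frames, angle, axes=(1, 2), reshape=False, order=1, mode="constant")
    if zoom != 1.0:
        frames = _zoom_frames(frames, zoom)
    if add_noise:
        frames = frames + rng.normal(0.0, aug.noise_sigma, size=frames.shape)
    if angle != 0.0 or zoom != 1.0 or add_noise:
        frames = np.clip(frames, 0.0, 1.0)
    return frames


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    """Plain Adam over a dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for k, g in grads.items():
            m = self.m.setdefault(k, np.zeros_like(g))
            v = self.v.setdefault(k, np.zeros_like(g))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 1
    grad_accum: int = 8
    patience: int = 10
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.patience > self.epochs:
            raise ValueError("patience must be <= epochs")


@dataclass
class TrainResult:
    params: Dict[str, np.ndarray]  # state at the epoch of minimum val loss
    config: ModelConfig
    history: pd.DataFrame  # per-epoch train/val loss and accuracy
    best_epoch: int  # 1-based
    stopped_epoch: int
    best_val_loss: float


def _clip_loss_acc(params, config, tokens, y):
    pred, _, _ = forward(params, tokens, config)
    loss = bce_from_logit(pred.logit, y)
    correct = (pred.y_hat >= 0.5) == (y >= 0.5)
    return loss, correct


def train_model(
    clips: Dict[str, np.ndarray],
    labels: Dict[str, int],
    plan: SplitPlan,
    model_config: ModelConfig,
    train_config: TrainConfig,
    fold: Optional[int] = None,
    val_loss_override: Optional[Sequence[float]] = None,
) -> TrainResult:
    """Train one model on a plan (or one CV fold) with early stopping.

    ``clips`` maps clip_id to preprocessed (T, H, W) pixel arrays in [0, 1].
    With ``fold=None`` the train/val partitions of ``plan`` are used; with
    ``fold=f`` the validation set is fold f and training is every other fold.
    ``val_loss_override`` substitutes an injected per-epoch validation-loss
    trace (the checkpoint-selection rule can then be exercised in isolation).
    Returns the parameter state at the epoch of *minimum* validation loss,
    never the final state.
    """
    if fold is None:
        train_ids = plan.clip_ids("train")
        val_ids = plan.clip_ids("val")
    else:
        cv = [c for c, p in plan.assignment.items() if p in ("train", "val")]
        train_ids = [c for c in cv if plan.folds.get(c) != fold]
        val_ids = [c for c in cv if plan.folds.get(c) == fold]
    if not train_ids:
        raise ValueError("empty training fold")

    rng = np.random.default_rng(train_config.seed)
    all_ids = train_ids + val_ids
    max_tokens = 0
    val_tokens = {}
    for cid in all_ids:
        grid = extract_patches(np.asarray(clips[cid], dtype=np.float64), model_config)
        max_tokens = max(max_tokens, grid.n_tokens)
        if cid in val_ids:
            val_tokens[cid] = grid.tokens
    params = init_params(model_config, max_tokens, rng)
    opt = Adam(lr=train_config.lr)

    best_val = np.inf
    best_params = copy.deepcopy(params)
    best_epoch = 0
    bad_epochs = 0
    rows = []
    stopped = 0
    for epoch in range(1, train_config.epochs + 1):
        order = list(rng.permutation(len(train_ids)))
        tr_losses, tr_correct = [], []
        accum = None
        n_in_accum = 0
        for pos, idx in enumerate(order):
            cid = train_ids[idx]
            frames = augment(clips[cid], train_config.aug, rng)
            grid = extract_patches(frames, model_config)
            loss, pred, grads = forward_backward(
                params, grid.tokens, float(labels[cid]), model_config
            )
            tr_losses.append(loss)
            tr_correct.append((pred.y_hat >= 0.5) == (labels[cid] >= 0.5))
            if accum is None:
                accum = grads
            else:
                for k in accum:
                    accum[k] += grads[k]
            n_in_accum += 1
            if n_in_accum == train_config.grad_accum or pos == len(order) - 1:
                for k in accum:
                    accum[k] /= n_in_accum
                opt.step(params, accum)
                accum, n_in_accum = None, 0

        if val_loss_override is not None:
            val_loss = float(val_loss_override[epoch - 1])
            val_acc = np.nan
        elif val_ids:
            stats_ = [
                _clip_loss_acc(params, model_config, val_tokens[c], float(labels[c]))
                for c in val_ids
            ]
            val_loss = float(np.mean([s[0] for s in stats_]))
            val_acc = float(np.mean([s[1] for s in stats_]))
        else:
            val_loss = float(np.mean(tr_losses))
            val_acc = np.nan
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(tr_losses)),
                "train_acc": float(np.mean(tr_correct)),
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_params = copy.deepcopy(params)
            bad_epochs = 0
        else:
            bad_epochs += 1
        stopped = epoch
        if bad_epochs >= train_config.patience:
            break
    return TrainResult(
        params=best_params,
        config=model_config,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        stopped_epoch=stopped,
        best_val_loss=float(best_val),
    )


# ---------------------------------------------------------------------------
# Metrics


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: Optional[float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_thresholds: np.ndarray

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "auc": self.auc,
        }


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    return tp, fp, tn, fn


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    sens = _safe_div(tp, tp + fn)
    spec = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    return {
        "accuracy": _safe_div(tp + tn, tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": _safe_div(2 * prec * sens, prec + sens),
    }


def roc_points(y_true: np.ndarray, scores: np.ndarray):
    """ROC by full threshold sweep; AUC by the trapezoidal rule."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thr, auc


def evaluate(
    y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """All five diagnostic metrics at ``threshold`` plus the ROC sweep.

    On a single-class truth vector the AUC is undefined and reported as
    ``None`` with a warning rather than a misleading 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    preds = scores >= threshold
    tp, fp, tn, fn = confusion_counts(y_true, preds)
    m = metrics_from_counts(tp, fp, tn, fn)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class test set: AUC is undefined", stacklevel=2)
        auc, fpr, tpr, thr = None, np.array([]), np.array([]), np.array([])
    else:
        fpr, tpr, thr, auc = roc_points(y_true, scores)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn, auc=auc,
        roc_fpr=fpr, roc_tpr=tpr, roc_thresholds=thr, **m,
    )


def evaluate_model(
    result_params: Dict[str, np.ndarray],
    model_config: ModelConfig,
    clips: Dict[str, np.ndarray],
    labels: Dict[str, int],
    clip_ids: Sequence[str],
    threshold: float = 0.5,
) -> tuple[MetricsReport, pd.DataFrame]:
    """Score a set of clips and compute the metrics report."""
    rows = []
    for cid in clip_ids:
        grid = extract_patches(np.asarray(clips[cid], dtype=np.float64), model_config)
        pred, _, _ = forward(result_params, grid.tokens, model_config)
        rows.append({"clip_id": cid, "label": labels[cid], "y_hat": pred.y_hat})
    df = pd.DataFrame(rows)
    report = evaluate(df["label"].to_numpy(), df["y_hat"].to_numpy(), threshold)
    return report, df


# ---------------------------------------------------------------------------
# Statistics


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on per-fold metric values.

    Zero-variance differences are flagged: p -> 0 for a consistent nonzero
    difference, p = 1 when the vectors are identical.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd <= 1e-12 * max(1.0, abs(mean)):  # zero up to float rounding
        if mean == 0.0:
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=float(np.sign(mean)) * np.inf, p=0.0, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), degenerate=False)


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVReport:
    per_fold: pd.DataFrame  # one row per fold with the five metrics + AUC
    mean: dict
    sd: dict
    results: List[TrainResult]


def cross_validate(
    clips: Dict[str, np.ndarray],
    labels: Dict[str, int],
    plan: SplitPlan,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
) -> CVReport:
    """Train one model per fold and aggregate per-fold metrics (mean +/- SD).

    Each fold's model is freshly initialized with a fold-indexed seed, so the
    folds are independent runs; the held-out test partition of ``plan`` never
    enters CV.
    """
    if not plan.folds:
        plan = make_folds(plan, k=k, seed=train_config.seed)
    rows = []
    results = []
    for f in range(1, k + 1):
        cfg_f = dataclasses.replace(train_config, seed=train_config.seed + 1000 * f)
        try:
            res = train_model(clips, labels, plan, model_config, cfg_f, fold=f)
            val_ids = [c for c, ff in plan.folds.items() if ff == f]
            report, _ = evaluate_model(
                res.params, model_config, clips, labels, val_ids,
                threshold=train_config.decision_threshold,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"cross-validation fold {f} failed: {exc}") from exc
        rows.append({"fold": f, **report.to_dict()})
        results.append(res)
    per_fold = pd.DataFrame(rows)
    metric_cols = ["accuracy", "sensitivity", "specificity", "precision", "f1", "auc"]
    mean = {c: float(per_fold[c].mean()) for c in metric_cols}
    sd = {c: float(per_fold[c].std(ddof=1)) for c in metric_cols}
    return CVReport(per_fold=per_fold, mean=mean, sd=sd, results=results)
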