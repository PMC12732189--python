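"""Synthetic fluoroscopy-like swallow videos with a planted invasion signal.

Real VFSS corpora are private, so every stage of this package is exercised on
a phantom that reproduces the *structural* nuisances of fluoroscopy exports —
a circular detector field of view with dark corners, a bright patient-info
band at the top of the frame, a circular targeting artifact in the first few
frames, variable clip length, per-subject anatomical jitter shared by all of a
subject's clips, and additive Gaussian noise — together with the signal of
interest: a bright bolus blob traversing a pharyngeal path, and, in abnormal
clips, a fraction of bolus material diverted into an airway region from a
sampled onset frame onward.

The geometry is deliberately minimal: the pharyngeal path is a three-segment
polyline from the upper-center to the lower-center of the field of view, and
the airway region is a disk offset anteriorly from the path midpoint.  The
bolus blob has compact support (truncated Gaussian), so in normal clips the
airway region contains *exactly* zero signal before noise — which makes the
planted abnormality a clean, verifiable ground truth for classifier and
saliency tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .io import LABEL_ABNORMAL, LABEL_NORMAL, FrameStack

__all__ = [
    "SyntheticConfig",
    "Anatomy",
    "SyntheticStudy",
    "make_anatomy",
    "render_clip",
    "generate_study",
    "airway_mask",
    "oracle_scores",
    "write_study",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-generation parameters.

    Defaults describe a desk-scale study: 40 subjects x 5 clips of 64x64
    frames, 30-60 frames long, with roughly half the clips abnormal (the
    clinical corpus the phantom stands in for was close to balanced).
    ``invasion_intensity_fraction`` scales the planted airway signal relative
    to the bolus peak; ``noise_sigma`` is additive Gaussian noise in [0,1]
    grayscale units.
    """

    n_subjects: int = 40
    clips_per_subject: int = 5
    abnormal_fraction: float = 0.5
    frame_hw: tuple[int, int] = (64, 64)
    length_range: tuple[int, int] = (30, 60)
    bolus_intensity: float = 0.8
    invasion_intensity_fraction: float = 0.6
    artifact_radius_range: tuple[int, int] = (5, 9)
    noise_sigma: float = 0.05
    subject_jitter_scale: float = 2.0
    info_band_frac: float = 0.12
    fov_margin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must lie in [0,1]")
        if self.n_subjects < 0 or self.clips_per_subject < 0:
            raise ValueError("counts must be >= 0")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range min must be <= max")
        if min(self.frame_hw) <= 0:
            raise ValueError(f"non-positive frame dimensions: {self.frame_hw}")


@dataclass(frozen=True)
class Anatomy:
    """Per-subject phantom geometry, shared across all of a subject's clips."""

    path_points: np.ndarray  # (4, 2) row/col control points of the polyline
    airway_center: tuple[float, float]
    airway_radius: float
    fov_center: tuple[float, float]
    fov_radius: float
    bolus_sigma: float


@dataclass
class SyntheticStudy:
    """A generated study: clips plus per-clip ground truth."""

    clips: List[FrameStack]
    labels: np.ndarray  # (n,) int, 1 = abnormal
    subject_ids: List[str]
    invasion_masks: List[np.ndarray]  # (H,W) bool; all-False for normal clips
    anatomies: dict  # subject_id -> Anatomy
    config: SyntheticConfig

    def __post_init__(self) -> None:
        n = len(self.clips)
        if not (len(self.labels) == len(self.subject_ids) == len(self.invasion_masks) == n):
            raise ValueError("clips, labels, subject_ids, invasion_masks must align")


def make_anatomy(config: SyntheticConfig, rng: np.random.Generator) -> Anatomy:
    """Sample one subject's jittered phantom geometry."""
    h, w = config.frame_hw
    base = np.array(
        [[0.18 * h, 0.50 * w],
         [0.40 * h, 0.46 * w],
         [0.62 * h, 0.50 * w],
         [0.85 * h, 0.55 * w]]
    )
    pts = base + rng.normal(0.0, config.subject_jitter_scale, size=base.shape)
    mid = 0.5 * (pts[1] + pts[2])
    # Airway disk sits anterior (low-column side in a lateral view) of the
    # path midpoint, far enough that the truncated bolus never touches it.
    airway_center = (float(mid[0] + 0.10 * h), float(mid[1] - 0.26 * w))
    airway_radius = 0.09 * min(h, w)
    fov_center = (h / 2.0, w / 2.0)
    fov_radius = min(h, w) / 2.0 - config.fov_margin
    return Anatomy(
        path_points=pts,
        airway_center=airway_center,
        airway_radius=float(airway_radius),
        fov_center=fov_center,
        fov_radius=float(fov_radius),
        bolus_sigma=0.04 * min(h, w),
    )


def _polyline_point(points: np.ndarray, s: float) -> np.ndarray:
    """Point at arc-length fraction ``s`` in [0,1] along a polyline."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = seg_len.sum()
    target = np.clip(s, 0.0, 1.0) * total
    acc = 0.0
    for i, ln in enumerate(seg_len):
        if acc + ln >= target or i == len(seg_len) - 1:
            t = 0.0 if ln == 0 else (target - acc) / ln
            return points[i] + t * seg[i]
        acc += ln
    return points[-1]


def fov_mask_for(anatomy: Anatomy, frame_hw: tuple[int, int]) -> np.ndarray:
    h, w = frame_hw
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - anatomy.fov_center[0]) ** 2 + (cc - anatomy.fov_center[1]) ** 2
    return d2 <= anatomy.fov_radius**2


def airway_mask(anatomy: Anatomy, frame_hw: tuple[int, int]) -> np.ndarray:
    """Boolean disk of the phantom's airway region."""
    h, w = frame_hw
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - anatomy.airway_center[0]) ** 2 + (cc - anatomy.airway_center[1]) ** 2
    return d2 <= anatomy.airway_radius**2


def _truncated_blob(shape, center, sigma, amplitude, truncate=2.5):
    """Gaussian blob with compact support (exact zero beyond truncate*sigma)."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    blob = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    blob[d2 > (truncate * sigma) ** 2] = 0.0
    return blob


def render_clip(
    anatomy: Anatomy,
    label: int,
    length: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    with_noise: bool = True,
    subject_id: Optional[str] = None,
) -> FrameStack:
    """Render one clip of ``length`` frames for a given subject anatomy.

    Abnormal clips deposit ``invasion_intensity_fraction`` of the bolus peak
    into the airway disk from an onset frame sampled uniformly in the middle
    third of the clip (so the signature always falls inside an interior
    temporal patch).  All randomness flows through ``rng``; equal seeds give
    byte-identical stacks.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    h, w = config.frame_hw
    if h <= 0 or w <= 0:
        raise ValueError(f"non-positive frame dimensions: {config.frame_hw}")
    abnormal = label == LABEL_ABNORMAL
    if abnormal and not 0.0 < config.invasion_intensity_fraction <= 1.0:
        raise ValueError(
            "invasion_intensity_fraction must lie in (0,1] for abnormal clips"
        )

    # Draw all per-clip randomness up front, in a fixed order.
    n_art = int(rng.integers(3, 11))
    art_radius = float(rng.uniform(*config.artifact_radius_range))
    art_center = (
        anatomy.fov_center[0] + float(rng.uniform(-0.1, 0.1) * h),
        anatomy.fov_center[1] + float(rng.uniform(-0.1, 0.1) * w),
    )
    onset = int(rng.integers(length // 3, max(length // 3 + 1, 2 * length // 3)))

    band_rows = int(round(config.info_band_frac * h))
    fov = fov_mask_for(anatomy, (h, w))
    rr, cc = np.mgrid[0:h, 0:w]
    ring = np.abs(np.hypot(rr - art_center[0], cc - art_center[1]) - art_radius) <= 1.0
    # by construction nothing but the invasion ever enters the airway region
    ring &= ~airway_mask(anatomy, (h, w))

    inv_amp = config.invasion_intensity_fraction * config.bolus_intensity
    inv_sigma = anatomy.airway_radius / 1.8
    invasion = _truncated_blob(
        (h, w), anatomy.airway_center, inv_sigma, inv_amp, truncate=np.inf
    )
    invasion[~airway_mask(anatomy, (h, w))] = 0.0  # confined to the airway disk

    frames = np.zeros((length, h, w), dtype=np.float64)
    for t in range(length):
        frame = frames[t]
        if t < n_art:
            frame[ring] = np.maximum(frame[ring], 0.85)
        s = 0.5 if length == 1 else t / (length - 1)
        pos = _polyline_point(anatomy.path_points, s)
        frame += _truncated_blob((h, w), pos, anatomy.bolus_sigma, config.bolus_intensity)
        if abnormal and t >= onset:
            frame += invasion
    if with_noise and config.noise_sigma > 0:
        frames = frames + rng.normal(0.0, config.noise_sigma, size=frames.shape)
    frames = np.clip(frames, 0.0, 1.0)
    frames[:, ~fov] = 0.0  # circular detector window: corners stay dark
    if band_rows:
        # Patient-info band is a burned-in overlay on the export, drawn on
        # top of the detector image across the full frame width.
        frames[:, :band_rows, :] = 0.9
    return FrameStack(
        frames=frames.astype(np.float32),
        fps=25.0,
        subject_id=subject_id,
        label=int(label),
        source_path="synthetic",
    )


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full study: per-subject anatomy, labels, clips, ground truth.

    Each subject's anatomy is jittered once and reused across all of that
    subject's clips; the abnormal share matches ``abnormal_fraction`` to the
    nearest clip.  Fixed ``config.seed`` reproduces the study exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects * config.clips_per_subject
    n_abn = int(round(config.abnormal_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_abn] = LABEL_ABNORMAL
    labels = labels[rng.permutation(n)]

    clips: List[FrameStack] = []
    subject_ids: List[str] = []
    masks: List[np.ndarray] = []
    anatomies: dict = {}
    idx = 0
    for s in range(config.n_subjects):
        sid = f"S{s:03d}"
        anatomy = make_anatomy(config, rng)
        anatomies[sid] = anatomy
        for _ in range(config.clips_per_subject):
            length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            label = int(labels[idx])
            clip = render_clip(anatomy, label, length, config, rng, subject_id=sid)
            clips.append(clip)
            subject_ids.append(sid)
            if label == LABEL_ABNORMAL:
                masks.append(airway_mask(anatomy, config.frame_hw))
            else:
                masks.append(np.zeros(config.frame_hw, dtype=bool))
            idx += 1
    return SyntheticStudy(
        clips=clips,
        labels=labels,
        subject_ids=subject_ids,
        invasion_masks=masks,
        anatomies=anatomies,
        config=config,
    )


def oracle_scores(study: SyntheticStudy) -> np.ndarray:
    """Mean intensity inside each clip's (anatomy-derived) airway disk.

    This pixel-sum oracle knows the planted geometry, so it upper-bounds what
    any learned classifier can achieve on the phantom; it separates noise-free
    clips perfectly and is used in tests to certify the signal is learnable.
    """
    scores = np.empty(len(study.clips))
    for i, clip in enumerate(study.clips):
        mask = airway_mask(study.anatomies[study.subject_ids[i]], clip.frame_shape)
        scores[i] = float(clip.frames[:, mask].mean())
    return scores


def write_study(study: SyntheticStudy, out_dir: str) -> pd.DataFrame:
    """Write clips as multi-page TIFF, labels as CSV, invasion masks as PNG."""
    import imageio.v3 as iio

    from .io import write_manifest, write_stack

    clip_dir = os.path.join(out_dir, "clips")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(clip_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    rows = []
    for i, clip in enumerate(study.clips):
        cid = f"clip{i:04d}"
        path = os.path.join(clip_dir, f"{cid}.tiff")
        write_stack(clip, path)
        if study.invasion_masks[i].any():
            iio.imwrite(
                os.path.join(mask_dir, f"{cid}_invasion.png"),
                (study.invasion_masks[i] * 255).astype(np.uint8),
            )
        rows.append(
            {
                "clip_id": cid,
                "subject_id": study.subject_ids[i],
                "label": int(study.labels[i]),
                "path": path,
                "n_frames": clip.n_frames,
            }
        )
    df = pd.DataFrame(rows)
    write_manifest(df[["clip_id", "subject_id", "label", "path"]], os.path.join(out_dir, "manifest.csv"))
    df.to_csv(os.path.join(out_dir, "labels.csv"), index=False)
    return df
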