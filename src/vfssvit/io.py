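"""Reading, writing and screening of VFSS frame stacks.

A videofluoroscopic swallowing study (VFSS) clip is a variable-length stack of
grayscale fluoroscopy frames recorded while a patient swallows a radio-opaque
bolus.  This module provides the :class:`FrameStack` container used throughout
the package, readers/writers for the common container formats (multi-page
TIFF, NPZ, AVI/MP4 and, optionally, DICOM multiframe), and the study-eligibility
screen: clips that are too short to contain a complete swallow (fewer than 25
frames at 25 fps), too small spatially, or unlabeled are excluded before any
training or evaluation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_NORMAL",
    "LABEL_ABNORMAL",
    "FrameStack",
    "EligibilityRules",
    "EligibilityDecision",
    "read_stack",
    "write_stack",
    "reduce_channels",
    "check_eligibility",
    "read_manifest",
    "write_manifest",
]

LABEL_NORMAL = 0
LABEL_ABNORMAL = 1

_LABEL_NAMES = {LABEL_NORMAL: "normal", LABEL_ABNORMAL: "abnormal", None: "unlabeled"}
_NAME_LABELS = {"normal": LABEL_NORMAL, "abnormal": LABEL_ABNORMAL,
                "0": LABEL_NORMAL, "1": LABEL_ABNORMAL, "unlabeled": None, "": None}


class EmptyStackError(ValueError):
    """Raised when a container holds zero frames."""


@dataclass
class FrameStack:
    """One VFSS clip: a ``(T, H, W)`` (or ``(T, H, W, C)`` pre channel
    reduction) array of intensities plus acquisition metadata.

    Intensities are kept as floating point; after preprocessing they lie in
    ``[0, 1]``.  ``label`` is ``1`` for abnormal (airway invasion), ``0`` for
    normal, ``None`` for unlabeled.
    """

    frames: np.ndarray
    fps: float = 25.0
    subject_id: Optional[str] = None
    label: Optional[int] = None
    source_path: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError(
                f"frames must be (T,H,W) or (T,H,W,C); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise EmptyStackError("frame stack holds zero frames")
        if min(self.frames.shape[1], self.frames.shape[2]) < 1:
            raise ValueError(f"non-positive frame dimensions: {self.frames.shape}")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def label_name(self) -> str:
        return _LABEL_NAMES.get(self.label, "unlabeled")

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        """Copy of this stack with new pixel data and identical metadata."""
        return replace(self, frames=frames)


@dataclass(frozen=True)
class EligibilityRules:
    """Screening rules applied before a clip enters the study.

    ``min_frames=25`` reflects that a typical swallow spans roughly one second
    at 25 fps; shorter clips are unlikely to contain a complete swallow.
    ``min_dim`` guards against narrow/cropped acquisitions and is configurable
    because the threshold is site dependent.
    """

    min_frames: int = 25
    min_dim: int = 128
    require_label: bool = True

    def __post_init__(self) -> None:
        if self.min_frames < 1:
            raise ValueError("min_frames must be >= 1")


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    reason: Optional[str] = None  # name of the failed rule when excluded


def check_eligibility(stack: FrameStack, rules: EligibilityRules) -> EligibilityDecision:
    """Decide whether a clip enters the study; a decision, never an exception."""
    if stack.n_frames < rules.min_frames:
        return EligibilityDecision(False, "min_frames")
    if min(stack.frame_shape) < rules.min_dim:
        return EligibilityDecision(False, "min_dim")
    if rules.require_label and stack.label is None:
        return EligibilityDecision(False, "no_label")
    return EligibilityDecision(True, None)


def reduce_channels(stack: FrameStack) -> FrameStack:
    """Keep only the first (brightness) channel of a pseudo-RGB clip.

    Fluoroscopy exports are often RGB with the second and third channels
    duplicating the first; only channel 0 is retained.  Single-channel input
    is returned unchanged.
    """
    f = stack.frames
    if f.ndim == 3:
        return stack
    n_ch = f.shape[-1]
    if n_ch == 1:
        return stack.with_frames(f[..., 0])
    if n_ch == 3:
        return stack.with_frames(f[..., 0])
    raise ValueError(f"expected 1 or 3 channels, got {n_ch}")


# ---------------------------------------------------------------------------
# Container I/O


def _infer_format(path: str, format_hint: Optional[str]) -> str:
    if format_hint:
        return format_hint.lower()
    ext = os.path.splitext(path)[1].lower()
    return {
        ".tif": "tiff", ".tiff": "tiff",
        ".npz": "npz", ".npy": "npy",
        ".avi": "video", ".mp4": "video", ".mov": "video",
        ".dcm": "dicom", ".dicom": "dicom",
    }.get(ext, "tiff")


def read_stack(path: str, format_hint: Optional[str] = None, **meta) -> FrameStack:
    """Read a clip from TIFF / NPZ / NPY / AVI / MP4 / DICOM multiframe.

    Multi-channel sources are passed through untouched so that
    :func:`reduce_channels` can apply the channel rule explicitly.
    """
    fmt = _infer_format(path, format_hint)
    if not os.path.exists(path):
        raise IOError(f"cannot read {fmt} stack: no such file: {path}")
    try:
        if fmt == "tiff":
            import tifffile

            frames = tifffile.imread(path)
        elif fmt == "npz":
            with np.load(path) as z:
                key = "frames" if "frames" in z.files else z.files[0]
                frames = z[key]
        elif fmt == "npy":
            frames = np.load(path)
        elif fmt == "video":
            frames = _read_video(path)
        elif fmt == "dicom":
            frames = _read_dicom(path)
        else:
            raise IOError(f"unknown format {fmt!r} for {path}")
    except (EmptyStackError, ImportError):
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with path+format context
        raise IOError(f"failed to read {fmt} stack from {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:  # single frame container
        frames = frames[None]
    if frames.size == 0 or frames.shape[0] == 0:
        raise EmptyStackError(f"{fmt} container at {path} holds zero frames")
    return FrameStack(frames=frames, source_path=path, **meta)


def _read_video(path: str) -> np.ndarray:
    try:
        import imageio.v3 as iio

        return np.asarray(iio.imread(path, plugin="pyav"))
    except Exception:
        import imageio

        reader = imageio.get_reader(path)
        frames = [np.asarray(fr) for fr in reader]
        reader.close()
        if not frames:
            raise EmptyStackError(f"video at {path} holds zero frames")
        return np.stack(frames)


def _read_dicom(path: str) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:
        raise ImportError(
            "DICOM support requires the optional pydicom dependency "
            "(install vfssvit[dicom])"
        ) from exc
    ds = pydicom.dcmread(path)
    return np.asarray(ds.pixel_array)


def write_stack(stack: FrameStack, path: str, format_hint: Optional[str] = None) -> None:
    """Write a clip losslessly (TIFF or NPZ); creates parent directories."""
    fmt = _infer_format(path, format_hint)
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, np.asarray(stack.frames))
    elif fmt == "npz":
        np.savez_compressed(path, frames=np.asarray(stack.frames))
    elif fmt == "npy":
        np.save(path, np.asarray(stack.frames))
    else:
        raise IOError(f"refusing to write lossy/unknown format {fmt!r}: {path}")


# ---------------------------------------------------------------------------
# Manifests

MANIFEST_COLUMNS = ["clip_id", "subject_id", "label", "path"]


def read_manifest(path: str) -> pd.DataFrame:
    """Read a ``clip_id,subject_id,label,path`` manifest CSV.

    Labels are normalized to {0, 1, <NA>} integers.
    """
    df = pd.read_csv(path, dtype={"clip_id": str, "subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "path"]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    df["label"] = (
        df["label"].astype(str).str.strip().str.lower().map(_NAME_LABELS).astype("Int64")
    )
    return df


def write_manifest(df: pd.DataFrame, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    out = df.copy()
    out["label"] = out["label"].map(lambda v: _LABEL_NAMES.get(v if pd.notna(v) else None))
    out.to_csv(path, index=False)
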