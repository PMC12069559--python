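"""Reading, validation and basic geometry of label-mask sequences.

A recording enters the pipeline as a stack of per-frame integer label masks
produced by an upstream vocal-fold segmentation (4 classes: background,
glottis, right fold, left fold), plus a JSON sidecar carrying the frame rate
and the image orientation.  This module validates that contract, extracts
per-frame region contours, and computes the glottal area waveform (GAW).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage import measure

BACKGROUND = 0
GLOTTIS = 1
RIGHT_VF = 2
LEFT_VF = 3

_VALID_LABELS = frozenset({BACKGROUND, GLOTTIS, RIGHT_VF, LEFT_VF})


class FormatError(ValueError):
    """Raised when a mask container violates the label contract."""


class MetadataError(ValueError):
    """Raised when the JSON sidecar is missing required keys."""


class MissingStructureError(ValueError):
    """Raised when a vocal-fold label is absent from a frame."""


@dataclass
class LabelMaskSequence:
    """A segmented high-speed recording: ``frames[t, row, col]`` with labels
    {0 background, 1 glottis, 2 right fold, 3 left fold}.

    After construction the orientation is normalized so that the dorsal
    (posterior) end of the folds is at row 0 and rows increase ventrally.
    """

    frames: np.ndarray
    fps: float
    dorsal_at_top: bool = True

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("frames must be a (T, H, W) stack with T >= 1")
        if self.fps <= 0:
            raise MetadataError("fps must be positive")
        present = np.unique(self.frames)
        bad = set(present.tolist()) - _VALID_LABELS
        if bad:
            raise FormatError(f"unknown label values in mask stack: {sorted(bad)}")
        if not self.dorsal_at_top:
            # normalize so dorsal is always at row 0
            self.frames = self.frames[:, ::-1, :].copy()
            self.dorsal_at_top = True

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])

    def validate_components(self) -> None:
        """Each fold label must form a single connected region per frame.

        Multiple components are tolerated when the largest dominates (speckle
        is dropped with a warning downstream); an empty fold label is an error.
        """
        for t in range(self.n_frames):
            frame = self.frames[t]
            for lab in (RIGHT_VF, LEFT_VF):
                if not np.any(frame == lab):
                    raise MissingStructureError(
                        f"fold label {lab} absent in frame {t}"
                    )


@dataclass
class ContourSet:
    """Per-frame closed region outlines in (row, col) pixel coordinates."""

    glottis_contour: np.ndarray  # (N, 2) or empty (0, 2)
    left_vf_contour: np.ndarray
    right_vf_contour: np.ndarray
    frame_index: int = 0


@dataclass
class GAWSeries:
    """Glottal area waveform: per-frame glottis pixel count."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"frame": np.arange(len(self.values), dtype=int),
             "area_px": self.values}
        ).to_csv(path, index=False)


def read_mask_sequence(path, meta_path) -> LabelMaskSequence:
    """Load a label-mask stack (multipage TIFF or NPZ with key ``labels``)
    together with its JSON sidecar ``{"fps": float, "dorsal_at_top": bool}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npz":
        with np.load(path) as npz:
            if "labels" not in npz:
                raise FormatError("NPZ container must hold key 'labels'")
            frames = npz["labels"]
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    meta = json.loads(Path(meta_path).read_text())
    if "fps" not in meta:
        raise MetadataError("metadata sidecar must supply 'fps'")
    return LabelMaskSequence(
        frames=np.asarray(frames, dtype=np.uint8),
        fps=float(meta["fps"]),
        dorsal_at_top=bool(meta.get("dorsal_at_top", True)),
    )


def write_mask_sequence(seq: LabelMaskSequence, path, meta_path) -> None:
    """Write the stack as multipage TIFF (uint8) or NPZ plus JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".npz":
        np.savez_compressed(path, labels=seq.frames.astype(np.uint8))
    else:
        tifffile.imwrite(path, seq.frames.astype(np.uint8))
    Path(meta_path).write_text(
        json.dumps({"fps": seq.fps, "dorsal_at_top": seq.dorsal_at_top})
    )


def _bounding_box(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def _largest_component(mask: np.ndarray, label_name: str) -> np.ndarray:
    from scipy import ndimage

    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n <= 1:
        return mask
    warnings.warn(
        f"{label_name}: {n} connected components; keeping the largest",
        stacklevel=3,
    )
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def _region_contour(mask: np.ndarray) -> np.ndarray:
    """Closed outline of a binary region via marching squares at level 0.5.

    Returns an (N, 2) array of (row, col) vertices in counter-clockwise
    order (image convention), or an empty (0, 2) array for an empty region.
    Work is restricted to the region's bounding box for speed.
    """
    if not mask.any():
        return np.empty((0, 2))
    r0, r1, c0, c1 = _bounding_box(mask)
    padded = np.pad(mask[r0:r1, c0:c1].astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) + [r0 - 1.0, c0 - 1.0]
    # drop duplicated closing vertex if present
    if len(contour) > 1 and np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    return contour


def extract_contours(seq: LabelMaskSequence, t: int) -> ContourSet:
    """Trace glottis and fold outlines of frame ``t`` at half-pixel precision.

    Fold labels must be present (a frame without visible folds cannot be
    analyzed); an empty glottis region yields an empty glottis contour.
    """
    if not 0 <= t < seq.n_frames:
        raise IndexError(f"frame index {t} outside [0, {seq.n_frames})")
    frame = seq.frames[t]
    nz = frame > 0
    if nz.any():  # restrict all label work to the occupied box
        r0, r1, c0, c1 = _bounding_box(nz)
        frame = frame[r0:r1, c0:c1]
        off = np.array([float(r0), float(c0)])
    else:
        off = np.zeros(2)
    out = {}
    for lab, name in ((GLOTTIS, "glottis"), (LEFT_VF, "left_vf"), (RIGHT_VF, "right_vf")):
        mask = frame == lab
        if not mask.any():
            if lab != GLOTTIS:
                raise MissingStructureError(
                    f"{name} (label {lab}) absent in frame {t}"
                )
            out[name] = np.empty((0, 2))
            continue
        mask = _largest_component(mask, name)
        out[name] = _region_contour(mask) + off
    return ContourSet(
        glottis_contour=out["glottis"],
        left_vf_contour=out["left_vf"],
        right_vf_contour=out["right_vf"],
        frame_index=t,
    )


def compute_gaw(seq: LabelMaskSequence) -> GAWSeries:
    """Glottal area waveform: per-frame count of glottis pixels."""
    values = np.count_nonzero(seq.frames == GLOTTIS, axis=(1, 2))
    return GAWSeries(values=values.astype(float), fps=seq.fps)
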