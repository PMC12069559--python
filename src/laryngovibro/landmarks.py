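"""Posterior points, anterior commissure, vibrational axes and opening angle.

Each fold's oscillatory part is bounded dorsally by a posterior point
(``P_r`` / ``P_l``, approximating the processus vocalis) and ventrally by the
anterior commissure ``A``.  Both are located from label adjacency in the
segmentation, stabilized over time with a sliding-window median, and joined
into per-fold vibrational axes.  The angle the two axes enclose at ``A`` is
the glottal opening angle Gamma(t) used for voice-onset analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_masks import GLOTTIS, LEFT_VF, RIGHT_VF, GAWSeries, LabelMaskSequence


class LandmarkFailureError(ValueError):
    """The folds share no adjacency and no glottis separates them."""


class DegenerateAxisError(ValueError):
    """Posterior point and anterior commissure coincide."""


@dataclass
class LandmarkTrack:
    """Per-frame landmark points, (T, 2) arrays of (row, col)."""

    P_r: np.ndarray
    P_l: np.ndarray
    A: np.ndarray
    smoothed: bool = False


@dataclass
class AxisTrack:
    """Per-fold oriented axes P -> A with Euclidean lengths (pixels)."""

    P_r: np.ndarray
    P_l: np.ndarray
    A: np.ndarray
    L_r: np.ndarray
    L_l: np.ndarray


@dataclass
class OpeningAngleSeries:
    """Opening angle Gamma(t) in degrees, hinged at the anterior commissure."""

    gamma: np.ndarray
    fps: float


def _dilate8(mask: np.ndarray) -> np.ndarray:
    """8-neighbourhood binary dilation via shifted ORs (fast on small crops)."""
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    out[:, 1:] |= out[:, :-1].copy()
    out[:, :-1] |= out[:, 1:].copy()
    return out


def _adjacency_pixels(region: np.ndarray, other: np.ndarray) -> np.ndarray:
    """(row, col) pixels of ``region`` 8-adjacent to ``other`` (or touching it)."""
    return np.argwhere(region & _dilate8(other))


def _extreme_point(pixels: np.ndarray, dorsal: bool) -> np.ndarray:
    """Most dorsal (min row) or most ventral (max row) adjacency pixel.

    Row ties are resolved by averaging columns, keeping the point centred on
    the contact zone rather than at an arbitrary corner.
    """
    row = pixels[:, 0].min() if dorsal else pixels[:, 0].max()
    cols = pixels[pixels[:, 0] == row, 1]
    return np.array([float(row), float(cols.mean())])


def detect_endpoints(frame: np.ndarray, frame_index: int = 0):
    """Raw (P_r, P_l, A) landmarks for one label frame.

    ``P_r``/``P_l`` are the most dorsal points of each fold's adjacency with
    the opposite fold or the glottis; ``A`` is the most ventral contact point
    between the two folds (falling back to fold/glottis adjacency when the
    folds are separated by an open glottis everywhere).
    """
    nz = frame > 0
    off = np.zeros(2)
    if nz.any():  # restrict work to the occupied bounding box
        rows = np.flatnonzero(nz.any(axis=1))
        cols = np.flatnonzero(nz.any(axis=0))
        frame = frame[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        off = np.array([float(rows[0]), float(cols[0])])
    right = frame == RIGHT_VF
    left = frame == LEFT_VF
    glottis = frame == GLOTTIS

    adj_r = _adjacency_pixels(right, left | glottis)
    adj_l = _adjacency_pixels(left, right | glottis)
    if adj_r.size == 0 or adj_l.size == 0:
        raise LandmarkFailureError(
            f"frame {frame_index}: folds share no adjacency and no glottis "
            "separates them"
        )
    P_r = _extreme_point(adj_r, dorsal=True)
    P_l = _extreme_point(adj_l, dorsal=True)
    # half-pixel boundary correction: the landmark sits on the region
    # boundary (pixel edge facing the glottis), not the pixel centre
    for P, region in ((P_r, right), (P_l, left)):
        centroid_col = np.argwhere(region)[:, 1].mean()
        P[1] += 0.5 * np.sign(P[1] - centroid_col)

    contact_r = _adjacency_pixels(right, left)
    contact_l = _adjacency_pixels(left, right)
    if contact_r.size and contact_l.size:
        # symmetric contact set: pixels of either fold touching the other
        A = (_extreme_point(contact_r, dorsal=False)
             + _extreme_point(contact_l, dorsal=False)) / 2.0
    else:
        # folds never touch directly: take the shared ventral end of the
        # fold/glottis adjacency zone
        A = (_extreme_point(adj_r, dorsal=False)
             + _extreme_point(adj_l, dorsal=False)) / 2.0
    return P_r + off, P_l + off, A + off


def detect_endpoints_sequence(seq: LabelMaskSequence) -> LandmarkTrack:
    """Raw per-frame landmarks for a whole sequence."""
    T = seq.n_frames
    P_r = np.empty((T, 2))
    P_l = np.empty((T, 2))
    A = np.empty((T, 2))
    for t in range(T):
        P_r[t], P_l[t], A[t] = detect_endpoints(seq.frames[t], t)
    return LandmarkTrack(P_r=P_r, P_l=P_l, A=A, smoothed=False)


def _window_starts(T: int, window: int, step: int) -> np.ndarray:
    if T <= window:
        return np.array([0])
    starts = np.arange(0, T - window + 1, step)
    if starts[-1] != T - window:  # make the last window flush with the end
        starts = np.append(starts, T - window)
    return starts


def smooth_landmarks(
    raw: LandmarkTrack,
    gaw: GAWSeries,
    window: int = 150,
    overlap: int = 25,
    closure_tol: float = 0.0,
    merge_closure: bool = True,
) -> LandmarkTrack:
    """Stabilize raw landmarks with a sliding-window median.

    Windows of ``window`` frames overlapping by ``overlap`` frames are
    aggregated by a coordinate-wise median assigned to the window centre;
    landmark tracks are linearly interpolated between centres and extended
    with the nearest centre value at the edges.  Within any window where the
    GAW reaches zero, complete glottal closure is assumed and the two
    posterior points are merged to their common midpoint.
    """
    if window <= overlap:
        raise ValueError("window must exceed overlap")
    T = len(raw.A)
    win = min(window, T)
    starts = _window_starts(T, win, window - overlap)
    centers = starts + (win - 1) / 2.0

    med_r = np.empty((len(starts), 2))
    med_l = np.empty((len(starts), 2))
    med_a = np.empty((len(starts), 2))
    for i, s in enumerate(starts):
        sl = slice(s, s + win)
        med_r[i] = np.median(raw.P_r[sl], axis=0)
        med_l[i] = np.median(raw.P_l[sl], axis=0)
        med_a[i] = np.median(raw.A[sl], axis=0)
        if merge_closure and np.min(gaw.values[sl]) <= closure_tol:
            mid = (med_r[i] + med_l[i]) / 2.0
            med_r[i] = mid
            med_l[i] = mid

    t_grid = np.arange(T, dtype=float)

    def interp(med: np.ndarray) -> np.ndarray:
        return np.stack(
            [np.interp(t_grid, centers, med[:, k]) for k in range(2)], axis=1
        )

    return LandmarkTrack(
        P_r=interp(med_r), P_l=interp(med_l), A=interp(med_a), smoothed=True
    )


def vibrational_axes(lm: LandmarkTrack) -> AxisTrack:
    """Per-fold axes: oriented segments from P_{r,l}(t) to A(t)."""
    L_r = np.linalg.norm(lm.A - lm.P_r, axis=1)
    L_l = np.linalg.norm(lm.A - lm.P_l, axis=1)
    bad = np.flatnonzero((L_r <= 0) | (L_l <= 0))
    if bad.size:
        raise DegenerateAxisError(
            f"posterior point coincides with anterior commissure in frames "
            f"{bad[:10].tolist()}"
        )
    return AxisTrack(P_r=lm.P_r, P_l=lm.P_l, A=lm.A, L_r=L_r, L_l=L_l)


def opening_angle(ax: AxisTrack, fps: float) -> OpeningAngleSeries:
    """Unsigned angle (degrees) between A-P_r and A-P_l, hinged at A."""
    u = ax.P_r - ax.A
    v = ax.P_l - ax.A
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu <= 0) or np.any(nv <= 0):
        raise DegenerateAxisError("degenerate axis in opening-angle input")
    cosang = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
    return OpeningAngleSeries(gamma=np.degrees(np.arccos(cosang)), fps=fps)


def landmarks_to_dataframe(lm: LandmarkTrack, ax: AxisTrack,
                           gamma: OpeningAngleSeries):
    """Flat per-frame table for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame": np.arange(len(lm.A), dtype=int),
            "Pr_row": lm.P_r[:, 0], "Pr_col": lm.P_r[:, 1],
            "Pl_row": lm.P_l[:, 0], "Pl_col": lm.P_l[:, 1],
            "A_row": lm.A[:, 0], "A_col": lm.A[:, 1],
            "L_r": ax.L_r, "L_l": ax.L_l,
            "gamma_deg": gamma.gamma,
        }
    )
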