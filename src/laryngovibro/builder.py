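"""Construction of the Laryngovibrogram and the Phonovibrogram baseline.

The LVG maps, for every frame, the signed distance of each fold's medial
tissue edge to that fold's own vibrational axis, normalized by the axis
length and resampled to 256 equidistant positions per fold.  Stacking the
left-fold profile (rows 0..255, posterior to anterior) on top of the
right-fold profile (rows 256..511, posterior to anterior) and concatenating
columns over time yields a 512 x T matrix of dimensionless deflections:
positive values are lateral excursions (toward the fold body), negative
values contralateral excursions (beyond the axis toward the opposite fold).

The PVG baseline measures instead the distance of the glottal outline to the
glottal symmetry axis, normalized by the glottal axis length, and therefore
only covers positions where the glottis opens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_masks import ContourSet, LabelMaskSequence, compute_gaw, extract_contours
from .landmarks import (
    AxisTrack,
    LandmarkTrack,
    detect_endpoints_sequence,
    smooth_landmarks,
    vibrational_axes,
)

N_POINTS = 256  # equidistant positions per fold

_SIGN_TIE_TOL = 1e-9


class DegenerateContourError(ValueError):
    """Contour cut points at P and A coincide."""


class UndefinedPositionError(ValueError):
    """The glottis never opens, so no medial glottal position exists."""


@dataclass
class FoldEdgeContour:
    """Medial fold edge: open polyline from P to A, (N, 2) row/col points."""

    points: np.ndarray
    side: str  # "left" | "right"
    frame_index: int = 0


@dataclass
class LVGMatrix:
    """Signed normalized deflections, shape (512, T).

    Rows 0..255: left fold, posterior (p=0) to anterior (p=1).
    Rows 256..511: right fold, same orientation.  The mirrored display
    layout (right half flipped so posterior edges face the outer borders)
    is applied at render time only.
    """

    D: np.ndarray
    fps: float
    gap: np.ndarray | None = None  # normalized glottal gap per (p, t)
    layout: str = "left-top-posterior-first"

    @property
    def n_frames(self) -> int:
        return int(self.D.shape[1])

    def save(self, path) -> None:
        extra = {} if self.gap is None else {"gap": self.gap}
        np.savez_compressed(path, D=self.D, fps=self.fps,
                            layout=self.layout, **extra)

    @classmethod
    def load(cls, path) -> "LVGMatrix":
        with np.load(path, allow_pickle=False) as npz:
            return cls(
                D=npz["D"],
                fps=float(npz["fps"]),
                gap=npz["gap"] if "gap" in npz else None,
                layout=str(npz["layout"]),
            )


@dataclass
class PVGMatrix:
    """PVG baseline: glottal-contour deflections, same 512 x T layout."""

    D: np.ndarray
    fps: float
    axis_P: np.ndarray | None = None  # per-frame glottal axis endpoints
    axis_A: np.ndarray | None = None
    layout: str = "left-top-posterior-first"

    def save(self, path) -> None:
        np.savez_compressed(path, D=self.D, fps=self.fps, layout=self.layout)


def point_segment_distance(points: np.ndarray, seg_a: np.ndarray,
                           seg_b: np.ndarray):
    """Exact Euclidean distance from points to the segment [seg_a, seg_b].

    The minimizing axis parameter is continuous over the whole segment, so
    interior points use the perpendicular foot and points beyond the ends
    use the end-point distance.  Returns ``(distances, signed_offsets)``
    where the signed offset is the perpendicular offset to the supporting
    line (used only to decide the side).
    """
    points = np.atleast_2d(points).astype(float)
    a = np.asarray(seg_a, dtype=float)
    d = np.asarray(seg_b, dtype=float) - a
    L2 = float(d @ d)
    if L2 <= 0:
        raise ValueError("degenerate segment")
    rel = points - a
    t = np.clip(rel @ d / L2, 0.0, 1.0)
    foot = a + t[:, None] * d
    dist = np.linalg.norm(points - foot, axis=1)
    cross = rel[:, 0] * d[1] - rel[:, 1] * d[0]
    offset = cross / np.sqrt(L2)
    return dist, offset


def _nearest_vertex(contour: np.ndarray, point: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(contour - point, axis=1)))


def split_and_orient(contour: np.ndarray, P: np.ndarray, A: np.ndarray,
                     side: str, frame_index: int = 0) -> FoldEdgeContour:
    """Cut a closed fold contour at the vertices nearest P and A and keep
    the medial arc, ordered from P to A.

    The medial arc is the one lying closer to the vibrational axis on the
    side opposite the fold body (the lateral arc wraps around the tissue and
    sits far out on the body side).
    """
    contour = np.asarray(contour, dtype=float)
    i = _nearest_vertex(contour, P)
    j = _nearest_vertex(contour, A)
    if i == j:
        raise DegenerateContourError(
            f"frame {frame_index}, {side} fold: P and A map to the same "
            "contour vertex"
        )
    M = len(contour)
    if i < j:
        arc1 = contour[i:j + 1]
        arc2 = np.concatenate([contour[j:], contour[:i + 1]])[::-1]
    else:
        arc1 = np.concatenate([contour[i:], contour[:j + 1]])
        arc2 = contour[j:i + 1][::-1]

    centroid = contour.mean(axis=0)
    _, off_c = point_segment_distance(centroid[None], P, A)
    lat = 1.0 if off_c[0] >= 0 else -1.0  # lateral = fold-body side

    def mean_lateral(arc: np.ndarray) -> float:
        _, off = point_segment_distance(arc, P, A)
        return float(np.mean(off * lat))

    edge = arc1 if mean_lateral(arc1) <= mean_lateral(arc2) else arc2
    if len(edge) < 2:
        raise DegenerateContourError(
            f"frame {frame_index}, {side} fold: medial arc has < 2 vertices"
        )
    return FoldEdgeContour(points=edge, side=side, frame_index=frame_index)


def deflection_profile(edge: FoldEdgeContour, P: np.ndarray, A: np.ndarray,
                       lateral_sign: float | None = None,
                       n_points: int = N_POINTS):
    """Signed, normalized deflection of a fold edge, resampled to
    ``n_points`` arc-length-equidistant positions from P to A.

    Each edge vertex contributes its exact point-to-segment distance to the
    axis, divided by the axis length; the sign is positive on the lateral
    (fold-body) side of the axis, negative on the contralateral side, and
    zero on the axis.  Returns ``(delta, xy)`` with the resampled profile
    and the corresponding resampled edge coordinates.
    """
    pts = edge.points
    L = float(np.linalg.norm(np.asarray(A) - np.asarray(P)))
    dist, offset = point_segment_distance(pts, P, A)
    if lateral_sign is None:
        # infer the lateral side from the edge itself: the dominant side
        lateral_sign = 1.0 if offset.sum() >= 0 else -1.0
    sign = np.sign(offset * lateral_sign)
    sign[np.abs(offset) < _SIGN_TIE_TOL] = 0.0
    delta = dist / L * sign

    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]
    if total <= 0:
        return np.zeros(n_points), np.tile(pts[0], (n_points, 1))
    s /= total
    grid = np.linspace(0.0, 1.0, n_points)
    delta_rs = np.interp(grid, s, delta)
    xy = np.stack([np.interp(grid, s, pts[:, k]) for k in range(2)], axis=1)
    return delta_rs, xy


def _lateral_sign(contour: np.ndarray, P: np.ndarray, A: np.ndarray) -> float:
    """Side of the axis on which the fold body (contour centroid) lies."""
    _, off = point_segment_distance(contour.mean(axis=0)[None], P, A)
    return 1.0 if off[0] >= 0 else -1.0


class LVGAssemblyError(RuntimeError):
    def __init__(self, failures):
        self.failures = failures
        idx = [f for f, _ in failures[:10]]
        super().__init__(
            f"LVG assembly failed for {len(failures)} frame(s), "
            f"first indices {idx}"
        )


def prepare_landmarks(seq: LabelMaskSequence, window: int = 150,
                      overlap: int = 25, merge_closure: bool = True):
    """Raw landmark detection, sliding-window smoothing and axis derivation.

    ``merge_closure=False`` skips the identification of the two posterior
    points in closure windows; this keeps the opening angle meaningful for
    adduction analysis, where forcing coincident axes would zero the angle
    up to a full smoothing window before the folds actually meet.
    """
    gaw = compute_gaw(seq)
    raw = detect_endpoints_sequence(seq)
    lm = smooth_landmarks(raw, gaw, window=window, overlap=overlap,
                          merge_closure=merge_closure)
    axes = vibrational_axes(lm)
    return lm, axes, gaw


def assemble_from_geometry(contour_sets: list[ContourSet],
                           lm: LandmarkTrack, fps: float,
                           n_points: int = N_POINTS) -> LVGMatrix:
    """Build the LVG matrix from per-frame fold contours and landmarks.

    This geometry-level entry point operates on Euclidean coordinates only,
    so the result is invariant under rigid rotation and uniform scaling of
    all inputs.  Frames whose profile extraction fails are collected and
    reported together.
    """
    T = len(contour_sets)
    D = np.zeros((2 * n_points, T))
    gap = np.zeros((n_points, T))
    failures = []
    for t, cs in enumerate(contour_sets):
        try:
            lat_l = _lateral_sign(cs.left_vf_contour, lm.P_l[t], lm.A[t])
            lat_r = _lateral_sign(cs.right_vf_contour, lm.P_r[t], lm.A[t])
            edge_l = split_and_orient(cs.left_vf_contour, lm.P_l[t], lm.A[t],
                                      "left", t)
            edge_r = split_and_orient(cs.right_vf_contour, lm.P_r[t], lm.A[t],
                                      "right", t)
            dl, xy_l = deflection_profile(edge_l, lm.P_l[t], lm.A[t], lat_l,
                                          n_points)
            dr, xy_r = deflection_profile(edge_r, lm.P_r[t], lm.A[t], lat_r,
                                          n_points)
        except Exception as exc:  # noqa: BLE001 - collected per frame
            failures.append((t, exc))
            continue
        D[:n_points, t] = dl
        D[n_points:, t] = dr
        L_l = np.linalg.norm(lm.A[t] - lm.P_l[t])
        L_r = np.linalg.norm(lm.A[t] - lm.P_r[t])
        gap[:, t] = np.linalg.norm(xy_l - xy_r, axis=1) / ((L_l + L_r) / 2.0)
    if failures:
        raise LVGAssemblyError(failures)
    return LVGMatrix(D=D, fps=fps, gap=gap)


def assemble_lvg(seq: LabelMaskSequence, lm: LandmarkTrack | None = None,
                 axes: AxisTrack | None = None, n_points: int = N_POINTS,
                 window: int = 150, overlap: int = 25) -> LVGMatrix:
    """Build the LVG matrix for a whole mask sequence.

    Landmarks/axes are computed (with the default 150/25 sliding window)
    when not supplied.
    """
    if lm is None or axes is None:
        lm, axes, _ = prepare_landmarks(seq, window=window, overlap=overlap)
    contour_sets = [extract_contours(seq, t) for t in range(seq.n_frames)]
    return assemble_from_geometry(contour_sets, lm, seq.fps, n_points)


def render_lvg(M: LVGMatrix, path, title: str = "LVG") -> None:
    """Render the matrix as a PNG with a diverging colormap.

    Display uses the mirrored layout: the right-fold half is flipped so the
    posterior edge of each fold faces the outer border of the image.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = M.D.shape[0] // 2
    disp = np.vstack([M.D[:n], M.D[n:][::-1]])
    vmax = max(np.abs(disp).max(), 1e-6)
    T = M.D.shape[1]
    fig, ax = plt.subplots(figsize=(max(4, T / 200), 5))
    im = ax.imshow(disp, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=[0, T / M.fps * 1e3, 100, -100])
    ax.set_xlabel("time [ms]")
    ax.set_ylabel("position p [%]  (left fold up, right fold down)")
    ax.set_yticks([-100, -50, 0, 50, 100])
    ax.set_yticklabels(["100", "50", "0 / 0", "50", "100"])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized deflection")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _glottal_axis_endpoints(contour: np.ndarray):
    """Dorsal-most and ventral-most points of a glottis outline."""
    i_top = int(np.argmin(contour[:, 0]))
    i_bot = int(np.argmax(contour[:, 0]))
    return contour[i_top], contour[i_bot]


def build_pvg(seq: LabelMaskSequence, lm: LandmarkTrack | None = None,
              n_points: int = N_POINTS, window: int = 150,
              overlap: int = 25) -> PVGMatrix:
    """PVG baseline: split the glottal outline at the glottal symmetry axis
    and measure axis distances normalized by the glottal axis length.

    The glottal axis joins the dorsal-most and ventral-most glottis contour
    points per frame and is stabilized with the same sliding-window median
    as the landmarks.  Closed-glottis frames produce zero columns.  The
    assignment of outline halves to the left/right fold rows follows the
    side on which the respective segmented fold lies.
    """
    T = seq.n_frames
    contours = []
    P_raw = np.full((T, 2), np.nan)
    A_raw = np.full((T, 2), np.nan)
    left_sign = 1.0
    for t in range(T):
        cs = extract_contours(seq, t)
        contours.append(cs.glottis_contour)
        if len(cs.glottis_contour) >= 3:
            P_raw[t], A_raw[t] = _glottal_axis_endpoints(cs.glottis_contour)
            if t == 0 or np.isnan(P_raw[:t]).all():
                left_sign = _lateral_sign(cs.left_vf_contour, P_raw[t], A_raw[t])
    if np.isnan(P_raw[:, 0]).all():
        return PVGMatrix(D=np.zeros((2 * n_points, T)), fps=seq.fps)

    # sliding-window median over open frames, interpolated across closures
    win = min(window, T)
    starts = _pvg_window_starts(T, win, window - overlap)
    centers, med_P, med_A = [], [], []
    for s in starts:
        sl = slice(s, s + win)
        if np.isnan(P_raw[sl, 0]).all():
            continue
        centers.append(s + (win - 1) / 2.0)
        med_P.append(np.nanmedian(P_raw[sl], axis=0))
        med_A.append(np.nanmedian(A_raw[sl], axis=0))
    centers = np.asarray(centers)
    med_P = np.asarray(med_P)
    med_A = np.asarray(med_A)
    t_grid = np.arange(T, dtype=float)
    P_s = np.stack([np.interp(t_grid, centers, med_P[:, k]) for k in range(2)], 1)
    A_s = np.stack([np.interp(t_grid, centers, med_A[:, k]) for k in range(2)], 1)

    D = np.zeros((2 * n_points, T))
    for t in range(T):
        outline = contours[t]
        if len(outline) < 3:
            continue
        P, A = P_s[t], A_s[t]
        g_len = float(np.linalg.norm(A - P))
        if g_len <= 0:
            continue
        dist, off = point_segment_distance(outline, P, A)
        proj = (outline - P) @ (A - P) / g_len**2
        for half, rows in ((left_sign, slice(0, n_points)),
                           (-left_sign, slice(n_points, 2 * n_points))):
            mask = off * half >= 0
            if mask.sum() < 2:
                continue
            order = np.argsort(proj[mask])
            pr = np.clip(proj[mask][order], 0.0, 1.0)
            dd = dist[mask][order] / g_len
            grid = np.linspace(0.0, 1.0, n_points)
            D[rows, t] = np.interp(grid, pr, dd)
    return PVGMatrix(D=D, fps=seq.fps, axis_P=P_s, axis_A=A_s)


def _pvg_window_starts(T: int, window: int, step: int) -> np.ndarray:
    from .landmarks import _window_starts

    return _window_starts(T, window, step)


def map_pvg_medial_position(pvg: PVGMatrix, axes: AxisTrack,
                            gaw_values: np.ndarray) -> float:
    """Relative position (fraction of fold length) of the medial PVG
    trajectory: the time-averaged glottal-axis midpoint projected onto the
    fold-axis parameterization.
    """
    open_frames = np.flatnonzero(gaw_values > 0)
    if open_frames.size == 0 or pvg.axis_P is None:
        raise UndefinedPositionError("glottis never opens in this sequence")
    mid = ((pvg.axis_P[open_frames] + pvg.axis_A[open_frames]) / 2.0).mean(axis=0)
    P = ((axes.P_l + axes.P_r) / 2.0)[open_frames].mean(axis=0)
    A = axes.A[open_frames].mean(axis=0)
    L2 = float((A - P) @ (A - P))
    p = float((mid - P) @ (A - P) / L2)
    return float(np.clip(p, 0.0, 1.0))
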