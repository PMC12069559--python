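"""Cycle segmentation and quantitative vibratory measures.

Every LVG row is a motion trajectory D(p, t): the signed normalized
deflection of one fold at fixed relative position p over time.  From the
trajectory at a position of interest (clinically, the medial position
p = 50%) this module derives:

* per-cycle relative normalized deflection (RND): peak-to-peak deflection
  within each oscillation cycle, in percent of the axis length, and its
  mean over all complete cycles;
* relative shimmer: mean absolute consecutive-cycle amplitude difference
  over the mean amplitude, in percent;
* relative jitter: same statistic on cycle durations, in percent;
* Q_RND: the min/max ratio of left vs right per-cycle RND (1 = perfect
  lateral amplitude symmetry), averaged over jointly segmented cycles;
* the lateral phase difference: the absolute time average of the wrapped
  difference between left and right instantaneous phases, per position,
  aggregated over the glottal-opening positions and over the full matrix;
* the fundamental frequency F0 from the glottal area waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .builder import LVGMatrix
from .io_masks import GAWSeries

# complex Morlet with centre angular frequency omega0 = 6:
# cmor{B}-{C} has psi(t) ~ exp(2*pi*i*C*t) * exp(-t^2/B); B=2 gives the
# unit-variance Gaussian envelope and C = 6/(2*pi) the omega0 = 6 carrier.
_MORLET = f"cmor2.0-{6.0 / (2.0 * np.pi):.10f}"

F0_BAND = (50.0, 500.0)


class UndefinedF0Error(ValueError):
    """No periodic component rises above the noise floor of the GAW."""


@dataclass
class Trajectory:
    """Deflection series of one fold at a fixed relative position."""

    values: np.ndarray
    side: str
    p: float
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CycleSegmentation:
    """Complete oscillation cycles delimited by trajectory minima.

    ``starts``/``ends`` are integer frame boundaries (consecutive cycles
    share a boundary); ``periods`` are the sub-frame refined boundary
    spacings used for jitter, so that the flat, discretized closure minima
    do not quantize the period estimates.
    """

    starts: np.ndarray  # frame of each cycle start (== previous cycle end)
    ends: np.ndarray
    amplitudes: np.ndarray  # per-cycle peak-to-peak amplitude A_j
    periods: np.ndarray  # per-cycle duration T_j in frames (float)

    @property
    def n_cycles(self) -> int:
        return int(len(self.starts))


def extract_trajectory(M: LVGMatrix, side: str, p: float) -> Trajectory:
    """Nearest-row trajectory at relative position ``p`` of one fold."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    n = M.D.shape[0] // 2
    row = int(round(p * (n - 1)))
    if side == "right":
        row += n
    elif side != "left":
        raise ValueError("side must be 'left' or 'right'")
    return Trajectory(values=M.D[row], side=side, p=p, fps=M.fps)


def _dominant_frequency(values: np.ndarray, fps: float,
                        band: tuple[float, float] = F0_BAND,
                        min_peak_factor: float = 10.0) -> float:
    """Periodogram peak in ``band`` refined by parabolic interpolation."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        raise UndefinedF0Error("signal is constant")
    nfft = int(2 ** np.ceil(np.log2(max(len(x) * 4, 256))))
    win = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * win, n=nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise UndefinedF0Error("analysis band empty at this frame rate")
    sub = spec[sel]
    floor = np.median(sub)
    k = int(np.argmax(sub))
    if sub[k] <= 0 or (floor > 0 and sub[k] < min_peak_factor * floor):
        raise UndefinedF0Error("no periodogram peak above the noise floor")
    i = np.flatnonzero(sel)[k]
    if 0 < i < len(spec) - 1 and spec[i - 1] > 0 and spec[i + 1] > 0:
        # parabolic refinement on log power
        y0, y1, y2 = np.log(spec[i - 1:i + 2])
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return float((i + shift) * fps / nfft)


def estimate_f0(gaw: GAWSeries) -> float:
    """Fundamental frequency (Hz) of the glottal area waveform."""
    return _dominant_frequency(gaw.values, gaw.fps)


def segment_cycles(tr: Trajectory, f0_hint: float | None = None,
                   prominence_frac: float = 0.1) -> CycleSegmentation:
    """Delimit oscillation cycles at successive minima of the trajectory.

    The series is lightly smoothed with a moving average of width about a
    quarter period before peak detection (prominence threshold: a fraction
    of the peak-to-peak range), so that within-cycle ripple does not split
    cycles.  Partial leading/trailing cycles are discarded; amplitudes are
    measured on the raw series.
    """
    x = tr.values
    if len(x) < 3 or np.ptp(x) == 0:
        return CycleSegmentation(*(np.empty(0, dtype=int),) * 2,
                                 amplitudes=np.empty(0), periods=np.empty(0))
    if f0_hint is None:
        try:
            f0_hint = _dominant_frequency(x, tr.fps)
        except UndefinedF0Error:
            return CycleSegmentation(np.empty(0, dtype=int),
                                     np.empty(0, dtype=int),
                                     np.empty(0), np.empty(0))
    width = max(1, int(round(tr.fps / (4.0 * f0_hint))))
    width += 1 - width % 2  # odd width: an even window shifts the series
    kernel = np.ones(width) / width
    # edge-replicate padding: zero-padding would bend the series ends and
    # bias the refined boundaries of the first and last cycles
    padded = np.pad(x, (width // 2, width // 2), mode="edge")
    xs = np.convolve(padded, kernel, mode="valid")
    minima, _ = sps.find_peaks(-xs, prominence=prominence_frac * np.ptp(xs))
    if len(minima) < 2:
        return CycleSegmentation(np.empty(0, dtype=int),
                                 np.empty(0, dtype=int),
                                 np.empty(0), np.empty(0))
    refined, ok = _refine_minima(xs, minima, edge_guard=width)
    # a leading/trailing boundary too close to the series edge cannot be
    # refined consistently with the interior ones: drop the cycle it bounds
    lo, hi = 0, len(minima)
    if not ok[0] and hi - lo > 2:
        lo += 1
    if not ok[-1] and hi - lo > 2:
        hi -= 1
    minima = minima[lo:hi]
    refined = refined[lo:hi]
    if len(minima) < 2:
        return CycleSegmentation(np.empty(0, dtype=int),
                                 np.empty(0, dtype=int),
                                 np.empty(0), np.empty(0))
    starts = minima[:-1].astype(int)
    ends = minima[1:].astype(int)
    amplitudes = np.array(
        [np.ptp(x[s:e + 1]) for s, e in zip(starts, ends)]
    )
    return CycleSegmentation(starts=starts, ends=ends,
                             amplitudes=amplitudes,
                             periods=np.diff(refined))


def _refine_minima(xs: np.ndarray, minima: np.ndarray,
                   edge_guard: int = 0):
    """Sub-frame cycle-boundary estimates at the detected minima.

    Trajectory minima at glottal closure are flat (tangential contact plus
    pixel discretization), so the raw minimum index is a biased boundary:
    its plateau centre drifts toward the longer neighbouring cycle.  Each
    boundary is instead taken as the slope-weighted mean of the two
    crossings of a low threshold on either side of the minimum; for a
    waveform whose shape scales with the local period, the period-dependent
    crossing offsets cancel under slope weighting.

    Returns ``(refined, ok)``; ``ok`` marks boundaries whose crossings were
    found with at least ``edge_guard`` samples of clearance from the series
    edge (where the smoothing is polluted by padding).
    """
    refined = minima.astype(float).copy()
    ok = np.zeros(len(minima), dtype=bool)
    for k, m in enumerate(minima):
        lo = minima[k - 1] if k > 0 else 0
        hi = minima[k + 1] if k + 1 < len(minima) else len(xs) - 1
        if m < edge_guard or len(xs) - 1 - m < edge_guard:
            continue
        base = xs[m]
        peak = min(xs[lo:m + 1].max(), xs[m:hi + 1].max())
        # crossings at 40% of the local range: high enough to sit on the
        # steep branch (away from the flattened, discretized closure
        # trough), low enough to stay clear of the rounded peaks
        level = base + 0.40 * (peak - base)
        if peak - base <= 0:
            continue
        # falling crossing, scanning left from the minimum
        left = np.flatnonzero(xs[lo:m + 1] >= level)
        right = np.flatnonzero(xs[m:hi + 1] >= level)
        if left.size == 0 or right.size == 0:
            continue
        i = lo + left[-1]  # xs[i] >= level > xs[i+1]
        j = m + right[0]  # xs[j-1] < level <= xs[j]
        if i < edge_guard or j > len(xs) - 1 - edge_guard:
            continue  # crossing sits where smoothing is padding-distorted
        s_l = xs[i] - xs[i + 1]
        s_r = xs[j] - xs[j - 1]
        if s_l <= 0 or s_r <= 0:
            continue
        t_l = i + (xs[i] - level) / s_l
        t_r = j - (xs[j] - level) / s_r
        refined[k] = (s_l * t_l + s_r * t_r) / (s_l + s_r)
        ok[k] = True
    return refined, ok


def rnd(cs: CycleSegmentation, tr: Trajectory):
    """Per-cycle relative normalized deflection and its mean, in percent.

    RND(p, j) is the max-min range of the deflection trajectory within
    cycle j; with J = 0 cycles the measure is undefined (None, not 0).
    """
    if cs.n_cycles < 1:
        return None, None
    per_cycle = np.array(
        [np.ptp(tr.values[s:e + 1]) for s, e in zip(cs.starts, cs.ends)]
    ) * 100.0
    return per_cycle, float(per_cycle.mean())


def shimmer(amplitudes) -> float | None:
    """Relative shimmer (%): mean absolute consecutive-cycle amplitude
    difference divided by the mean amplitude."""
    a = np.asarray(getattr(amplitudes, "amplitudes", amplitudes), dtype=float)
    if len(a) < 2:
        return None
    mean_a = a.mean()
    if mean_a == 0:
        return None
    return float(np.abs(np.diff(a)).mean() / mean_a * 100.0)


def jitter(periods) -> float | None:
    """Relative jitter (%): mean absolute consecutive-cycle period
    difference divided by the mean period."""
    t = np.asarray(getattr(periods, "periods", periods), dtype=float)
    if len(t) < 2:
        return None
    return float(np.abs(np.diff(t)).mean() / t.mean() * 100.0)


def q_rnd(rnd_left: np.ndarray, rnd_right: np.ndarray):
    """Per-pair amplitude-symmetry quotient min/max and its mean.

    Pairs where both RNDs are zero are skipped (undefined ratio); the
    second return value counts the pairs actually used.
    """
    rl = np.asarray(rnd_left, dtype=float)
    rr = np.asarray(rnd_right, dtype=float)
    if rl.shape != rr.shape:
        raise ValueError("left/right per-cycle RNDs must be paired")
    hi = np.maximum(rl, rr)
    ok = hi > 0
    q = np.full(len(rl), np.nan)
    q[ok] = np.minimum(rl[ok], rr[ok]) / hi[ok]
    mean = float(np.nanmean(q)) if ok.any() else None
    return q, mean, int(ok.sum())


def joint_cycles(tr_left: Trajectory, tr_right: Trajectory,
                 f0_hint: float | None = None,
                 prominence_frac: float = 0.1) -> CycleSegmentation:
    """Common cycle boundaries from the summed unsigned deflection signal,
    so that left and right per-cycle measures share the cycle index."""
    combined = Trajectory(
        values=np.abs(tr_left.values) + np.abs(tr_right.values),
        side="joint", p=tr_left.p, fps=tr_left.fps,
    )
    return segment_cycles(combined, f0_hint, prominence_frac)


def _cycle_rnd(values: np.ndarray, cs: CycleSegmentation) -> np.ndarray:
    return np.array(
        [np.ptp(values[s:e + 1]) for s, e in zip(cs.starts, cs.ends)]
    ) * 100.0


def instantaneous_phase(values: np.ndarray, fps: float, f0: float,
                        backend: str = "morlet") -> np.ndarray:
    """Per-frame instantaneous phase (rad, in (-pi, pi]) of a trajectory.

    ``morlet``: argument of the complex Morlet (omega0 = 6) wavelet
    transform at the scale matching ``f0``.  ``hilbert``: argument of the
    analytic signal.
    """
    x = np.asarray(values, dtype=float)
    x = x - x.mean(axis=-1, keepdims=True)
    if not 0.0 < f0 < fps / 2.0:
        raise ValueError("f0 must lie in (0, fps/2)")
    if backend == "hilbert":
        return np.angle(sps.hilbert(x, axis=-1))
    if backend != "morlet":
        raise ValueError("backend must be 'morlet' or 'hilbert'")
    scale = pywt.frequency2scale(_MORLET, f0 / fps)
    coef, _ = pywt.cwt(x, [scale], _MORLET, axis=-1, method="fft")
    return np.angle(coef[0])


def lateral_phase_difference(phi_l: np.ndarray, phi_r: np.ndarray,
                             method: str = "mean-of-arguments") -> float:
    """Average lateral phase difference in [0, pi] for one position.

    The per-frame difference is wrapped onto (-pi, pi] on the unit circle;
    the default takes the absolute value of its arithmetic time average
    (arg inside the sum).  ``method='circular'`` instead takes the argument
    of the averaged unit phasors.
    """
    d = np.angle(np.exp(1j * (np.asarray(phi_l) - np.asarray(phi_r))))
    if method == "circular":
        return float(np.abs(np.angle(np.mean(np.exp(1j * d)))))
    if method != "mean-of-arguments":
        raise ValueError("method must be 'mean-of-arguments' or 'circular'")
    return float(np.abs(np.mean(d)))


def opening_positions(M: LVGMatrix, threshold: float = 0.01) -> np.ndarray:
    """Row positions (per fold) whose time-maximum normalized glottal gap
    exceeds ``threshold`` of the axis length."""
    if M.gap is None:
        raise ValueError("LVG matrix carries no gap information")
    return np.flatnonzero(M.gap.max(axis=1) > threshold)


def phase_difference_profile(M: LVGMatrix, f0: float,
                             backend: str = "morlet",
                             opening_threshold: float = 0.01,
                             method: str = "mean-of-arguments"):
    """Per-position lateral phase difference and its aggregates.

    Returns ``(per_position, mean_opening, mean_full)`` where the first is
    a length-256 array, the second averages over positions inside the
    glottal-opening range (None when that range is empty), and the third
    averages over all positions.
    """
    n = M.D.shape[0] // 2
    phi = instantaneous_phase(M.D, M.fps, f0, backend)
    d = np.angle(np.exp(1j * (phi[:n] - phi[n:])))
    if method == "circular":
        per_pos = np.abs(np.angle(np.mean(np.exp(1j * d), axis=1)))
    else:
        per_pos = np.abs(d.mean(axis=1))
    full = float(per_pos.mean())
    try:
        op = opening_positions(M, opening_threshold)
    except ValueError:
        op = np.empty(0, dtype=int)
    mean_op = float(per_pos[op].mean()) if op.size else None
    return per_pos, mean_op, full


@dataclass
class MeasureReport:
    """All per-position measures at one evaluation position, plus the
    phase-difference aggregates and F0 for the sequence."""

    p: float
    rnd_left: float | None = None
    rnd_right: float | None = None
    rnd_left_cycles: np.ndarray | None = None
    rnd_right_cycles: np.ndarray | None = None
    shimmer_left: float | None = None
    shimmer_right: float | None = None
    jitter_left: float | None = None
    jitter_right: float | None = None
    q_rnd_cycles: np.ndarray | None = None
    q_rnd_mean: float | None = None
    phase_diff: float | None = None
    phase_diff_opening: float | None = None
    phase_diff_full: float | None = None
    f0_hz: float | None = None
    n_cycles_left: int = 0
    n_cycles_right: int = 0
    n_cycles_joint: int = 0

    def to_dict(self) -> dict:
        def pct(x):
            return None if x is None else round(float(x), 2)

        def rad(x):
            return None if x is None else round(float(x), 3)

        return {
            "p": self.p,
            "rnd_left_pct": pct(self.rnd_left),
            "rnd_right_pct": pct(self.rnd_right),
            "shimmer_left_pct": pct(self.shimmer_left),
            "shimmer_right_pct": pct(self.shimmer_right),
            "jitter_left_pct": pct(self.jitter_left),
            "jitter_right_pct": pct(self.jitter_right),
            "q_rnd_mean": rad(self.q_rnd_mean),
            "phase_diff_rad": rad(self.phase_diff),
            "phase_diff_opening_rad": rad(self.phase_diff_opening),
            "phase_diff_full_rad": rad(self.phase_diff_full),
            "f0_hz": None if self.f0_hz is None else round(self.f0_hz, 1),
            "n_cycles_left": self.n_cycles_left,
            "n_cycles_right": self.n_cycles_right,
            "n_cycles_joint": self.n_cycles_joint,
        }


def compute_report(M: LVGMatrix, gaw: GAWSeries | None = None,
                   p: float = 0.5, backend: str = "morlet",
                   prominence_frac: float = 0.1,
                   opening_threshold: float = 0.01) -> MeasureReport:
    """Full measure set at position ``p`` for one LVG matrix."""
    tr_l = extract_trajectory(M, "left", p)
    tr_r = extract_trajectory(M, "right", p)

    f0 = None
    if gaw is not None:
        try:
            f0 = estimate_f0(gaw)
        except UndefinedF0Error:
            f0 = None
    if f0 is None:
        try:
            f0 = _dominant_frequency(
                np.abs(tr_l.values) + np.abs(tr_r.values), M.fps
            )
        except UndefinedF0Error:
            return MeasureReport(p=p)

    rep = MeasureReport(p=p, f0_hz=f0)

    cs_l = segment_cycles(tr_l, f0, prominence_frac)
    cs_r = segment_cycles(tr_r, f0, prominence_frac)
    rep.n_cycles_left = cs_l.n_cycles
    rep.n_cycles_right = cs_r.n_cycles
    rep.rnd_left_cycles, rep.rnd_left = rnd(cs_l, tr_l)
    rep.rnd_right_cycles, rep.rnd_right = rnd(cs_r, tr_r)
    rep.shimmer_left = shimmer(cs_l)
    rep.shimmer_right = shimmer(cs_r)
    rep.jitter_left = jitter(cs_l)
    rep.jitter_right = jitter(cs_r)

    cs_j = joint_cycles(tr_l, tr_r, f0, prominence_frac)
    rep.n_cycles_joint = cs_j.n_cycles
    if cs_j.n_cycles >= 1:
        rnd_l = _cycle_rnd(tr_l.values, cs_j)
        rnd_r = _cycle_rnd(tr_r.values, cs_j)
        rep.q_rnd_cycles, rep.q_rnd_mean, _ = q_rnd(rnd_l, rnd_r)

    phi_l = instantaneous_phase(tr_l.values, M.fps, f0, backend)
    phi_r = instantaneous_phase(tr_r.values, M.fps, f0, backend)
    rep.phase_diff = lateral_phase_difference(phi_l, phi_r)
    _, rep.phase_diff_opening, rep.phase_diff_full = phase_difference_profile(
        M, f0, backend, opening_threshold
    )
    return rep
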