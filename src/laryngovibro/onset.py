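"""Voice-onset analysis: phase segmentation and adduction quantification.

A non-stationary recording of a voice onset divides into three phases: the
pre-phonatory phase (vocal-fold adduction, no oscillation), the onset phase
(from the first fold oscillations up to and including the first cycle that
reaches full glottal closure), and sustained phonation.  Adduction speed is
quantified by the slope (degrees/second) of an ordinary least-squares fit
to the opening angle Gamma(t) over a fixed window immediately preceding the
start of oscillation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_masks import GAWSeries, LabelMaskSequence, compute_gaw
from .landmarks import OpeningAngleSeries, opening_angle
from .measures import (
    F0_BAND,
    Trajectory,
    UndefinedF0Error,
    _dominant_frequency,
    segment_cycles,
)

PRE_WINDOW = 1000  # frames (250 ms at 4000 fps)


class NoOnsetError(ValueError):
    """The sequence contains no transition into oscillation."""


@dataclass
class OnsetProfile:
    """Phase boundaries and adduction metrics of one voice onset."""

    t_osc_start: int
    t_first_closure: int | None  # None: oscillation never fully closes
    pre_phonatory: tuple[int, int]  # [start, end) frame interval
    onset: tuple[int, int]  # [t_osc_start, t_first_closure]
    sustained: tuple[int, int]
    n_onset_cycles: int  # complete open cycles before the closing cycle
    gamma_slope: float | None  # degrees/second, negative = adduction
    regression_window: int
    f0_sustained: float | None
    open_ended: bool = False


def _oscillation_envelope(gaw: GAWSeries,
                          band: tuple[float, float] = F0_BAND) -> np.ndarray:
    """Magnitude of the analytic signal of the band-passed GAW.

    The GAW of a rasterized scene moves in discrete area jumps; a short
    moving average (~1 ms) spreads those staircase impulses before the
    band-pass so that slow adduction ramps do not masquerade as
    oscillation energy.
    """
    nyq = gaw.fps / 2.0
    hi = min(band[1], 0.95 * nyq)
    width = max(1, int(round(gaw.fps / 1000.0)))
    x = np.convolve(gaw.values, np.ones(width) / width, mode="same")
    sos = sps.butter(4, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    # causal filtering: a zero-phase pass would smear the oscillation
    # onset backward by the filter ringing and bias the detected start
    filtered = sps.sosfilt(sos, x - x[0])
    return np.abs(sps.hilbert(filtered))


def segment_onset_phases(gaw: GAWSeries, threshold_frac: float = 0.1,
                         closure_tol: float = 0.0,
                         pre_window: int = PRE_WINDOW):
    """Locate the oscillation start and the first full-closure cycle.

    The oscillation start is the first frame where the envelope of the
    band-passed GAW exceeds ``threshold_frac`` of its sustained-phase level
    (median over the last quarter of the sequence).  Cycles are then
    delimited on the GAW; the onset phase ends with the first cycle whose
    GAW minimum reaches ``closure_tol`` pixels.
    """
    T = len(gaw.values)
    env = _oscillation_envelope(gaw)
    sustained_level = np.median(env[3 * T // 4:])
    if sustained_level <= 0:
        raise NoOnsetError("no oscillation found in the sequence")
    threshold = threshold_frac * sustained_level
    # persistent exceedance: ignore transient blips (filter start-up,
    # single-frame segmentation jumps) shorter than ~5 ms
    hold = max(1, int(round(gaw.fps / 200.0)))
    edge_skip = int(round(gaw.fps / 25.0))  # causal-filter start-up region
    above = env > threshold
    above[:edge_skip] = False
    runs = np.convolve(above.astype(float), np.ones(hold), mode="valid")
    sustained_above = runs >= hold  # above[i : i + hold] all exceed
    if not sustained_above.any():
        raise NoOnsetError("no transition into oscillation found")
    t_osc_start = int(np.argmax(sustained_above))
    if t_osc_start <= edge_skip + hold:
        raise NoOnsetError(
            "sequence already oscillating at frame 0 (no pre-phonatory "
            "phase)"
        )

    # cycle segmentation on the GAW from the oscillation start onward
    tail = Trajectory(values=gaw.values[t_osc_start:], side="gaw", p=0.5,
                      fps=gaw.fps)
    try:
        f0 = _dominant_frequency(gaw.values[3 * T // 4:], gaw.fps)
    except UndefinedF0Error:
        f0 = None
    cs = segment_cycles(tail, f0_hint=f0)

    # the oscillation start itself opens the first cycle: prepend it when
    # the first detected minimum lies a at least half period downstream
    bounds = list(zip(cs.starts.tolist(), cs.ends.tolist()))
    t0_est = (gaw.fps / f0) if f0 else (
        float(np.median(cs.periods)) if cs.n_cycles else 0.0)
    if bounds and bounds[0][0] >= 0.5 * t0_est:
        bounds.insert(0, (0, bounds[0][0]))

    # closures are attributed to the cycle they end, so the shared start
    # boundary is excluded; a closure candidate within the first half
    # period after the detected onset is the tail of the adducted
    # pre-phonatory phase, not an oscillation cycle
    t_first_closure = None
    n_open = 0
    for s, e in bounds:
        lo = t_osc_start + s + 1
        win = gaw.values[lo:t_osc_start + e + 1]
        if win.size and win.min() <= closure_tol and (
                lo + int(np.argmin(win)) - t_osc_start >= 0.5 * t0_est):
            t_first_closure = int(t_osc_start + e)
            break
        n_open += 1

    pre_start = max(0, t_osc_start - pre_window)
    open_ended = t_first_closure is None
    if open_ended:
        warnings.warn("oscillation never reaches full closure; onset phase "
                      "is open-ended", stacklevel=2)
        onset_iv = (t_osc_start, T - 1)
        sustained_iv = (T - 1, T - 1)
    else:
        onset_iv = (t_osc_start, t_first_closure)
        sustained_iv = (t_first_closure + 1, T)
    return {
        "t_osc_start": t_osc_start,
        "t_first_closure": t_first_closure,
        "pre_phonatory": (pre_start, t_osc_start),
        "onset": onset_iv,
        "sustained": sustained_iv,
        "n_onset_cycles": n_open,
        "open_ended": open_ended,
    }


def angular_velocity(gamma: OpeningAngleSeries, window_end: int,
                     window: int = PRE_WINDOW) -> float:
    """OLS slope of Gamma(t) vs time in seconds over the ``window`` frames
    preceding ``window_end``; negative values indicate adduction."""
    start = window_end - window
    if start < 0:
        warnings.warn(
            f"only {window_end} frames available before the onset; "
            "shortening the regression window", stacklevel=2)
        start = 0
    y = gamma.gamma[start:window_end]
    if len(y) < 2:
        raise ValueError("regression window holds fewer than 2 frames")
    t = np.arange(start, window_end) / gamma.fps
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def analyze_onset(seq: LabelMaskSequence, window: int = 150,
                  overlap: int = 25,
                  regression_window: int = PRE_WINDOW,
                  closure_tol: float = 0.0) -> OnsetProfile:
    """Full voice-onset analysis of a mask sequence."""
    from .builder import prepare_landmarks
    from .landmarks import vibrational_axes
    from .measures import estimate_f0

    # no closure merging here: merged posterior points force the opening
    # angle to zero a full smoothing window before the folds meet
    lm, axes, gaw = prepare_landmarks(seq, window=window, overlap=overlap,
                                      merge_closure=False)
    gamma = opening_angle(axes, seq.fps)
    phases = segment_onset_phases(gaw, closure_tol=closure_tol,
                                  pre_window=regression_window)
    slope = angular_velocity(gamma, phases["t_osc_start"], regression_window)

    f0_sus = None
    s0, s1 = phases["sustained"]
    if s1 - s0 > 50:
        try:
            f0_sus = _dominant_frequency(gaw.values[s0:s1], gaw.fps)
        except UndefinedF0Error:
            pass
    return OnsetProfile(
        t_osc_start=phases["t_osc_start"],
        t_first_closure=phases["t_first_closure"],
        pre_phonatory=phases["pre_phonatory"],
        onset=phases["onset"],
        sustained=phases["sustained"],
        n_onset_cycles=phases["n_onset_cycles"],
        gamma_slope=slope,
        regression_window=regression_window,
        f0_sustained=f0_sus,
        open_ended=phases["open_ended"],
    )
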