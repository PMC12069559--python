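"""Synthetic vocal-fold kinematics with known ground truth.

Generates label-mask sequences emulating segmented laryngeal high-speed
video, so every pipeline stage can be validated against analytic ground
truth without clinical recordings.  The geometric model:

* The folds meet at the midline column; each fold's medial edge is the
  midline displaced laterally by a half-sine spatial mode (zero at the
  posterior point and the anterior commissure, maximal mid-fold) times a
  raised-sinusoid time course ``a * (1 + sin(theta(t) + phi_side))`` that
  touches the midline (full closure) once per cycle, so the per-cycle
  peak-to-peak normalized deflection is ``2 a``.
* Cycle-wise perturbations draw independent per-cycle amplitude factors
  and period factors, giving controllable shimmer and jitter.
* A wedge term hinged at the anterior commissure opens the folds dorsally
  by a prescribed opening angle: a linear adduction ramp (voice onset) or
  a constant divergence (paresis resting position).
* A polyp is a static medial bump on one fold; with a blocked opening the
  folds are forced into contact from the bump to the anterior commissure.
* Overshoot is a shared medial-edge offset toward one side, active during
  the closed phase, producing equal-magnitude opposite-sign deflections.

Defaults mirror a typical clinical acquisition: 256 x 256 px frames at
4000 fps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_masks import (
    BACKGROUND,
    GLOTTIS,
    LEFT_VF,
    RIGHT_VF,
    LabelMaskSequence,
    write_mask_sequence,
)


class SpecError(ValueError):
    """Geometrically impossible generator specification."""


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording (all fractions are relative
    to the vibrational-axis length)."""

    # geometry
    height: int = 256
    width: int = 256
    fps: float = 4000.0
    n_frames: int = 2000
    dorsal_row: int = 48
    ventral_row: int = 208
    fold_halfwidth: int = 88  # lateral extent of each fold band, px

    # oscillation
    f0: float = 125.0
    amp_left: float = 0.035  # normalized amplitude fraction a_l
    amp_right: float = 0.035
    phase_offset: float = 0.0  # rad, added to the left fold
    amp_jitter: float = 0.0  # sd of per-cycle amplitude factor
    period_jitter: float = 0.0  # sd of per-cycle period factor

    # wedge opening (degrees): constant divergence or adduction ramp
    wedge_deg: float = 0.0
    onset: bool = False
    gamma_start_deg: float = 0.0
    adduction_rate_deg_s: float = 0.0  # negative = adduction
    n_open_cycles: int = 4  # open cycles before the first closure
    onset_residual_gap: float = 0.02  # initial extra gap fraction

    # lesion / overshoot
    polyp_position: float | None = None  # p0 along the fold
    polyp_extent: float = 0.25
    polyp_height: float = 0.06
    polyp_blocked: bool = False
    overshoot: float = 0.0  # shared offset fraction, toward the right fold

    # deterministic cycle-period pattern (frames), cycled; overrides
    # period_jitter when set
    period_pattern: tuple | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amp_left", "amp_right", "overshoot",
                     "amp_jitter", "period_jitter"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise SpecError(f"{name} must lie in [0, 1)")
        if not 0 < self.f0 < self.fps / 2:
            raise SpecError("f0 must lie below the Nyquist frequency")
        if not 0 <= self.dorsal_row < self.ventral_row < self.height:
            raise SpecError("axis rows must satisfy 0 <= dorsal < ventral < H")
        L = self.ventral_row - self.dorsal_row
        max_disp = (max(self.amp_left, self.amp_right) * 2 + self.overshoot
                    + self.onset_residual_gap) * L
        if max_disp + self.fold_halfwidth > self.width / 2 - 1:
            raise SpecError("folds would leave the frame; reduce amplitudes")

    @property
    def axis_length(self) -> float:
        return float(self.ventral_row - self.dorsal_row)


def _cycle_schedule(spec: SyntheticSpec, n_osc_frames: int, rng):
    """Per-cycle periods (frames) and amplitude factors for both folds."""
    T0 = spec.fps / spec.f0
    if spec.period_pattern:
        T0 = float(np.mean(spec.period_pattern))
    n_cycles = int(np.ceil(n_osc_frames / T0)) + 2
    if spec.period_pattern:
        periods = np.resize(np.asarray(spec.period_pattern, dtype=float),
                            n_cycles)
    else:
        periods = T0 * (1.0 + spec.period_jitter
                        * rng.standard_normal(n_cycles))
        periods = np.clip(periods, 0.5 * T0, 1.5 * T0)
    amp_fac = {
        side: 1.0 + spec.amp_jitter * rng.standard_normal(n_cycles)
        for side in ("left", "right")
    }
    for side in amp_fac:
        amp_fac[side] = np.clip(amp_fac[side], 0.1, 2.0)
    return periods, amp_fac


def _phase_and_cycle(periods: np.ndarray, tau: np.ndarray):
    """Continuous oscillation phase theta(tau) (starting at closure,
    theta = -pi/2) and the 0-based cycle index per frame."""
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    idx = np.searchsorted(bounds, tau, side="right") - 1
    idx = np.clip(idx, 0, len(periods) - 1)
    frac = (tau - bounds[idx]) / periods[idx]
    theta = 2.0 * np.pi * (idx + frac) - np.pi / 2.0
    return theta, idx, bounds


def generate_sequence(spec: SyntheticSpec):
    """Render the mask sequence and its ground-truth manifest.

    Returns ``(LabelMaskSequence, manifest)`` where the manifest records
    the exact per-cycle amplitudes and periods, the imposed phase offset,
    the opening angle per frame and the oscillation start frame.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_frames
    H, W = spec.height, spec.width
    L = spec.axis_length
    mid = (W - 1) / 2.0  # midline column (127.5 for W=256)
    rows = np.arange(spec.dorsal_row, spec.ventral_row + 1)
    p = (rows - spec.dorsal_row) / L  # relative position per row
    spatial = np.sin(np.pi * p)  # half-sine mode, zero at P and A
    lever = spec.ventral_row - rows  # wedge lever arm, hinged at A

    # --- temporal structure -------------------------------------------------
    if spec.onset:
        if spec.adduction_rate_deg_s >= 0 or spec.gamma_start_deg <= 0:
            raise SpecError("onset requires gamma_start_deg > 0 and a "
                            "negative adduction rate")
        n_pre = int(round(spec.gamma_start_deg
                          / abs(spec.adduction_rate_deg_s) * spec.fps))
        if n_pre >= T:
            raise SpecError("adduction ramp longer than the sequence")
    else:
        n_pre = 0
    n_osc = T - n_pre
    periods, amp_fac = _cycle_schedule(spec, n_osc, rng)
    tau = np.arange(n_osc, dtype=float)
    theta, cyc_idx, bounds = _phase_and_cycle(periods, tau)

    # wedge half-angle per frame (radians); constant divergence or ramp
    gamma_deg = np.zeros(T)
    if spec.onset:
        ramp = spec.gamma_start_deg * (1.0 - np.arange(n_pre) / n_pre)
        gamma_deg[:n_pre] = ramp
    elif spec.wedge_deg > 0:
        gamma_deg[:] = spec.wedge_deg
    half_wedge = np.tan(np.radians(gamma_deg) / 2.0)

    # residual opening gap during the onset phase (fraction of L)
    # extra glottal gap during the onset phase: held through the open
    # cycles, then ramped to zero inside the following (closing) cycle
    residual = np.zeros(n_osc)
    if spec.onset:
        T0 = spec.fps / spec.f0
        hold = spec.n_open_cycles * T0
        ramp = 0.6 * T0
        residual = spec.onset_residual_gap * np.clip(
            1.0 - (tau - hold) / ramp, 0.0, 1.0)

    # --- per-frame medial-edge displacements (pixels), (T, n_rows) ----------
    osc = np.zeros((T, rows.size, 2))  # [:, :, 0] left, [:, :, 1] right
    envelope = 1.0 + np.sin(theta[:, None] + spec.phase_offset)
    osc[n_pre:, :, 0] = (spec.amp_left * amp_fac["left"][cyc_idx][:, None]
                         * envelope)
    osc[n_pre:, :, 1] = (spec.amp_right * amp_fac["right"][cyc_idx][:, None]
                         * (1.0 + np.sin(theta[:, None])))
    osc[n_pre:] += residual[:, None, None]
    osc *= (L * spatial)[None, :, None]

    g_l = osc[:, :, 0] + half_wedge[:, None] * lever[None, :]
    g_r = osc[:, :, 1] + half_wedge[:, None] * lever[None, :]

    if spec.polyp_position is not None:
        bump = np.cos(np.pi * (p - spec.polyp_position)
                      / spec.polyp_extent) ** 2
        bump[np.abs(p - spec.polyp_position) > spec.polyp_extent / 2] = 0.0
        g_r = g_r - spec.polyp_height * L * bump[None, :]
        if spec.polyp_blocked:
            # forced contact from the lesion to the commissure: both edges
            # meet at the line midway between them (the polyp indents the
            # opposite fold)
            blocked = p >= spec.polyp_position - spec.polyp_extent / 2
            contact = (g_r - g_l) / 2.0
            g_l[:, blocked] = -contact[:, blocked]
            g_r[:, blocked] = contact[:, blocked]

    e_l = mid - g_l
    e_r = mid + g_r
    # contact where the polyp (or asymmetry) pushes the edges across
    cross = e_r < e_l
    if cross.any():
        mean = (e_l + e_r) / 2.0
        e_l = np.where(cross, mean, e_l)
        e_r = np.where(cross, mean, e_r)

    if spec.overshoot > 0:
        shift = np.zeros((T, rows.size))
        active = np.clip(-np.sin(theta), 0.0, None)
        shift[n_pre:] = (spec.overshoot * L
                         * active[:, None] * spatial[None, :])
        e_l = e_l + shift
        e_r = e_r + shift

    # --- rasterize ----------------------------------------------------------
    cols = np.arange(W)
    frames = np.zeros((T, H, W), dtype=np.uint8)
    band = slice(spec.dorsal_row, spec.ventral_row + 1)
    left_max = np.floor(e_l).astype(int)  # pixel centres <= e_l
    right_min = np.ceil(e_r).astype(int)
    lat_lo = int(np.floor(mid)) - spec.fold_halfwidth
    lat_hi = int(np.ceil(mid)) + spec.fold_halfwidth
    c = cols[None, None, :]
    left_mask = (c >= lat_lo) & (c <= left_max[:, :, None])
    right_mask = (c <= lat_hi) & (c >= right_min[:, :, None])
    glottis_mask = (c > left_max[:, :, None]) & (c < right_min[:, :, None])
    sub = frames[:, band, :]
    sub[left_mask] = LEFT_VF
    sub[right_mask] = RIGHT_VF
    sub[glottis_mask] = GLOTTIS
    frames[:, band, :] = sub

    seq = LabelMaskSequence(frames=frames, fps=spec.fps, dorsal_at_top=True)

    # --- ground truth -------------------------------------------------------
    complete = bounds[1:] <= n_osc  # cycles fully inside the recording
    n_complete = int(np.count_nonzero(complete))
    manifest = {
        "spec": asdict(spec),
        "axis_length_px": L,
        "f0_hz": spec.f0,
        "phase_offset_rad": spec.phase_offset,
        "t_osc_start": n_pre,
        "n_complete_cycles": n_complete,
        "cycle_periods_frames": periods[:n_complete].tolist(),
        "cycle_amplitudes_left": (
            2.0 * spec.amp_left * amp_fac["left"][:n_complete]).tolist(),
        "cycle_amplitudes_right": (
            2.0 * spec.amp_right * amp_fac["right"][:n_complete]).tolist(),
        "gamma_deg": gamma_deg.tolist(),
        "adduction_rate_deg_s": spec.adduction_rate_deg_s if spec.onset else 0.0,
        "n_open_cycles": spec.n_open_cycles if spec.onset else 0,
    }
    return seq, manifest


# --- canonical scenarios ----------------------------------------------------

def healthy_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Sustained phonation of a healthy larynx: near-symmetric amplitudes,
    small cycle-to-cycle perturbations, slight inter-fold phase lag."""
    defaults = dict(amp_left=0.0333, amp_right=0.035, phase_offset=0.1,
                    amp_jitter=0.033, period_jitter=0.043, f0=125.0,
                    seed=seed)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def symmetric_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Perfectly symmetric, unperturbed phonation (identity checks)."""
    defaults = dict(amp_left=0.035, amp_right=0.035, seed=seed)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def paresis_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Unilateral paresis: reduced right amplitude, resting divergence,
    raised perturbations."""
    defaults = dict(amp_left=0.04, amp_right=0.02, phase_offset=0.3,
                    amp_jitter=0.07, period_jitter=0.1, wedge_deg=3.0,
                    f0=110.0, seed=seed)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def polyp_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Unilateral polyp on the right fold at 63% of the fold length,
    extent 25%, blocking the opening from the lesion to the commissure."""
    defaults = dict(amp_left=0.025, amp_right=0.025, amp_jitter=0.1,
                    period_jitter=0.15, polyp_position=0.63,
                    polyp_extent=0.25, polyp_height=0.06,
                    polyp_blocked=True, f0=140.0, seed=seed)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def overshoot_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Joint closed-phase excursion of both folds beyond their axes."""
    defaults = dict(amp_left=0.035, amp_right=0.035, overshoot=0.02,
                    amp_jitter=0.02, period_jitter=0.02, seed=seed)
    defaults.update(kw)
    return SyntheticSpec(**defaults)


def onset_spec(seed: int = 0, hard: bool = False, **kw) -> SyntheticSpec:
    """Voice onset: linear adduction ramp, then oscillation that reaches
    full closure after four open cycles.  'Hard' uses a steeper ramp and a
    higher pitch."""
    if hard:
        defaults = dict(gamma_start_deg=24.22, adduction_rate_deg_s=-85.35,
                        f0=210.0)
    else:
        defaults = dict(gamma_start_deg=18.98, adduction_rate_deg_s=-61.07,
                        f0=178.0)
    defaults.update(dict(onset=True, n_frames=2400, amp_left=0.033,
                         amp_right=0.035, seed=seed))
    defaults.update(kw)
    return SyntheticSpec(**defaults)


SCENARIOS = {
    "healthy": healthy_spec,
    "symmetric": symmetric_spec,
    "paresis": paresis_spec,
    "polyp": polyp_spec,
    "overshoot": overshoot_spec,
    "onset": onset_spec,
}


def write_fixture_suite(out_dir, seed: int = 0, **overrides) -> list[Path]:
    """Write the canonical seeded fixtures: three healthy repeats, paresis,
    polyp, overshoot, and a normal and a hard voice onset (8 sequences with
    ground-truth manifests).  Deterministic for a fixed seed; ``overrides``
    (e.g. ``n_frames``) apply to every scenario."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jobs = [
        ("healthy_rep1", healthy_spec(seed, **overrides)),
        ("healthy_rep2", healthy_spec(seed + 1, **overrides)),
        ("healthy_rep3", healthy_spec(seed + 2, **overrides)),
        ("paresis", paresis_spec(seed + 3, **overrides)),
        ("polyp", polyp_spec(seed + 4, **overrides)),
        ("overshoot", overshoot_spec(seed + 5, **overrides)),
        ("onset_normal", onset_spec(seed + 6, hard=False, **overrides)),
        ("onset_hard", onset_spec(seed + 7, hard=True, **overrides)),
    ]
    written = []
    for name, spec in jobs:
        seq, manifest = generate_sequence(spec)
        tif = out_dir / f"{name}.tif"
        write_mask_sequence(seq, tif, out_dir / f"{name}.json")
        (out_dir / f"{name}_manifest.json").write_text(
            json.dumps(manifest))
        written.append(tif)
    return written
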