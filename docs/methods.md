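# Methods

This note documents the models, estimators and numerical choices behind
the package, and what the synthetic validation does and does not show.

## Geometry extraction

**Contours.** Region outlines are traced with marching squares at level
0.5 on per-label binary masks, giving closed polylines at half-pixel
precision with stable perimeter geometry for distance computations. When a
fold label splits into several connected components (segmentation
speckle), the largest is kept and a warning is emitted; an absent fold
label is an error, an empty glottis is a valid closed state. All
coordinates are 0-based `(row, col)` with the dorsal end at row 0 after
orientation normalization (the sidecar's `dorsal_at_top` flag is applied
on load).

**Landmarks.** The posterior point of each fold is the most dorsal pixel
of that fold 8-adjacent to the opposite fold or the glottis; the anterior
commissure is the most ventral contact point between the two folds,
averaged over both folds' adjacency sets so it is unbiased under mirror
symmetry. Row ties average the columns. A half-pixel correction moves each
posterior point from the pixel centre to the region boundary (away from
the fold's own centroid); without it every opening angle is inflated by a
constant ≈ 2·atan(0.5/L).

**Temporal stabilization.** Landmarks are smoothed with a sliding window
of 150 frames overlapping by 25: the coordinate-wise *median* per window is
assigned to the window centre and linearly interpolated between centres
(edge frames take the nearest centre). The median was chosen over the mean
for robustness to single-frame landmark jumps; both the aggregator and the
interpolation are configurable. If the glottal area waveform (GAW) reaches
zero anywhere inside a window, complete closure is assumed there and the
two posterior points are merged to the midpoint of their window medians,
making the two vibrational axes coincide.

For **voice-onset analysis** the closure merge is disabled
(`merge_closure=False`): merging zeroes the opening angle for every window
that touches a closure instant, i.e. up to a full window before the folds
actually meet, which systematically steepens the measured adduction slope.
The merge exists to stabilize the LVG axes during sustained phonation and
is kept there.

## LVG construction

Each fold's closed contour is cut at the vertices nearest P and A; the
medial arc (the one with the smaller mean lateral offset) is kept and
ordered P→A. Deflections are exact point-to-segment distances — the
minimizing axis position is continuous, interior points use the
perpendicular foot and points beyond the ends the end-point distance —
divided by the axis length. The sign is decided by the side of the axis:
positive on the side of the fold body (contour centroid), negative beyond
the axis toward the opposite fold, zero within 1e-9 of the axis. Signed
values are resampled by cumulative arc length to 256 equidistant positions
with linear interpolation. No clamping is applied; deflections larger than
the axis length would pass through unchanged.

The stored matrix keeps both halves posterior→anterior (rows 0–255 left,
256–511 right), which makes trajectory indexing `round(p·255)` uniform;
the mirrored display layout (posterior edges facing the outer borders) is
applied at render time only. The conceptual 180° rotation of the left fold
is a visualization device — per-fold distances are rotation invariant — so
no coordinate transform is performed.

Because every quantity is a Euclidean distance ratio, the matrix is
invariant under uniform scaling and rigid rotation of all input
coordinates (verified to 1e-3; numerically it holds to machine precision
at the geometry level).

The per-position glottal gap (distance between the resampled left and
right edges, normalized by the mean axis length) is stored alongside the
matrix; the *glottal-opening range* is the set of positions whose
time-maximum gap exceeds 1 % of the axis length (configurable).

**PVG baseline.** The glottal symmetry axis joins the dorsal-most and
ventral-most glottis contour points, smoothed with the same 150/25 window
(windows with no open frame are skipped and interpolated across). The
glottal outline is split at this axis; each half's axis distances,
normalized by glottal axis length, are resampled to 256 points ordered by
axis projection. Closed frames give zero columns. The medial-PVG position
is the time-averaged glottal-axis midpoint projected onto the fold-axis
parameterization.

## Cycle segmentation and perturbation measures

Cycles are delimited at successive minima of the trajectory after a light
moving average (odd width ≈ fps/(4·f₀); an even window would shift the
series by half a sample). Minima are found by peak detection on the
negated series with prominence ≥ 10 % of the peak-to-peak range
(configurable); partial leading/trailing cycles are discarded. Per-cycle
amplitudes A_j are peak-to-peak ranges of the *raw* series within the
cycle — RND(p,j) is exactly this quantity ×100.

**Sub-frame boundary refinement.** At glottal closure the trajectory
minimum is flat (tangential contact plus pixel discretization), and the
plateau centre drifts toward the longer neighbouring cycle, which shrinks
measured period differences and biases jitter low. Each boundary is
therefore refined as the slope-weighted mean of the two crossings of a
threshold at 40 % of the local range: for a waveform whose shape scales
with the local period the period-dependent crossing offsets cancel exactly
under slope weighting. The 40 % level keeps the crossings on the steep
branch, away from both the flattened trough and the rounded peaks; at 25 %
the residual smoothing asymmetry still shrank jitter by ~13 %, at 40 % by
~7 %. Boundaries closer than 0.35 periods to the series edge are left
unrefined (their outer flank is truncated). Integer boundaries are kept
for amplitude windows; the refined (float) spacings feed jitter.

Q_RND pairs left and right cycles by a joint segmentation of
|D_l| + |D_r|, so Eq.-style per-cycle ratios share a common cycle index;
pairs with both RNDs zero are skipped and counted.

**Phase.** Instantaneous phase is the argument of the complex Morlet
(ω₀ = 6, implemented as the `cmor2.0-0.9549` wavelet) transform at the
scale matching F₀; a Hilbert analytic-signal backend is available for
cross-checking. The lateral phase difference wraps φ_l − φ_r onto (−π, π]
on the unit circle per frame, then takes the absolute arithmetic time
average (arg inside the sum). A circular-mean variant (arg of the averaged
unit phasors) is selectable; the two differ only for broad or bimodal
phase-difference distributions. Aggregates average the per-position values
over the opening range (ΔΘ̄_op) and over all 256 positions (ΔΘ̄_LVG) —
per-position first, then the arithmetic mean across positions.

**F₀** is the dominant peak of the Hann-windowed, zero-padded periodogram
of the mean-removed GAW in 50–500 Hz, refined by log-parabolic
interpolation; a peak below 10× the in-band median power is rejected as
noise. Under cycle-period perturbation the estimate tracks the realized
mean cycle rate of the recording, which can differ from the nominal f₀ of
a generator by a few Hz over short sequences.

## Voice onset

The oscillation start is detected on the magnitude of the analytic signal
of the band-passed (50–500 Hz) GAW, *causally* filtered — zero-phase
filtering smears the onset backward by the filter ringing and biases the
detected start early by tens of frames. The GAW is pre-smoothed with a
~1 ms moving average so that the discrete area jumps of a slowly adducting
(rasterized or coarsely segmented) glottis do not masquerade as
oscillation energy. The start is the first frame where the envelope
exceeds 10 % of the sustained-phase median persistently (≈5 ms), ignoring
the causal filter's start-up region (~fps/25 frames). Cycles are then
delimited on the GAW; the onset phase ends with the first cycle whose GAW
minimum reaches zero pixels (a closure tolerance is available for leaky
closure), closures being attributed to the cycle they end. The
pre-phonatory phase is the 1000 frames (250 ms at 4000 fps) before the
start. Adduction speed γ is the OLS slope of Γ(t) against time in seconds
over that window; the window is shortened with a warning when fewer frames
exist.

## Synthetic kinematics

The generator emulates, at the level of label masks, the features the
pipeline measures — it is a kinematic phantom, not an image model:

- folds meet at the midline column; each medial edge is displaced
  laterally by a half-sine spatial mode (zero at P and A, maximal
  mid-fold, matching the observation that amplitude peaks near the middle
  of the membranous fold) times a raised sinusoid
  a·(1 + sin θ(t) + φ_side) that touches the midline once per cycle —
  per-cycle peak-to-peak normalized deflection is exactly 2a;
- θ(t) advances 2π per cycle over per-cycle durations T₀(1 + η_j); the
  per-cycle amplitude factor is (1 + ξ_j); η, ξ are independent Gaussian
  draws per cycle (and per side for ξ), fully determined by the seed. A
  deterministic period pattern can replace the random schedule;
- a wedge hinged at the anterior commissure opens the folds dorsally by a
  prescribed angle: a linear ramp for adduction (onset) or a constant
  divergence (paresis resting position);
- a polyp is a static raised-cosine medial bump on the right fold
  (defaults: centre 63 % of fold length, extent 25 %, height 6 % — a
  ventral-medial lesion); with `polyp_blocked` the folds are forced into
  contact from the lesion to the commissure, indenting the opposite fold;
- overshoot shifts both medial edges toward one side during the closed
  phase, producing equal-magnitude opposite-sign deflection bands;
- defaults mirror a typical clinical acquisition: 256×256 px, 4000 fps,
  axis length 160 px; the healthy scenario uses f₀ = 125 Hz, amplitude
  fractions 0.0333/0.035, amplitude/period perturbations of 3.3 %/4.3 %
  and a 0.1 rad inter-fold lag, placing RND, shimmer, jitter, Q_RND and
  ΔΘ̄ in the healthy clinical range; onset scenarios use
  (Γ₀ = 18.98°, γ = −61.07°/s, f₀ = 178 Hz) and
  (24.22°, −85.35°/s, 210 Hz), with full closure after four open cycles.

What the phantom does **not** model: real edge roughness and segmentation
error, superior–inferior motion of the visible edge, mucosal-wave
propagation, camera illumination, and fold-axis obliquity to the pixel
grid. The last point matters for interpretation: with grid-aligned axes,
deflections quantize to 1-pixel steps (1/L ≈ 0.6 % of axis length). Mean
quantities (RND, Q_RND, phase, F₀) are essentially unaffected, but
*differences* of per-cycle amplitudes fall below the quantization floor
when the imposed shimmer is healthy-scale (~3–4 %); the parameter-recovery
cohort therefore imposes pathological-scale perturbations (shimmer ~13 %,
jitter ~11 %, the clinical polyp/paresis range), where recovery within
15 % is demonstrated. Passing tests show the estimators are correct and
unbiased above the discretization floor; they do not certify sensitivity
to sub-pixel amplitude variation.

## Validation problem sizes

The test suite generates its data at run time: identity and structural
checks on a 600-frame symmetric sequence; recovery checks on a 1200-frame
healthy sequence; the seeded recovery cohort uses 50 replicates of 2000
frames (256×256 px, 4000 fps) with imposed amplitude ratio 0.7, phase
offset 0.3 rad and the pathological perturbation magnitudes above; onset
checks use full 2400-frame ramp-plus-phonation sequences and 20-seed noisy
regression at σ = 0.5°. Fixture-suite and CLI tests use shorter, smaller
frames purely as I/O round-trip material.

## Known limitations

- Landmarks come from label adjacency only; anatomically exact
  localization of the processus vocalis is out of scope (P is an
  approximation by construction).
- The closure-merge rule is window-granular: axes coincide for a whole
  window once any closure occurs in it.
- Jitter retains a small negative bias (~7 % relative at clinical
  magnitudes) from residual smoothing asymmetry at cycle boundaries.
- Γ is reported only over the observed window; no extrapolation toward
  maximal adduction is attempted, and the maximum observed angle need not
  reflect it.
- The colormap and layout of rendered images are a documented convention,
  not a fidelity claim.
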