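# Methods

## Coordinate and sign conventions

Kymographs are stored with rows = frames (time increasing downward) and
columns = distance along the neurite, increasing toward the growth cone.
Anterograde motion therefore has positive slope (p/f). Readers normalise
other orientations via `flip_x` / `flip_t`. Velocity profiles use distances
relative to the T-zone: 0 at the retrograde→anterograde transition,
positive toward the axon, negative into the P-domain.

Calibration is never defaulted: physical units require an explicit pixel
size (μm) and frame interval (s), supplied as arguments, a JSON sidecar
(`pixel_size_um`, `frame_interval_s`), or ImageJ-style TIFF tags, in that
order of precedence. 1 p/f = pixel_size / frame_interval × 3600 μm/h.

## The flow estimator

`lk_flow` solves the 1-D brightness-constancy equation I_x·v + I_t = 0 by
least squares over a square window of Gaussian-smoothed derivatives.
Numerical choices:

- **Pre-smoothing** `smoothing_sigma = 2.5 px`. The dominant error of a
  discrete gradient estimator on an oriented pattern is a spectral bias
  (the ratio of discrete-derivative transfer functions), which shrinks
  with the square of the pattern's bandwidth; σ = 2.5 keeps the bias below
  ~1% across the full angle sweep while leaving 2-px-wide strokes easily
  detectable.
- **4th-order central differences** (`derivative_order = 4`, stencil
  (−f₂+8f₁−8f₋₁+f₋₂)/12). Plain central differences carry an
  orientation-dependent bias ∝ k²(cos²θ − sin²θ) that vanishes only at
  45°; the 4th-order stencil pushes the residual to O(k⁴), cutting the
  benchmark AAE by an order of magnitude. Order 2 remains available.
- **Window** 9 px, uniform weights: the variance/locality compromise; on
  pure-translation kymographs larger windows only help against noise.
- **Validity.** A pixel is valid when its windowed spatial-gradient energy
  exceeds both an absolute floor (`min_gradient = 1e−6`) and a relative
  floor (`rel_gradient = 5e−3` of the image maximum, rejecting noise-only
  background), lies outside a border margin (window/2 + 2σ + 1, where the
  derivative stencils touch the edge), and its estimate satisfies
  |v| ≤ `max_velocity` (100 p/f — a kymograph cannot resolve motion at
  grid-width scale per frame, and reciprocal blow-ups from the rotated
  branch would otherwise poison column means). Invalid pixels are excluded
  from every statistic; they are never zero-filled.

`kymoflow` runs the same kernel on the original kymograph and its 90°
axis swap. The swap is implemented as the anti-transpose (transpose with
both axes reversed): a lossless involution that maps a streak of slope v
exactly to slope 1/v with the sign preserved, so the back-transform is
v ← 1/v plus the same index map, with |v_rot| < 1e−6 marked invalid
rather than inverted. Branch merging per pixel, with
`switch_threshold = 1 p/f` (the symmetry point of the construction) and a
±20% hysteresis band:

- both branches valid: unrotated below the band, rotated above it, the
  mean of both inside it (their leading biases have opposite sign, so the
  average partially cancels);
- one branch valid: it is used only inside its reliable half-range
  (sub-threshold for the unrotated branch, supra-threshold for the
  rotated), since a lone branch claiming the other regime is almost
  always a gradient artefact.

Only multiples of 90° are merged. Arbitrary-angle rotation of a kymograph
(bicubic) is provided for completeness but deliberately not combined: it
requires resampling (no longer lossless) and adds nothing on 1-D motion.

## The line benchmark

91 kymographs (128×128), one anti-aliased straight line each (2 px wide,
linear coverage profile), rotated from 0° (horizontal = infinitely fast)
to −90° (vertical = stationary) in 1° steps through the grid centre; true
velocity is cot|angle|. Grids are quantized to 8 bits by default, as
exported drawn-trace rasters are; width, intensity, noise, bit depth and
seed are parameters. Statistics are computed on line-support pixels (the
background has no defined ground-truth motion; `--stat-domain` exposes
alternatives).

The AAE converts per-pixel velocities to angles through
θ(v) = −arctan2(1, v) — monotone and continuous through v = 0, mapping
positive v into (−90°, 0°), zero to −90°, and negative v beyond −90°, so
near-stationary estimates average without wrap-around — then takes the
per-image mean angle and averages |mean − truth| over the set. The full
AAE covers −1°…−90°; a restricted AAE covers −3°…−90°. The 0° image
(infinite velocity) is excluded from both, and −90° is excluded only from
velocity-ratio summaries (its true velocity is 0). Per-angle means use
plain arithmetic averaging, legitimate because all angles sit in a single
quadrant.

On the default (noise-free) benchmark both the baseline and the augmented
estimator resolve all angles well — a clean oriented pattern makes the
gradient ratio an easy orientation estimate at any speed — with the
augmented estimator more accurate at every fast angle (AAE 0.037° vs
0.040°, paired t-test p ≈ 1e−4) and within 10% of the true velocity up to
28.6 p/f. The regimes separate sharply under noise (sd 0.1 of line
intensity): the baseline's spatial gradients for near-horizontal lines
drown in noise and its velocity error exceeds 10% beyond ~7 p/f, while
the rotated branch keeps fast estimates accurate; the inversion v = 1/v_rot
does skew the mean of the noisiest fast estimates (a Jensen effect —
medians stay centred), which bounds the augmented estimator's accurate
range under heavy noise to roughly 15–20 p/f.

## The neurite simulator

`synthkymo.simulate_neurite_kymograph` emulates speckle imaging of one
growing neurite at the kymograph level. Defaults are chosen to mimic a
rapidly growing sensory-neuron axon and are the conditions under which
the recovery tests run:

| parameter | default | meaning |
|---|---|---|
| `gc_velocity` | 24 μm/h | growth-cone advance |
| `retro_velocity` | −97 μm/h | P-domain retrograde flow (lab frame) |
| `p_domain_width` | 5 μm | retrograde zone behind the leading edge |
| `decay_length` | 150 μm | exponential friction-like decay of bulk flow with distance from the T-zone (or any `axon_profile` callable) |
| `fast_event_rate_antero/retro` | 0.5 / 0.38 min⁻¹ | Poisson rates of fast transport events |
| `fast_speed_mean/sd` | 0.1 / 0.05 μm/s | event speeds, normal truncated at 0 |
| `speckle_density` | 2 μm⁻¹ | fiducial speckles |
| `noise_sd` | 0.05 | additive Gaussian noise (speckle amplitudes 0.5–1) |
| `duration`, grid | 25 min, 300×256 at 0.1 μm, 5 s | keeps a 24 μm/h cone inside the field |

Speckles advect with the piecewise bulk field (retrograde inside the
P-domain, `axon_profile` along the axon, discontinuity at the T-zone that
advances with the cone); material is replenished at the advancing leading
edge and the proximal boundary, and P-domain speckles are removed when
they reach the T-zone, standing in for actin-network disassembly there.
Fast events are superimposed brighter streaks crossing the centre column
at a uniformly random frame. Ground truth carries the per-pixel bulk flow
(fast events are excluded from it by design), the event list, and the
leading-edge track.

Not emulated: photobleaching, speckle appearance/disappearance kinetics,
2-D growth-cone shape, intensity heterogeneity along the neurite. Passing
recovery tests therefore show the pipeline is correct for idealised
speckle kinematics, not that it is robust to every imaging artefact of
real recordings.

## Alignment, profiles, statistics

- Growth-cone tracking (`edge`): per frame the most distal column above an
  Otsu threshold, gaps interpolated (>50% gaps is an error), median filter
  of 5; velocity from the least-squares slope. A supplied polyline
  (`trace`) bypasses detection; which landmark to track is genuinely open
  (leading edge vs a C-domain feature), so both routes exist.
- Shearing translates each row by −(position[t] − position[0]) with linear
  interpolation; values are moved, never rescaled, so the multiset of
  velocities is preserved up to interpolation. Columns distal of the
  aligned cone column are background and are masked before profiling
  (`mask_beyond_edge`).
- Profiles: column-wise mean over valid pixels with a normal-approximation
  95% CI (1.96·sd/√n); empty columns are dropped. T-zone detection scans
  raw sign changes from the distal end; when several exist, a 5-bin median
  filter (robust to single poisoned bins, which a short moving mean is
  not) picks the physical one, and the crossing is linearly interpolated
  between the raw bracketing bins. Reported values are never smoothed.
  Without any crossing the caller chooses an error or an unaligned flag.
- Across-cell averaging interpolates onto a shared 1-μm grid over the
  intersection of supports; the CI is across cells. Regression is OLS with
  a t-based 95% slope CI; a flat response returns slope 0 with r² = 0
  rather than NaN.
- Endpoint velocity (net displacement over elapsed time) reproduces the
  classic two-point scoring of docked-mitochondria traces and equals the
  time-weighted mean of instantaneous slopes exactly.

## Flux and mass budget

A trace counts toward flux once, regardless of how often it re-crosses
the centre column (speckles are counted, not crossings), provided its
least-squares velocity reaches the fast threshold — 0.05 μm/s by default,
the lower edge of the MT-motor range (0.05–5 μm/s), exposed as a flag
because the field's operational definition (crossing the paths of slower
neighbours) is qualitative. Budget arithmetic is exact in its unrounded
fields; `rounded()` renders the conventional table precision (fluxes
2 d.p., MT/h 1 d.p., transported length to the μm when ≥ 10, growth
1 d.p.). The generated event speeds straddle the fast threshold, so the
counting-unbiasedness tests run at threshold 0 to separate counting from
classification.

## Test-suite problem sizes

Simulation-based tests use the default 300×256 grid; the population
regression uses 20 cells with growth velocities ~N(24, 5²) μm/h coupled
1:1 to bulk flow, and flux recovery uses 100 seeds of an events-only
(speckle-free, 64-column) configuration. Bulk-recovery tests disable fast
events, which are not part of the bulk field being recovered and are
measured by the flux module instead; a companion test keeps them enabled
and tolerates their documented contamination of the P-domain mean. The
whole suite completes in well under a minute.

## Known limitations

- The combined estimator's mean is skew-biased for very fast motion under
  heavy noise (inversion of a noisy near-zero rotated velocity); prefer
  medians, larger windows, or stronger smoothing there.
- Branch selection is per pixel with a fixed threshold; no spatial
  regularisation or confidence weighting across branches.
- Edge-based growth-cone detection assumes the cone is the most distal
  bright structure; debris distal of the cone defeats it (use `trace`).
- Profiles assume a single T-zone; kymographs with several
  retrograde→anterograde transitions are disambiguated by the median
  filter but not modelled.
- Recordings whose growth velocity changes sharply should be split into
  row ranges by the caller; no automatic change-point detection.
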