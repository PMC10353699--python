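# Methods

## Model and assumptions

Particles are treated as passive tracers in the overdamped (creeping
flow) limit: `Re ≪ 1` and `Stk ≪ 1` for every condition studied, so
inertia is neglected and each particle moves at the instantaneous sum of
the local drift velocities plus Brownian noise. Per frame of duration
`Δt = 1/frame_rate` the update is

```
x ← x + [u_conv(x) + v_D(x) + v_T·ĝ + v_attr(ζ)·r̂_tip]·Δt + √(2·D·Δt)·η
```

with `η` standard normal per axis, `v_D = −D_T·∇T` the thermophoretic
drift, `v_T` the Stokes terminal velocity (applied only in the side-view
"vertical" geometry, where gravity lies in the image plane), and
`v_attr` the near-field attraction described below. Forward-Euler
stepping at one step per frame is adequate because all drift speeds are
tens of µm/s and the fields vary over tens to hundreds of µm; optional
sub-stepping (`substeps` parameter) is available for stiffer
configurations. A fixed integer seed drives a single `numpy` generator
per simulation call, recorded in the output, making runs bit-reproducible.

The simulator does **not** solve heat transfer, electromagnetics or
hydrodynamic coupling. The convection plume, the temperature-gradient
field and the attraction law are parametrized stand-ins with the right
ranges and monotonicities, not CFD solutions:

- **Convection**: magnitude `u0·exp(−r/decay_length)` around the tip,
  directed upward ("plume", vertical setups) or radially inward
  ("inflow"), with `decay_length` defaulting to 300 µm — convection is a
  several-hundred-µm-range effect. `u0` defaults to 50 µm/s, an
  order-of-magnitude choice: the source experiments report laser powers
  and resulting particle velocities (tens of µm/s) but never the flow
  field itself, so the plume speed is a free scenario parameter.
- **Temperature gradient**: magnitude `gT0·exp(−r/range)` pointing toward
  the (hot) tip, `range` = 30 µm by default — thermophoresis is a
  few-tens-of-µm near-field effect. `gT0` defaults to 1e5 K/m, again an
  order-of-magnitude choice.
- **Attraction**: `v_attr = k·|ζ|·exp(−r/attraction_range)`, linear in
  the zeta-potential magnitude. No first-principles ζ→force law is
  available for this system; linearity is the simplest monotone choice
  and reproduces the observed ordering (more negative ζ ⇒ stronger
  accumulation). The term is disabled in distilled water ("DIW" medium
  flag): with no dissolved ions there is no Seebeck field to act on the
  particle's double layer. Default `k` = 5e-7 (m/s)/mV puts a −20 mV
  particle at 10 µm/s near the tip, comparable to the convection scale.
- **Capture**: in the top-view geometry a particle entering a capture
  radius of the tip is immobilized. The experiments show persistent
  swarms but no microscopic sticking model; immobilization is the
  simplest rule that produces progressive darkening. Default radius
  2·d_p per particle; accumulation scenarios pass an explicit 12 µm so
  the swarm is spatially extended rather than a point pile.

**Rendering.** Physical coordinates are y-up (gravity −y); images are
y-down with 0-based indices and pixel centers on integers; the renderer
owns the conversion and the kinematics module inverts it. Particles are
anti-aliased disks (edge coverage `clip(r + 0.5 − dist, 0, 1)`) of their
physical radius divided by the pixel size; rods, cocci and chains are
unions of 2–10 overlapping disks with a fixed random orientation, which
affects rendering only. Overlapping particles attenuate the backlight
multiplicatively (each scales local intensity by
`particle_intensity/background`), so one cell renders exactly at
`particle_intensity` while stacked cells in a swarm get darker — this is
what makes image darkness a usable concentration proxy, and it lets a
moderate single-cell contrast coexist with a strongly dark swarm.
Gaussian intensity noise of configurable sd is added and clipped to
[0, 255].

## Analysis choices

- **Detection** uses the scikit-image circular Hough transform on Canny
  edges; the `sensitivity` threshold acts on the normalized accumulator
  (fraction of circle perimeter supported). Duplicate peaks are
  suppressed at a minimum center separation equal to the smallest search
  radius. Accumulator peaks are integer-valued; a sub-pixel refinement by
  darkness-weighted centroid is applied by default (disable with
  `refine=False`), bringing typical center errors from ~0.5 px to ~0.01 px
  on rendered spheres.
- **Linking** is greedy closest-position matching, faithful to the
  per-particle nearest-neighbour description rather than globally optimal
  assignment. Trajectories claim detections in descending head-score
  order; links beyond `max_link_distance` (default 2 × the largest
  radius, to forbid teleporting links) are rejected; exact distance ties
  go to the lowest detection index with a logged warning. Gap bridging
  exists but is off by default — the reference procedure drops
  out-of-focus tracks instead (`reject_out_of_frame` with a minimum
  length fraction).
- **Frame rate is mandatory metadata.** Source recordings exist at both
  30 fps and 28 fps; nothing in the package assumes a rate.
- **Velocities** are per-step finite differences
  `(pos_{i+1} − pos_i)·pixel_size·frame_rate`; ensemble statistics take
  per-trajectory means first, then mean ± sd across trajectories (the sd
  convention across trajectories is this package's choice; error-bar
  semantics are otherwise unspecified upstream). `Re` and `Stk` use the
  tracked ensemble speed as the fluid speed and the fiber diameter
  (220 µm default) as the characteristic length. The Stokes number uses
  the standard relaxation-time form `ρ_p·d_p²·u/(18·μ·L)`, a documented
  choice since only its interpretation, not its formula, is given
  upstream.
- **Normalization** rescales each frame affinely so its robust 1st/99th
  intensity percentiles land on the across-frame median targets; it
  removes offset drift and flicker, passes degenerate constant frames
  through with a warning, and is idempotent to within a grey level.
- **Concentration** is `C = 255 − mean(I)` per 10×10-px filter window in
  a 4×4 block placed adjacent to the tip on the accumulation side
  (explicit tip coordinate from config or simulator truth; automatic tip
  detection is out of scope). The block placement errors out rather than
  silently clipping at frame edges.
- **Smoothing.** The moving average (default 300 frames = 10.7 s at
  28 fps) is centered with shrinking windows at the edges — no invented
  padding. The rlowess smoother (default 200 frames = 7.1 s at 28 fps)
  is robust locally weighted *quadratic* regression: tricube distance
  weights times bisquare robustness weights re-derived from residuals
  over 4 passes, with the bisquare scale 6·MAD computed over residuals
  that are not numerically exact fits (otherwise a partly-flat noiseless
  series collapses the weight vector). It reproduces a noiseless
  quadratic exactly and suppresses isolated spikes. No installed library
  offers robust local quadratic smoothing (statsmodels lowess is local
  linear), so it is implemented here and cross-checked against
  statsmodels on smooth data in the test suite.
- **S_accum** is the least-squares slope of smoothed C(t) over the first
  10 s after laser-on, averaged over the 4 windows nearest the tip
  (whether the upstream value averages all 16 windows is unstated; the
  near-tip subset is the default and configurable). The smoothing is
  applied to the early period only: a robust smoother run across a long
  saturated tail would treat the initial rise as an outlying minority and
  flatten it.
- **A_accum** counts dark pixels (below a fixed or Otsu threshold) inside
  a rectangular ROI spanning the window block ±20 px at the final/stated
  frame, times the pixel area (0.89² µm² at the reference magnification).
  The fiber silhouette is excluded by mask. Saturation is declared at the
  first frame where smoothed C stays within 2% of its maximum for ≥5 s —
  an operationalization of "saturated", which has no stated rule.
- **Classification thresholds** (0.5, 2.0 s⁻¹) on S_accum are a
  calibration: the unique round values separating the No/Weak/Strong
  groups of the reference table. Classification keys on S_accum rather
  than area because one chain-forming species (SAg) scatters into
  clusters with substantial total dark area but no coherent swarm; an
  area rule would mislabel it.

## Synthetic scenarios and what passing means

The canonical scenarios (in `ptep.scenarios`) freeze the study
conditions at sizes that run in seconds: tracking uses 24 spheres over
200 frames at 30 fps in a 360×240-px field (full-length in-frame
trajectories by construction); accumulation uses 120 bacteria-sized
particles over 13 s at 14 fps in a 200×200-px field, with starting
positions on a non-overlapping jittered grid that leaves the capture
zone clear (the tip region starts particle-free, so any darkening is
transported there by the physics); the Brownian control uses 500
particles at D = 1 µm²/s. These are reduced-scale versions of 8-minute,
30-fps laboratory recordings — the reduction is a package choice to keep
the validation loop fast.

Passing tests on these scenarios demonstrates that the analysis chain is
*internally correct*: it recovers what the simulator injected (positions,
velocities, diffusion constants, attraction rank order, medium effects).
It does not demonstrate robustness to everything real video contains —
uneven illumination beyond affine drift, focus drift, motile cells,
aggregation, non-circular cell images at low magnification — and Hough
detection specifically is validated for spheres; for rods/cocci/chains it
is best-effort, as in the source procedure.

## Numerical notes and limitations

- Exact distance ties in linking are broken deterministically (lowest
  index) and logged; sub-pixel refinement can be disabled to recover pure
  accumulator output.
- `settling_velocity` signs follow `ρ_p − ρ_f` (buoyant particles rise);
  `classify_motion` compares upward drag with net weight at relative
  tolerance 1e-6, returning "equilibrium" at balance.
- Degenerate inputs raise rather than guess: empty detection input,
  length-1 trajectories, smoothing windows longer than the series,
  constant-intensity frames (warned, passed through), ROIs or window
  grids off-frame, missing required config fields (named in the error).
- Ground-truth velocities store the deterministic drift evaluated at the
  pre-step position; with `D = 0` finite differencing of positions
  recovers them to machine precision, which the tests rely on.
- The simulator conserves particle count; captured particles are frozen,
  not removed. No hydrodynamic interactions, no particle–particle forces,
  no shape-dependent drag corrections (shape affects rendering and,
  optionally, capture only).
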