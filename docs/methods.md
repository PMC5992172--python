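# Methods

This note documents the models, estimators and numerical choices behind
`slideforce`, and what the synthetic assays do and do not establish about
real data.

## Bead-in-trap model

A microsphere of drag coefficient `γ_b` (default 9.4 × 10⁻⁶ pN·s/nm, the
Stokes drag of a 1 µm silica sphere in water) in a harmonic optical trap
of stiffness `k` (default 0.05 pN/nm; instruments typically operate at
0.05–0.1 pN/nm) undergoes overdamped Brownian motion. Free-bead
displacement per axis is an Ornstein–Uhlenbeck process with relaxation
rate `λ = k/γ_b` and stationary variance `k_B·T/k`, so the recorded force
`F = k·x + offset` satisfies equipartition, `var(F) = k·k_B·T` per axis.
The simulator uses the exact discrete-time OU update
`x_{i+1} = a·x_i + s·√(1−a²)·ξ` with `a = e^{−λΔt}`, which is unbiased at
any sample rate — an Euler step would inflate or deflate the variance and
corrupt the equipartition diagnostic. The two trap axes are simulated
independently with equal stiffness; x–y crosstalk is not modeled.

After the bead binds a transported filament the link is modeled as rigid:
bead and filament co-move, and the filament advances along the transport
axis at `v(F) = v₀ − F/γ`, the linear force–velocity relation with
unloaded velocity `v₀` and team friction coefficient `γ`. The force
component along transport then relaxes exponentially (time constant
`γ/k`) to the plateau `γ·v₀`; the perpendicular bead displacement stays
frozen at its value at binding, since the bound bead–filament complex has
effectively infinite drag and its thermal fluctuations are negligible.
Consequently post-binding traces are deterministic given the binding
state; estimator noise in simulated recoveries comes from the thermal
baseline through the offset estimate. Linkage compliance is not modeled.
If a detachment force is set, the link breaks when the motor-load
magnitude `|F − offset|` exceeds it (the constant detector offset is not
a mechanical load) and the free-bead process resumes, with optional
rebinding after a fixed delay.

Geometry presets pin `(v₀, γ)` to the four anchorage regimes:
gliding 270 nm/s with γ·v₀ = 10 pN, sliding 57 nm/s with 0.7 pN,
non-aligned 180 nm/s with 5.9 pN, microtubule-anchored 205 nm/s with
6 pN.

## Trace estimators

* **Offset**: per-axis arithmetic mean over a pre-attachment window
  (default 5 s; at least 10 samples).
* **Binding detection**: the force magnitude (offset-subtracted, vector
  norm) is smoothed with a 0.1 s moving average; a binding event is a
  rise of its central-difference derivative above 2 pN/s that is
  confirmed by the magnitude exceeding 2 pN within 1 s. After an event,
  search resumes once the magnitude falls below half the confirm level,
  so detachment/rebinding sequences yield multiple events. Thresholds
  are configurable; the defaults resolve binding to well under a second
  at gliding-scale forces but will not flag sub-pN sliding events, which
  sit below the thermal noise floor (≈0.45 pN RMS at k = 0.05 pN/nm) —
  those are quantified by force–velocity fits instead.
* **Plateau selection**: the window ends at detachment (smoothed
  magnitude dropping below 20% of its running maximum after exceeding
  1 pN) or at the trace end. Candidate starts are scanned forward from
  the binding time in 0.25 s steps; a start is accepted when the
  Theil–Sen slope of the smoothed magnitude is within ±0.1 pN/s both
  locally (over the first 2 s, which keeps the rising edge out) and over
  the whole remaining window (robust to brief dips). The earliest
  accepted start gives the longest window; traces whose attachment broke
  during the ramp yield no plateau. Manual windows can be supplied
  through `TraceAnnotation` when automatic selection is unsuitable.
* **Stopping force**: per-axis plateau means minus offsets, combined by
  Pythagoras. Averaging signed per-axis values before taking the
  magnitude avoids the rectification bias that averaging |F| would
  introduce; this is safe because plateaus sit far from zero force. All
  samples in the window are averaged, including brief dips.

A diagnostic `estimate_stiffness_equipartition` checks recorded traces
for consistency with the nominal trap stiffness; it is not a
calibration (instrument power-spectrum calibration is out of scope).

## Force–velocity fits

Force is regressed on velocity (never the reverse, regardless of which
was the set quantity) because the target is a force difference: the
stopping force is the fitted force change between the unloaded velocity
and stall, `F_stop = |slope|·v₀`. Quality weights in (0, 1], rating how
steady each segment's sliding was, multiply the squared residuals; the
rating scale is taken as given. Constant-force and constant-velocity
segments are pooled. The intercept is left free rather than pinned to
(v₀, 0). The transport axis is oriented by the sign of the unloaded
velocity so backward (assisting) loads enter negatively. Standard errors
come from the weighted normal equations (statsmodels WLS);
`stopping_force_from_fit` propagates an optional uncertainty on `v₀` in
quadrature. Note that velocity noise sits in the regressor, so the slope
magnitude carries a small attenuation bias — about 0.5% at the default
scan design (11 setpoints spanning ±5 pN, 20 nm/s velocity noise) —
which is far below the recovery tolerances used in testing. Nonlinear
force–velocity models are deliberately out of scope: over the measured
range the relation is linear.

## Passive forces

* **Entropic crosslinker force** `F = N·k_B·T/L` (1-D ideal gas of N
  diffusible crosslinkers confined in an overlap of length L), with
  `k_B = 0.0138065 pN·nm/K` and default `T = 298 K`. The dilute-gas
  validity condition is not enforced. The overlap-shortening generator
  integrates `dL/dt = −μ·(F_motor − N·k_B·T/L)` (explicit Euler with a
  step bounded well below the distance to stall, so the approach is
  monotone), runs until within 0.5% of the stall length
  `L* = N·k_B·T/F_motor`, and appends a settle tail at the stalled
  length. `stall_overlap_inversion` verifies the series has stalled and
  reads the motor force back as `N·k_B·T/L_final`.
* **Buckling force** `prefactor·EI/L²` with `EI` in N·m² (default
  6 × 10⁻²⁴, the standard microtubule flexural rigidity) and `L` in µm,
  converted to pN. The default prefactor is 4π, matching the convention
  of the assay literature this package mirrors; the classical Euler
  clamped–clamped prefactor 4π² (exactly π times larger) is available as
  `EULER_CLAMPED_PREFACTOR`. Both conventions are exposed rather than
  silently harmonized.

## Motility statistics

Instantaneous velocities are frame-to-frame displacements over frame
intervals; a filament's velocity is their unweighted mean (kymograph
slopes, inherently averaged, pass through unchanged; hand-marked
end-to-pivot distances are treated as ordinary tracks, with no swivel
correction). Population statistics weight each filament's mean by its
observation duration. The weighted SD uses frequency-weight
normalization `Σw(v−m)²/(W − W̄)` (total minus mean weight), which
reduces to the `n−1` formula for equal weights; both weighted and raw
statistics are reported since published summaries do not always state
which was used. The weighted median is the smallest value at which the
cumulative weight reaches half the total. Boxplot quartiles use linear
interpolation between order statistics — fixed and documented so the
brute-force test oracle is exact — with outliers outside
`[q1 − 1.5·IQR, q3 + 1.5·IQR]` and whiskers at the most extreme
non-outliers.

Motor counts divide background-subtracted integrated intensity by the
mean single-fluorophore intensity (negative net intensity clips to zero
with a warning); synthetic intensities are gamma-distributed per
fluorophore with a set mean and coefficient of variation. The
surface-density route multiplies filament length by a reach band
(default 50 nm, the motor contour-length scale over which a
surface-bound motor can engage a filament) and the surface density.

## What the synthetic assays do not capture

The generators reproduce the statistical structure the estimators assume
— OU baselines, a noiseless linear force–velocity law, iid Gaussian
localization noise, gamma-distributed fluorophore brightness — with
parameters at realistic assay scales. They omit instrument drift,
surface interactions, z-crosstalk, bead-linkage compliance, motor-number
fluctuations, photobleaching, and any mechanistic stepping model.
Passing recovery tests therefore demonstrates estimator correctness
under the stated model, not robustness to every artifact of real
recordings; the manual-override paths (explicit windows, externally
supplied weights) exist for exactly those cases.

## Problem sizes used in validation

Recovery tests use 100 simulated gliding traces (30 s at 1 kHz, binding
at 8 s) for the plateau route, 200 simulated scans (11 setpoints spanning
±5 pN) for the friction-fit route, a 3 × 3 grid of (N, motor force) for
the crosslinker balance, and 1000 random samples for the statistics
oracles — sizes chosen to match typical experimental campaigns while
keeping the suite quick to run.
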