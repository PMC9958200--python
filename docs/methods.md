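# Methods

## Model

`hillmuscle` implements a three-element Hill-type muscle model: a
contractile element (CE) and parallel elastic element (PEE) in series with
an elastic element (SEE), contracting at fixed muscle–tendon-unit (MTU)
length.  Forces are expressed in units of the maximum isometric force
`P0`, CE lengths in optimal lengths `L0`, and the default parameters
describe the plantar flexors of young adult men.

### Activation dynamics

Activation is driven by the concentration `a` of an activator (free Ca²⁺)
in a single compartment.  Each stimulus opens a release window of duration
`pulse_width` during which

    da/dt = (1 − a) / τ₁,

and outside release windows the activator is removed with

    da/dt = − a / τ₂.

Both phases are linear, so the transient is propagated *analytically*
between event boundaries (pulse on/off); the integration step `dt` only
controls the output sampling (default 0.1 ms).  Saturation (`a = 1`)
corresponds to 10 µM free Ca²⁺, i.e. pCa 5, which maps the activator onto
the force–pCa axis of skinned-fibre experiments.

Release for closely spaced stimuli is attenuated ("inactivation of
release"): the window of pulse *i* ≥ 2 is scaled by

    1 − (1 − A) · exp(−isi / r),

where `isi` is the interval to the immediately preceding pulse, `A = 0.2`
is the *minimum* relative release reached as `isi → 0` (i.e. maximum
inactivation of 80%) and `r = 350 ms` the recovery time constant.  Note
the coefficient: the model's steady-state behaviour (the ~29% gap between
the 100 and 200 Hz steady-state activator levels, and ~97% cross-bridge
activation at 200 Hz under a halved release) requires the *minimum
release* reading of `A`; with only 20% maximum inactivation those values
would be ~17% and ~99%.

Cross-bridge (thin-filament) activation is a sigmoid of the activator,

    Act = aⁿᴴ / (aⁿᴴ + a₅₀ⁿᴴ),

algebraically identical to the Hill force–pCa form
`1/(1 + 10^{nH (pCa − pCa₅₀)})`.  Ageing deficits in instantaneous Ca²⁺
availability are modelled by a `release_scale` factor applied pointwise to
the activator *seen by the sigmoid*, leaving the kinetics untouched.

The steady state of periodic stimulation is computed in closed form: each
period is release followed by decay, both linear, so the per-period map is
affine in `a`; its fixed point and the period mean follow directly.  A
long-simulation oracle agrees to 1e−4 (tested).

### Contractile element

Active CE force is `fgc · Act · FL(l) · FV(v)`:

* `FL` — piecewise-linear force–length factor: zero below 0.35 `L0`,
  ascending limb to a plateau at 1.0 spanning 0.90–1.05 `L0`, descending
  limb to zero at 1.8 `L0` (loss of filament overlap).  Breakpoints are
  ordinary parameters and can be overridden.
* `FV` — Hill force–velocity relation, shortening positive:
  `P/P0 = K(1 − V/Vmax)/(K + V/Vmax)` with curvature `K = a/P0 = 0.10`;
  eccentric branch `P/P0 = c − k(1 + V/Vmax)/(1 − q·V/Vmax)` with
  `c, k, q = 1.8, 0.8, 7` and `c − k = 1` so the branches join with value
  1 at `V = 0`.  The eccentric branch equals `c` exactly at a lengthening
  speed of `Vmax`; the closed-form inverse therefore clamps force demands
  at or above `c` to `−Vmax`, avoiding the hyperbola's pole.
* `fgc` — force-generating capacity, a pure multiplicative scale analogous
  to PCSA, used to model atrophy (default 1).  It scales active force
  only; PEE and SEE are expressed in `P0` units and are untouched.

### Passive elements

PEE: exponential toe region,
`P/P0 = (exp(k_PEE (L − L_slack)/ε_PEE) − 1)/(exp(k_PEE) − 1)` with
`k_PEE, L_slack, ε_PEE = 4, 0.98, 0.57`; zero at or below slack, 1 `P0` at
`L_slack + ε_PEE`.

SEE: power-law load–deformation `P = (x/x₀)^b` with `x₀ = ε_SEE · L_SEE =
15 mm`, so normalised stiffness `k_SEE = L0/(ε_SEE·L_SEE) = 3.33 P0·L0⁻¹`.
The exponent `b = 2` (quadratic toe typical of tendon) is a free shape
constant; stiffness scenarios rescale the deformation axis (`×1.5`
stiffness → deformation at `P0` ÷ 1.5), preserving `b`.

### Fixed-end simulation

The MTU length is fixed at the passive equilibrium for the requested
initial CE length (SEE deformation solving `SEE = PEE`, closed form).  At
each step the SEE deformation follows from the length constraint, the
required CE force from the massless-junction balance
`SEE = active + PEE` (clamped at zero when the CE would be compressed —
the model has no compressive element), and the CE velocity from the
inverse force–velocity relation; `l_ce` is integrated with explicit RK4 at
`dt = 0.1 ms`.  Halving `dt` changes the peak twitch force by < 0.1%
(tested).

Degenerate regime: when `fgc · Act · FL < 1e−6` the force–velocity
relation no longer determines the velocity (and is sign-indeterminate
exactly at passive equilibrium), so the CE is relaxed toward the
passive-equilibrium length with a bounded first-order rule (τ = 5 ms,
|v| ≤ Vmax).  An unstimulated muscle is therefore exactly stationary.  In
this near-zero-force regime, and in brief onset/tail intervals where the
demanded force exceeds the eccentric ceiling `c` while activation is
~1e−5, the recorded CE force (computed from the realized, clamped
velocity) deviates from the SEE force by up to ~3e−4 `P0`; wherever the
force–velocity relation is unclamped the balance holds to better than
1e−10 `P0` (tested).  Twitch metrics are insensitive to this tail
behaviour because both are measured at forces two to three orders of
magnitude larger.

### Twitch metrics, force–frequency, summation

Contraction time (CT) is stimulus-to-peak of active force and
half-relaxation time (HRT) peak-to-half-decay, with parabolic peak
refinement and linear interpolation of the half crossing (sub-sample
accurate).  Force–frequency points are the mean active force over the
final interpulse period of a train extended (from 1 s, doubling to at most
5 s) until the last two period means agree to 0.5%; curves are normalised
to the control 200 Hz maximum so scenario deficits are visible.  The
summation ratio is the peak force of a 6-pulse, 100 Hz (50 ms) tetanus
over the twitch peak.

## Ageing scenarios

Scenarios are named, field-wise composable parameter modifications
shipped in `scenarios.yaml`: release scaling ×0.7/×0.5; removal-rate
reduction of 30/50% (τ₂ × 1/0.7 and × 2); pCa₅₀ −0.05/−0.10 (implemented
as `a₅₀ × 10^Δ`); `nH` ± 1; `Vmax` ×0.7/×0.5; `a/P0` +0.05; `k_SEE`
×0.7/×1.5; type I fractional area 0.60 → 0.70/0.80; and the combined
presets (release + sensitivity, release ×0.7 + uptake-rate ×0.6,
τ₂ ×1/0.7 + pCa₅₀ −0.10).

The fibre-type shift decomposes the Ca²⁺ removal *rate constant* (1/τ₂),
`Vmax` and `nH` into slow/fast components by inverting
`x_slow·p_slow + x_fast·(1 − p_slow) = x_whole` with fixed slow/fast
ratios (0.5, 0.3, 0.6 respectively) at `p_slow = 0.60`, recomposes at the
new fraction, and shifts pCa₅₀ additively with a slow-minus-fast gap of
0.15 pCa units (the fibre difference is stated in pCa units, so the
additive form is used; the multiplicative alternative on `a₅₀` is not the
default).  `a/P0` is deliberately not included in the composite.
Decompose→recompose is exact at the original fraction (tested).

## Twitch fitting

The objective is the sum of squared relative CT and HRT errors plus a
quadratic penalty (weight 10) on the relative amplitude outside a ±10%
band around the target ("about 0.2 `P0`" is a soft requirement).
Minimisation is bounded Nelder–Mead with seeded restart perturbations
(deterministic given `FitSpec.seed`); a twitch simulation costs
milliseconds and the objective is non-smooth at metric crossings, so a
derivative-free simplex is appropriate.  Young mode frees τ₁, τ₂, a₅₀
with `nH`/`Vmax` held at 3 and 6; old mode anchors directional bounds at
the young solution (τ₂ may only increase; `Vmax`, `k_SEE`, FGC only
decrease; `a₅₀` only increase) with FGC free in (0.5, 1].  When FGC and τ₂
are both free the fit probes the FGC–τ₂ trade-off direction and reports a
`multiple_solutions` flag when the objective is flat there — slower Ca²⁺
removal raises twitch force, so a deeper FGC cut can be compensated by
more uptake slowing.  Note the amplitude band interacts with timing: with
a tight ±10% band and this model's shape constants, matching CT/HRT
exactly pushes the amplitude to the band edge; widening the band to ±20%
makes the timing fit exact.

## Synthetic experimental twitches

The generator emulates the group-mean plantar-flexion twitches used as
fitting targets (young: CT 123.6 ms, HRT 100.2 ms; older: CT 154.8 ms,
HRT 129.0 ms, amplitude 0.82× young).  The waveform is a gamma-shaped
transient

    f(t) = peak · (t/CT)^k · exp(k − t/θ),  CT = k·θ,

which peaks exactly at CT; the shape exponent `k` is solved by
root-finding so the half-relaxation time matches.  A difference of two
exponentials was rejected: its half-relaxation time is at least 1.678 × CT
(the τ_rise → τ_decay limit), whereas measured twitches have HRT ≈ 0.8 ×
CT.  The gamma family covers every HRT/CT ratio > 0.  Optional Gaussian
noise is added after shaping; cohort sampling draws CT/HRT/amplitude from
independent truncated normals (CT, HRT in [40, 400] ms, amplitude > 0),
reproducibly from a seed.

What the generator does *not* emulate: stimulus artefacts, potentiation,
dynamometer torque-to-force conversion, baseline drift, or correlated
noise.  Tests passing against it show the fitting and metric machinery is
correct for clean single transients, not that the model fits arbitrary
experimental recordings.

## Free shape constants and calibration

Two pieces of the model are not fixed by published constants: the FL
breakpoints and the SEE exponent `b`.  The control model is calibrated so
a twitch from 1.0 `L0` with the default parameter table reproduces the
young experimental twitch (CT 125 ms, HRT 102.5 ms, amplitude ~0.2 `P0`).
With `b = 2`, an ascending limb from 0.35 `L0` and a plateau spanning
0.90–1.05 `L0` the control twitch gives CT 122.6 ms, HRT 103.7 ms, peak
0.215 `P0` — the closest attainable over a scan of `b ∈ [2, 3]` and
ascending-limb onsets in [0.35, 0.50] (CT varies only within ~117–123 ms
across that scan).  The broad plateau is consistent with whole-muscle
force–length relationships being wider than the sarcomere curve
(fibre-length heterogeneity).  Scenario *percent-change* results move by
under ~1.5 points across the scanned shapes, so conclusions about the
ageing scenarios are insensitive to these choices; absolute twitch
timings carry a ±3 ms uncertainty from them.

## Problem sizes and defaults

Twitch simulations run 1 s at `dt = 0.1 ms` (10⁴ RK4 steps, ~0.1 s on one
core); force–frequency points use 1–5 s trains at the same step; fits use
0.8 s twitches at `dt = 0.2 ms` (the objective is invariant to the grid
below 0.2 ms, tested) with a 400-iteration simplex budget.  These sizes
were chosen because every reported quantity is converged at them (halving
`dt` moves peak force < 0.1%, period-mean convergence tolerance 0.5%).

## Known limitations

* No history dependence (residual force enhancement/depression), no
  pennation, no temperature or fatigue effects, no compressive element.
* The eccentric branch tends to `c + k/q ≈ 1.91` (not `c`) as lengthening
  speed grows; velocities are therefore restricted to `[−Vmax, Vmax]` by
  the demand clamp.
* "Active force" is reported as `fgc·Act·FL·FV`; at shared lengths the
  FL-scaled interaction with passive structures is not separated out.
* The per-pulse inactivation rule uses only the immediately preceding
  interstimulus interval; cumulative store depletion is not modelled.
* Whether atrophy (FGC) should also scale the passive elements is an open
  modelling question; here it scales active force only.
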