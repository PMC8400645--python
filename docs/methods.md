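# Methods

## Scope and model structure

`circort` integrates a 19-state deterministic ODE system coupling four
physiological sub-models: a mean-field sleep/wake flip-flop, a van der Pol
circadian pacemaker with photic entrainment, a Goodwin-type HPA axis with
central glucocorticoid-receptor (GR) feedback, and peripheral
mineralocorticoid/glucocorticoid receptor pools.  The coupling is
unidirectional from sleep and circadian processes into the HPA axis: the
pacemaker paces CRH synthesis (a rectified SCN readout through the
saturating gain `1 + S/(1+S)`, bounded in [1, 2]), and sleep raises CRH
clearance by the factor `1 + k_s`.  There is no feedback from cortisol to
sleep; that is a deliberate scope boundary, not an oversight (see
Limitations).

All time is in hours with t = 0 at midnight.  Hormone and receptor
concentrations are in arbitrary model units; every reported phase or
amplitude effect is relative, so the units never enter the results.

## Parameter provenance and calibration

Sleep-switch and pacemaker constants start from the published
Phillips–Robinson / Kronauer-lineage values (Q_max = 100 s⁻¹, θ = 10 mV,
σ = 3 mV, τ_v = τ_m = 10 s, ν_vm = 2.1, ν_mv = 1.8 mV·s, χ = 45 h,
γ = 0.23, κ = 12/π h, f = 0.99669, k_B = 0.55, β = 0.0075 min⁻¹,
I₀ = 9500 lux, b = 0.4).  A small set of coupling/scale knobs was then
calibrated, with `calibration.py` providing the machinery, to the model's
target phenotypes:

| knob | value | fixes |
|---|---|---|
| τ_c | 24.35 h | free-running period and entrained phase |
| A_v | −7.6 mV | sleep duration / VLPO operating point |
| ν_vc | −3.0 mV | circadian modulation of sleep timing |
| μ | 3.2 nM·s | homeostatic weight (sleep-onset phase) |
| α₀, p | 0.3 min⁻¹, 0.92 | photic drive strength and dim-light response |
| SCN phase/gain/offset | −2.2 rad, 1.0, 0.2 | cortisol peak shortly after wake |
| k_s | 0.3 | strength of sleep inhibition of CRH |

The calibrated defaults reproduce: wake at 06:37 and sleep onset at 22:52
(≈ 7.8 h sleep) under the nominal 12 h / 1000 lux photoperiod; circadian
sleep drive `C(t)` peaking at ≈ 15:50; cortisol peaking ≈ 25 min after
wake with its nadir ≈ 2.7 h before sleep onset; a free-running cortisol
period of 24.35 h in darkness; GR occupancy ≈ 0.49 and MR occupancy ≈ 0.90
at the cortisol nadir; and a 1.5 h cortisol peak delay at 40 lux evening
light.  These are computed, not asserted: the test suite and
`scripts/acceptance.py` re-derive each one by simulation.

### The light-intensity exponent

The photoreceptor activation rate is `α = α₀ (I/I₀)^p`.  With the
historical exponents p ∈ [0.5, 0.6], dim evening light (10–40 lux held
from dusk until the model's own sleep onset) destabilizes entrainment
altogether in this configuration: a small circadian delay postpones sleep,
which extends the evening light window and erodes morning light through
the wake gate, producing runaway phase delay.  The committed p = 0.92
(with α₀ raised to 0.3 min⁻¹ to preserve the bright-light drive) weakens
dim light relative to daylight enough that the delay saturates at ≈ 1.5 h
for 40 lux while remaining monotone in intensity.  This is a calibration
choice of the package, made once against the evening-light phenotype.

### HPA dynamics near the oscillatory threshold

The central HPA loop is parameterized so that its autonomous linearization
is near-critically damped with a resonant period of ≈ 24.3 h, and the
nuclear feedback complex turns over fast (k_T = k_re = 0.8 h⁻¹).  Strongly
relaxation-like (limit-cycle) parameterizations were explored and
rejected: under the square-wave forcing of imposed sleep schedules they
period-double, so the "adapted" rhythm alternates between two day shapes.
The committed regime entrains 1:1 across the full CSR × evening-light
grid; the free-running rhythm in darkness is carried by the
still-oscillating pacemaker, which is what the constant-darkness period
measurement reports.

## Schedule forcing

CSR schedules are imposed through continuous drives, not by resetting
states: during a scheduled sleep window 15 mV is added to the VLPO drive,
and during scheduled wake 30 mV is *subtracted* from it ("wake effort" as
arousal-mediated VLPO suppression).  An additive excitatory drive on the
monoaminergic population — the more obvious implementation — cannot work
here: pulling the system out of an established sleep state against a
homeostatic pressure of ~25 mV would require an MA drive of order
100 mV, which saturates the firing-rate sigmoid and, through
χḢ = −H + μQ_m, blows up the homeostat.  VLPO suppression flips the same
switch at physiological drive magnitudes and keeps every state continuous
and bounded.  Under forcing, the realized transitions match the scheduled
window edges to within ~1 min, and the behavioral sleep indicator passed
to the HPA module always follows the realized Q_m/Q_v classification.

The habitual window used by the CSR builders is the model's own realized
schedule (22.86, 6.62), so a zero-restriction forced protocol coincides
with the free-running nominal trajectory (verified to < 1% in cortisol).

## Numerical integration

The vector field is smooth except at three kinds of switching: the
behavioral state (sign of Q_m − Q_v), the wake gate on light
(sign of Q_m − Q_th, with the Heaviside convention H(0) = 0), and
scheduled forcing/stress edges.  The engine never lets the solver step
across a discontinuity: scheduled edges are precomputed breakpoints, and
state-dependent switches are located by `solve_ivp` event detection
(direction-restricted to the crossing the current mode allows, which also
prevents re-triggering at a just-handled event); integration restarts at
each breakpoint with the discrete mode updated.  Defaults: LSODA,
rtol 10⁻⁶, atol 10⁻⁸, max step 0.25 h, output grid 6 min.  Halving the
tolerances changes the final-day cortisol trace by well under 0.1%
(asserted in the tests), and repeated runs are bit-identical.

`run_to_steady_cycle` iterates the daily Poincaré map (the full state at
successive midnights) until the per-state relative sup-norm change falls
below 10⁻⁴ (5·10⁻⁴ for evening-light conditions, whose phase creeps for
tens of days near the entrainment equilibrium), then returns two
analysis days.  Every study run starts from a committed adapted-nominal
state, so nominal re-adapts in ~1 day and schedule manipulations in ~20–30
days.  Stress pulses are withheld during adaptation and applied on the
final adapted day, matching their definition as acute perturbations.

Problem sizes used by the test suite and acceptance script — two analysis
days per condition at 6 min sampling, 40 days of constant darkness for the
free-running period (10 discarded), 28 h continuations for each stress
onset — were chosen as the smallest runs on which every reported quantity
is stable to the estimator's resolution (peak times to ~1 min via 3-point
quadratic refinement).

## Metrics conventions

Peak and nadir times are refined off-grid by local quadratic
interpolation; traces are treated as circular over 24 h.  Phase
differences use the circular convention (−12, +12] h with delays
positive.  A trace is rejected as ambiguous if a secondary local maximum
comes within 5% of the peak-to-nadir range of the primary.  The quiescent
period is the longest contiguous window below nadir + 0.25 × range (the
threshold is a documented convention; only directional comparisons are
made with it).  The stress response is the trapezoidal ΔAUC of cortisol
over 4 h from stressor onset, between stressed and unstressed runs on the
same grid; the default stressor is a 3× multiplication of CRH synthesis
for 0.5 h (magnitude and duration are free choices — the time-of-day
contrasts they support are insensitive to the gain across 2–5×).
Receptor occupancy is (F_R + F_R^N)/R_T against the *total* pool; a
nuclear-only readout is exposed as an option.

## Reproduced phenomenology

On the calibrated defaults the simulator reproduces, by computation in the
test suite: monotone increases of the cortisol nadir and of the peak-time
delay with symmetric restriction 0→4 h; a larger phase delay when
restriction is imposed by delaying sleep onset than by the symmetric
schedule; a larger amplitude reduction (with smaller phase change at
moderate restriction) when imposed by advancing wake; rising minimum MR
occupancy with restriction; evening-maximal stress responsivity whose
peak is reduced under 4 h restriction; and stronger amplitude dampening
when restriction is combined with evening light, traceable to a reduced
circadian drive amplitude.  One caveat is recorded: at the most extreme
4 h restriction the wake-advance condition's phase delay (2.32 h)
marginally exceeds the symmetric condition's (2.27 h), so the
"phase-preserving" character of wake advance holds for restrictions up to
3 h and is asserted at the 2 h matched restriction.

## Limitations

* No ultradian cortisol pulsatility and no cortisol awakening response;
  the model operates on circadian time scales only.
* No feedback from the HPA axis onto sleep propensity.
* Evening light is only modeled up to 40 lux, and the photoperiod is an
  idealized symmetric 12 h profile.
* Hormone units are arbitrary; only relative/phase readouts are
  meaningful.
* The synthetic experiments characterize this model, not human data: the
  directional CSR effects agree qualitatively with the experimental
  literature, but magnitudes (e.g. the ~1–2 h delays) are properties of
  the calibrated parameter set.
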