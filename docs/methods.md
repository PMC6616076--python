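# Methods

`streamseg` models sequential auditory stream segregation in
cochlear-implant (CI) listeners as competition between three cortical
percept units, and links the simulated percept to delay-detection d′
through an ideal observer.  This note documents the model, its parameters,
the numerical choices, and what the synthetic-data pipeline does and does
not establish.

## The modeling pipeline

A trial presents a sequence of alternating A and B sounds at 5.89 sounds/s
(inter-onset interval ≈ 169.8 ms) for 1.24 s (7 sounds) or 3.96 s
(23 sounds).  A and B differ by a perceptual pitch difference Δpitch,
expressed in percent of a reference difference (100% corresponds to the
pitch contrast between two electrodes far apart on a CI array).  The last
B sound is delayed by Δt = 48.5 ms; detecting that delay is easy when A and
B are heard as separate streams, so predicted d′ tracks the probability of
a segregated percept.

**1. Stimulus.**  Symbolic event timelines only (onset, duration, label).
Tone duration defaults to half the inter-onset interval; events are
labelled A, B, A, B, …; the number of events is `floor(duration × rate)`.

**2. Cortical input.**  Each sound excites three units — A-stream,
B-stream, and an integrated AB unit located midway between the A and B
feature values — with amplitude given by the weighting function

    w(d, t) = Q(t) · L · exp(−R(t) · d / σ),

where `d` is the pitch distance between the sound and the unit (0, Δpitch/2
or Δpitch), `L` is an amplitude factor and `σ` a lateral decay constant.
`Q(t)` (amplitude adaptation, 1 → 0.85) and `R(t)` (tuning sharpening,
0.2 → 1.8) relax exponentially with a 0.5-s time constant measured from
sequence onset.  Tuning that starts broad and sharpens is the build-up
mechanism: early in the sequence even a large Δpitch feeds the integrated
unit; seconds later the cross-feature input has collapsed and the stream
units win.  The endpoint values of `Q` and `R` are package defaults (the
profiles' shapes are not constrained beyond "exponential decay, τ = 0.5 s"
by the behavioral literature this emulates); they were fixed once, during
the single calibration pass described below, and are configuration-exposed.

**3. Competition.**  Wilson–Cowan-style rate units with recurrent
excitation, slow subtractive adaptation, and additive Ornstein–Uhlenbeck
noise inside a logistic gain:

    τ_u u̇_j = −u_j + F(I_j + α u_j − Σ_k β_jk u_k − g a_j + n_j)
    τ_a ȧ_j = −a_j + u_j,     F(x) = 1 / (1 + e^{−slope (x − θ)})

The inhibition matrix is all-to-all but *not* uniform: stream units inhibit
each other with β_i = 0.85; the integrated unit inhibits each stream unit
with β_ab_out = 0.8 but receives only β_ab_in = 0.3 from each.  This
directional asymmetry is an explicit integration bias and it is load-bearing.
Under a uniform matrix the three units are statistically exchangeable
whenever Δpitch = 0 (all three inputs are then pointwise identical), so the
integrated unit would be the strict maximum exactly ⅓ of the time and the
readout would report segregation with probability ⅔ at zero feature
difference — for any choice of the remaining parameters.  Perception
instead defaults to integration at zero feature difference, and the
bias reproduces that: at Δpitch = 0 the model spends ≈ 99% of the sequence
integrated.  The asymmetry can be read as the integrated interpretation
being the perceptual default that the streams must actively break, which is
the standard description of why segregation *builds up* rather than starts.

Remaining defaults: α = 0.6, g = 0.15, τ_u = 80 ms, τ_a = 1.2 s, γ = 0.09
(stationary noise s.d.), τ_n = 100 ms, slope 10, threshold 0.3.  Two
regime choices matter and were made deliberately:

* τ_u is slower than a single tone, so percept dominance persists across
  the silent gaps of the pulsatile input.  With a fast membrane (τ_u ≈
  10 ms) the activities collapse between tones and the readout degenerates
  into an event-locked oscillation with no percept continuity.
* Switching is noise-dominated (small g, larger γ).  With strong
  adaptation the ensemble of trials rings: every trial's first dominance
  epoch ends at about the same time, so the build-up function overshoots
  and sags instead of rising to a plateau.  Weak adaptation plus noise
  desynchronizes switching across trials and yields the observed smooth,
  monotone build-up that saturates after ~2–4 s.

All competition parameters were calibrated in one pass against qualitative
criteria only — integration default at Δpitch = 0, monotone build-up
reaching a plateau below 1, plateau increasing with Δpitch, spontaneous
switching on long trials, and spread compression when L drops — and then
frozen.  The fitting stage never touches them.

**4. Build-up function.**  The readout is winner-take-all: the percept is
integrated at time t iff u_AB(t) strictly exceeds both stream activities
(ties count as segregated).  The build-up function is the time-binned mean
of the segregated indicator over N trials (bin width 100 ms).

**5. Ideal observer.**  A trial is labelled segregated if the majority of
readout samples in a decision window — the delayed B event ± one
inter-onset interval — are segregated.  With segregated-trial fraction p,
hit rate H = p + (1 − p)·0.5 and false-alarm rate 0.5, both clipped to
[1/(2N), 1 − 1/(2N)], give d′ = Φ⁻¹(H) − Φ⁻¹(F).  d′ is 0 at p = 0 and
caps at Φ⁻¹(1 − 1/2000) ≈ 3.29 for N = 1,000.  The chance rate is
configurable for forced-choice geometries.  Δt influences predictions only
through the stimulus timeline and the window position.

## Fitting

Only the weighting-function parameters are fit: σ alone (L fixed at 0.6),
or σ and L jointly.  The objective is the averaged mean error (AME) — the
mean absolute difference between predicted and measured mean d′ across all
(Δpitch × duration) conditions; RMSE is available as an option.  The
optimizer is a real-coded genetic algorithm (population 24, 40 generations,
tournament selection, blend crossover, Gaussian mutation, elitism of one).
Search evaluations use 200 trials per condition with common random numbers
— every candidate sees the same noise paths, which are generated once per
fit since they do not depend on (σ, L) — and the winner is re-evaluated at
the study's N = 1,000 with fresh noise.  Bounds default to σ ∈ [5, 150],
L ∈ [0.05, 1.2].  Reported values follow the emulated study's convention
(σ and AME to one significant figure, L to two) while raw values are kept.

## Synthetic behavioral studies

`synthetic_data` emulates the structure of the CI delay-detection
experiments: a Δpitch grid {0, 12.5, 25, 50, 75, 100}%, durations
{1.24, 3.96} s, 8 listeners (between the 7- and 9-listener groups of the
emulated experiments).  Condition-level true d′ comes from the model itself
at a known (σ*, L*) = (30, 0.35) with N = 1,000 trials; per-listener scores
add Gaussian noise on the d′ scale (default s.d. 0.3, a realistic
magnitude for small-group CI psychophysics) and are floored at 0.
Generation happens at the d′ summary level: no button presses, adaptive
tracks, bias, or lapses are simulated.  Consequently, passing the recovery
experiment shows that the fitting machinery can identify the weighting
parameters from data *with the model's own structure*; it does not show
that real listeners' data satisfy that structure, nor calibrate the
listener-noise model against real variability.

## Numerical choices

* Integration: fixed-step Heun (predictor–corrector) for the drift,
  dt = 1 ms, with the OU noise advanced by its exact one-step recursion
  and treated as a known input path within each step.  Noise-free
  trajectories agree with a 10×-finer-step reference to ~4·10⁻⁴ sup-norm
  at the defaults.  Over horizons containing adaptation-driven dominance
  switches, any fixed-step scheme shows O(1) pointwise divergence from a
  finer reference because infinitesimal shifts in a switch time change the
  trajectory by the inter-attractor distance; convergence is therefore
  assessed on probe horizons without deterministic switches.
* Event envelopes carry 5-ms raised-cosine on/off ramps by default
  (rectangular available), keeping the input continuous for the fixed-step
  integrator; CI stimuli are ramped in practice as well.
* Initial conditions: all states 0 (pre-stimulus silence).  The first
  samples are exact ties and count as segregated under the strict readout;
  per-trial switching statistics skip the first 100 ms for this reason.
* Reproducibility: every random stream is keyed by
  `SeedSequence([master_seed, condition_index, trial, unit])`.  Identical
  seeds give bit-identical trajectories; distinct conditions may share
  trial keys deliberately (common random numbers) to tighten paired
  contrasts.
* Degenerate inputs: collapsed GA bounds return the single admissible
  point; an empty decision window, mismatched dt between currents and
  integrator, or non-finite activities raise immediately with the
  offending quantity named.

## Known limitations

* The competition stage is a three-unit caricature: no tonotopic array, no
  spiking, no attention, and the inhibition asymmetry is a phenomenological
  stand-in for whatever circuit makes integration the default percept.
* At large Δpitch the model's short-sequence d′ keeps growing while
  listeners' scores saturate; the model only saturates in the plateau
  region (long sequences).  Capturing short-sequence saturation would
  require reshaping the Q/R decays, which is deliberately out of scope
  because the behavioral build-up time course in CI listeners is not yet
  characterized well enough to constrain them.
* Percept-duration statistics (dominance-time distributions) are not
  modeled or validated; only the binary readout's time-binned mean and
  per-trial majority label are used.
* d′ predictions inherit Monte-Carlo error of order `sqrt(p(1−p)/N)`
  (≈ 0.016 in p at N = 1,000); comparisons in the test suite carry twice
  that as slack.
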