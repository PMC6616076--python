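# streamseg

Neural-competition modeling of auditory stream segregation for
cochlear-implant (CI) listeners.

When a sequence of alternating A and B sounds is played, listeners either
group it into one stream (integration) or hear two parallel streams
(segregation).  Segregation becomes more likely as the perceptual
difference between A and B grows, and it *builds up* over the first
seconds of listening.  CI users show the same trends as normal-hearing
listeners in delay-detection experiments, with larger inter-subject
variability.  `streamseg` implements a complete modeling pipeline for such
data, aimed at auditory and computational-neuroscience researchers:

1. **stimulus** — symbolic timelines of alternating A/B sounds
   (presentation rate 5.89 sounds/s; durations 1.24 and 3.96 s; a Δt =
   48.5 ms delay on the last B sound, the target of the behavioral task);
2. **cortical_input** — the weighting function
   ω(Δpitch, t) = Q(t)·L·exp(−R(t)·Δpitch/σ) that converts the timeline
   into pulsatile currents I_A, I_B, I_AB driving three percept units;
3. **competition** — a three-unit rate network (mutual inhibition,
   recurrent excitation, slow adaptation, Ornstein–Uhlenbeck noise) whose
   winner-take-all readout is the binary percept over time;
4. **buildup** — time-binned averaging of the percept across N trials
   (the build-up function) and per-trial classification;
5. **ideal_observer** — maps the segregated-trial fraction p to
   d′ = Φ⁻¹(p + (1−p)/2) − Φ⁻¹(1/2), the yes/no sensitivity of an observer
   with perfect hits on segregated trials and chance on integrated ones;
6. **fitting** — genetic-algorithm estimation of (σ, L) by minimizing the
   averaged mean error (AME) against a behavioral d′ table;
7. **synthetic_data** — generator of realistic per-listener d′ tables from
   known parameters, closing the loop with parameter-recovery experiments.

The model and the numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Predict d′ for a mid-range pitch difference at both sequence durations,
and inspect the build-up:

```python
from streamseg import ModelConfig, predict_condition
from streamseg.buildup import buildup_function

model = ModelConfig()          # frozen package defaults, L=0.6, sigma=40
for duration in (1.24, 3.96):
    pred, traces = predict_condition(
        delta_pitch=50.0, duration=duration, delta_t=0.0485,
        model_config=model, n_trials=1000, master_seed=0,
        return_traces=True,
    )
    bf = buildup_function(traces, model.bin_width)
    print(f"duration={duration:.2f}s  p_seg={pred.p_segregated:.3f}  "
          f"dprime={pred.dprime:.2f}  final_bin={bf.proportion_segregated[-1]:.2f}")
```

Output:

```
duration=1.24s  p_seg=0.127  dprime=0.16  final_bin=0.15
duration=3.96s  p_seg=0.877  dprime=1.54  final_bin=0.84
```

The short sequence ends while the percept is still mostly integrated
(p ≈ 0.13, d′ near chance); after four seconds segregation has built up to
p ≈ 0.88 and the ideal observer scores d′ ≈ 1.5.  Raising the pitch
difference raises both numbers; setting `model.with_input(L=0.35)`
(the amplitude regime that best describes CI listeners) compresses the
differences between easy and hard conditions — a more ambiguous percept.

The same pipeline is scriptable from a shell:

```bash
streamseg predict --seed 0 --out out/          # d' for the default grid
streamseg buildup --n-trials 1000 --delta-pitch 50 --duration 3.96 --out out/
streamseg generate --out study/                # synthetic behavioral study
streamseg fit --data study/condition_means.csv --free sigma,L --out fit/
streamseg recover --out recovery/              # generate + fit + errors
```

Every command writes CSV/JSON artifacts plus a `manifest.json` (config,
seeds, version, wall time) from which the run can be regenerated exactly.

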