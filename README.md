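# imgdecouple

Decoupling detection and wavelet salvaging for instrumented-mouthguard
(iMG) head-impact kinematics.

## The problem

Instrumented mouthguards measure six-degree-of-freedom head kinematics
through their coupling to the upper dentition. When the mouthguard moves
relative to the teeth during an impact ("decoupling"), 100–500 Hz artifact
oscillations ride on the sensor channels and can inflate the reported peak
linear acceleration by more than 100% on average — corrupting exactly the
quantity injury-surveillance studies care about. This package, aimed at
injury-biomechanics researchers working with iMG field or laboratory data,
implements a complete treatment chain:

1. **Processing** — raw accelerometer (g) and gyroscope (rad/s) channels
   sampled at 3200 Hz over a −10 to +40 ms window around an 8-g trigger
   are re-oriented to SAE J211, low-pass filtered (phaseless 4th-order
   Butterworth, 175 Hz linear / 250 Hz gyro), differentiated with a
   five-point stencil, and transported to the head center of gravity with
   the rigid-body relation
   `a_CG = a_P + ω × (ω × r) + α × r`.
2. **Detection** — four features feed a k-nearest-neighbor classifier
   (k = 4, Manhattan distance on z-scored features): the percent of
   spectral content between 100 and 500 Hz on linear-acceleration Z (f1)
   and angular-acceleration Y (f3), the time-order rank of the global
   maximum among the post-trigger peaks of the resultant linear
   acceleration (f4), and the time of the spectrogram maximum of
   angular-acceleration Y from a Hamming-windowed STFT with 12-ms windows
   and 90% overlap (f7).
3. **Salvaging** — each raw channel of a decoupled event is decomposed
   into a shift-invariant (maximal-overlap) wavelet multiresolution
   analysis (db10, 5 levels; details D1–D5 spanning nominal dyadic bands
   800–1600 … 50–100 Hz plus an approximation below 50 Hz). Per level,
   the relative energy `E_r = Σ x_n² / Σ x_i²` of each 10-ms section is
   compared against the primary section (0–10 ms linear, 10–20 ms
   angular); levels whose late sections exceed the primary by more than
   10 percentage points are rejected as artifact, D1/D2 are always
   rejected, the approximation is always kept, and the pre-trigger
   portion of every level re-enters the reconstruction. The salvaged
   event is re-processed and re-classified to verify the repair.
4. **Baselines** — three simpler predictors for comparison: the
   Delta-prox proximity change, the manufacturer's 0/1/2 quality grade
   (0 → coupled, 1/2 → decoupled), and per-device two-means proximity
   thresholding gated by a 0.9 silhouette score.

Because laboratory/field iMG datasets of this kind are not publicly
deposited, a synthetic impact generator with analytic ground truth
(half-sine pulses, 25–100 g, rigid 3–5 ms or padded 10–12 ms durations,
late damped-sinusoid decoupling artifacts) exercises the whole chain and
quantifies accuracy against known truth.

## Worked example

```python
from imgdecouple.simulate import (ImpactScenario, ArtifactSpec, SimConfig,
                                  simulate_coupled_event, inject_decoupling)
from imgdecouple.signals import process_event
from imgdecouple.evaluate import post_trigger_peak, percent_error
from imgdecouple.salvage import salvage_event

cfg = SimConfig()
scenario = ImpactScenario(peak_lin_g=75.0, lin_duration_ms=11.0,
                          direction=(0.8, 0.2, 0.57))
record, truth = simulate_coupled_event(scenario, cfg, seed=7)
spec = ArtifactSpec(onset_ms=14.0, freq_hz=170.0, amplitude_ratio=3.0,
                    gyro_amplitude_ratio=0.5)
decoupled = inject_decoupling(record, truth, spec, seed=8)

truth_peak = post_trigger_peak(truth.resultant_lin)
raw_peak = post_trigger_peak(process_event(decoupled).resultant_lin)
res = salvage_event(decoupled)
salv_peak = post_trigger_peak(process_event(res.salvaged_record).resultant_lin)
print(f"true {truth_peak:.1f} g | measured {raw_peak:.1f} g "
      f"({percent_error(raw_peak, truth_peak):+.1f}%) | "
      f"salvaged {salv_peak:.1f} g "
      f"({percent_error(salv_peak, truth_peak):+.1f}%)")
```

prints

```
true 75.0 g | measured 161.2 g (+115.0%) | salvaged 72.1 g (-3.8%)
```

The injected 170 Hz artifact more than doubles the apparent peak; level
selection rejects the contaminated detail bands (only the approximation
survives on linear Z) and the reconstructed peak lands within 4% of truth.

The same chain is available from the shell:

```sh
imgdecouple simulate --n 160 --decoupled-frac 0.25 --seed 1 --out events/
imgdecouple features --events events/ --out features.csv
imgdecouple train    --features features.csv --out model.json
imgdecouple salvage  --events events/ --model model.json --out salvaged/
imgdecouple run      --n 160 --seed 1 --out run/     # full demo pipeline
```

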