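# Methods

This note documents the models, conventions and numerical choices behind
`imgdecouple`, in the order data flows through the package.

## Signal model and processing conventions

An event is a six-channel record — three linear accelerometer channels in
g and three gyroscope channels in rad/s — sampled at 3200 Hz from 10 ms
before to 40 ms after the moment any single sensor axis crosses 8 g
(t = 0 at the trigger sample). Processing to head-CG kinematics follows
the standard iMG chain:

* **Re-orientation.** A 3×3 orthonormal matrix (checked to 1e-9) rotates
  sensor-frame vectors into the SAE J211 head frame. Synthetic data uses
  the identity; real devices must supply their calibration in the JSON
  sidecar.
* **Filtering.** "Fourth-order phaseless low-pass" is implemented as a
  2nd-order Butterworth applied forward and backward (`filtfilt`), the
  usual impact-biomechanics construction: the two passes square the
  magnitude response (effective order 4) and cancel each other's phase.
  `FilterSpec.order_per_pass` exposes the alternative reading (4 per
  pass). Defaults: 175 Hz linear, 250 Hz gyro. Gyro channels are
  filtered **before** differentiation; the reverse order would amplify
  noise before attenuating it.
* **Differentiation.** Five-point central stencil
  `(f[-2h] − 8f[-h] + 8f[h] − f[2h])/(12h)`, exact through quartics;
  the two samples at each edge use 2nd-order one-sided differences
  (the edge treatment is a package choice; results at the window edges
  never drive features or selection rules).
* **CG transport.** `a_CG = a_P + ω×(ω×r) + α×r` per sample, with `r`
  pointing from the CG to the sensor point P. The sign convention is
  closed by construction: the simulator generates sensor data with the
  exact inverse relation, and a round-trip test requires the processed
  peak to recover the ground-truth peak. Accelerations are stored in g
  and converted to m/s² only inside the transport. The default synthetic
  lever arm (0.08, 0, 0.06) m places the sensor anterior/inferior of the
  CG, plausible for an upper-dentition device; it is a configurable
  convention, not a measurement.

## Features

* **Band content (f1–f3).** The signal is zero-padded to 5× its length,
  and the one-sided spectrum |FFT|·2/N up to Nyquist is normalised into a
  distribution of spectral content over frequency; the feature is the
  CDF difference between 500 and 100 Hz, in percent. The distribution
  weights bins by **power** (squared amplitude) by default: under power
  weighting a pure in-band tone concentrates >99% of its content in the
  band, whereas amplitude weighting leaves 10–15% of the mass in
  rectangular-window leakage sidelobes of even a pure tone (their
  amplitude decays only as 1/Δf). `FeatureConfig.spectrum_weight =
  "amplitude"` switches to the direct amplitude cumulation. Both
  readings are scale-invariant and give 100% on the full band.
* **Peak order (f4).** Local maxima of the resultant linear acceleration
  are strict-neighbour peaks with no prominence threshold (plateaus
  collapse to their first sample); peaks before t = 0 are discarded as
  pre-trigger artifacts; the feature is the 1-based time-order rank of
  the global maximum, ties resolving to the earliest.
* **Spectrogram timing (f5–f7).** Hamming-windowed STFT with 12-ms
  segments (38 samples) and 90% overlap (hop 4); the feature is the
  center time of the bin holding the global magnitude maximum, reported
  in ms relative to the trigger. Bins centred before t = 0 are eligible:
  the window is short enough that clamping would only hide genuinely
  early energy. The full −10…+40 ms window feeds both FFT and STFT.

The final classifier uses f1 (linear Z), f3 (angular-acceleration Y), f4
and f7 (angular-acceleration Y); f2/f5/f6 are computed on request.

## Detector

Instance-based KNN with k = 4, city-block distance, uniform votes, on
per-feature z-scores fitted from training data only. Two deterministic
tie rules are fixed because 4-neighbour voting needs them: 2–2 vote ties
predict *decoupled* (sensitivity to true decoupling is worth more than
specificity, since salvaging a coupled event is nearly benign), and
distance ties at the k-th neighbour admit the lexicographically first
event id. Cross-validation is stratified 10-fold with a required seed
(default 20250208), the standardizer refitted inside every training fold.
Serialisation embeds the full standardized training set — an
instance-based learner has no other weights.

## Salvaging

Each raw channel is filtered (175/250 Hz), then decomposed with the
SWT-based additive multiresolution analysis (`pywt.mra`, db10, 5 levels)
— the same filter bank as the maximal-overlap DWT MRA up to boundary
handling, shift-invariant and summing exactly back to the input. Nominal
dyadic sub-bands at 3200 Hz: D1 800–1600, D2 400–800, D3 200–400, D4
100–200, D5 50–100, A 0–50 Hz. Signals are reflection-padded on both
ends by one level-5 filter support (capped at signal length − 1, rounded
up so the padded length is a multiple of 2⁵) and trimmed after.

Selection uses the relative section energy `E_r` (a level's sum of
squares in one 10-ms section over its total), on a grid aligned to the
trigger:

* D1 and D2 are always rejected; the approximation is always kept.
* Linear channels: D3–D5 rejected iff the 10–20 or 20–30 ms section
  exceeds the 0–10 ms primary by more than 0.10. The "10% relative
  energy" increment is read additively, in fractions of the within-level
  section share — the only reading under which the rule compares like
  with like.
* Gyro channels: D3 always rejected (angular signals are slower); the
  primary section shifts to 10–20 ms (angular velocity peaks later),
  compared against 20–30 and 30–40 ms; D4 is rejected outright when it
  carries more than 10% of the channel's total component energy. The
  outright rule's denominator (total energy across all six components of
  that channel) is the only well-defined whole-level reading; it is
  applied to gyro channels only, where the angular-velocity modification
  belongs, with `SalvageConfig.outright_on_linear` to extend it.
* A level with zero energy has an undefined section profile and is kept
  as harmless silence.
* Reconstruction adds the approximation and kept details for t ≥ 0 and
  **all** details before t = 0, so the pre-trigger baseline always
  reproduces the input regardless of selection.
* The partial pre-trigger section participates in `E_r` totals but never
  in keep/reject comparisons; sections beyond 30 ms (linear) / 40 ms
  (angular) are likewise never comparison inputs.

Salvaged channels are pushed back through the standard processing chain
(the second filter pass is harmless: the passband reapplication changes
a 10-ms half-sine peak by well under 2%), features re-extracted, and the
event re-classified; `salvage_success` records whether the verdict
flipped to coupled. Salvaging is intended for decoupled-classified events
only; the CLI salvages others only behind `--force-coupled`.

## Proximity baselines

Delta-prox compares |post − pre| against a strict threshold; the
manufacturer's value is proprietary, so the default (30 units) is a free
parameter chosen so simulated coupled events at the default reading noise
(sd 5 units around a 200-unit on-teeth mean) essentially never cross it.
Quality maps 0 → coupled, 1/2 → decoupled. The per-device k-means method
clusters a device's readings into two groups (deterministic
initialisation at the 10th/90th percentiles; readings sorted first so the
fit is order-invariant), gates on a mean silhouette of 0.9 (Euclidean,
1-D), and thresholds at the midpoint of the cluster means; pre/post
readings above/below the threshold give the four-state verdict, and the
binary collapse counts everything but "coupled" as decoupled. Lab-style
use pools only per-impact pre/mid/post readings per device, because a
field series from a device that never moves before impacts is biased
toward on-teeth values.

## Synthetic study conditions

The generator's defaults are the study conditions, fixed once:

* Severities 25/50/75/100 g; half-sine linear pulses of 3–5 ms
  (rigid-like) or 10–12 ms (padded-like); the pulse is timed so the
  strongest axis crosses 8 g, rising, exactly at t = 0. Angular velocity
  is a raised cosine peaking 5 ms after the linear peak (angular signals
  peak later in coupled impacts), capped at the 35 rad/s gyro range.
  Sensor noise: white Gaussian, sd 0.5 g / 0.3 rad/s.
* Overall 40% of events are rigid-like, but only 15% of *decoupled*
  events are: laboratory decoupling arose overwhelmingly under padded
  impacts.
* Decoupling artifacts are damped sinusoids on linear Z and gyro X/Y
  (random phase split between the gyro axes), onset 8–30 ms, decay
  constant 5–15 ms, frequency drawn from 115–250 Hz — the lower part of
  the 100–500 Hz artifact band, where artifacts survive the acquisition
  filters strongly enough to visibly corrupt peaks. Amplitudes
  (2.3–4.0× the true peak resultant linear acceleration on linear Z;
  0.30–0.65× the true angular-velocity peak on the gyros) were
  calibrated once so that typical post-processing of decoupled events
  inflates peak linear acceleration by ≈ +120% on average at the
  160-event replica — the error scale reported for decoupled laboratory
  impacts — and were not revisited.
* Proximity: a two-state latent model per device (on-teeth mean 200,
  off-teeth 60, sd 5); decoupled events read off-teeth from mid-impact
  onward. Quality grades are label-correlated but noisy (60% correct).

What the simulator does **not** emulate: jaw-clack or chewing noise,
helmet/neck compliance, multi-impact windows, sensor calibration error
and clock drift, and the heavy-tailed artifact statistics of real field
data. Passing tests therefore demonstrate that the chain is implemented
correctly and behaves as designed under controlled artifact models — not
that the detector's synthetic operating point transfers to any particular
field population.

## Numerical choices and degenerate inputs

All-zero signals make the band features undefined (explicit error rather
than NaN); empty confusion-matrix margins yield NaN metrics rather than
exceptions so fold aggregation survives; all-identical proximity readings
give an "unclear" device; zero-energy wavelet levels are kept. Pipeline
agreement pairs with no jointly defined events (e.g. an all-unclear
device) are reported as null. Every stochastic step takes an explicit
seed, and the demo pipeline's report is bit-reproducible for a fixed
config.

## Problem sizes

The test suite and the acceptance script use a 160-event replica
(120 coupled / 40 decoupled) for detection and salvaging statistics,
60-event sets for shared fixtures, and 100–1000-draw checks for the
numerical oracles — sizes at which every reported statistic is stable to
well within its acceptance margin while the whole suite runs in seconds.
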