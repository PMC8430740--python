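# Methods

## Problem and model

`vitalsentry` monitors hourly bivariate vital-sign streams — body temperature
(°C) and heart rate (bpm) — for health issues, using reconstruction error as
the anomaly score. Two models are implemented:

**GRU autoencoder (GRU-AE).** Three stacked GRU layers in an encode/decode
shape (hidden widths 128 → 32 → 128 by default) process the signal hour by
hour; a fully connected sigmoid head maps the last hidden state back to the
two input channels:

    u_t = σ(W_u x_t + U_u h_{t−1})
    r_t = σ(W_r x_t + U_r h_{t−1})
    h̃_t = tanh(W x_t + r_t ⊙ (U h_{t−1}))
    h_t = u_t ⊙ h_{t−1} + (1 − u_t) ⊙ h̃_t
    y_t = σ(W_y h³_t + b_y)

The gate equations deliberately carry no bias terms; only the output head has
a bias. Two readings of the candidate-memory equation are possible —
`tanh(Wx + r ⊙ (Uh))` and `tanh(Wx + U(r ⊙ h))`; the first is adopted. The
per-hour anomaly score is `Loss_t = ½‖y_t − x_t‖²` on normalized channels,
and the training objective is its sum over time.

**Feedforward baseline.** A per-sample sigmoid stack 2 → 128 → 32 → 128 → 2
with squared-error loss. It sees each hourly sample in isolation, so it can
only learn the joint *marginal* distribution of (temperature, heart rate);
it is structurally blind to time-of-day and to persistence — the contrast
the benchmark is designed to expose, and the reason a sequence model should
win on anomalies that are only anomalous in context.

Both models train only on healthy data: an autoencoder fitted to healthy
signal reconstructs it well and reconstructs anything off the healthy
manifold poorly.

## Gradients and optimization

No autodiff framework is used; gradients are computed by backpropagation
through time, derived by hand and verified against central finite
differences (relative tolerance 1e-4 on small instances — the correctness
contract is the finite-difference check, not the derivation). The
implementation batches all input-side products across timesteps into single
matrix products; only hidden-to-hidden terms stay in the time loop.

Defaults: learning rate 0.01, 4000 epochs, mini-batches of 64 windows,
Adam. Adam is the default because fixed-rate descent at 0.01 is fragile on
recurrent nets; `optimizer="sgd"` gives literal fixed-rate gradient descent.
Weights initialize uniformly in ±√(1/hidden); hidden states start at zero,
where every state component provably stays in (−1, 1). Training runs in
float32 for speed; inference always runs in float64 so hour-by-hour
streaming and whole-sequence scoring agree to machine precision.
Because every unit is bounded (sigmoid/tanh), the loss cannot overflow; the
divergence guard (non-finite loss → error advising a smaller learning rate)
exists for pathological configurations.

## Preprocessing

Channels are min–max scaled to [0.1, 0.9] on the *training* range (the
sigmoid head cannot emit raw °C/bpm; the 0.1/0.9 margins avoid saturation).
Test-set values are deliberately not clipped — fever pushes the temperature
channel above 0.9 and that excursion *is* the signal. The chronological
split keeps weeks 1..train_weeks for training (healthy-only by
construction) and re-bases test hour indices to 1.

Training uses fixed-length windows with non-overlapping stride. The default
window is 168 h (one week). An earlier 24-hour default was rejected after a
diagnostic showed a train/deploy mismatch: monitoring carries hidden state
across the whole multi-week stream, and a model trained only on 24-hour
horizons from zero state drifts once past hour 24, tripling its healthy-hour
loss floor and degrading AUC. Week-long windows cost the same per epoch
(same total timesteps) and match the deployed horizon far better.

## Threshold calibration and monitoring

The alarm threshold is the nearest-rank 99.5th percentile (the ⌈q·n⌉-th
order statistic) of pooled healthy training losses, *computed in streaming
mode* — each training subject's sequence is scored exactly the way the
monitor will score it, so the calibration distribution matches deployment.
The monitor normalizes each arriving sample with the training-time scaler,
advances the carried GRU state (never reset within a subject, always reset
between subjects), and flags hours whose loss exceeds the threshold;
`min_consecutive > 1` optionally requires a run of exceedances, since brief
exercise spikes are an expected healthy confounder. An alarm is emitted at
each transition into the unhealthy state. A subject is judged unhealthy iff
at least one hour is flagged.

## Evaluation conventions

The positive class is **healthy** throughout: TP = predicted healthy &
actually healthy, FP = predicted healthy & actually unhealthy (a missed
illness), TPR = TP/(TP+FN), FPR = FP/(FP+TN). AUC uses the rank formula
`AUC = (Σ_{i∈healthy} rank_i − M(M+1)/2)/(M·N)` on the healthiness score
(negated loss), with average ranks on ties — equal to the exhaustive
pairwise win probability (ties ½) and to the trapezoidal area under the
swept ROC, both asserted in tests. Negating the loss before ranking matters:
mixing the healthy-as-positive convention with a raw anomaly score silently
yields 1 − AUC. Per-subject AUC is computed only for subjects whose test
window contains both classes; single-class subjects are excluded from the
mean and counted separately. Undefined ratios (empty classes) are reported
as NaN with a warning, never silently zero.

## Synthetic cohort generator

The generator emulates a 2000-subject, 24-week hourly study (8,064,000
samples; weeks 1–20 train, 21–24 test; 613 subjects with health-issue
episodes; 978 male / 1022 female, ages 18–50 uniform). Healthy signal per
channel = mean + circadian sinusoid + Gaussian noise, plus Poisson-placed
1–2 h activity spikes (exercise: heart rate +25–60 bpm, temperature
+0.2–0.5 °C) that are labeled *healthy* — the stated confounder a monitor
must not flag. Defaults: temperature 36.6 ± 0.1 °C (sd) with ±0.4 °C
circadian amplitude; heart rate 72 ± 3 bpm with ±10 bpm amplitude; 2
spikes/week. Episodes (fever 37.3–38.0 °C with heart rate 99–170 bpm, drawn
uniformly per hour with 2-hour edge ramps pulled toward the range minima)
last 5–12 h, 1–2 per affected subject, placed only in the test weeks so the
training period is healthy-only. Each subject draws from an independent
stream keyed by (seed, subject index), making cohorts bit-identical for a
given (config, seed).

What the simulator does *not* model: physiological thermoregulation or
cardiovascular dynamics, age/sex effects on the signals, sensor dropout or
artifacts, gradual illness onset beyond the linear ramp, or any coupling
between temperature and heart rate beyond their shared circadian phase and
shared spikes. Passing end-to-end tests therefore shows that the method
recovers episodes of the injected kind under these idealized conditions —
not that it would perform identically on wearable-device data.

The printed-sample fixture of the two example test subjects preserves the
physiologically impossible 1140 bpm reading verbatim with a `suspect` flag
(opt-in correction to 114 bpm); provenance fidelity beats silent repair.

## Benchmark problem sizes

The end-to-end comparison trains both models at full architecture
(128/32/128) on a 40-subject, 6-week cohort (weeks 1–4 train, 5–6 test, 10
episode subjects) for 300 epochs, averaged over seeds 1–3 — sizes chosen so
a complete run finishes on a single desk CPU while preserving the study's
structure (healthy-only training, chronological split, episodes confined to
the test window). The full 2000-subject configuration is generated and
counted in tests, but models are not trained at that scale here.

## Known limitations

- The GRU-AE's advantage hinges on temporal structure in the data; on
  signals whose anomalies are grossly out of marginal range, the memoryless
  baseline is nearly as good, and the measured AUC gap is small.
- Threshold calibration assumes the training weeks are truly healthy;
  contamination inflates the threshold.
- The rank-formula AUC is exact but O(n log n) per subject; pooled AUC over
  millions of hours is memory-bound (it materializes the pooled score
  vector).
- Windows shorter than the deployed stream horizon reintroduce the drift
  mismatch described above; keep the training window at or above the scale
  of the monitored sequences where feasible.
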