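# vitalsentry

Reconstruction-error health monitoring of multivariate vital-sign time
series, for researchers and engineers building wearable-device health
alarms: a **GRU autoencoder** (GRU-AE) scores every hour of a subject's body
temperature (°C) and heart rate (bpm) by how poorly it can be reconstructed,
and flags hours whose loss exceeds a threshold calibrated on healthy data.
A memoryless feedforward autoencoder baseline, the streaming alarm workflow,
rank-statistic ROC/AUC evaluation, and a synthetic circadian cohort
simulator (for end-to-end testing without any data download) are included.

## Model

Three stacked GRU layers (hidden widths 128 → 32 → 128) followed by a fully
connected sigmoid head, applied to the normalized hourly signal x_t ∈ ℝ²:

    u_t = σ(W_u x_t + U_u h_{t−1})           update gate
    r_t = σ(W_r x_t + U_r h_{t−1})           reset gate
    h̃_t = tanh(W x_t + r_t ⊙ (U h_{t−1}))    candidate memory
    h_t = u_t ⊙ h_{t−1} + (1 − u_t) ⊙ h̃_t
    y_t = σ(W_y h³_t + b_y)                  reconstruction

trained on **healthy data only** to minimize Σ_t ½‖y_t − x_t‖². At
monitoring time, Loss_t = ½‖y_t − x_t‖² is the anomaly score; an hour is
flagged unhealthy iff Loss_t exceeds the 99.5th-percentile (nearest-rank) of
pooled healthy training losses. Evaluation follows the healthy-as-positive
convention (TP = predicted healthy & actually healthy) with AUC computed by
the rank formula `(Σ_{i∈healthy} rank_i − M(M+1)/2)/(M·N)` on the negated
loss. Gradients are exact backpropagation-through-time in numpy, verified
against finite differences. See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

```python
import numpy as np
from vitalsentry import (
    CohortConfig, GruAutoencoder, MonitorConfig, calibrate_threshold,
    chronological_split, cohort_windows, fit_normalizer, generate_cohort,
    monitor_stream,
)
from vitalsentry.monitor import streaming_training_losses

cfg = CohortConfig(n_subjects=10, n_weeks=6, train_weeks=4,
                   n_unhealthy_subjects=3, n_male=5, seed=101)
cohort = generate_cohort(cfg)
train, test = chronological_split(cohort)
scaler = fit_normalizer(train)                      # [0.1, 0.9] on train range

wb = cohort_windows(train, scaler)                  # week-long windows
model = GruAutoencoder(n_epochs=300, random_state=101).fit(wb.windows)
thr = calibrate_threshold(streaming_training_losses(model, train, scaler))

sick = next(s for s in test.series if s.label.max() == 1)
trace, alarms, verdicts = monitor_stream(
    sick, MonitorConfig(model=model, normalizer=scaler, threshold=thr))
ep = test.episodes[test.episodes.subject_id == sick.subject_id]
print(f"threshold {thr:.5f}; {len(alarms)} alarm(s) at hours "
      f"{[a.hour_index for a in alarms]}; true episodes "
      f"{list(zip(ep.start_hour, ep.end_hour))}")
```

Output:

```
threshold 0.00130; 5 alarm(s) at hours [135, 209, 215, 230, 306]; true episodes [(209, 214), (135, 139)]
```

The model was never shown an episode, yet both injected fever episodes
trigger alarms exactly at their onset hours (135 and 209): in-episode
reconstruction loss jumps orders of magnitude above the healthy floor. The
alarm at 215 is the state recovering just after an episode ends; 230 and
306 are isolated false alarms on healthy exercise spikes — the expected
cost of a 99.5th-percentile threshold, suppressible with
``min_consecutive=2``. On the bundled benchmark (40 subjects, 6 weeks, 10
episode subjects, seeds 1–3) the GRU-AE's mean per-subject AUC is 0.988
against the memoryless baseline's 0.981: both rank grossly out-of-range
fever hours well, but only the recurrent model holds its advantage when
episode values overlap the healthy marginal range.

The same pipeline is scriptable from the shell:

```bash
vitalsentry simulate --subjects 40 --weeks 6 --train-weeks 4 --unhealthy 10 \
    --seed 1 --out cohort.csv
vitalsentry train    --cohort cohort.csv --train-weeks 4 --epochs 300 \
    --seed 1 --out gru.npz
vitalsentry monitor  --cohort cohort.csv --checkpoint gru.npz --out alarms.csv
```

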