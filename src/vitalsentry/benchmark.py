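"""Scaled-down end-to-end detection benchmark.

Trains both models on the healthy training weeks of a small synthetic cohort
and reports per-subject AUCs on the test weeks.  Problem sizes default to a
40-subject, 6-week cohort (weeks 1–4 train, 5–6 test) with 10 episode
subjects and 300 training epochs — small enough for a desk run while keeping
the full 128/32/128 architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import evaluate_models
from .models import Autoencoder, GruAutoencoder
from .monitor import MonitorConfig, calibrate_threshold, streaming_training_losses
from .preprocessing import chronological_split, cohort_windows, fit_normalizer
from .synthetic import CohortConfig, generate_cohort


@dataclass
class BenchmarkResult:
    seed: int
    gru_subject_auc: float
    ae_subject_auc: float
    gru_pooled_auc: float
    ae_pooled_auc: float
    reports: dict


def run_benchmark(
    seed: int,
    n_subjects: int = 40,
    n_weeks: int = 6,
    train_weeks: int = 4,
    n_unhealthy: int = 10,
    n_epochs: int = 300,
    window_length: int = 168,
    calibration_quantile: float = 0.995,
) -> BenchmarkResult:
    """Generate → split → train both models → evaluate; fully seeded."""
    cfg = CohortConfig(
        n_subjects=n_subjects,
        n_weeks=n_weeks,
        train_weeks=train_weeks,
        n_unhealthy_subjects=n_unhealthy,
        n_male=round(n_subjects * 978 / 2000),
        seed=seed,
    )
    cohort = generate_cohort(cfg)
    train, test = chronological_split(cohort)
    scaler = fit_normalizer(train)

    wb = cohort_windows(train, scaler, window_length=window_length)
    gru = GruAutoencoder(n_epochs=n_epochs, random_state=seed).fit(wb.windows)
    gru_train_losses = streaming_training_losses(gru, train, scaler)

    X = np.concatenate([scaler.transform(s.values()) for s in train.series])
    ae = Autoencoder(n_epochs=n_epochs, random_state=seed).fit(X)
    ae_train_losses = ae.score_samples(X)

    configs = {
        "gru_ae": MonitorConfig(
            model=gru,
            normalizer=scaler,
            threshold=calibrate_threshold(gru_train_losses, calibration_quantile),
        ),
        "ae": MonitorConfig(
            model=ae,
            normalizer=scaler,
            threshold=calibrate_threshold(ae_train_losses, calibration_quantile),
        ),
    }
    reports = evaluate_models(test, configs)
    return BenchmarkResult(
        seed=seed,
        gru_subject_auc=reports["gru_ae"].subject_auc_mean,
        ae_subject_auc=reports["ae"].subject_auc_mean,
        gru_pooled_auc=reports["gru_ae"].pooled_auc,
        ae_pooled_auc=reports["ae"].pooled_auc,
        reports=reports,
    )
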