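"""Streaming health monitoring: score, threshold, alarm.

Each incoming hourly sample is normalized, pushed through the trained
reconstruction model (hidden state carried across hours within a subject,
reset between subjects), and scored by Loss_t = ½‖y_t − x_t‖².  Hours whose
loss exceeds a calibrated threshold — by default the 99.5th nearest-rank
percentile of pooled healthy training losses — are flagged unhealthy, and an
alarm is emitted at each transition into the unhealthy state.  A subject is
judged unhealthy if any hour of their stream is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .exceptions import ConfigurationError, ShapeError
from .models import Autoencoder, GruAutoencoder, LossTrace
from .preprocessing import VitalScaler
from .synthetic import VitalSeries


@dataclass
class MonitorConfig:
    """Deployed monitoring settings for one trained model."""

    model: GruAutoencoder | Autoencoder
    normalizer: VitalScaler
    threshold: float
    calibration_quantile: float = 0.995
    min_consecutive: int = 1

    def validate(self) -> None:
        if self.threshold <= 0:
            raise ConfigurationError("threshold must be > 0")
        if not 0 < self.calibration_quantile <= 1:
            raise ConfigurationError("calibration_quantile must be in (0, 1]")
        if self.min_consecutive < 1:
            raise ConfigurationError("min_consecutive must be >= 1")


@dataclass
class AlarmEvent:
    """One transition into the unhealthy state."""

    subject_id: str
    hour_index: int
    loss: float
    threshold: float


def calibrate_threshold(healthy_losses, quantile: float = 0.995) -> float:
    """Nearest-rank quantile (the ⌈q·n⌉-th order statistic) of pooled losses.

    ``healthy_losses`` may be an array, a LossTrace, or a collection of
    either; everything is pooled before ranking.
    """
    if not 0 < quantile <= 1:
        raise ConfigurationError("quantile must be in (0, 1]")
    pooled = _pool(healthy_losses)
    if pooled.size == 0:
        raise ValueError("cannot calibrate a threshold from an empty loss collection")
    k = max(ceil(quantile * pooled.size), 1)
    return float(np.sort(pooled)[k - 1])


def _pool(losses) -> np.ndarray:
    if isinstance(losses, LossTrace):
        return np.asarray(losses.per_timestep, dtype=float).ravel()
    if isinstance(losses, np.ndarray):
        return losses.astype(float).ravel()
    parts = [_pool(x) for x in losses]
    return np.concatenate(parts) if parts else np.array([])


def _flag_runs(exceed: np.ndarray, min_consecutive: int) -> np.ndarray:
    """Hours belonging to a run of >= min_consecutive consecutive exceedances."""
    if min_consecutive <= 1:
        return exceed.copy()
    verdict = np.zeros_like(exceed)
    n = len(exceed)
    i = 0
    while i < n:
        if exceed[i]:
            j = i
            while j < n and exceed[j]:
                j += 1
            if j - i >= min_consecutive:
                verdict[i:j] = True
            i = j
        else:
            i += 1
    return verdict


def monitor_stream(series: VitalSeries, config: MonitorConfig):
    """Score one subject's stream; returns (LossTrace, alarms, verdicts).

    Verdicts are per-hour booleans (True = unhealthy).  Hidden state is
    carried across the whole stream and never reset mid-subject, so scoring
    the series in one pass equals scoring it hour by hour.
    """
    config.validate()
    X = series.values()
    if X.shape[1] != config.normalizer.n_features_in_:
        raise ShapeError(
            f"series has {X.shape[1]} channels, normalizer expects "
            f"{config.normalizer.n_features_in_}"
        )
    Xn = config.normalizer.transform(X)
    losses = np.asarray(config.model.score_samples(Xn), dtype=float).ravel()
    exceed = losses > config.threshold
    verdicts = _flag_runs(exceed, config.min_consecutive)
    alarms = []
    prev = False
    for i, v in enumerate(verdicts):
        if v and not prev:
            alarms.append(
                AlarmEvent(
                    subject_id=series.subject_id,
                    hour_index=int(series.hour_index[i]),
                    loss=float(losses[i]),
                    threshold=config.threshold,
                )
            )
        prev = bool(v)
    trace = LossTrace(per_timestep=losses, hour_index=series.hour_index.copy())
    return trace, alarms, verdicts


def subject_verdict(verdicts) -> str:
    """Subject-level call: 'unhealthy' iff any hourly verdict is unhealthy."""
    v = np.asarray(verdicts)
    if v.size == 0:
        raise ValueError("cannot judge a subject with no hourly verdicts")
    return "unhealthy" if bool(v.any()) else "healthy"


def streaming_training_losses(model, cohort, normalizer) -> np.ndarray:
    """Healthy-loss pool for calibration, scored the way the monitor scores.

    Each training subject's whole sequence is pushed through the model as one
    carried-state stream, so the calibration distribution matches deployment
    rather than the (shorter) training windows.
    """
    pools = []
    for s in cohort.series:
        Xn = normalizer.transform(s.values())
        pools.append(np.asarray(model.score_samples(Xn), dtype=float).ravel())
    return np.concatenate(pools)


def monitor_cohort(cohort, config: MonitorConfig):
    """Monitor every subject; returns (alarms, per-subject verdict dict)."""
    all_alarms: list[AlarmEvent] = []
    verdicts: dict[str, str] = {}
    for s in cohort.series:
        _, alarms, v = monitor_stream(s, config)
        all_alarms.extend(alarms)
        verdicts[s.subject_id] = subject_verdict(v)
    return all_alarms, verdicts
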