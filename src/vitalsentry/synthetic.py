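"""Synthetic vital-sign cohort simulator.

Generates labeled hourly bivariate (body temperature, heart rate) series for a
cohort of subjects.  Healthy signal = circadian sinusoid + Gaussian noise +
occasional short activity spikes (exercise; labeled healthy).  Health-issue
episodes (fever plus elevated heart rate) are injected into a fixed number of
subjects, by default only within the test weeks, so the training period
contains healthy data only.

The default configuration emulates a 2000-subject, 24-week study sampled
hourly (8,064,000 samples) with 613 subjects carrying at least one episode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, RangeError

HOURS_PER_WEEK = 168
CHANNELS = ("temperature_c", "heart_rate_bpm")

# circadian minimum sits in the early morning; phase shift puts the peak
# in the late afternoon (hour ~20 solar time)
_CIRCADIAN_PHASE_HOURS = 8.0


@dataclass
class EpisodeSpec:
    """Shape of an injected health-issue episode.

    onset_window : (first, last) absolute 1-based hour between which the
        episode may start; ``None`` means "within the test weeks" and is
        resolved by the cohort config.
    duration_range : inclusive bounds on episode length, hours.
    fever_temp_range : °C bounds for in-episode temperature draws.
    episode_hr_range : bpm bounds for in-episode heart-rate draws.
    transition : ramp length in hours at each episode edge; ramp values are
        pulled toward the lower bound of the range so every in-episode sample
        stays inside the configured range.
    """

    onset_window: tuple[int, int] | None = None
    duration_range: tuple[int, int] = (5, 12)
    fever_temp_range: tuple[float, float] = (37.3, 38.0)
    episode_hr_range: tuple[float, float] = (99.0, 170.0)
    transition: int = 2

    def validate(self) -> None:
        for name in ("duration_range", "fever_temp_range", "episode_hr_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"EpisodeSpec.{name} is empty: {lo} > {hi}")
        if self.duration_range[0] < 0:
            raise ConfigurationError("EpisodeSpec.duration_range must be nonnegative")
        if self.transition < 0:
            raise ConfigurationError("EpisodeSpec.transition must be nonnegative")


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort (defaults: the study design)."""

    n_subjects: int = 2000
    n_weeks: int = 24
    train_weeks: int = 20
    n_unhealthy_subjects: int = 613
    n_male: int = 978
    age_range: tuple[int, int] = (18, 50)
    healthy_temp_mean: float = 36.6
    healthy_temp_sd: float = 0.1
    healthy_hr_mean: float = 72.0
    healthy_hr_sd: float = 3.0
    circadian_amplitude_temp: float = 0.4
    circadian_amplitude_hr: float = 10.0
    activity_spike_rate: float = 2.0  # events / week, labeled healthy
    episodes_per_subject: tuple[int, int] = (1, 2)
    episode_spec: EpisodeSpec = field(default_factory=EpisodeSpec)
    allow_training_episodes: bool = False
    seed: int = 0

    @property
    def n_hours(self) -> int:
        return self.n_weeks * HOURS_PER_WEEK

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_weeks < 1:
            raise ConfigurationError("n_subjects and n_weeks must be >= 1")
        if self.n_unhealthy_subjects > self.n_subjects:
            raise ConfigurationError(
                f"n_unhealthy_subjects ({self.n_unhealthy_subjects}) exceeds "
                f"n_subjects ({self.n_subjects})"
            )
        if self.n_male > self.n_subjects:
            raise ConfigurationError(
                f"n_male ({self.n_male}) exceeds n_subjects ({self.n_subjects})"
            )
        if not 0 < self.train_weeks <= self.n_weeks:
            raise ConfigurationError(
                f"train_weeks ({self.train_weeks}) must be in 1..n_weeks ({self.n_weeks})"
            )
        if self.age_range[0] > self.age_range[1]:
            raise ConfigurationError("age_range is empty")
        self.episode_spec.validate()
        if self.episode_spec.fever_temp_range[0] <= self.healthy_temp_mean:
            raise ConfigurationError(
                "fever_temp_range lower bound must exceed healthy_temp_mean"
            )

    def resolved_episode_spec(self) -> EpisodeSpec:
        """Episode spec with the onset window made explicit."""
        spec = self.episode_spec
        if spec.onset_window is not None:
            return spec
        start = 1 if self.allow_training_episodes else self.train_weeks * HOURS_PER_WEEK + 1
        return replace(spec, onset_window=(start, self.n_hours))


@dataclass
class VitalSeries:
    """One subject's hourly bivariate signal with per-hour health labels.

    ``label`` is 1 for unhealthy hours (inside injected episodes) and 0
    otherwise; ``hour_index`` is 1-based and consecutive within its split.
    """

    subject_id: str
    sex: str
    age: int
    hour_index: np.ndarray
    temperature: np.ndarray
    heart_rate: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.hour_index)
        if not (len(self.temperature) == len(self.heart_rate) == len(self.label) == n):
            raise ConfigurationError("VitalSeries channel/label lengths differ")
        if n and not np.all(np.diff(self.hour_index) == 1):
            raise ConfigurationError("hour_index must increase by exactly 1")

    def __len__(self) -> int:
        return len(self.hour_index)

    def values(self) -> np.ndarray:
        """(T, 2) array of [temperature_c, heart_rate_bpm]."""
        return np.column_stack([self.temperature, self.heart_rate])


@dataclass
class Cohort:
    """A collection of :class:`VitalSeries` plus the episode ground truth."""

    series: list[VitalSeries]
    episodes: pd.DataFrame  # columns: subject_id, start_hour, end_hour
    config: CohortConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_samples(self) -> int:
        return sum(len(s) for s in self.series)

    def __iter__(self):
        return iter(self.series)


def _circadian(hour_index: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    phase = 2.0 * np.pi * ((hour_index % 24) - _CIRCADIAN_PHASE_HOURS) / 24.0
    return mean + amplitude * np.sin(phase)


def _healthy_signal(rng: np.random.Generator, config: CohortConfig, n_hours: int):
    hours = np.arange(1, n_hours + 1)
    temp = _circadian(hours, config.healthy_temp_mean, config.circadian_amplitude_temp)
    temp = temp + rng.normal(0.0, config.healthy_temp_sd, n_hours)
    hr = _circadian(hours, config.healthy_hr_mean, config.circadian_amplitude_hr)
    hr = hr + rng.normal(0.0, config.healthy_hr_sd, n_hours)

    # exercise bouts: brief simultaneous HR + temperature elevation, healthy
    n_spikes = rng.poisson(config.activity_spike_rate * config.n_weeks)
    for _ in range(n_spikes):
        start = int(rng.integers(0, n_hours))
        dur = int(rng.integers(1, 3))
        sl = slice(start, min(start + dur, n_hours))
        hr[sl] += rng.uniform(25.0, 60.0)
        temp[sl] += rng.uniform(0.2, 0.5)
    return hours, temp, hr


def inject_episode(
    series: VitalSeries,
    spec: EpisodeSpec,
    seed: int | np.random.Generator,
    onset: int | None = None,
    duration: int | None = None,
) -> VitalSeries:
    """Return a copy of ``series`` with one health-issue episode injected.

    In-episode temperature and heart rate are drawn uniformly within the
    spec's ranges, with edge ramps of ``spec.transition`` hours pulled toward
    each range's lower bound.  Labels are set unhealthy exactly inside the
    episode; every sample outside is bit-identical to the input.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is None:
        duration = int(rng.integers(spec.duration_range[0], spec.duration_range[1] + 1))
    if len(series) == 0:
        raise RangeError("cannot inject an episode into an empty series")
    first, last = int(series.hour_index[0]), int(series.hour_index[-1])
    out = VitalSeries(
        subject_id=series.subject_id,
        sex=series.sex,
        age=series.age,
        hour_index=series.hour_index.copy(),
        temperature=series.temperature.copy(),
        heart_rate=series.heart_rate.copy(),
        label=series.label.copy(),
    )
    if duration == 0:
        return out
    if onset is None:
        w0, w1 = spec.onset_window if spec.onset_window is not None else (first, last)
        w0, w1 = max(w0, first), min(w1, last)
        hi = w1 - duration + 1
        if hi < w0:
            raise RangeError(
                f"episode of duration {duration} does not fit in onset window ({w0}, {w1})"
            )
        onset = int(rng.integers(w0, hi + 1))
    if onset < first or onset + duration - 1 > last:
        raise RangeError(
            f"episode [{onset}, {onset + duration - 1}] outside series hours "
            f"[{first}, {last}]"
        )
    i0 = onset - first
    sl = slice(i0, i0 + duration)

    ramp = np.minimum(np.arange(1, duration + 1), np.arange(duration, 0, -1))
    frac = np.minimum(ramp / (spec.transition + 1.0), 1.0)
    t_lo, t_hi = spec.fever_temp_range
    h_lo, h_hi = spec.episode_hr_range
    out.temperature[sl] = t_lo + frac * (rng.uniform(t_lo, t_hi, duration) - t_lo)
    out.heart_rate[sl] = h_lo + frac * (rng.uniform(h_lo, h_hi, duration) - h_lo)
    out.label[sl] = 1
    return out


def episode_truth(series: VitalSeries) -> np.ndarray:
    """Ground-truth vector with healthy as the positive class (healthy ↔ 1)."""
    return (1 - series.label).astype(np.int8)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> Cohort:
    """Generate a reproducible labeled cohort.

    Each subject draws from an independent stream keyed by (seed, subject
    index), so the cohort is bit-identical for a given (config, seed)
    regardless of generation order.  ``seed`` overrides ``config.seed``.
    """
    config = config if config is not None else CohortConfig()
    config.validate()
    seed = config.seed if seed is None else int(seed)

    master = np.random.default_rng([seed, 0])
    unhealthy = set(
        master.choice(config.n_subjects, config.n_unhealthy_subjects, replace=False).tolist()
    )
    males = set(master.choice(config.n_subjects, config.n_male, replace=False).tolist())
    spec = config.resolved_episode_spec()

    width = len(str(max(config.n_subjects - 1, 1)))
    all_series: list[VitalSeries] = []
    episode_rows: list[tuple[str, int, int]] = []
    e_lo, e_hi = config.episodes_per_subject
    for i in range(config.n_subjects):
        rng = np.random.default_rng([seed, i + 1])
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        hours, temp, hr = _healthy_signal(rng, config, config.n_hours)
        s = VitalSeries(
            subject_id=f"S{i:0{width}d}",
            sex="M" if i in males else "F",
            age=age,
            hour_index=hours,
            temperature=temp,
            heart_rate=hr,
            label=np.zeros(config.n_hours, dtype=np.int8),
        )
        if i in unhealthy:
            n_ep = int(rng.integers(e_lo, e_hi + 1))
            placed: list[tuple[int, int]] = []
            for _ in range(max(n_ep, 1)):
                for _try in range(200):
                    dur = int(
                        rng.integers(spec.duration_range[0], spec.duration_range[1] + 1)
                    )
                    dur = max(dur, 1)  # unhealthy subjects must carry >= 1 labeled hour
                    w0, w1 = spec.onset_window
                    hi_start = min(w1, config.n_hours) - dur + 1
                    onset = int(rng.integers(w0, hi_start + 1))
                    if all(onset + dur - 1 < a or onset > b for a, b in placed):
                        break
                else:  # pragma: no cover - extremely unlikely with default sizes
                    continue
                s = inject_episode(s, spec, rng, onset=onset, duration=dur)
                placed.append((onset, onset + dur - 1))
                episode_rows.append((s.subject_id, onset, onset + dur - 1))
        all_series.append(s)

    episodes = pd.DataFrame(episode_rows, columns=["subject_id", "start_hour", "end_hour"])
    return Cohort(series=all_series, episodes=episodes, config=config)
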