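"""Channel scaling, chronological splitting, and sequence windowing.

The model's output layer is a sigmoid, so raw °C / bpm cannot be
reconstructed directly; channels are affinely mapped to [0.1, 0.9] on the
*training* range, leaving margin against sigmoid saturation.  Test-set
anomalies may leave that interval after scaling — they are deliberately not
clipped, since the excursion is the anomaly signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import MinMaxScaler

from .exceptions import ConfigurationError, DegenerateChannelError, RangeError
from .synthetic import HOURS_PER_WEEK, Cohort, VitalSeries


class VitalScaler(MinMaxScaler):
    """Per-channel min–max map of the training range onto [0.1, 0.9].

    A thin wrapper over :class:`sklearn.preprocessing.MinMaxScaler` that
    refuses constant channels (sklearn silently maps them to the interval
    minimum) and never clips, so out-of-range test values keep their
    excursion.
    """

    def __init__(self, feature_range: tuple[float, float] = (0.1, 0.9)):
        if not feature_range[0] < feature_range[1]:
            raise ConfigurationError("feature_range must satisfy low < high")
        super().__init__(feature_range=feature_range, clip=False)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        spans = np.nanmax(X, axis=0) - np.nanmin(X, axis=0)
        flat = np.flatnonzero(spans == 0)
        if flat.size:
            raise DegenerateChannelError(
                f"channel(s) {flat.tolist()} are constant on the training data"
            )
        return super().fit(X, y)


def fit_normalizer(
    train: Cohort | np.ndarray, target_low: float = 0.1, target_high: float = 0.9
) -> VitalScaler:
    """Fit a :class:`VitalScaler` on a training cohort (or raw (n, C) array)."""
    if isinstance(train, Cohort):
        X = np.concatenate([s.values() for s in train.series], axis=0)
    else:
        X = np.asarray(train, dtype=float)
    return VitalScaler(feature_range=(target_low, target_high)).fit(X)


def _split_series(s: VitalSeries, cut: int) -> tuple[VitalSeries, VitalSeries]:
    train = VitalSeries(
        subject_id=s.subject_id,
        sex=s.sex,
        age=s.age,
        hour_index=s.hour_index[:cut].copy(),
        temperature=s.temperature[:cut].copy(),
        heart_rate=s.heart_rate[:cut].copy(),
        label=s.label[:cut].copy(),
    )
    test = VitalSeries(
        subject_id=s.subject_id,
        sex=s.sex,
        age=s.age,
        hour_index=np.arange(1, len(s) - cut + 1),  # re-based to 1 within split
        temperature=s.temperature[cut:].copy(),
        heart_rate=s.heart_rate[cut:].copy(),
        label=s.label[cut:].copy(),
    )
    return train, test


def chronological_split(
    cohort: Cohort, train_weeks: int | None = None
) -> tuple[Cohort, Cohort]:
    """Split every subject at the end of week ``train_weeks``.

    Train keeps hours 1..train_weeks*168; test holds the remainder with
    hour_index re-based to 1.  The episode table is clipped and re-based
    accordingly.
    """
    if train_weeks is None:
        train_weeks = cohort.config.train_weeks if cohort.config is not None else 20
    n_weeks = (
        cohort.config.n_weeks
        if cohort.config is not None
        else max(len(s) for s in cohort.series) // HOURS_PER_WEEK
    )
    if train_weeks >= n_weeks:
        raise ConfigurationError(
            f"train_weeks ({train_weeks}) must be < n_weeks ({n_weeks})"
        )
    cut = train_weeks * HOURS_PER_WEEK
    train_series, test_series = [], []
    for s in cohort.series:
        tr, te = _split_series(s, cut)
        train_series.append(tr)
        test_series.append(te)

    ep = cohort.episodes
    train_ep = ep[ep.start_hour <= cut].copy()
    if len(train_ep):
        train_ep["end_hour"] = train_ep["end_hour"].clip(upper=cut)
    test_ep = ep[ep.end_hour > cut].copy()
    if len(test_ep):
        test_ep["start_hour"] = (test_ep["start_hour"] - cut).clip(lower=1)
        test_ep["end_hour"] = test_ep["end_hour"] - cut
    return (
        Cohort(train_series, train_ep.reset_index(drop=True), cohort.config),
        Cohort(test_series, test_ep.reset_index(drop=True), cohort.config),
    )


@dataclass
class WindowBatch:
    """Fixed-length multichannel segments with their (subject, start-hour) origins."""

    windows: np.ndarray  # (n_windows, window_length, n_channels)
    window_length: int
    stride: int
    origins: list[tuple[str, int]]

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(
    series: VitalSeries, window_length: int = 168, stride: int | None = None
) -> WindowBatch:
    """Slice one series into windows; count = floor((T − L)/stride) + 1."""
    if stride is None:
        stride = window_length
    T = len(series)
    if T < window_length:
        raise RangeError(f"series length {T} shorter than window {window_length}")
    if window_length < 1 or stride < 1:
        raise ConfigurationError("window_length and stride must be >= 1")
    X = series.values()
    n = (T - window_length) // stride + 1
    idx = np.arange(n)[:, None] * stride + np.arange(window_length)[None, :]
    windows = X[idx]
    origins = [(series.subject_id, int(series.hour_index[i * stride])) for i in range(n)]
    return WindowBatch(windows, window_length, stride, origins)


def cohort_windows(
    cohort: Cohort,
    scaler: VitalScaler | None = None,
    window_length: int = 168,
    stride: int | None = None,
) -> WindowBatch:
    """Windows pooled across all subjects, optionally normalized."""
    parts, origins = [], []
    stride = window_length if stride is None else stride
    for s in cohort.series:
        wb = make_windows(s, window_length, stride)
        parts.append(wb.windows)
        origins.extend(wb.origins)
    windows = np.concatenate(parts, axis=0)
    if scaler is not None:
        shp = windows.shape
        windows = scaler.transform(windows.reshape(-1, shp[-1])).reshape(shp)
    return WindowBatch(windows, window_length, stride, origins)
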