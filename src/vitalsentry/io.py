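"""File formats: cohort CSV, alarm logs, model checkpoints, printed fixtures.

Cohort files are plain comma-separated UTF-8 with a mandatory header:
subject_id, sex, age, split, hour_index, temperature_c, heart_rate_bpm, label.
Checkpoints are a single ``.npz`` container holding every weight matrix, the
fitted scaler statistics, training config and seed, with a JSON metadata
record — readable from any language with an npz/zip reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .models import AeParams, Autoencoder, GruAeParams, GruAutoencoder
from .gru import GruLayerParams
from .preprocessing import VitalScaler
from .synthetic import Cohort, VitalSeries

COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "split",
    "hour_index",
    "temperature_c",
    "heart_rate_bpm",
    "label",
]

CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# cohort CSV


def write_vitals(path, cohort: Cohort, split: str = "all") -> None:
    """Write a cohort as CSV; episodes (if any) go to ``<path>.episodes.csv``."""
    frames = []
    for s in cohort.series:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "sex": s.sex,
                    "age": s.age,
                    "split": split,
                    "hour_index": s.hour_index,
                    "temperature_c": s.temperature,
                    "heart_rate_bpm": s.heart_rate,
                    "label": np.where(s.label == 1, "unhealthy", "healthy"),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if cohort.episodes is not None and len(cohort.episodes):
        cohort.episodes.to_csv(f"{path}.episodes.csv", index=False)


def read_vitals(path) -> Cohort:
    """Read a cohort CSV, validating columns, numeric cells and hour order."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "sex": str, "label": str})
    except (OSError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot read {path}: {e}") from e
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ("age", "hour_index", "temperature_c", "heart_rate_bpm"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise FormatError(f"{path}: non-numeric value in '{col}' at line {row}")
        df[col] = numeric
    series = []
    for sid, g in df.groupby("subject_id", sort=True):
        hours = g["hour_index"].to_numpy(dtype=int)
        steps = np.diff(hours)
        if len(hours) and (steps != 1).any():
            bad_pos = int(np.argmax(steps != 1))
            row = int(g.index[bad_pos + 1]) + 2
            raise FormatError(
                f"{path}: non-consecutive hour_index for subject {sid} at line {row}"
            )
        series.append(
            VitalSeries(
                subject_id=str(sid),
                sex=str(g["sex"].iloc[0]),
                age=int(g["age"].iloc[0]),
                hour_index=hours,
                temperature=g["temperature_c"].to_numpy(dtype=float),
                heart_rate=g["heart_rate_bpm"].to_numpy(dtype=float),
                label=(g["label"].to_numpy() == "unhealthy").astype(np.int8),
            )
        )
    episodes = pd.DataFrame(columns=["subject_id", "start_hour", "end_hour"])
    ep_path = f"{path}.episodes.csv"
    try:
        episodes = pd.read_csv(ep_path, dtype={"subject_id": str})
    except OSError:
        pass
    return Cohort(series=series, episodes=episodes, config=None)


def write_alarm_log(path, alarms) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": a.subject_id,
                "hour_index": a.hour_index,
                "loss": a.loss,
                "threshold": a.threshold,
            }
            for a in alarms
        ],
        columns=["subject_id", "hour_index", "loss", "threshold"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path, model, scaler: VitalScaler, threshold: float | None = None,
                    extra: dict | None = None) -> None:
    """Persist a trained model + scaler (+ deployed threshold) to one npz file."""
    arrays: dict[str, np.ndarray] = {}
    if isinstance(model, GruAutoencoder):
        kind = "gru_ae"
        for i, lp in enumerate(model.params_.layers):
            for name in ("Wu", "Wr", "W", "Uu", "Ur", "U"):
                arrays[f"layer{i}_{name}"] = getattr(lp, name)
        arrays["Wy"] = model.params_.Wy
        arrays["by"] = model.params_.by
    elif isinstance(model, Autoencoder):
        kind = "ae"
        for i, (W, b) in enumerate(zip(model.params_.weights, model.params_.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
    else:
        raise FormatError(f"unsupported model type {type(model).__name__}")
    arrays["scaler_min"] = scaler.data_min_
    arrays["scaler_max"] = scaler.data_max_
    arrays["loss_history"] = np.asarray(getattr(model, "loss_history_", []), dtype=float)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_kind": kind,
        "hyperparameters": model.get_params(),
        "feature_range": list(scaler.feature_range),
        "threshold": threshold,
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, scaler, threshold, meta).

    Round-trip guarantee: the restored model's forward outputs are
    bit-identical to the saved model's.
    """
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise FormatError(
                f"unsupported checkpoint format version {meta.get('format_version')}"
            )
        hp = meta["hyperparameters"]
        for key in ("hidden_sizes",):
            if key in hp and isinstance(hp[key], str):
                hp[key] = tuple(
                    int(v) for v in hp[key].strip("()").split(",") if v.strip()
                )
        if meta["model_kind"] == "gru_ae":
            model = GruAutoencoder(**_coerce_hp(hp))
            n_layers = len(model.hidden_sizes)
            layers = [
                GruLayerParams(
                    **{n: z[f"layer{i}_{n}"] for n in ("Wu", "Wr", "W", "Uu", "Ur", "U")}
                )
                for i in range(n_layers)
            ]
            model.params_ = GruAeParams(layers=layers, Wy=z["Wy"], by=z["by"])
            model.n_channels_ = model.params_.n_channels
        elif meta["model_kind"] == "ae":
            model = Autoencoder(**_coerce_hp(hp))
            weights, biases, i = [], [], 0
            while f"W{i}" in z:
                weights.append(z[f"W{i}"])
                biases.append(z[f"b{i}"])
                i += 1
            model.params_ = AeParams(weights=weights, biases=biases)
            model.n_channels_ = weights[0].shape[1]
        else:
            raise FormatError(f"unknown model kind {meta['model_kind']!r}")
        model.loss_history_ = z["loss_history"].tolist()
        lo, hi = meta["feature_range"]
        scaler = VitalScaler(feature_range=(float(lo), float(hi)))
        scaler.fit(np.vstack([z["scaler_min"], z["scaler_max"]]))
    return model, scaler, meta.get("threshold"), meta


def _coerce_hp(hp: dict) -> dict:
    out = dict(hp)
    for k in ("learning_rate",):
        if k in out:
            out[k] = float(out[k])
    for k in ("n_epochs", "batch_size", "random_state", "verbose"):
        if k in out and out[k] is not None:
            out[k] = int(out[k])
    if "hidden_sizes" in out and not isinstance(out["hidden_sizes"], tuple):
        out["hidden_sizes"] = tuple(int(v) for v in out["hidden_sizes"])
    if "shuffle" in out:
        out["shuffle"] = out["shuffle"] in (True, "True", "true", 1)
    return out


# ---------------------------------------------------------------------------
# printed unhealthy-sample fixture (two example test subjects)


@dataclass
class Table1Fixture:
    """Printed unhealthy samples of one example test subject."""

    test_set: int
    rows: pd.DataFrame  # time_sequence, temperature_c, heart_rate_bpm, suspect


_SET1 = [
    (667, 37.6, 80, False),
    (668, 37.4, 68, False),
    (669, 37.3, 162, False),
    (670, 37.7, 168, False),
    (671, 38.0, 165, False),
    (672, 37.7, 169, False),
]

# time 604's printed heart rate of 1140 bpm is physiologically impossible
# (suspected misprint of 114); it is preserved verbatim and only replaced
# when the caller opts in.
_SET2 = [
    (131, 37.5, 66, False),
    (132, 37.7, 70, False),
    (133, 38.0, 110, False),
    (134, 37.9, 100, False),
    (135, 37.6, 99, False),
    (601, 37.7, 89, False),
    (602, 37.5, 101, False),
    (603, 37.3, 65, False),
    (604, 37.1, 1140, True),
    (605, 37.0, 125, False),
    (606, 37.8, 110, False),
]


def load_table1_fixture(correct_suspect: bool = False) -> tuple[Table1Fixture, Table1Fixture]:
    """The printed unhealthy test-set samples of the two example subjects.

    With ``correct_suspect=True`` the impossible 1140 bpm reading is replaced
    by 114 bpm; by default the printed value is returned verbatim.
    """
    out = []
    for k, rows in ((1, _SET1), (2, _SET2)):
        df = pd.DataFrame(
            rows, columns=["time_sequence", "temperature_c", "heart_rate_bpm", "suspect"]
        )
        if correct_suspect:
            df.loc[df.suspect, "heart_rate_bpm"] = 114
        out.append(Table1Fixture(test_set=k, rows=df))
    return tuple(out)
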