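"""Evaluation metrics with the healthy-as-positive convention.

The orientation is unusual and deliberate: the positive class is *healthy*.
TP = predicted healthy & actually healthy, TN = predicted unhealthy &
actually unhealthy, FP = predicted healthy & actually unhealthy (a missed
health issue), FN = predicted unhealthy & actually healthy (a false alarm).
TPR = TP/(TP+FN), FPR = FP/(FP+TN), accuracy = (TP+TN)/total.

AUC uses the rank formula: with all units ranked ascending by healthiness
score (the negated reconstruction loss), M healthy and N unhealthy units,

    AUC = (Σ_{i ∈ healthy} rank_i − M(M+1)/2) / (M·N)

with tied scores given average ranks — identical to the probability that a
random healthy unit outranks a random unhealthy one (ties count ½), and to
the trapezoidal area under the swept ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import ShapeError

HEALTHY, UNHEALTHY = 1, 0  # canonical encoding of actual/predicted labels


def mae_rmse(y, yhat) -> tuple[float, float]:
    """Mean absolute error and root mean squared error (RMSE ≥ MAE always)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("mae_rmse requires at least one value")
    if y.shape != yhat.shape:
        raise ShapeError(f"length mismatch: {y.shape} vs {yhat.shape}")
    err = y - yhat
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


@dataclass
class ConfusionCounts:
    """Confusion counts with healthy as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def _ratio(self, num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined: empty denominator class", stacklevel=3)
            return float("nan")
        return num / den

    @property
    def tpr(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn, "TPR")

    @property
    def fpr(self) -> float:
        return self._ratio(self.fp, self.fp + self.tn, "FPR")

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.total, "accuracy")


def _as_binary(labels) -> np.ndarray:
    a = np.asarray(labels)
    if a.dtype.kind in "US":
        mapped = np.where(a == "healthy", HEALTHY, np.where(a == "unhealthy", UNHEALTHY, -1))
        if (mapped == -1).any():
            raise ValueError("labels must be 'healthy'/'unhealthy' or 0/1")
        return mapped.astype(int)
    a = a.astype(int)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("binary labels must be 0 (unhealthy) or 1 (healthy)")
    return a


def confusion(actual, predicted) -> ConfusionCounts:
    """Confusion counts from actual/predicted labels (healthy=1 or strings)."""
    a = _as_binary(actual)
    p = _as_binary(predicted)
    if a.shape != p.shape:
        raise ShapeError("actual and predicted label vectors differ in length")
    return ConfusionCounts(
        tp=int(np.sum((p == HEALTHY) & (a == HEALTHY))),
        tn=int(np.sum((p == UNHEALTHY) & (a == UNHEALTHY))),
        fp=int(np.sum((p == HEALTHY) & (a == UNHEALTHY))),
        fn=int(np.sum((p == UNHEALTHY) & (a == HEALTHY))),
    )


def rank_auc(healthiness_scores, actual) -> float:
    """AUC by the rank formula (average ranks on ties)."""
    s = np.asarray(healthiness_scores, dtype=float).ravel()
    a = _as_binary(actual)
    M = int(np.sum(a == HEALTHY))
    N = int(np.sum(a == UNHEALTHY))
    if M == 0 or N == 0:
        missing = "healthy" if M == 0 else "unhealthy"
        raise ValueError(f"AUC undefined: no {missing} units present")
    ranks = rankdata(s)  # ascending, average ties
    return float((ranks[a == HEALTHY].sum() - M * (M + 1) / 2.0) / (M * N))


def roc_points(healthiness_scores, actual) -> np.ndarray:
    """(FPR, TPR) points from sweeping the threshold over distinct scores.

    At threshold τ a unit is predicted healthy iff score ≥ τ; τ runs from
    above the maximum (predict all unhealthy, point (0,0)) down through every
    distinct score (final point (1,1)).  Points are returned in sweep order,
    nondecreasing in both coordinates.
    """
    s = np.asarray(healthiness_scores, dtype=float).ravel()
    a = _as_binary(actual)
    M = int(np.sum(a == HEALTHY))
    N = int(np.sum(a == UNHEALTHY))
    if M == 0 or N == 0:
        missing = "healthy" if M == 0 else "unhealthy"
        raise ValueError(f"ROC undefined: no {missing} units present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    healthy_sorted = (a[order] == HEALTHY).astype(float)
    cum_tp = np.cumsum(healthy_sorted)
    cum_fp = np.cumsum(1.0 - healthy_sorted)
    # keep only the last index of each tied block (threshold = that score)
    last_of_block = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = cum_tp[last_of_block] / M
    fpr = cum_fp[last_of_block] / N
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


@dataclass
class EvalReport:
    """Metric bundle for one model on one test cohort."""

    model_name: str
    pooled_confusion: ConfusionCounts
    subject_confusion: ConfusionCounts
    pooled_auc: float
    subject_auc_mean: float
    subject_aucs: dict[str, float]
    n_subjects_auc_excluded: int
    roc: np.ndarray
    mae: float
    rmse: float
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        sc = self.subject_confusion
        lines = [
            f"model: {self.model_name}",
            f"per-hour pooled AUC: {self.pooled_auc:.4f}",
            f"mean per-subject AUC: {self.subject_auc_mean:.4f} "
            f"(over {len(self.subject_aucs)} subjects; "
            f"{self.n_subjects_auc_excluded} single-class subjects excluded)",
            f"subject-level overall accuracy: {sc.accuracy:.4f} "
            f"({sc.tp + sc.tn}/{sc.total})",
            f"subject-level accuracy on unhealthy subjects: "
            f"{_safe_div(sc.tn, sc.tn + sc.fp):.4f} ({sc.tn}/{sc.tn + sc.fp})",
            f"reconstruction MAE: {self.mae:.5f}  RMSE: {self.rmse:.5f} "
            f"(normalized units)",
        ]
        return "\n".join(lines)


def _safe_div(a, b):
    return a / b if b else float("nan")


def roc_and_auc(losses, actual) -> dict:
    """ROC sweep + rank AUC from per-unit anomaly losses and actual labels.

    The healthiness score is the negated loss; the trapezoidal area under the
    swept ROC equals the rank-formula AUC to numerical precision.
    """
    scores = -np.asarray(losses, dtype=float).ravel()
    auc = rank_auc(scores, actual)
    roc = roc_points(scores, actual)
    return {"roc": roc, "auc": auc}


def evaluate_models(test_cohort, monitor_configs: dict) -> dict[str, EvalReport]:
    """Side-by-side evaluation of trained monitors on a labeled test cohort.

    ``monitor_configs`` maps model names to :class:`~vitalsentry.monitor.MonitorConfig`.
    For each model: per-hour losses per subject (state carried over the whole
    test stream), per-subject AUC over subjects with both classes, pooled
    per-hour AUC, and subject-level confusion from the thresholded verdicts
    (actual subject label: unhealthy iff the subject has ≥1 unhealthy hour).
    """
    from .monitor import monitor_stream, subject_verdict

    reports = {}
    for name, cfg in monitor_configs.items():
        pooled_losses, pooled_actual = [], []
        subj_actual, subj_pred = [], []
        subject_aucs, excluded = {}, 0
        abs_err, sq_err, n_err = 0.0, 0.0, 0
        for s in test_cohort.series:
            trace, _, verdicts = monitor_stream(s, cfg)
            healthy = (1 - s.label).astype(int)  # healthy-as-positive truth
            pooled_losses.append(trace.per_timestep)
            pooled_actual.append(healthy)
            if 0 < healthy.sum() < len(healthy):
                subject_aucs[s.subject_id] = rank_auc(-trace.per_timestep, healthy)
            else:
                excluded += 1
            subj_actual.append(HEALTHY if s.label.max() == 0 else UNHEALTHY)
            subj_pred.append(
                HEALTHY if subject_verdict(verdicts) == "healthy" else UNHEALTHY
            )
            Xn = cfg.normalizer.transform(s.values())
            recon = _reconstruct(cfg.model, Xn)
            abs_err += float(np.abs(recon - Xn).sum())
            sq_err += float(((recon - Xn) ** 2).sum())
            n_err += Xn.size
        losses = np.concatenate(pooled_losses)
        actual = np.concatenate(pooled_actual)
        pooled = roc_and_auc(losses, actual)
        pooled_pred = np.where(
            losses > cfg.threshold, UNHEALTHY, HEALTHY
        )
        reports[name] = EvalReport(
            model_name=name,
            pooled_confusion=confusion(actual, pooled_pred),
            subject_confusion=confusion(subj_actual, subj_pred),
            pooled_auc=pooled["auc"],
            subject_auc_mean=(
                float(np.mean(list(subject_aucs.values()))) if subject_aucs else float("nan")
            ),
            subject_aucs=subject_aucs,
            n_subjects_auc_excluded=excluded,
            roc=pooled["roc"],
            mae=abs_err / n_err,
            rmse=float(np.sqrt(sq_err / n_err)),
        )
    return reports


def _reconstruct(model, Xn):
    out = model.reconstruct(Xn)
    return out[0] if isinstance(out, tuple) else out
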