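"""SVM classification and repeated stratified k-fold evaluation.

The positive class is AMD throughout.  Five metrics are reported:

* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* accuracy    = (TP + TN) / (TP + TN + FP + FN)
* AUROC       — rank-based (Mann-Whitney) estimate: the probability that
  a random positive outscores a random negative, ties counted 1/2;
  scores are the SVM decision-function values, never hard labels.
* Cohen's kappa = (p_o - p_e) / (1 - p_e) with p_o the observed accuracy
  and p_e the chance agreement from the marginal products.

Protocol: for each repetition a fresh stratified k-fold split (k = 5
gives the 80/20 train/test ratio); within each fold features are
z-scored on the training split only, an SVM (default RBF kernel, C = 1)
is fitted and the held-out split scored.  Each repetition's out-of-fold
predictions are pooled into one confusion matrix and one AUROC — pooling
is well defined for AUROC on small folds, per-fold averaging is not.
Aggregates over repetitions are mean, (sample) std, and the
maximum-accuracy and maximum-kappa repetitions.

Stratified folds are used because AMD cohorts are typically unbalanced;
they guarantee both classes appear in every training split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, UndefinedMetricError, ValidationError
from .features import FeatureVector
from .types import LABEL_AMD

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "auroc", "kappa")


@dataclass
class ConfusionMatrix:
    """Binary confusion counts, positive class = AMD."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a nonnegative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        t = np.asarray(y_true, dtype=bool)
        p = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int(np.sum(t & p)),
            fp=int(np.sum(~t & p)),
            tn=int(np.sum(~t & ~p)),
            fn=int(np.sum(t & ~p)),
        )

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}


def confusion_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as exact ratios."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    if cm.total == 0:
        raise UndefinedMetricError("accuracy undefined: no cases")
    sens = cm.tp / (cm.tp + cm.fn)
    spec = cm.tn / (cm.tn + cm.fp)
    acc = (cm.tp + cm.tn) / cm.total
    return sens, spec, acc


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between predicted and true labels."""
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("kappa undefined: no cases")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if p_e == 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC with tie-averaging; labels truthy = positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC undefined: both classes must be present")
    r = rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class RepetitionResult:
    """Pooled out-of-fold outcome of one k-fold repetition."""

    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    scores: np.ndarray
    y_true: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    auroc: float
    kappa: float

    def metrics(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}

    def to_dict(self) -> dict:
        return {
            "fold_matrices": [c.to_dict() for c in self.fold_matrices],
            "pooled": self.pooled.to_dict(),
            "scores": [float(v) for v in self.scores],
            "y_true": [int(v) for v in self.y_true],
            **{m: float(getattr(self, m)) for m in METRIC_NAMES},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RepetitionResult":
        return cls(
            fold_matrices=[ConfusionMatrix(**c) for c in d["fold_matrices"]],
            pooled=ConfusionMatrix(**d["pooled"]),
            scores=np.asarray(d["scores"], dtype=float),
            y_true=np.asarray(d["y_true"], dtype=int),
            **{m: d[m] for m in METRIC_NAMES},
        )


@dataclass
class EvalReport:
    """Per-repetition metrics plus mean/std/max aggregates and protocol."""

    repetitions: list[RepetitionResult]
    protocol: dict

    def aggregates(self) -> dict:
        """Recompute mean/std/max-accuracy/max-kappa rows from repetitions."""
        rows = {m: np.array([r.metrics()[m] for r in self.repetitions]) for m in METRIC_NAMES}
        i_acc = int(np.argmax(rows["accuracy"]))
        i_kap = int(np.argmax(rows["kappa"]))
        ddof = 1 if len(self.repetitions) > 1 else 0
        return {
            "mean": {m: float(rows[m].mean()) for m in METRIC_NAMES},
            "std": {m: float(rows[m].std(ddof=ddof)) for m in METRIC_NAMES},
            "max_accuracy": {m: float(rows[m][i_acc]) for m in METRIC_NAMES},
            "max_kappa": {m: float(rows[m][i_kap]) for m in METRIC_NAMES},
        }

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "repetitions": [r.to_dict() for r in self.repetitions],
            "aggregates": self.aggregates(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            repetitions=[RepetitionResult.from_dict(r) for r in d["repetitions"]],
            protocol=d["protocol"],
        )


def _as_xy(table: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    if not table:
        raise ValidationError("empty feature table")
    n = len(table[0].values)
    if any(len(fv.values) != n for fv in table):
        raise ValidationError("ragged feature vectors")
    X = np.stack([fv.values for fv in table])
    y = np.array([fv.label == LABEL_AMD for fv in table], dtype=bool)
    return X, y


def repeated_kfold_evaluate(table: list[FeatureVector], k: int = 5,
                            repetitions: int = 100,
                            train_fraction_check: float | None = None,
                            svm_settings: dict | None = None,
                            seed: int = 0) -> EvalReport:
    """Repeated stratified k-fold SVM evaluation of one feature table.

    Parameters
    ----------
    train_fraction_check
        If given, assert that 1 - 1/k matches this fraction (e.g. 0.8
        with k = 5) before running.
    svm_settings
        Keys ``kernel`` (default "rbf"), ``C`` (1.0), ``gamma`` ("scale").
    seed
        Master seed; per-repetition split seeds are derived from it, so
        a fixed seed yields a bit-identical report.
    """
    from sklearn.model_selection import StratifiedKFold

    X, y = _as_xy(table)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if min(n_pos, n_neg) < k:
        raise ValidationError(
            f"stratified {k}-fold needs >= {k} cases per class "
            f"(have {n_pos} AMD / {n_neg} control)"
        )
    if train_fraction_check is not None and abs((1 - 1 / k) - train_fraction_check) > 1e-9:
        raise ConfigError(
            f"k={k} implies train fraction {1 - 1 / k:.3f}, not {train_fraction_check}"
        )
    settings = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
    settings.update(svm_settings or {})

    rep_seeds = np.random.SeedSequence(seed).generate_state(repetitions) % (2**31)
    n = len(y)
    reps: list[RepetitionResult] = []
    for r in range(repetitions):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rep_seeds[r]))
        scores = np.empty(n)
        preds = np.empty(n, dtype=bool)
        fold_cms: list[ConfusionMatrix] = []
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[train_idx])) < 2:
                raise ValidationError("a class is absent from a training split")
            expected = n / k
            if abs(len(test_idx) - expected) > 1.0:
                raise ValidationError("fold sizes deviate from n/k by more than 1")
            scaler = StandardScaler().fit(X[train_idx])
            clf = SVC(kernel=settings["kernel"], C=settings["C"],
                      gamma=settings["gamma"])
            clf.fit(scaler.transform(X[train_idx]), y[train_idx])
            Xt = scaler.transform(X[test_idx])
            scores[test_idx] = clf.decision_function(Xt)
            preds[test_idx] = clf.predict(Xt)
            fold_cms.append(ConfusionMatrix.from_predictions(y[test_idx], preds[test_idx]))
        pooled = ConfusionMatrix.from_predictions(y, preds)
        sens, spec, acc = confusion_metrics(pooled)
        reps.append(
            RepetitionResult(
                fold_matrices=fold_cms,
                pooled=pooled,
                scores=scores,
                y_true=y.astype(int),
                sensitivity=sens,
                specificity=spec,
                accuracy=acc,
                auroc=auroc(scores, y),
                kappa=cohen_kappa(pooled),
            )
        )
    protocol = {
        "k": k,
        "repetitions": repetitions,
        "seed": int(seed),
        "n_cases": n,
        "n_amd": n_pos,
        "n_control": n_neg,
        "svm": {"kernel": settings["kernel"], "C": float(settings["C"]),
                "gamma": settings["gamma"] if isinstance(settings["gamma"], str)
                else float(settings["gamma"])},
        "standardization": "z-score fitted on training folds only",
        "pooling": "per-repetition out-of-fold predictions",
    }
    return EvalReport(repetitions=reps, protocol=protocol)
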