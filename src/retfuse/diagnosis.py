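"""Hybrid classification: ANN + SVM + naive Bayes with majority voting.

The three classifiers consume the standardized 16-D fused feature
vector. The ANN is a 16-12-9-2 feed-forward network (sigmoid hidden
activations, softmax output) trained by gradient descent; the SVM uses a
Gaussian RBF (default) or MLP/sigmoid kernel; the naive Bayes assumes
per-feature Gaussian likelihoods and decides by the maximum a
posteriori rule. The ensemble's final label is the class with at least
two of the three votes. Evaluation metrics (sensitivity, specificity,
PPV, NPV, diagnostic accuracy) come from the confusion counts, with ME
as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import nn
from .features import FeatureVector

POSITIVE = "me"
NEGATIVE = "healthy"


# ---------------------------------------------------------------- containers

@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN with ME as the positive class."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def update(self, true_label: str, predicted: str) -> None:
        if true_label == POSITIVE:
            if predicted == POSITIVE:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted == POSITIVE:
                self.fp += 1
            else:
                self.tn += 1


@dataclass
class MetricReport:
    """SE/SP/PPV/NPV/A in [0, 1]; metrics with zero denominators are None."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "SE": self.sensitivity,
            "SP": self.specificity,
            "PPV": self.ppv,
            "NPV": self.npv,
            "A": self.accuracy,
        }


@dataclass
class Diagnosis:
    """Per-classifier votes plus the majority-vote final label."""

    votes: dict[str, str]
    final: str
    posterior: dict[str, float] = field(default_factory=dict)
    csme_grade: str | None = None


# ------------------------------------------------------------ preprocessing

@dataclass
class FeatureScaler:
    """Z-score standardization with train-split statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, float)
        std = x.std(axis=0)
        std[std < 1e-12] = 1.0
        return cls(mean=x.mean(axis=0), std=std)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.std


def _as_matrix(features: list[FeatureVector] | np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(features, np.ndarray):
        return np.asarray(features, float), None
    if len(features) == 0:
        raise ValueError("empty feature list")
    x = np.stack([fv.values for fv in features])
    labels = [fv.label for fv in features]
    if any(l is None for l in labels):
        return x, None
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels], int)
    return x, y


def _require_two_classes(y: np.ndarray) -> None:
    if y is None or np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")


# ----------------------------------------------------------------- ANN

class ANNModel:
    """Feed-forward 16-12-9-2 network: sigmoid hidden layers, softmax output."""

    hidden = (12, 9)

    def __init__(self, n_inputs: int = 16, seed: int = 0) -> None:
        layers = [
            nn.Dense(self.hidden[0]),
            nn.Sigmoid(),
            nn.Dense(self.hidden[1]),
            nn.Sigmoid(),
            nn.Dense(2),
        ]
        self.net = nn.Sequential(layers, (n_inputs,), seed=seed)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.net.forward(np.asarray(x, np.float32)))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def train_ann(
    features: list[FeatureVector] | np.ndarray,
    labels: np.ndarray | None = None,
    seed: int = 0,
    epochs: int = 500,
    lr: float = 0.5,
) -> ANNModel:
    """Full-batch gradient-descent training of the 16-12-9-2 ANN.

    Expects standardized features; fully deterministic for a fixed seed.
    """
    x, y = _as_matrix(features)
    if labels is not None:
        y = np.asarray(labels, int)
    _require_two_classes(y)
    model = ANNModel(n_inputs=x.shape[1], seed=seed)
    opt = nn.SGD(model.net, lr=lr, momentum=0.0)
    xf = np.asarray(x, np.float32)
    for _ in range(epochs):
        logits = model.net.forward(xf, train=True)
        probs = nn.softmax(logits)
        d = probs.copy()
        d[np.arange(len(y)), y] -= 1.0
        model.net.backward((d / len(y)).astype(np.float32))
        opt.step()
    return model


# ----------------------------------------------------------------- SVM

def train_svm(
    features: list[FeatureVector] | np.ndarray,
    labels: np.ndarray | None = None,
    kernel: str = "rbf",
    c: float = 1.0,
    gamma: float = 1.0 / 16.0,
    mlp_scale: float = 1.0 / 16.0,
    mlp_offset: float = -1.0,
    seed: int = 0,
):
    """Binary SVM with a Gaussian RBF or MLP (sigmoid/tanh) kernel."""
    x, y = _as_matrix(features)
    if labels is not None:
        y = np.asarray(labels, int)
    _require_two_classes(y)
    if kernel == "rbf":
        clf = SVC(C=c, kernel="rbf", gamma=gamma, random_state=seed)
    elif kernel == "mlp":
        clf = SVC(C=c, kernel="sigmoid", gamma=mlp_scale, coef0=mlp_offset, random_state=seed)
    else:
        raise ValueError(f"unknown SVM kernel {kernel!r} (use 'rbf' or 'mlp')")
    clf.fit(x, y)
    return clf


# ------------------------------------------------------------- naive Bayes

class GaussianNBModel:
    """Gaussian naive Bayes by the MAP rule, evaluated in log space.

    Priors are class frequencies; each feature gets a Gaussian
    likelihood with per-class mean and variance (floored at 1e-9).
    """

    def __init__(self, priors: np.ndarray, means: np.ndarray, variances: np.ndarray) -> None:
        self.priors = priors
        self.means = means
        self.variances = variances

    def joint_log_likelihood(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        out = np.empty((x.shape[0], self.priors.size))
        for k in range(self.priors.size):
            var = self.variances[k]
            ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + (x - self.means[k]) ** 2 / var, axis=1)
            out[:, k] = np.log(self.priors[k]) + ll
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.joint_log_likelihood(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.joint_log_likelihood(x).argmax(axis=1)


def train_nb(
    features: list[FeatureVector] | np.ndarray,
    labels: np.ndarray | None = None,
    var_floor: float = 1e-9,
) -> GaussianNBModel:
    x, y = _as_matrix(features)
    if labels is not None:
        y = np.asarray(labels, int)
    _require_two_classes(y)
    classes = np.unique(y)
    priors = np.array([(y == k).mean() for k in classes])
    means = np.stack([x[y == k].mean(axis=0) for k in classes])
    variances = np.stack([np.maximum(x[y == k].var(axis=0), var_floor) for k in classes])
    return GaussianNBModel(priors=priors, means=means, variances=variances)


# --------------------------------------------------------------- ensemble

def _label_of(index: int) -> str:
    return POSITIVE if index == 1 else NEGATIVE


def predict_ensemble(ann: ANNModel, svm, nb: GaussianNBModel,
                     fv: FeatureVector | np.ndarray,
                     scaler: FeatureScaler | None = None) -> Diagnosis:
    """Each model votes; the final label is the class with >= 2 of 3 votes."""
    x = fv.values if isinstance(fv, FeatureVector) else np.asarray(fv, float)
    x = np.atleast_2d(x)
    if scaler is not None:
        x = scaler.transform(x)
    votes_idx = {
        "ann": int(ann.predict(x)[0]),
        "svm": int(svm.predict(x)[0]),
        "nb": int(nb.predict(x)[0]),
    }
    votes = {name: _label_of(i) for name, i in votes_idx.items()}
    final = POSITIVE if sum(votes_idx.values()) >= 2 else NEGATIVE
    posterior = {
        "ann": float(ann.predict_proba(x)[0, 1]),
        "nb": float(nb.predict_proba(x)[0, 1]),
    }
    return Diagnosis(votes=votes, final=final, posterior=posterior)


def majority_label(votes: dict[str, str]) -> str:
    """Mode of three binary votes (no ties possible)."""
    n_positive = sum(1 for v in votes.values() if v == POSITIVE)
    return POSITIVE if n_positive >= 2 else NEGATIVE


# ---------------------------------------------------------------- metrics

def classification_metrics(counts: ConfusionCounts) -> MetricReport:
    """SE, SP, PPV, NPV and diagnostic accuracy from confusion counts.

    A metric whose denominator is zero is reported as None; an entirely
    empty table is an error.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero cases")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return MetricReport(
        sensitivity=ratio(counts.tp, counts.tp + counts.fn),
        specificity=ratio(counts.tn, counts.tn + counts.fp),
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        npv=ratio(counts.tn, counts.tn + counts.fn),
        accuracy=(counts.tp + counts.tn) / counts.total,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a| + |b|); two empty masks score 1."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("dice requires masks of one shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


# ----------------------------------------------------------- cross-validation

def kfold_cv(
    trainer,
    features: list[FeatureVector] | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold accuracy for one trainer spec.

    ``trainer(x_train, y_train)`` must return a model with ``predict``.
    Reports per-fold accuracies and their maximum (the conventional
    "max accuracy achieved" summary).
    """
    x, y = _as_matrix(features)
    if labels is not None:
        y = np.asarray(labels, int)
    _require_two_classes(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(y):
        raise ValueError("k cannot exceed the number of samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(x, y):
        scaler = FeatureScaler.fit(x[train_idx])
        model = trainer(scaler.transform(x[train_idx]), y[train_idx])
        pred = model.predict(scaler.transform(x[test_idx]))
        accs.append(float((pred == y[test_idx]).mean()))
    return {"fold_accuracies": accs, "max_accuracy": max(accs)}
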