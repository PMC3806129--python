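"""RBF-SVM residue classifier: normalization, grid search, protein-grouped CV,
prediction and evaluation.

Features are min-max normalized to [0, 1] on the training data (test values
clipped into the training range; constant columns map to 0).  Hyperparameters
C and gamma are chosen by exhaustive grid search with cross-validated MCC on
a random subset of training proteins, mirroring the usual libsvm protocol.
Cross-validation always partitions *proteins*, never residues of one protein
across folds, so that evaluation reflects generalization to unseen structures.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

__all__ = [
    "Normalizer", "TrainedModel", "EvalReport",
    "default_param_grid", "grid_search", "train", "cross_validate",
    "predict_proba", "evaluate", "save_model", "load_model",
    "protein_folds",
]


@dataclass
class Normalizer:
    """Per-column min-max transform fitted on training data."""

    mins: np.ndarray
    ranges: np.ndarray  # zero ranges stored as 0 and handled in transform

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit normalizer on empty matrix")
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins=mins, ranges=ranges)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mins.shape[0]:
            raise ValueError(
                f"feature layout mismatch: normalizer expects {self.mins.shape[0]} "
                f"columns, got {X.shape[1]}")
        safe = np.where(self.ranges > 0, self.ranges, 1.0)
        out = (X - self.mins) / safe
        out[:, self.ranges == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


@dataclass
class TrainedModel:
    svc: SVC
    normalizer: Normalizer
    C: float
    gamma: float
    layout_fingerprint: str

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive (binding) class, in [0, 1]."""
        Xn = self.normalizer.transform(X)
        pos_col = int(np.where(self.svc.classes_ == 1)[0][0])
        return self.svc.predict_proba(Xn)[:, pos_col]


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float
    roc: List[Tuple[float, float]]
    n_positive: int
    n_negative: int
    undefined: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, float]:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "mcc": self.mcc, "auc": self.auc,
            "n_positive": self.n_positive, "n_negative": self.n_negative,
        }


def _layout_fingerprint(n_features: int) -> str:
    return hashlib.sha1(f"depthsite-layout-v1-{n_features}".encode()).hexdigest()[:12]


def default_param_grid() -> List[Tuple[float, float]]:
    """Log2-spaced libsvm-style grid: C in 2^-5..2^15, gamma in 2^-15..2^3."""
    cs = [2.0 ** e for e in range(-5, 16, 2)]
    gammas = [2.0 ** e for e in range(-15, 4, 2)]
    return [(c, g) for c in cs for g in gammas]


def protein_folds(groups: Sequence[str], k: int, seed: int) -> List[np.ndarray]:
    """Partition sample indices into k folds by protein, shuffled by seed.

    Every sample of a protein lands in exactly one fold.
    """
    groups = np.asarray(groups)
    proteins = np.array(sorted(set(groups.tolist())))
    if len(proteins) < k:
        raise ValueError(f"need >= {k} proteins for {k}-fold CV, have {len(proteins)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(proteins)
    folds = []
    for chunk in np.array_split(proteins, k):
        folds.append(np.nonzero(np.isin(groups, chunk))[0])
    return folds


def train(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
          seed: int = 0) -> TrainedModel:
    """Fit the probabilistic RBF-SVM on labeled samples (1 = binding)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    normalizer = Normalizer.fit(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, probability=True,
              random_state=seed)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter about probability=True
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(normalizer.transform(X), y)
    return TrainedModel(svc=svc, normalizer=normalizer, C=C, gamma=gamma,
                        layout_fingerprint=_layout_fingerprint(X.shape[1]))


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def grid_search(X: np.ndarray, y: np.ndarray, groups: Sequence[str],
                protein_subset_size: int = 30,
                grid: Optional[List[Tuple[float, float]]] = None,
                seed: int = 0, inner_k: int = 3) -> Tuple[float, float]:
    """Pick (C, gamma) maximizing cross-validated MCC on a protein subset.

    A random subset of ``protein_subset_size`` proteins (all of them when
    fewer are available) is drawn with the given seed; each grid point is
    scored by pooled out-of-fold MCC over an inner protein-grouped CV.
    """
    grid = grid if grid is not None else default_param_grid()
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=int)
    proteins = np.array(sorted(set(groups.tolist())))
    rng = np.random.default_rng(seed)
    subset = rng.choice(proteins, size=min(protein_subset_size, len(proteins)),
                        replace=False)
    mask = np.isin(groups, subset)
    Xs, ys, gs = np.asarray(X, dtype=float)[mask], y[mask], groups[mask]
    if len(np.unique(ys)) < 2:
        raise ValueError("grid-search protein subset contains a single class")

    k = min(inner_k, len(set(gs.tolist())))
    folds = protein_folds(gs, k, seed)
    best, best_mcc = grid[0], -np.inf
    for C, gamma in grid:
        preds = np.zeros(len(ys))
        ok = True
        for test_idx in folds:
            train_mask = np.ones(len(ys), dtype=bool)
            train_mask[test_idx] = False
            if len(np.unique(ys[train_mask])) < 2:
                ok = False
                break
            m = train(Xs[train_mask], ys[train_mask], C, gamma, seed=seed)
            preds[test_idx] = m.predict_proba(Xs[test_idx])
        if not ok:
            continue
        mcc = _confusion_metrics(preds >= 0.5, ys)[4]
        if mcc > best_mcc:
            best, best_mcc = (C, gamma), mcc
    return best


def cross_validate(X: np.ndarray, y: np.ndarray, groups: Sequence[str],
                   C: float, gamma: float, k: int = 5, seed: int = 0,
                   threshold: float = 0.5) -> EvalReport:
    """Protein-grouped k-fold CV; pooled out-of-fold predictions are scored."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = protein_folds(groups, k, seed)
    preds = np.full(len(y), np.nan)
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = train(X[train_mask], y[train_mask], C, gamma, seed=seed)
        preds[test_idx] = model.predict_proba(X[test_idx])
    assert not np.isnan(preds).any(), "every sample must be predicted exactly once"
    return evaluate(preds, y, threshold=threshold)


def evaluate(predictions: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Confusion-matrix rates, MCC and the ROC/AUC of the probability scores.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined`` rather than returned as NaN.
    """
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    acc, prec, sens, spec, mcc, undefined = _confusion_metrics(
        predictions >= threshold, labels, with_flags=True)

    if len(np.unique(labels)) == 2:
        fpr, tpr, _ = roc_curve(labels, predictions)
        auc = float(np.trapezoid(tpr, fpr))
        roc = list(zip(fpr.tolist(), tpr.tolist()))
    else:
        auc, roc = 0.0, []
        undefined = undefined + ["auc"]
    return EvalReport(
        accuracy=acc, precision=prec, sensitivity=sens, specificity=spec,
        mcc=mcc, auc=auc, roc=roc,
        n_positive=int((labels == 1).sum()), n_negative=int((labels == 0).sum()),
        undefined=undefined)


def _confusion_metrics(pred_pos: np.ndarray, labels: np.ndarray,
                       with_flags: bool = False):
    tp = int(np.sum(pred_pos & (labels == 1)))
    tn = int(np.sum(~pred_pos & (labels == 0)))
    fp = int(np.sum(pred_pos & (labels == 0)))
    fn = int(np.sum(~pred_pos & (labels == 1)))
    n = tp + tn + fp + fn
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = ratio(tp + tn, n, "accuracy")
    prec = ratio(tp, tp + fp, "precision")
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    if with_flags:
        return acc, prec, sens, spec, mcc, undefined
    return acc, prec, sens, spec, mcc


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist the classifier, normalizer and layout fingerprint."""
    joblib.dump({
        "format": "depthsite-model-v1",
        "svc": model.svc,
        "normalizer_mins": model.normalizer.mins,
        "normalizer_ranges": model.normalizer.ranges,
        "C": model.C, "gamma": model.gamma,
        "layout_fingerprint": model.layout_fingerprint,
    }, path)


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format") != "depthsite-model-v1":
        raise ValueError(f"{path}: not a depthsite model archive")
    return TrainedModel(
        svc=blob["svc"],
        normalizer=Normalizer(mins=blob["normalizer_mins"],
                              ranges=blob["normalizer_ranges"]),
        C=blob["C"], gamma=blob["gamma"],
        layout_fingerprint=blob["layout_fingerprint"])
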