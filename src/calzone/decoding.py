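"""Population decoding of session stage or anxiety category.

Cells are the samples: each row of the feature matrix is one cell's
column-z-scored mean activity per zone (stage decoding) or per peri-visit
time bin (anxiety decoding).  A soft-margin support-vector classifier with a
radial-basis kernel (K = exp(-sigma * ||x - y||^2), fixed sigma and cost, or
an optional 8-point cost grid confirmed by stratified k-fold
cross-validation on the training split) is trained on a stratified fraction
of the cells and evaluated on the rest.  Accuracy is benchmarked against the
no-information rate — the held-out majority-class fraction — with a
one-sided exact binomial test, and optionally against a label-permutation
null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC

from . import statcore

__all__ = ["DecodeReport", "build_features", "train_eval", "permutation_control"]


@dataclass
class DecodeReport:
    accuracy: float
    no_information_rate: float
    n_test: int
    binomial_p: float
    confusion: np.ndarray
    classes: list[str]
    cv_accuracy: float
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "no_information_rate": self.no_information_rate,
            "n_test": self.n_test,
            "binomial_p": self.binomial_p,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
            "cv_accuracy": self.cv_accuracy,
            "hyperparameters": self.hyperparameters,
        }


def build_features(
    summaries: pd.DataFrame,
    label_col: str,
    feature_cols: list[str] | None = None,
    cell_col: str = "cell_id",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix (cells x summaries, z-scored per column) and labels.

    ``summaries`` has one row per cell with its per-zone (or per-time-bin)
    mean activity columns and a label column.  Rows with any missing feature
    are dropped with a log count.
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in summaries.columns
            if c not in (label_col, cell_col) and np.issubdtype(summaries[c].dtype, np.number)
        ]
    if not feature_cols:
        raise ValueError("no feature columns found")
    sub = summaries[feature_cols + [label_col]].dropna()
    X = sub[feature_cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant feature column cannot be z-scored")
    X = (X - X.mean(axis=0)) / sd
    y = sub[label_col].astype(str).to_numpy()
    return X, y, feature_cols


def train_eval(
    features: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.7,
    folds: int = 10,
    sigma: float = 0.87,
    cost: float = 1.0,
    seed: int = 0,
    tune_costs: int = 0,
    max_resplits: int = 10,
) -> DecodeReport:
    """Stratified split, RBF-kernel SVC, held-out accuracy vs the NIR.

    ``sigma`` is the RBF width in K = exp(-sigma * ||x - y||^2) (sklearn's
    ``gamma``).  With ``tune_costs`` = m > 0, an m-point power-of-2 cost grid
    is searched by stratified k-fold cross-validation on the training split;
    otherwise the fixed cost is only confirmed by cross-validation.  The
    exact binomial test is one-sided (greater), success probability = NIR.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(str)
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    for attempt in range(max_resplits):
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, random_state=split_seed, stratify=y
        )
        if set(y_tr) == set(classes):
            break
    else:
        raise RuntimeError("could not produce a training split with all classes")

    n_folds = min(folds, int(np.min(np.unique(y_tr, return_counts=True)[1])))
    n_folds = max(n_folds, 2)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=split_seed)

    chosen_cost = cost
    if tune_costs > 0:
        grid = cost * 2.0 ** np.arange(tune_costs)
        best_acc = -1.0
        for c in grid:
            acc = cross_val_score(
                SVC(kernel="rbf", gamma=sigma, C=c), X_tr, y_tr, cv=cv
            ).mean()
            if acc > best_acc:
                best_acc, chosen_cost = float(acc), float(c)
        cv_acc = best_acc
    else:
        cv_acc = float(
            cross_val_score(
                SVC(kernel="rbf", gamma=sigma, C=cost), X_tr, y_tr, cv=cv
            ).mean()
        )

    model = SVC(kernel="rbf", gamma=sigma, C=chosen_cost)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    conf = confusion_matrix(y_te, pred, labels=classes)
    n_test = int(conf.sum())
    n_correct = int(np.trace(conf))
    accuracy = n_correct / n_test
    # no-information rate: majority-class fraction of the held-out labels
    _, counts = np.unique(y_te, return_counts=True)
    nir = float(counts.max() / n_test)
    if nir >= 1.0:
        binom_p = 1.0
    else:
        binom_p = statcore.exact_binomial(n_correct, n_test, nir, "greater").p_value
    return DecodeReport(
        accuracy=accuracy,
        no_information_rate=nir,
        n_test=n_test,
        binomial_p=binom_p,
        confusion=conf,
        classes=classes,
        cv_accuracy=cv_acc,
        hyperparameters={
            "sigma": sigma,
            "cost": chosen_cost,
            "folds": n_folds,
            "train_frac": train_frac,
            "seed": seed,
        },
    )


def permutation_control(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    **train_kwargs,
) -> dict:
    """Label-permutation null for the decoder.

    Re-runs train_eval on label-shuffled copies; empirical
    p = (1 + #{perm accuracy >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for a stable empirical p")
    observed = train_eval(features, labels, seed=seed, **train_kwargs).accuracy
    rng = np.random.default_rng(seed)
    y = np.asarray(labels).astype(str)
    perm_acc = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        perm_acc[i] = train_eval(
            features, y_perm, seed=int(rng.integers(0, 2**31 - 1)), **train_kwargs
        ).accuracy
    p = (1 + int((perm_acc >= observed).sum())) / (n_perm + 1)
    return {
        "observed_accuracy": float(observed),
        "perm_accuracies": perm_acc,
        "empirical_p": float(p),
        "n_perm": n_perm,
    }
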