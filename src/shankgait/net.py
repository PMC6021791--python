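"""Frailty-stage classification with a small neural network.

A single hidden layer of TanH units (default five) with a softmax
read-out, trained on the six gait parameters to predict the three
frailty stages.  Evaluation follows the protocol used for such
cohort-scale models:

* k-fold cross-validation (default 8 folds; with 161 subjects the
  folds hold 20-21 subjects and each model trains on ~141);
* one-vs-rest ROC curves and AUC per stage on the pooled
  out-of-fold probabilities;
* percentile bootstrap confidence intervals for the per-stage AUC,
  recomputing the full cross-validation on each resample (default
  500 iterations, 95% level).

Features are z-scored on each training fold before fitting.  All
randomness — weight initialisation, fold assignment, resampling —
derives from explicit seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .parameters import PARAM_FIELDS

__all__ = [
    "NetConfig",
    "RocResult",
    "BootstrapCI",
    "train_mlp",
    "kfold_cv_predict",
    "roc_auc_ovr",
    "bootstrap_auc_ci",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimisation settings for the classifier.

    ``hidden_nodes`` may be an int (one hidden layer) or a tuple for
    stacked layers; the activation is fixed to TanH.  The optimiser,
    penalty and iteration cap are not part of the scientific claim and
    are exposed for reproducibility.
    """

    hidden_nodes: int | tuple = 5
    l2_penalty: float = 1e-3
    max_iterations: int = 500
    tol: float = 1e-6
    seed: int = 0
    features: tuple = tuple(PARAM_FIELDS)

    @property
    def hidden_layer_sizes(self) -> tuple:
        if isinstance(self.hidden_nodes, int):
            if self.hidden_nodes < 1:
                raise ValueError("hidden_nodes must be >= 1")
            return (self.hidden_nodes,)
        return tuple(self.hidden_nodes)


@dataclass(frozen=True)
class RocResult:
    """Per-class one-vs-rest ROC curve and its area."""

    label: object
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class BootstrapCI:
    label: object
    lower: float
    upper: float
    level: float = 0.95
    iterations: int = 500
    samples: np.ndarray = field(default=None, repr=False)  # type: ignore


def _make_pipeline(config: NetConfig, seed: int | None = None) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=config.hidden_layer_sizes,
                    activation="tanh",
                    solver="lbfgs",
                    alpha=config.l2_penalty,
                    max_iter=config.max_iterations,
                    tol=config.tol,
                    random_state=config.seed if seed is None else seed,
                ),
            ),
        ]
    )


def train_mlp(X, y, config: NetConfig | None = None) -> Pipeline:
    """Fit the TanH network on standardised features.

    The returned estimator is a scaler + network pipeline, so the
    z-scoring learned on the training data travels with the model.
    Training is deterministic for a given config seed (full-batch
    quasi-Newton optimisation, seeded initial weights).
    """
    config = config or NetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    model = _make_pipeline(config)
    _fit(model, X, y)
    return model


def _fit(model: Pipeline, X, y) -> None:
    # max_iterations is a configured stopping rule, not a failure.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)


def kfold_cv_predict(
    X,
    y,
    k: int = 8,
    config: NetConfig | None = None,
    seed: int = 0,
    stratified: bool = True,
    max_resample: int = 20,
):
    """Pooled out-of-fold class probabilities from k-fold CV.

    Subjects are randomly partitioned into ``k`` folds; each subject's
    probabilities come from the model trained on the other folds.  The
    default partition is stratified by class — fold sizes are the same
    as a plain random split (20/21 subjects for a 161-subject cohort
    at k=8) but every training fold is guaranteed to see every class,
    and the cross-validated AUC is unbiased at chance level under
    label permutation (an unstratified split of a rare class makes
    training and test class proportions anti-correlate, dragging the
    null AUC below 0.5).  ``stratified=False`` restores the plain
    random split; a partition that leaves a training fold without one
    of the classes is then redrawn (up to ``max_resample`` times) and
    the redraw count is recorded in the returned info dict.

    Returns (probs, classes, info): probs is (n, n_classes) aligned
    with the input order, classes the label order of its columns.
    """
    config = config or NetConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < k:
        raise ValueError("need at least k subjects")
    classes = np.unique(y)
    info = {"resampled_partitions": 0, "stratified": stratified}
    if stratified and np.min(np.unique(y, return_counts=True)[1]) >= k:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(kf.split(X, y))
    else:
        info["stratified"] = False
        for attempt in range(max_resample):
            kf = KFold(n_splits=k, shuffle=True, random_state=seed + attempt)
            splits = list(kf.split(X))
            if all(np.unique(y[tr]).size == classes.size for tr, _ in splits):
                break
            info["resampled_partitions"] += 1
        else:
            raise RuntimeError(
                "could not draw a partition with every class in every training fold"
            )
    probs = np.zeros((n, classes.size))
    ss = np.random.SeedSequence(seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]
    for f, (tr, te) in enumerate(splits):
        model = _make_pipeline(config, seed=fold_seeds[f])
        _fit(model, X[tr], y[tr])
        p = model.predict_proba(X[te])
        cols = {c: i for i, c in enumerate(model.classes_)}
        for ci, c in enumerate(classes):
            probs[te, ci] = p[:, cols[c]]
    return probs, classes, info


def roc_auc_ovr(probs, labels, classes=None) -> list[RocResult]:
    """One-vs-rest ROC and trapezoid AUC per class.

    The trapezoid area over the threshold-swept ROC equals the
    Mann-Whitney probability that a random positive outranks a random
    negative (ties counted half).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.ndim == 1:
        probs = probs[:, None]
    if np.any(probs < -1e-9) or np.any(probs > 1 + 1e-9):
        raise ValueError("probabilities must lie in [0, 1]")
    if classes is None:
        classes = np.unique(labels)
    out = []
    for ci, c in enumerate(classes):
        pos = labels == c
        if pos.all() or not pos.any():
            raise ValueError(f"class {c!r} needs both positives and negatives")
        fpr, tpr, _ = roc_curve(pos.astype(int), probs[:, ci])
        out.append(RocResult(c, fpr, tpr, float(_trapezoid_auc(fpr, tpr))))
    return out


def bootstrap_auc_ci(
    X,
    y,
    B: int = 500,
    k: int = 8,
    config: NetConfig | None = None,
    seed: int = 0,
    level: float = 0.95,
    max_redraw: int = 50,
) -> list[BootstrapCI]:
    """Percentile bootstrap CI of the per-class CV AUC.

    Each of the ``B`` iterations resamples subjects with replacement
    (unstratified), reruns the full k-fold cross-validation on the
    resample and records the per-class one-vs-rest AUC; the interval
    is the (alpha/2, 1-alpha/2) percentile band.  Resamples missing a
    class, or leaving a class without both positives and negatives,
    are redrawn.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap iterations")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    aucs = np.zeros((B, classes.size))
    redraws = 0
    for b in range(B):
        for _ in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size == classes.size:
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a resample containing every class")
        probs, cls, _ = kfold_cv_predict(
            X[idx], y[idx], k=k, config=config,
            seed=int(rng.integers(2**31)),
        )
        for r in roc_auc_ovr(probs, y[idx], cls):
            aucs[b, list(cls).index(r.label)] = r.auc
    alpha = 1 - level
    out = []
    for ci, c in enumerate(classes):
        lo, hi = np.percentile(aucs[:, ci], [100 * alpha / 2, 100 * (1 - alpha / 2)])
        out.append(
            BootstrapCI(c, float(lo), float(hi), level, B, aucs[:, ci].copy())
        )
    return out


def cohort_features(table, features: Sequence[str] = PARAM_FIELDS):
    """(X, y) from a cohort table: six gait parameters vs stage label."""
    X = table[list(features)].to_numpy(dtype=float)
    y = table["stage"].to_numpy()
    return X, y
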