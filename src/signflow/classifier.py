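"""RBF-kernel soft-margin SVM over the asymmetric domain encoding.

Training delegates to libsvm through scikit-learn's ``SVC``. The fitted
machine is frozen into a ``TrainedModel`` holding the support vectors, dual
coefficients and bias explicitly; prediction-time scoring evaluates

    f(x) = sum_i alpha_i * exp(-gamma * ||sv_i - x||^2) + b

directly from those arrays, so a serialized model reproduces its scores
exactly and a model file is self-describing (versioned header, solver
settings, vocabulary fingerprint and the ordered vocabulary itself).

The decision score is a signed margin, not a probability: positive sign
means the scored orientation looks like a verified upstream->downstream
relation, magnitude is confidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .features import FeatureInstance, instance_labels, instances_to_dense

__all__ = [
    "HyperParams",
    "TrainedModel",
    "rbf_kernel",
    "rbf_gram",
    "train",
    "decision_score",
    "decision_scores",
    "grid_search",
    "save_model",
    "load_model",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

MODEL_FORMAT = "signflow-model/1"
SOLVER_TOL = 1e-3

# LIBSVM-guide style coarse power-of-two grids.
DEFAULT_C_GRID: Tuple[float, ...] = (2.0 ** -5, 2.0 ** -1, 2.0 ** 3, 2.0 ** 7, 2.0 ** 11, 2.0 ** 15)
DEFAULT_GAMMA_GRID: Tuple[float, ...] = (2.0 ** -15, 2.0 ** -11, 2.0 ** -7, 2.0 ** -3, 2.0 ** 1)


@dataclass(frozen=True)
class HyperParams:
    """Soft-margin regularizer C and RBF width gamma, both strictly positive."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.C > 0):
            raise ValueError(f"C must be positive, got {self.C}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be positive, got {self.gamma}")


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||x - y||^2) for two dense vectors over one vocabulary."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    diff = x - y
    return float(np.exp(-gamma * float(diff @ diff)))


def rbf_gram(X: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """Pairwise RBF kernel matrix between the rows of X and Y."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-gamma * d2)


@dataclass
class TrainedModel:
    """Frozen SVM: support vectors, dual coefficients (alpha_i * y_i), bias.

    ``vocab_domains`` is the ordered vocabulary the model was trained on;
    scoring refuses instances encoded against a different vocabulary.
    ``train_pair_keys`` records the unordered training pairs so that
    independent tests and network prediction can guard against overlap.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    hyperparams: HyperParams
    vocab_domains: Tuple[str, ...]
    fingerprint: str
    train_pair_keys: frozenset = frozenset()
    tol: float = SOLVER_TOL

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]


def train(
    instances: Sequence[FeatureInstance],
    hp: HyperParams,
    vocab,
    seed: int = 0,
) -> TrainedModel:
    """Fit the RBF SVM on labeled instances encoded against ``vocab``.

    Deterministic for fixed inputs: the libsvm SMO path involves no random
    tie-breaking for binary classification without probability estimates;
    ``seed`` is recorded for interface stability.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("no training instances")
    y = instance_labels(instances)
    classes = set(y.tolist())
    if classes != {-1, 1}:
        raise ValueError(f"training data must contain both classes, got labels {sorted(classes)}")
    X = instances_to_dense(instances, len(vocab))
    svc = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf", tol=SOLVER_TOL, shrinking=True, random_state=seed)
    svc.fit(X, y)
    # binary problem with classes_ == [-1, 1]: decision_function > 0 <=> class +1
    return TrainedModel(
        support_vectors=np.array(svc.support_vectors_, dtype=np.float64),
        dual_coef=np.array(svc.dual_coef_[0], dtype=np.float64),
        intercept=float(svc.intercept_[0]),
        hyperparams=hp,
        vocab_domains=tuple(vocab.domains),
        fingerprint=vocab.fingerprint,
        train_pair_keys=frozenset(inst.pair_key for inst in instances),
    )


def _check_fingerprint(model: TrainedModel, vocab_fingerprint: Optional[str]) -> None:
    if vocab_fingerprint is not None and vocab_fingerprint != model.fingerprint:
        raise ValueError(
            "vocabulary fingerprint mismatch: model was trained with "
            f"{model.fingerprint}, instances encoded with {vocab_fingerprint}"
        )


def decision_scores(
    model: TrainedModel,
    instances: Sequence[FeatureInstance],
    vocab_fingerprint: Optional[str] = None,
) -> np.ndarray:
    """Signed decision values for a batch of instances."""
    _check_fingerprint(model, vocab_fingerprint)
    X = instances_to_dense(list(instances), model.n_features)
    K = rbf_gram(X, model.support_vectors, model.hyperparams.gamma)
    return K @ model.dual_coef + model.intercept


def decision_score(
    model: TrainedModel,
    instance: FeatureInstance,
    vocab_fingerprint: Optional[str] = None,
) -> float:
    """Signed decision value for one instance (positive = verified-direction class)."""
    return float(decision_scores(model, [instance], vocab_fingerprint)[0])


def grid_search(
    instances: Sequence[FeatureInstance],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    k_inner: int = 5,
    seed: int = 0,
    vocab=None,
) -> HyperParams:
    """Pick (C, gamma) maximizing mean pair-grouped inner-CV instance accuracy.

    The two orientations of one pair always share an inner fold (one is a
    deterministic mirror of the other; splitting them leaks). Ties are broken
    toward smaller C, then smaller gamma.
    """
    if not C_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    instances = list(instances)
    n_features = len(vocab) if vocab is not None else (max(g for i in instances for g in i.values) + 1)
    y = instance_labels(instances)
    X = instances_to_dense(instances, n_features)

    folds = _grouped_instance_folds(instances, k_inner, seed)
    best: Optional[HyperParams] = None
    best_acc = -1.0
    for C in sorted(set(float(c) for c in C_grid)):
        for gamma in sorted(set(float(g) for g in gamma_grid)):
            correct = 0
            for test_idx in folds:
                train_mask = np.ones(len(instances), dtype=bool)
                train_mask[test_idx] = False
                y_tr = y[train_mask]
                if len(set(y_tr.tolist())) < 2:
                    raise ValueError("degenerate inner fold: training portion lost a class")
                svc = SVC(C=C, gamma=gamma, kernel="rbf", tol=SOLVER_TOL)
                svc.fit(X[train_mask], y_tr)
                correct += int(np.sum(svc.predict(X[test_idx]) == y[test_idx]))
            acc = correct / len(instances)
            if acc > best_acc + 1e-12:
                best_acc = acc
                best = HyperParams(C=C, gamma=gamma)
    assert best is not None
    return best


def _grouped_instance_folds(instances: List[FeatureInstance], k: int, seed: int) -> List[np.ndarray]:
    """Round-robin deal of shuffled pair groups into k folds of instance indices."""
    groups: Dict[Tuple[str, str], List[int]] = {}
    for i, inst in enumerate(instances):
        groups.setdefault(inst.pair_key, []).append(i)
    keys = sorted(groups)
    if k < 2 or k > len(keys):
        raise ValueError(f"need 2 <= k <= {len(keys)} pair groups, got k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    folds: List[List[int]] = [[] for _ in range(k)]
    for slot, key_idx in enumerate(order):
        folds[slot % k].extend(groups[keys[key_idx]])
    return [np.array(sorted(f), dtype=np.int64) for f in folds]


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as a single self-describing JSON file."""
    payload = {
        "format": MODEL_FORMAT,
        "tol": model.tol,
        "C": model.hyperparams.C,
        "gamma": model.hyperparams.gamma,
        "intercept": model.intercept,
        "fingerprint": model.fingerprint,
        "vocabulary": list(model.vocab_domains),
        "dual_coef": model.dual_coef.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "train_pair_keys": sorted("\t".join(k) for k in model.train_pair_keys),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedModel:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"unrecognized model format: {payload.get('format')!r}")
    return TrainedModel(
        support_vectors=np.array(payload["support_vectors"], dtype=np.float64),
        dual_coef=np.array(payload["dual_coef"], dtype=np.float64),
        intercept=float(payload["intercept"]),
        hyperparams=HyperParams(C=float(payload["C"]), gamma=float(payload["gamma"])),
        vocab_domains=tuple(payload["vocabulary"]),
        fingerprint=payload["fingerprint"],
        train_pair_keys=frozenset(tuple(k.split("\t")) for k in payload["train_pair_keys"]),
        tol=float(payload["tol"]),
    )
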