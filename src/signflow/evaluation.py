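"""Experiment orchestration: grouped k-fold CV, independent test, prediction.

The unit of cross-validation is the pair, never the instance: the two
orientation instances of one pair are mirror images of each other, so
letting them land in different folds leaks the training fold's labels into
the test fold and inflates instance accuracy. ``make_folds`` therefore
shuffles pairs and deals them round-robin; hyperparameter search is nested
(an inner grouped CV on each outer training split only).

``single_domain_baseline`` implements the naive alternative the feature
encoding is designed to beat: per-domain upstream/downstream odds learned
from the training pairs, combined by majority vote. It captures any signal
a single domain carries but is blind to domain combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .classifier import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    SOLVER_TOL,
    HyperParams,
    TrainedModel,
    decision_scores,
    grid_search,
    train,
)
from .data_io import DirectedPairSet, ProteinDomainMap, UndirectedPairSet
from .decision import DecisionPolicy, DirectionCall, fuse, fuse_bags
from .features import (
    DomainVocabulary,
    FeatureInstance,
    PairBag,
    build_training_bags,
    encode_pair,
    instance_labels,
    instances_to_dense,
)
from .metrics import MetricsReport, build_report

__all__ = [
    "FoldPlan",
    "ExperimentConfig",
    "make_folds",
    "cross_validate",
    "independent_test",
    "predict_network",
    "instance_cv_accuracy",
    "single_domain_baseline",
    "FrequencyBaseline",
]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of pairs to folds; both orientations of a pair share a fold."""

    k: int
    assignment: Dict[Tuple[str, str], int]
    seed: int

    def fold_of(self, bag: PairBag) -> int:
        return self.assignment[bag.pair_key]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a CV/test run needs beyond the data itself."""

    k: int = 20
    seed: int = 0
    epsilon: float = 0.1
    C_grid: Tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: Tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_k: int = 5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    @property
    def policy(self) -> DecisionPolicy:
        return DecisionPolicy(epsilon=self.epsilon)


def make_folds(bags: Sequence[PairBag], k: int, seed: int) -> FoldPlan:
    """Shuffle pairs with ``seed`` and deal them round-robin into ``k`` folds."""
    bags = list(bags)
    keys = [bag.pair_key for bag in bags]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate pairs in fold input")
    if k > len(bags):
        raise ValueError(f"k={k} exceeds the number of pairs ({len(bags)})")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(bags))
    assignment = {keys[idx]: slot % k for slot, idx in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def _fit_fold(
    train_bags: List[PairBag],
    vocab: DomainVocabulary,
    config: ExperimentConfig,
    fold_seed: int,
) -> TrainedModel:
    instances: List[FeatureInstance] = []
    for bag in train_bags:
        instances.append(bag.fwd)
        instances.append(bag.rev)
    if len(config.C_grid) == 1 and len(config.gamma_grid) == 1:
        hp = HyperParams(C=config.C_grid[0], gamma=config.gamma_grid[0])
    else:
        hp = grid_search(
            instances,
            C_grid=config.C_grid,
            gamma_grid=config.gamma_grid,
            k_inner=min(config.inner_k, len(train_bags)),
            seed=fold_seed,
            vocab=vocab,
        )
    return train(instances, hp, vocab, seed=fold_seed)


def cross_validate(
    bags: Sequence[PairBag],
    vocab: DomainVocabulary,
    config: ExperimentConfig,
    n_dropped_null: int = 0,
) -> MetricsReport:
    """Pair-grouped k-fold CV with nested grid search; pooled out-of-fold report.

    Every bag must carry labeled instances and a verified direction. Micro
    metrics and AUC are computed on the pooled out-of-fold instance scores;
    macro_accuracy on the pooled out-of-fold fused bags.
    """
    bags = list(bags)
    plan = make_folds(bags, config.k, config.seed)
    pooled_labels: List[int] = []
    pooled_scores: List[float] = []
    fused: List[PairBag] = []
    for fold in range(plan.k):
        train_bags = [b for b in bags if plan.fold_of(b) != fold]
        test_bags = [b for b in bags if plan.fold_of(b) == fold]
        if not test_bags:
            continue
        model = _fit_fold(train_bags, vocab, config, fold_seed=config.seed * 1009 + fold)
        test_instances = [b.fwd for b in test_bags] + [b.rev for b in test_bags]
        scores = decision_scores(model, test_instances, vocab.fingerprint)
        pooled_labels.extend(instance_labels(test_instances).tolist())
        pooled_scores.extend(scores.tolist())
        n = len(test_bags)
        for i, bag in enumerate(test_bags):
            bag.score_fwd = float(scores[i])
            bag.score_rev = float(scores[n + i])
            bag.call = fuse(bag.score_fwd, bag.score_rev, config.policy)
        fused.extend(test_bags)
    return build_report(
        pooled_labels,
        pooled_scores,
        bags=fused,
        n_dropped_null=n_dropped_null,
        epsilon=config.epsilon,
    )


def independent_test(
    model: TrainedModel,
    test_pairs: DirectedPairSet,
    domain_map: ProteinDomainMap,
    policy: DecisionPolicy,
) -> MetricsReport:
    """Evaluate a trained model on held-out verified pairs.

    Test pairs are encoded against the model's own vocabulary; pairs whose
    proteins share no training domain degenerate to null vectors and are
    dropped (counted in the report). Any overlap with the training pairs is
    fatal.
    """
    overlap = sorted(test_pairs.pair_keys() & model.train_pair_keys)
    if overlap:
        shown = ", ".join(f"({a}, {b})" for a, b in overlap[:10])
        raise ValueError(f"{len(overlap)} test pair(s) overlap the training set: {shown}")
    vocab = DomainVocabulary(domains=model.vocab_domains)
    bags, dropped = build_training_bags(test_pairs, domain_map, vocab)
    fuse_bags(bags, model, policy)
    labels: List[int] = []
    scores: List[float] = []
    for bag in bags:
        labels.extend([1, -1])
        scores.extend([bag.score_fwd, bag.score_rev])
    return build_report(labels, scores, bags=bags, n_dropped_null=dropped, epsilon=policy.epsilon)


def predict_network(
    model: TrainedModel,
    undirected_pairs: UndirectedPairSet,
    domain_map: ProteinDomainMap,
    policy: DecisionPolicy,
    allow_train_overlap: bool = False,
) -> Tuple[List[PairBag], int, int]:
    """Score and fuse every encodable unordered pair in canonical orientation.

    Returns (fused bags, null pairs dropped, pairs skipped for training
    overlap). Pairs identical to a training pair are skipped unless
    ``allow_train_overlap``; the fused call is orientation-equivariant, so
    the canonical lexicographic orientation is presentation only.
    """
    vocab = DomainVocabulary(domains=model.vocab_domains)
    bags: List[PairBag] = []
    dropped = 0
    skipped = 0
    for a, b in undirected_pairs.pairs:
        if not allow_train_overlap and (a, b) in model.train_pair_keys:
            skipped += 1
            continue
        bag = encode_pair(a, b, domain_map, vocab)
        if bag is None:
            dropped += 1
            continue
        bags.append(bag)
    fuse_bags(bags, model, policy)
    return bags, dropped, skipped


def instance_cv_accuracy(
    bags: Sequence[PairBag],
    vocab: DomainVocabulary,
    hp: HyperParams,
    k: int,
    seed: int,
    grouped: bool = True,
) -> float:
    """Out-of-fold instance accuracy with or without pair grouping.

    The ungrouped variant shuffles instances individually, so a test
    instance's mirror image is almost always in the training fold — the
    leakage the grouped design exists to prevent. Used to quantify that
    inflation; production evaluation is always grouped.
    """
    instances: List[FeatureInstance] = []
    for bag in bags:
        instances.append(bag.fwd)
        instances.append(bag.rev)
    y = instance_labels(instances)
    X = instances_to_dense(instances, len(vocab))
    rng = np.random.default_rng(seed)
    n = len(instances)
    if grouped:
        order = rng.permutation(len(bags))
        fold_of = np.empty(n, dtype=np.int64)
        for slot, bag_idx in enumerate(order):
            fold_of[2 * bag_idx] = slot % k
            fold_of[2 * bag_idx + 1] = slot % k
    else:
        fold_of = rng.permutation(n) % k
    correct = 0
    for fold in range(k):
        test_mask = fold_of == fold
        svc = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf", tol=SOLVER_TOL)
        svc.fit(X[~test_mask], y[~test_mask])
        correct += int(np.sum(svc.predict(X[test_mask]) == y[test_mask]))
    return correct / n


@dataclass
class FrequencyBaseline:
    """Per-domain upstream/downstream odds with majority-vote fusion.

    For each domain g the training pairs contribute counts of g appearing on
    the upstream vs the downstream side. At prediction time every domain
    carried by exactly one protein of the pair votes for the orientation its
    odds favor; the majority wins, ties are undetermined. Domains shared by
    both proteins cancel and unseen domains abstain.
    """

    log_odds: Dict[str, float] = field(default_factory=dict)

    def fit(self, pairs: DirectedPairSet, domain_map: ProteinDomainMap) -> "FrequencyBaseline":
        up_counts: Dict[str, int] = {}
        down_counts: Dict[str, int] = {}
        for up, down, _ in pairs.pairs:
            for d in domain_map.domains(up):
                up_counts[d] = up_counts.get(d, 0) + 1
            for d in domain_map.domains(down):
                down_counts[d] = down_counts.get(d, 0) + 1
        self.log_odds = {}
        for d in set(up_counts) | set(down_counts):
            # add-one smoothing keeps singletons from voting with infinite weight
            self.log_odds[d] = math.log((up_counts.get(d, 0) + 1) / (down_counts.get(d, 0) + 1))
        return self

    def predict(self, a: str, b: str, domain_map: ProteinDomainMap) -> DirectionCall:
        votes = 0
        a_doms = domain_map.domains(a)
        b_doms = domain_map.domains(b)
        for d in a_doms - b_doms:
            lo = self.log_odds.get(d, 0.0)
            votes += (lo > 0) - (lo < 0)
        for d in b_doms - a_doms:
            lo = self.log_odds.get(d, 0.0)
            votes -= (lo > 0) - (lo < 0)
        if votes > 0:
            return DirectionCall.A_TO_B
        if votes < 0:
            return DirectionCall.B_TO_A
        return DirectionCall.UNDETERMINED


def single_domain_baseline(
    bags: Sequence[PairBag],
    domain_map: ProteinDomainMap,
    k: int,
    seed: int,
) -> float:
    """Out-of-fold macro accuracy of the per-domain-frequency baseline.

    Uses the same pair-grouped folds as ``cross_validate`` so the comparison
    against the kernel pipeline is like for like.
    """
    bags = list(bags)
    plan = make_folds(bags, k, seed)
    hits = 0
    for fold in range(plan.k):
        train_bags = [b for b in bags if plan.fold_of(b) != fold]
        test_bags = [b for b in bags if plan.fold_of(b) == fold]
        train_pairs = DirectedPairSet(
            pairs=[
                (b.true_upstream, b.b if b.true_upstream == b.a else b.a, None)
                for b in train_bags
            ]
        )
        baseline = FrequencyBaseline().fit(train_pairs, domain_map)
        for bag in test_bags:
            call = baseline.predict(bag.a, bag.b, domain_map)
            correct_call = DirectionCall.A_TO_B if bag.true_upstream == bag.a else DirectionCall.B_TO_A
            hits += int(call is correct_call)
    return hits / len(bags)
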