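"""Asymmetric domain-presence feature encoding for directed protein pairs.

Every protein is reduced to its set of Pfam domain accessions. The domains
of all training proteins form an ordered vocabulary G; a putative direction
A→B over a pair is encoded as a vector over G whose component for domain g is

    +1  if A has g and B does not,
    -1  if B has g and A does not,
     2  if both proteins have g,
     0  otherwise.

The encoding is deliberately asymmetric: swapping the roles of A and B flips
every +1 to -1 and back while leaving 2 and 0 fixed, so the two orientations
of one pair yield two distinct, mirrored instances. A pair in which either
protein shares no domain with the vocabulary carries no usable signal; it
encodes to the null vector and is dropped.

Vectors are stored sparsely (component index -> value); zeros are implicit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .data_io import DirectedPairSet, ProteinDomainMap
from .decision import DirectionCall

__all__ = [
    "DomainVocabulary",
    "FeatureInstance",
    "PairBag",
    "build_vocabulary",
    "encode_orientation",
    "encode_pair",
    "build_training_bags",
    "build_training_set",
    "instances_to_dense",
    "instance_labels",
]


@dataclass(frozen=True)
class DomainVocabulary:
    """Ordered domain universe of a training corpus.

    domains : tuple of str
        Lexicographically sorted domain accessions; position = integer index.
    n_missing_proteins : int
        Training proteins absent from the domain map (treated as empty sets).
    """

    domains: Tuple[str, ...]
    n_missing_proteins: int = 0
    index: Dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {d: g for g, d in enumerate(self.domains)})

    def __len__(self) -> int:
        return len(self.domains)

    def __contains__(self, domain: str) -> bool:
        return domain in self.index

    @property
    def fingerprint(self) -> str:
        """Hash of the ordered domain list; guards model/vocabulary mismatch."""
        h = hashlib.sha256("\n".join(self.domains).encode("utf-8"))
        return h.hexdigest()[:16]


@dataclass
class FeatureInstance:
    """One orientation of a pair: sparse vector plus optional class label.

    ``values`` maps vocabulary index -> value in {-1, 1, 2}; zeros are never
    stored. ``label`` is +1 for an experimentally verified direction, -1 for
    its reverse, None for prediction-time instances.
    """

    up: str
    down: str
    values: Dict[int, int]
    label: Optional[int] = None

    @property
    def pair_key(self) -> Tuple[str, str]:
        """Unordered identity of the underlying pair (groups the two orientations)."""
        return (self.up, self.down) if self.up <= self.down else (self.down, self.up)

    def dense(self, n_features: int) -> np.ndarray:
        vec = np.zeros(n_features, dtype=np.float64)
        for g, v in self.values.items():
            vec[g] = v
        return vec


@dataclass
class PairBag:
    """A protein pair with its two orientation instances and fused outcome.

    ``true_upstream`` records, for verified pairs, which protein is the known
    upstream; it is None for prediction-time bags. Scores and the call are
    populated by decision fusion.
    """

    a: str
    b: str
    fwd: FeatureInstance
    rev: FeatureInstance
    true_upstream: Optional[str] = None
    tag: Optional[str] = None
    score_fwd: Optional[float] = None
    score_rev: Optional[float] = None
    call: Optional[DirectionCall] = None

    @property
    def pair_key(self) -> Tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)

    @property
    def call_correct(self) -> Optional[bool]:
        """Whether the fused call names exactly the verified direction."""
        if self.call is None or self.true_upstream is None:
            return None
        if self.call is DirectionCall.A_TO_B:
            return self.true_upstream == self.a
        if self.call is DirectionCall.B_TO_A:
            return self.true_upstream == self.b
        return False


def build_vocabulary(domain_map: ProteinDomainMap, training_pairs: DirectedPairSet) -> DomainVocabulary:
    """Collect the domains of every protein occurring in the training pairs.

    Proteins missing from the map contribute nothing and are counted in
    ``n_missing_proteins``. Raises ``ValueError`` if the union is empty.
    """
    proteins = set()
    for up, down, _ in training_pairs.pairs:
        proteins.add(up)
        proteins.add(down)
    missing = sum(1 for p in proteins if p not in domain_map.entries)
    union: set = set()
    for p in proteins:
        union |= domain_map.domains(p)
    if not union:
        raise ValueError("empty domain vocabulary: no training protein carries any domain")
    return DomainVocabulary(domains=tuple(sorted(union)), n_missing_proteins=missing)


def encode_orientation(
    up: str,
    down: str,
    domain_map: ProteinDomainMap,
    vocab: DomainVocabulary,
) -> Optional[FeatureInstance]:
    """Encode the putative direction ``up`` → ``down``; None if the pair is null.

    Null means either protein shares no domain with the vocabulary (including
    proteins absent from the map entirely).
    """
    if len(vocab) == 0:
        raise ValueError("cannot encode against an empty vocabulary")
    up_doms = _vocab_domains(domain_map.domains(up), vocab)
    down_doms = _vocab_domains(domain_map.domains(down), vocab)
    if not up_doms or not down_doms:
        return None
    values: Dict[int, int] = {}
    for d in up_doms | down_doms:
        g = vocab.index[d]
        if d in up_doms and d in down_doms:
            values[g] = 2
        elif d in up_doms:
            values[g] = 1
        else:
            values[g] = -1
    return FeatureInstance(up=up, down=down, values=values)


def _vocab_domains(domains: FrozenSet[str], vocab: DomainVocabulary) -> set:
    return {d for d in domains if d in vocab.index}


def encode_pair(
    a: str,
    b: str,
    domain_map: ProteinDomainMap,
    vocab: DomainVocabulary,
) -> Optional[PairBag]:
    """Encode both orientations of (a, b); None if the pair is null.

    The two orientations are null together: nullity depends only on the two
    domain sets, not on the direction.
    """
    fwd = encode_orientation(a, b, domain_map, vocab)
    if fwd is None:
        return None
    rev = encode_orientation(b, a, domain_map, vocab)
    assert rev is not None
    return PairBag(a=a, b=b, fwd=fwd, rev=rev)


def build_training_bags(
    directed_pairs: DirectedPairSet,
    domain_map: ProteinDomainMap,
    vocab: DomainVocabulary,
) -> Tuple[List[PairBag], int]:
    """Encode verified directed pairs into labeled bags.

    For each encodable pair (up, down) the forward instance is labeled +1
    (the verified direction) and the reverse instance -1. Returns the bags
    and the count of null pairs dropped.
    """
    bags: List[PairBag] = []
    dropped = 0
    for up, down, tag in directed_pairs.pairs:
        bag = encode_pair(up, down, domain_map, vocab)
        if bag is None:
            dropped += 1
            continue
        bag.fwd.label = 1
        bag.rev.label = -1
        bag.true_upstream = up
        bag.tag = tag
        bags.append(bag)
    if not bags:
        raise ValueError("no training pair is encodable (all null vectors)")
    return bags, dropped


def build_training_set(
    directed_pairs: DirectedPairSet,
    domain_map: ProteinDomainMap,
    vocab: DomainVocabulary,
) -> List[FeatureInstance]:
    """Flat labeled instance list: two instances per encodable verified pair."""
    bags, _ = build_training_bags(directed_pairs, domain_map, vocab)
    instances: List[FeatureInstance] = []
    for bag in bags:
        instances.append(bag.fwd)
        instances.append(bag.rev)
    return instances


def instances_to_dense(instances: List[FeatureInstance], n_features: int) -> np.ndarray:
    """Stack sparse instances into a dense (n_instances, n_features) array."""
    X = np.zeros((len(instances), n_features), dtype=np.float64)
    for i, inst in enumerate(instances):
        for g, v in inst.values.items():
            X[i, g] = v
    return X


def instance_labels(instances: List[FeatureInstance]) -> np.ndarray:
    labels = np.empty(len(instances), dtype=np.int64)
    for i, inst in enumerate(instances):
        if inst.label is None:
            raise ValueError(f"unlabeled instance for pair ({inst.up}, {inst.down})")
        labels[i] = inst.label
    return labels
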