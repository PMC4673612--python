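"""Synthetic interaction worlds with planted domain-direction laws.

A world is a domain universe, a population of proteins (each a random domain
set) and a sample of interacting pairs whose true signal-flow direction is
decided by planted rules of the form "the upstream protein must carry these
domains (and lack those), the downstream protein likewise". Rules can be
combined, prioritized and made mutually exclusive, which is enough to plant
both a single-domain law (one kinase-like domain upstream, one
substrate-like domain downstream) and genuinely non-additive laws where no
single domain's frequency differs between the two sides.

Label noise flips the recorded direction of a pair with fixed probability;
the pre-noise truth is kept alongside so recovery can be measured. Pairs
matching no rule carry no direction and are discarded, as are ambiguous
pairs whose two orientations match rules of equal priority — a coin-flipped
label would contaminate the noise-free condition.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

import numpy as np

from .data_io import (
    DirectedPairSet,
    ProteinDomainMap,
    write_directed_pairs,
    write_domain_map,
)

__all__ = [
    "DirectionRule",
    "WorldSpec",
    "World",
    "generate_world",
    "single_rule_world",
    "nonlinear_world",
    "write_world",
]


@dataclass(frozen=True)
class DirectionRule:
    """Conjunctive membership rule deciding that one orientation is upstream.

    An orientation (X, Y) matches when X carries every ``up_required`` domain
    and none of ``up_forbidden``, and Y carries every ``down_required`` and
    none of ``down_forbidden``. Higher ``priority`` wins when several rules
    match.
    """

    up_required: FrozenSet[str] = frozenset()
    down_required: FrozenSet[str] = frozenset()
    up_forbidden: FrozenSet[str] = frozenset()
    down_forbidden: FrozenSet[str] = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        if not (self.up_required | self.down_required | self.up_forbidden | self.down_forbidden):
            raise ValueError("a direction rule must constrain at least one domain")

    def matches(self, up_domains: FrozenSet[str], down_domains: FrozenSet[str]) -> bool:
        return (
            self.up_required <= up_domains
            and self.down_required <= down_domains
            and not (self.up_forbidden & up_domains)
            and not (self.down_forbidden & down_domains)
        )


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of one synthetic world.

    n_domains : int
        Size of the domain universe (signal + background accessions).
    n_proteins : int
        Population size from which pairs are sampled.
    domains_per_protein : (int, int)
        Inclusive range of background domains drawn uniformly per protein.
    rules : tuple of DirectionRule
        The planted direction law; priorities must be unique.
    n_pairs : int
        Directed pairs to emit; generation fails if 10x oversampling of
        candidate pairs yields fewer.
    noise : float
        Probability of flipping a recorded direction, in [0, 1].
    signal_probs : mapping domain -> probability
        Domains excluded from uniform background sampling and included
        independently with the given probability (controls how often the
        rule-relevant domains occur).
    """

    n_domains: int
    n_proteins: int
    domains_per_protein: Tuple[int, int]
    rules: Tuple[DirectionRule, ...]
    n_pairs: int
    noise: float = 0.0
    seed: int = 0
    signal_probs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_domains <= 0 or self.n_proteins <= 0 or self.n_pairs <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError(f"noise must be in [0, 1], got {self.noise}")
        lo, hi = self.domains_per_protein
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid domains_per_protein range {self.domains_per_protein}")
        priorities = [r.priority for r in self.rules]
        if len(set(priorities)) != len(priorities):
            raise ValueError("rule priorities must be unique")


@dataclass
class World:
    """A generated world plus its pre-noise ground truth."""

    spec: WorldSpec
    domain_map: ProteinDomainMap
    directed: DirectedPairSet
    truth: Dict[Tuple[str, str], Tuple[str, str]]  # pair key -> (true up, true down)
    n_no_rule: int = 0
    n_ambiguous: int = 0
    n_flipped: int = 0


def _domain_names(n: int) -> List[str]:
    return [f"PF{i:05d}" for i in range(1, n + 1)]


def generate_world(spec: WorldSpec) -> World:
    """Sample proteins and directed pairs under the planted rule set.

    Candidate unordered pairs are sampled without replacement (up to 10x
    ``n_pairs``); for each, a coin decides which orientation is tested
    first, and the highest-priority rule matching that orientation fixes
    the true direction. Pairs matching no rule in either orientation carry
    no direction, and pairs matching in both orientations are ambiguous
    under the planted law; both kinds are discarded and counted. The
    recorded direction is then flipped with probability ``noise``.
    """
    rng = np.random.default_rng(spec.seed)
    universe = _domain_names(spec.n_domains)
    unknown = set(spec.signal_probs) - set(universe)
    if unknown:
        raise ValueError(f"signal_probs refer to domains outside the universe: {sorted(unknown)}")
    background = [d for d in universe if d not in spec.signal_probs]
    lo, hi = spec.domains_per_protein
    if hi > len(background):
        raise ValueError("domains_per_protein range exceeds the background pool")

    proteins = [f"P{i:04d}" for i in range(1, spec.n_proteins + 1)]
    entries: Dict[str, FrozenSet[str]] = {}
    signal_items = sorted(spec.signal_probs.items())
    for name in proteins:
        k = int(rng.integers(lo, hi + 1))
        doms = set(np.array(background)[rng.choice(len(background), size=k, replace=False)]) if k else set()
        for d, p in signal_items:
            if rng.random() < p:
                doms.add(d)
        entries[name] = frozenset(doms)
    domain_map = ProteinDomainMap(entries=entries)

    n_possible = spec.n_proteins * (spec.n_proteins - 1) // 2
    n_candidates = min(10 * spec.n_pairs, n_possible)
    seen: set = set()
    candidates: List[Tuple[str, str]] = []
    while len(candidates) < n_candidates:
        i, j = rng.integers(0, spec.n_proteins, size=2)
        if i == j:
            continue
        key = (int(min(i, j)), int(max(i, j)))
        if key in seen:
            continue
        seen.add(key)
        candidates.append((proteins[key[0]], proteins[key[1]]))

    by_priority = sorted(spec.rules, key=lambda r: -r.priority)
    directed: List[Tuple[str, str, Optional[str]]] = []
    truth: Dict[Tuple[str, str], Tuple[str, str]] = {}
    n_no_rule = n_ambiguous = n_flipped = 0
    for a, b in candidates:
        if len(directed) >= spec.n_pairs:
            break
        first, second = (a, b) if rng.random() < 0.5 else (b, a)
        p_first = _best_priority(by_priority, domain_map.domains(first), domain_map.domains(second))
        p_second = _best_priority(by_priority, domain_map.domains(second), domain_map.domains(first))
        if p_first is None and p_second is None:
            n_no_rule += 1
            continue
        if p_first is not None and p_second is not None:
            # both orientations satisfy the law: no directional information
            n_ambiguous += 1
            continue
        up, down = (first, second) if p_first is not None else (second, first)
        truth[(min(up, down), max(up, down))] = (up, down)
        if spec.noise > 0 and rng.random() < spec.noise:
            up, down = down, up
            n_flipped += 1
        directed.append((up, down, None))

    if len(directed) < spec.n_pairs:
        raise RuntimeError(
            f"rule set unsatisfiable at this domain density: "
            f"{len(directed)}/{spec.n_pairs} directed pairs found in {n_candidates} candidates"
        )
    return World(
        spec=spec,
        domain_map=domain_map,
        directed=DirectedPairSet(pairs=directed),
        truth=truth,
        n_no_rule=n_no_rule,
        n_ambiguous=n_ambiguous,
        n_flipped=n_flipped,
    )


def _best_priority(rules_desc, up_doms, down_doms) -> Optional[int]:
    for rule in rules_desc:  # sorted by descending priority
        if rule.matches(up_doms, down_doms):
            return rule.priority
    return None


# Signal domains of the presets: two "up-regulating" accessions and one
# "down-regulated" accession, by convention the first three of the universe.
UP1, UP2, DOWN1 = "PF00001", "PF00002", "PF00003"


def single_rule_world(seed: int, n_pairs: int = 400, noise: float = 0.0) -> World:
    """Preset: one linear law — upstream carries UP1, downstream carries DOWN1.

    Signal domains occur in ~45% of proteins so that enough candidate pairs
    match; any per-domain statistic separates the two sides, making this the
    easy, linearly-structured benchmark.
    """
    spec = WorldSpec(
        n_domains=22,
        n_proteins=250,
        domains_per_protein=(2, 4),
        rules=(DirectionRule(up_required=frozenset({UP1}), down_required=frozenset({DOWN1}), priority=0),),
        n_pairs=n_pairs,
        noise=noise,
        seed=seed,
        signal_probs={UP1: 0.45, DOWN1: 0.45},
    )
    return generate_world(spec)


def nonlinear_world(seed: int, n_pairs: int = 400, noise: float = 0.05) -> World:
    """Preset: a non-additive law over two up-regulating and one down-regulated domain.

    The orientation (X, Y) is upstream exactly when an odd number of
    {UP1 in X, UP2 in X, DOWN1 in Y} holds — four mutually exclusive
    conjunctive branches, one of which is the textbook pattern "X carries
    both up-regulating domains and Y carries the down-regulated domain".
    With each signal domain present in half the proteins, every single
    domain occurs equally often on the upstream and downstream side, so no
    per-domain frequency statistic separates the directions; only the
    combination does. The background is kept sparse (at most two background
    domains per protein) so the law remains recoverable from 400 pairs;
    proteins that happen to carry no domain at all degenerate to null
    vectors downstream, exercising the null-filtering path.
    """
    rules = (
        DirectionRule(
            up_required=frozenset({UP1, UP2}), down_required=frozenset({DOWN1}), priority=3
        ),
        DirectionRule(
            up_required=frozenset({UP1}), up_forbidden=frozenset({UP2}),
            down_forbidden=frozenset({DOWN1}), priority=2,
        ),
        DirectionRule(
            up_required=frozenset({UP2}), up_forbidden=frozenset({UP1}),
            down_forbidden=frozenset({DOWN1}), priority=1,
        ),
        DirectionRule(
            up_forbidden=frozenset({UP1, UP2}), down_required=frozenset({DOWN1}), priority=0
        ),
    )
    spec = WorldSpec(
        n_domains=12,
        n_proteins=300,
        domains_per_protein=(0, 2),
        rules=rules,
        n_pairs=n_pairs,
        noise=noise,
        seed=seed,
        signal_probs={UP1: 0.5, UP2: 0.5, DOWN1: 0.5},
    )
    return generate_world(spec)


def write_world(world: World, out_dir) -> Dict[str, Path]:
    """Write the world as the standard TSV inputs plus a truth table.

    Emits ``domains.tsv`` (protein -> domain list), ``directed_pairs.tsv``
    (the noisy recorded directions, i.e. what a curated database would
    contain) and ``truth_pairs.tsv`` (the pre-noise directions, for
    evaluation only). Files are byte-deterministic given the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "domains": out_dir / "domains.tsv",
        "directed": out_dir / "directed_pairs.tsv",
        "truth": out_dir / "truth_pairs.tsv",
    }
    write_domain_map(world.domain_map, paths["domains"])
    write_directed_pairs(world.directed, paths["directed"])
    truth_set = DirectedPairSet(pairs=[(up, down, None) for up, down in
                                       (world.truth[k] for k in sorted(world.truth))])
    write_directed_pairs(truth_set, paths["truth"])
    return paths
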