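import pytest

from signflow.data_io import DirectedPairSet, ProteinDomainMap
from signflow.features import DomainVocabulary, FeatureInstance, PairBag, build_vocabulary


@pytest.fixture
def toy_domain_map() -> ProteinDomainMap:
    return ProteinDomainMap(
        entries={
            "P1": frozenset({"d1", "d2"}),
            "P2": frozenset({"d2", "d3"}),
            "P3": frozenset({"d1"}),
            "P4": frozenset(),
            "P5": frozenset({"zz"}),  # annotated, but outside any training vocabulary
        }
    )


@pytest.fixture
def toy_vocab() -> DomainVocabulary:
    return DomainVocabulary(domains=("d1", "d2", "d3", "d4"))


def make_bag(a="A", b="B", score_fwd=None, score_rev=None, call=None, true_upstream=None):
    """Minimal hand-built bag for I/O and metric tests."""
    fwd = FeatureInstance(up=a, down=b, values={0: 1})
    rev = FeatureInstance(up=b, down=a, values={0: -1})
    return PairBag(
        a=a, b=b, fwd=fwd, rev=rev,
        score_fwd=score_fwd, score_rev=score_rev, call=call, true_upstream=true_upstream,
    )


@pytest.fixture(scope="session")
def linear_world_cv():
    """Shared single-rule world (seed 7) with vocabulary and labeled bags."""
    from signflow.features import build_training_bags
    from signflow.synthetic import single_rule_world

    world = single_rule_world(seed=7, n_pairs=400, noise=0.0)
    vocab = build_vocabulary(world.domain_map, world.directed)
    bags, dropped = build_training_bags(world.directed, world.domain_map, vocab)
    return world, vocab, bags, dropped
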