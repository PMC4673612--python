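import numpy as np
import pytest

from signflow.classifier import HyperParams, train
from signflow.data_io import DirectedPairSet, UndirectedPairSet
from signflow.decision import DecisionPolicy, DirectionCall, fuse
from signflow.evaluation import (
    ExperimentConfig,
    FrequencyBaseline,
    cross_validate,
    independent_test,
    instance_cv_accuracy,
    make_folds,
    predict_network,
    single_domain_baseline,
)
from signflow.features import build_training_bags, build_vocabulary
from signflow.synthetic import single_rule_world

POLICY = DecisionPolicy(epsilon=0.1)
SMALL_CONFIG = dict(C_grid=(8.0,), gamma_grid=(0.5,))


@pytest.fixture(scope="module")
def small_world():
    world = single_rule_world(seed=13, n_pairs=80)
    vocab = build_vocabulary(world.domain_map, world.directed)
    bags, dropped = build_training_bags(world.directed, world.domain_map, vocab)
    return world, vocab, bags, dropped


class TestMakeFolds:
    def test_round_robin_sizes(self, small_world):
        _, _, bags, _ = small_world
        plan = make_folds(bags[:40], k=20, seed=0)
        sizes = np.bincount([plan.fold_of(b) for b in bags[:40]], minlength=20)
        assert sizes.tolist() == [2] * 20

    def test_same_seed_same_plan(self, small_world):
        _, _, bags, _ = small_world
        assert make_folds(bags, 5, seed=3) == make_folds(bags, 5, seed=3)
        assert make_folds(bags, 5, seed=3) != make_folds(bags, 5, seed=4)

    def test_no_pair_split_across_folds(self, small_world):
        _, _, bags, _ = small_world
        plan = make_folds(bags, k=7, seed=1)
        for bag in bags:
            assert plan.fold_of(bag) == plan.assignment[bag.pair_key]

    def test_fold_sizes_differ_by_at_most_one(self, small_world):
        _, _, bags, _ = small_world
        plan = make_folds(bags, k=7, seed=1)
        sizes = np.bincount([plan.fold_of(b) for b in bags], minlength=7)
        assert sizes.max() - sizes.min() <= 1

    def test_k_larger_than_pairs_fatal(self, small_world):
        _, _, bags, _ = small_world
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(bags[:5], k=6, seed=0)


class TestCrossValidate:
    def test_out_of_fold_instance_count(self, small_world):
        _, vocab, bags, dropped = small_world
        config = ExperimentConfig(k=5, seed=0, **SMALL_CONFIG)
        report = cross_validate(bags, vocab, config, n_dropped_null=dropped)
        assert report.n_instances == 2 * len(bags)
        assert report.n_pairs == len(bags)

    def test_deterministic_end_to_end(self, small_world):
        _, vocab, bags, _ = small_world
        config = ExperimentConfig(k=5, seed=2, **SMALL_CONFIG)
        r1 = cross_validate(bags, vocab, config)
        r2 = cross_validate(bags, vocab, config)
        assert r1.to_dict() == r2.to_dict()

    def test_leave_one_pair_out_boundary(self):
        world = single_rule_world(seed=17, n_pairs=12)
        vocab = build_vocabulary(world.domain_map, world.directed)
        bags, _ = build_training_bags(world.directed, world.domain_map, vocab)
        config = ExperimentConfig(k=len(bags), seed=0, **SMALL_CONFIG)
        report = cross_validate(bags, vocab, config)
        assert report.n_pairs == len(bags)

    def test_random_labels_give_chance_auc(self):
        """Fully noisy directions are unlearnable: AUC hovers around 0.5."""
        aucs = []
        for seed in range(5):
            world = single_rule_world(seed=400 + seed, n_pairs=150, noise=0.5)
            vocab = build_vocabulary(world.domain_map, world.directed)
            bags, _ = build_training_bags(world.directed, world.domain_map, vocab)
            config = ExperimentConfig(k=5, seed=seed, **SMALL_CONFIG)
            aucs.append(cross_validate(bags, vocab, config).auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.05


class TestIndependentTest:
    def _split(self, n_train=120, n_test=40, seed=19):
        world = single_rule_world(seed=seed, n_pairs=n_train + n_test)
        train_pairs = DirectedPairSet(pairs=world.directed.pairs[:n_train])
        test_pairs = DirectedPairSet(pairs=world.directed.pairs[n_train:])
        return world, train_pairs, test_pairs

    def _fit(self, world, train_pairs):
        vocab = build_vocabulary(world.domain_map, train_pairs)
        bags, _ = build_training_bags(train_pairs, world.domain_map, vocab)
        instances = [b.fwd for b in bags] + [b.rev for b in bags]
        return train(instances, HyperParams(C=8, gamma=0.5), vocab)

    def test_generalizes_within_one_world(self):
        world, train_pairs, test_pairs = self._split()
        model = self._fit(world, train_pairs)
        report = independent_test(model, test_pairs, world.domain_map, POLICY)
        assert report.macro_accuracy >= 0.9
        assert report.n_pairs + report.n_dropped_null == len(test_pairs)

    def test_overlap_with_training_fatal(self):
        world, train_pairs, test_pairs = self._split()
        model = self._fit(world, train_pairs)
        contaminated = DirectedPairSet(pairs=test_pairs.pairs + train_pairs.pairs[:1])
        with pytest.raises(ValueError, match="overlap"):
            independent_test(model, contaminated, world.domain_map, POLICY)

    def test_unencodable_test_pairs_counted_as_dropped(self):
        world, train_pairs, test_pairs = self._split()
        model = self._fit(world, train_pairs)
        # a pair of proteins the training vocabulary knows nothing about
        world.domain_map.entries["X1"] = frozenset({"ALIEN1"})
        world.domain_map.entries["X2"] = frozenset({"ALIEN2"})
        extended = DirectedPairSet(pairs=test_pairs.pairs + [("X1", "X2", None)])
        report = independent_test(model, extended, world.domain_map, POLICY)
        assert report.n_dropped_null >= 1


class TestPredictNetwork:
    def test_calls_match_fuse_of_scores(self, small_world):
        world, vocab, bags, _ = small_world
        model = train([b.fwd for b in bags] + [b.rev for b in bags], HyperParams(C=8, gamma=0.5), vocab)
        undirected = UndirectedPairSet(pairs=[("P0001", "P0002"), ("P0003", "P0010")])
        called, dropped, skipped = predict_network(
            model, undirected, world.domain_map, POLICY, allow_train_overlap=True
        )
        for bag in called:
            assert (bag.a, bag.b) == (min(bag.a, bag.b), max(bag.a, bag.b))
            assert bag.call is fuse(bag.score_fwd, bag.score_rev, POLICY)

    def test_training_pairs_skipped_unless_allowed(self, small_world):
        world, vocab, bags, _ = small_world
        model = train([b.fwd for b in bags] + [b.rev for b in bags], HyperParams(C=8, gamma=0.5), vocab)
        first = bags[0]
        undirected = UndirectedPairSet(pairs=[first.pair_key])
        called, _, skipped = predict_network(model, undirected, world.domain_map, POLICY)
        assert skipped == 1 and not called
        called, _, skipped = predict_network(
            model, undirected, world.domain_map, POLICY, allow_train_overlap=True
        )
        assert skipped == 0 and len(called) == 1

    def test_empty_input_empty_output(self, small_world):
        world, vocab, bags, _ = small_world
        model = train([b.fwd for b in bags] + [b.rev for b in bags], HyperParams(C=8, gamma=0.5), vocab)
        called, dropped, skipped = predict_network(model, UndirectedPairSet(), world.domain_map, POLICY)
        assert called == [] and dropped == 0 and skipped == 0


class TestBaseline:
    def test_learns_single_domain_rule(self, small_world):
        """On a linear world the per-domain odds baseline is clearly above chance.

        It does not approach 1.0 even at zero noise: background domains in the
        symmetric difference cast random-sign votes that dilute the two
        informative ones — exactly the weakness of per-domain statistics.
        """
        world, _, bags, _ = small_world
        acc = single_domain_baseline(bags, world.domain_map, k=5, seed=0)
        assert acc >= 0.65

    def test_predict_returns_undetermined_on_tie(self):
        baseline = FrequencyBaseline(log_odds={})
        from signflow.data_io import ProteinDomainMap

        dm = ProteinDomainMap(entries={"A": frozenset({"d1"}), "B": frozenset({"d2"})})
        assert baseline.predict("A", "B", dm) is DirectionCall.UNDETERMINED


class TestInstanceCv:
    def test_grouped_and_ungrouped_run(self, small_world):
        _, vocab, bags, _ = small_world
        hp = HyperParams(C=8, gamma=0.5)
        g = instance_cv_accuracy(bags, vocab, hp, k=5, seed=0, grouped=True)
        u = instance_cv_accuracy(bags, vocab, hp, k=5, seed=0, grouped=False)
        assert 0.0 <= g <= 1.0 and 0.0 <= u <= 1.0
        # noise-free linear world: both near-perfect
        assert g >= 0.9
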