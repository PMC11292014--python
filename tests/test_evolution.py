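import numpy as np
import pytest

from reha.evolution import (
    EvolutionConfig,
    Individual,
    crossover_trees,
    evaluate_fitness,
    initialize_population,
    mutate_individual,
    run_evolution,
    select_parents,
    tree_fitness,
)
from reha.io_model import ValidationError
from reha.rxa_core import MultiTest, PairTest, ProteinRanking
from reha.synthetic import CohortConfig, generate_cohort
from reha.tree import InternalNode, Leaf, RehaTree, _depth, serialize_tree, tree_summary

from .conftest import make_labels, make_matrix, random_dataset, random_tree

CLASSES = ("A", "B")
FAST = dict(population_size=10, max_generations=15, stall_generations=5,
            candidate_pool_size=20, max_surrogates=2, relief_k=2)


def planted_dataset(seed=0, n_proteins=12, n_per_class=8, noise=0.0):
    """P0/P1 form a perfect order reversal between classes; rest is noise."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.normal(20, 2, size=(n_proteins, n))
    values[0] = np.r_[np.full(n_per_class, 10.0), np.full(n_per_class, 12.0)]
    values[1] = 11.0
    values += rng.normal(0, noise, size=values.shape)
    m = make_matrix(values)
    y = make_labels(m.sample_ids, [0] * n_per_class + [1] * n_per_class, CLASSES)
    return m, y


class TestEvaluateFitness:
    def test_single_leaf_accuracy_only(self, rng):
        m, y = random_dataset(rng, 4, 10)
        y = make_labels(m.sample_ids, [0] * 7 + [1] * 3, CLASSES)
        cfg = EvolutionConfig(w_acc=1.0, w_cons=0.0, w_rank=0.0, w_comp=0.0)
        ind = Individual(RehaTree(Leaf("A", {"A": 7, "B": 3}), CLASSES))
        assert evaluate_fitness(ind, m, y, None, cfg) == pytest.approx(0.7)

    def test_useless_node_penalized(self, rng):
        m, y = planted_dataset()
        cfg = EvolutionConfig(w_comp=0.02)
        flat = RehaTree(Leaf("A", {"A": 8, "B": 8}), CLASSES)
        # a node with both children predicting A changes no prediction
        node = InternalNode(MultiTest(PairTest("P2", "P3")),
                            Leaf("A", {"A": 4, "B": 4}), Leaf("A", {"A": 4, "B": 4}))
        deep = RehaTree(node, CLASSES)
        f_flat, _ = tree_fitness(flat, m, y, None, cfg)
        f_deep, _ = tree_fitness(deep, m, y, None, cfg)
        assert f_deep < f_flat

    def test_hand_computed_weighted_sum(self):
        values = np.array([
            [1, 1, 1, 3, 3, 3.0],   # reversal vs P1
            [2, 2, 2, 2, 2, 2.0],
            [5, 5, 5, 9, 9, 5.0],
            [9, 9, 9, 5, 5, 9.0],
        ])
        m = make_matrix(values)
        y = make_labels(m.sample_ids, [0, 0, 0, 1, 1, 1], CLASSES)
        ranking = ProteinRanking({"P0": 1.0, "P1": 0.5, "P2": 0.2, "P3": 0.0})
        mt = MultiTest(PairTest("P0", "P1"), [PairTest("P2", "P3")], [0.8], "left")
        t = RehaTree(InternalNode(mt, Leaf("A", {"A": 3, "B": 0}),
                                  Leaf("B", {"A": 0, "B": 3})), CLASSES)
        cfg = EvolutionConfig(w_acc=1.0, w_cons=0.1, w_rank=0.1, w_comp=0.02)
        F, comps = tree_fitness(t, m, y, ranking, cfg)
        # primary splits classes perfectly; surrogate P2<P3 votes
        # L,L,L,R,R,L.  Class-A samples: (L,L) -> left, all correct.
        # s3,s4: (R,R) -> right, correct.  s5: (R,L) 1-1 tie -> surrogate
        # vote alone -> left -> predicted A, truth B.  Accuracy 5/6.
        assert comps[0] == pytest.approx(5 / 6)
        assert comps[1] == pytest.approx(0.8)     # mean surrogate similarity
        assert comps[2] == pytest.approx((1.0 + 0.5 + 0.2 + 0.0) / 4)
        assert comps[3] == 1
        assert F == pytest.approx(1.0 * 5 / 6 + 0.1 * 0.8 + 0.1 * 0.425 - 0.02)


class TestInitializePopulation:
    def test_population_size_and_determinism(self):
        m, y = planted_dataset(noise=0.3)
        cfg = EvolutionConfig(seed=4, **FAST)
        ranking = None
        pop1 = initialize_population(m, y, ranking, cfg)
        pop2 = initialize_population(m, y, ranking, cfg)
        assert len(pop1) == cfg.population_size
        assert ([serialize_tree(i.tree) for i in pop1]
                == [serialize_tree(i.tree) for i in pop2])

    def test_noiseless_planted_pair_appears_in_initial_roots(self):
        # root splits are drawn uniformly from the 10 best pairs at the root,
        # so the perfect planted pair shows up in a sizeable population
        m, y = planted_dataset(noise=0.0)
        cfg = EvolutionConfig(seed=1, population_size=40, max_generations=5,
                              stall_generations=3, candidate_pool_size=12, relief_k=2)
        pop = initialize_population(m, y, None, cfg)
        hits = sum(
            1 for ind in pop
            if isinstance(ind.tree.root, InternalNode)
            and ind.tree.root.test.primary.proteins == frozenset({"P0", "P1"})
        )
        assert hits >= 1
        from reha.tree import _depth

        assert all(_depth(ind.tree.root) <= cfg.max_depth for ind in pop)

    def test_single_class_rejected(self, rng):
        m, _ = random_dataset(rng, 4, 6)
        y = make_labels(m.sample_ids, [0] * 6, CLASSES)
        with pytest.raises(ValidationError):
            initialize_population(m, y, None, EvolutionConfig(**FAST))


class TestSelectParents:
    def _pop(self, n):
        return [Individual(RehaTree(Leaf("A", {"A": 1}), CLASSES), fitness=float(i))
                for i in range(n)]

    def test_pressure_one_is_uniform(self):
        pop = self._pop(4)
        cfg = EvolutionConfig(population_size=4, selection_pressure=1.0, elitism_count=0)
        rng = np.random.default_rng(0)
        draws = [select_parents(pop, cfg, rng) for _ in range(2000)]
        flat = [ind.fitness for batch in draws for ind in batch]
        counts = np.bincount(np.array(flat, dtype=int), minlength=4)
        assert counts.min() > 0.8 * counts.max()

    def test_pressure_two_n_two_always_best(self):
        pop = self._pop(2)
        cfg = EvolutionConfig(population_size=2, selection_pressure=2.0, elitism_count=0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            for chosen in select_parents(pop, cfg, rng):
                assert chosen.fitness == 1.0

    def test_empirical_frequencies_match_formula(self):
        n, s = 5, 1.8
        pop = self._pop(n)
        cfg = EvolutionConfig(population_size=n + 1, selection_pressure=s, elitism_count=1)
        rng = np.random.default_rng(42)
        total = 100_000
        got = np.zeros(n)
        draws = 0
        while draws < total:
            for ind in select_parents(pop, cfg, rng):
                got[int(ind.fitness)] += 1
                draws += 1
        p_expected = np.array([(2 - s) / n + 2 * r * (s - 1) / (n * (n - 1))
                               for r in range(n)])
        freq = got / got.sum()
        sigma = np.sqrt(p_expected * (1 - p_expected) / got.sum())
        assert np.all(np.abs(freq - p_expected) < 3 * sigma + 1e-9)


class TestCrossover:
    def test_two_leaves_swap(self, rng):
        a = Individual(RehaTree(Leaf("A", {"A": 2}), CLASSES))
        b = Individual(RehaTree(Leaf("B", {"B": 3}), CLASSES))
        o1, o2 = crossover_trees(a, b, rng)
        assert o1.tree.root.label == "B" and o2.tree.root.label == "A"

    def test_self_crossover_preserves_predictions(self, rng):
        from reha.tree import predict_matrix

        m, _ = random_dataset(rng, 8, 10)
        t = random_tree(m.protein_ids, CLASSES, rng)
        ind = Individual(t)
        o1, o2 = crossover_trees(ind, ind, rng)
        assert predict_matrix(o1.tree, m) == predict_matrix(t, m)
        assert predict_matrix(o2.tree, m) == predict_matrix(t, m)

    def test_offspring_satisfy_invariants(self, rng):
        pids = [f"P{i}" for i in range(8)]
        for _ in range(200):
            a = Individual(random_tree(pids, CLASSES, rng))
            b = Individual(random_tree(pids, CLASSES, rng))
            o1, o2 = crossover_trees(a, b, rng)
            for o in (o1, o2):
                assert _depth(o.tree.root) <= o.tree.max_depth
                for leaf_counts in _leaf_count_sums(o.tree.root):
                    assert leaf_counts >= 1
            # parents untouched
            assert serialize_tree(a.tree) and serialize_tree(b.tree)


def _leaf_count_sums(node):
    if isinstance(node, Leaf):
        yield sum(node.counts.values())
    else:
        yield from _leaf_count_sums(node.left)
        yield from _leaf_count_sums(node.right)


class TestMutation:
    def test_zero_probability_is_identity(self, rng):
        m, y = planted_dataset(noise=0.5)
        cfg = EvolutionConfig(mutation_prob=0.0, **FAST)
        pop = initialize_population(m, y, None, cfg)
        ind = pop[0]
        out = mutate_individual(ind, m, y, None, cfg, np.random.default_rng(0))
        assert serialize_tree(out.tree) == serialize_tree(ind.tree)

    def test_many_mutations_keep_invariants(self):
        m, y = planted_dataset(noise=0.5)
        cfg = EvolutionConfig(mutation_prob=0.5, seed=3, **FAST)
        pop = initialize_population(m, y, None, cfg)
        rng = np.random.default_rng(7)
        ind = pop[0]
        structures = set()
        for _ in range(150):
            ind = mutate_individual(ind, m, y, None, cfg, rng)
            assert _depth(ind.tree.root) <= cfg.max_depth
            assert all(c >= 1 for c in _leaf_count_sums(ind.tree.root))
            structures.add(tree_summary(ind.tree).n_internal_nodes)
        assert len(structures) > 1  # structural operators actually fire


class TestRunEvolution:
    def test_noiseless_planted_pair_reaches_perfect_training_accuracy(self):
        m, y = planted_dataset(noise=0.0)
        cfg = EvolutionConfig(seed=5, **FAST)
        ind = run_evolution(m, y, cfg)
        assert ind.fitness_components[0] == 1.0

    def test_determinism_same_seed_identical_trees(self):
        m, y = planted_dataset(noise=0.5, seed=2)
        cfg = EvolutionConfig(seed=9, **FAST)
        a = run_evolution(m, y, cfg)
        b = run_evolution(m, y, cfg)
        assert serialize_tree(a.tree) == serialize_tree(b.tree)
        assert a.fitness == b.fitness

    def test_elitism_makes_best_fitness_monotone(self):
        m, y = planted_dataset(noise=1.0, seed=3)
        cfg = EvolutionConfig(seed=11, **FAST)
        _, history = run_evolution(m, y, cfg, return_history=True)
        assert all(b >= a - 1e-12 for a, b in zip(history, history[1:]))

    def test_population_invariants_via_small_cohort(self):
        cfg = CohortConfig(group_sizes=(8, 8), class_names=("NG", "PD"),
                           n_proteins=40, n_de_proteins=4, n_reversal_pairs=1,
                           reversal_gap=2.0, residual_sd=0.4, seed=21)
        m, y, _, truth = generate_cohort(cfg)
        ecfg = EvolutionConfig(seed=2, **FAST)
        ind = run_evolution(m, y, ecfg)
        # strong planted signal: training accuracy well above majority rate
        assert ind.fitness_components[0] > 0.75
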