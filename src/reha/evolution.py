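"""Evolutionary induction of relative-expression trees.

A generational evolutionary algorithm searches the space of multi-test trees:
individuals are initialized greedily on bootstrap resamples, propagated by
linear-ranking selection with elitism, recombined by subtree crossover, and
varied by a two-level mutation (structural edits of the tree, and intra-node
edits of a multi-test cluster).  Fitness is a scalarized multi-objective
score: training accuracy, cluster consistency (mean surrogate similarity),
mean discrimination rank of the proteins used, minus a complexity penalty per
internal node.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .io_model import ExpressionMatrix, SampleLabels, ValidationError
from .rxa_core import (
    MultiTest,
    PairTest,
    ProteinRanking,
    _rank_matrix,
    relief_f_rank,
)
from .tree import (
    InternalNode,
    Leaf,
    RehaTree,
    _depth,
    _iter_internal,
    _majority_leaf,
    prune_tree,
    tree_summary,
)


@dataclass
class EvolutionConfig:
    """Hyperparameters of the evolutionary search.

    The fitness weights trade off accuracy (``w_acc``), cluster consistency
    (``w_cons``), protein discrimination rank (``w_rank``) and a complexity
    penalty per internal node (``w_comp``).
    """

    population_size: int = 64
    max_generations: int = 200
    stall_generations: int = 30
    elitism_count: int = 1
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    selection_pressure: float = 1.8
    seed: int = 0
    candidate_pool_size: int = 200
    max_surrogates: int = 3
    theta: float = 0.8
    w_acc: float = 1.0
    w_cons: float = 0.1
    w_rank: float = 0.1
    w_comp: float = 0.02
    max_depth: int = 4
    init_top_pairs: int = 10
    surrogate_candidates: int = 30
    min_node_samples: int = 5
    purity_stop: float = 0.95
    relief_k: int = 10

    def __post_init__(self):
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if not (0 <= self.elitism_count < self.population_size):
            raise ValidationError("elitism_count must be < population_size")
        for name in ("crossover_prob", "mutation_prob", "theta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0,1]")
        if not (1.0 <= self.selection_pressure <= 2.0):
            raise ValidationError("selection_pressure must lie in [1,2]")


@dataclass
class Individual:
    """A candidate tree with its scalarized fitness and components."""

    tree: RehaTree
    fitness: float | None = None
    fitness_components: tuple | None = None


def tree_fitness(tree: RehaTree, m: ExpressionMatrix, y: SampleLabels,
                 ranking: ProteinRanking | None, cfg: EvolutionConfig):
    """Scalarized fitness of a tree on training data.

    Returns ``(F, (accuracy, consistency, rank_score, n_internal))``.
    """
    from .tree import training_accuracy

    acc = training_accuracy(tree, m, y)
    internal = list(_iter_internal(tree.root))
    if internal:
        cons = float(np.mean([
            np.mean(n.test.similarities) if n.test.similarities else 1.0
            for n in internal
        ]))
    else:
        cons = 1.0
    proteins = tree_summary(tree).distinct_proteins
    if proteins and ranking is not None:
        rank_score = float(np.mean([ranking.weight(p) for p in proteins]))
    else:
        rank_score = 0.0
    n_internal = len(internal)
    F = (cfg.w_acc * acc + cfg.w_cons * cons + cfg.w_rank * rank_score
         - cfg.w_comp * n_internal)
    return F, (acc, cons, rank_score, n_internal)


def evaluate_fitness(ind: Individual, m: ExpressionMatrix, y: SampleLabels,
                     ranking: ProteinRanking | None, cfg: EvolutionConfig) -> float:
    """Evaluate and store the fitness of an individual; returns F."""
    F, comps = tree_fitness(ind.tree, m, y, ranking, cfg)
    ind.fitness = F
    ind.fitness_components = comps
    return F


# ---------------------------------------------------------------------------
# vectorized search engine


class _Engine:
    """Vectorized pair scoring / tree operations over a fixed training matrix.

    The candidate pool is the top-K proteins by discrimination rank; all
    unordered pool pairs are pre-evaluated (order and tie indicators per
    sample) so that per-node top-pair search and surrogate similarity reduce
    to boolean column reductions.
    """

    def __init__(self, m: ExpressionMatrix, y: SampleLabels, cfg: EvolutionConfig,
                 ranking: ProteinRanking | None):
        if len(y.classes) != 2:
            raise ValidationError("evolution requires a binary task")
        self.m = m
        self.classes = y.classes
        self.cfg = cfg
        self.ranking = ranking
        self.yv = y.y(m.sample_ids)
        if len(set(self.yv)) < 2:
            raise ValidationError("training data must contain both classes")
        self.values = m.values
        self.mask = m.missing_mask
        self.ranks = _rank_matrix(m.values)
        self.pidx = {p: i for i, p in enumerate(m.protein_ids)}
        if ranking is not None:
            pool = ranking.top(cfg.candidate_pool_size)
        else:
            pool = sorted(m.protein_ids)[: cfg.candidate_pool_size]
        self.pool = pool
        pool_rows = np.array([self.pidx[p] for p in pool])
        ii, jj = np.triu_indices(len(pool), k=1)
        self.ai, self.bi = pool_rows[ii], pool_rows[jj]
        self.pair_names = [(pool[i], pool[j]) for i, j in zip(ii, jj)]
        va, vb = self.values[self.ai], self.values[self.bi]
        self.valid = ~(self.mask[self.ai] | self.mask[self.bi])
        with np.errstate(invalid="ignore"):
            self.less = np.where(self.valid, va < vb, False)
            self.eq = np.where(self.valid, va == vb, False)
        self.gap = np.where(
            self.valid, (self.ranks[self.bi] - self.ranks[self.ai]), np.nan
        ).astype(np.float32)

    # -- pair search -------------------------------------------------------

    def top_pairs(self, cols: np.ndarray, top_n: int):
        """Best pairs on the given sample columns, canonically oriented.

        Returns a list of (pair_index, flip, PairTest, delta, gamma) sorted by
        (delta desc, gamma desc, stored pair index) — pairs for which one
        class has no co-measured sample are excluded.
        """
        yv = self.yv[cols]
        f = np.empty((2, len(self.ai)))
        g = np.empty((2, len(self.ai)))
        ok = np.ones(len(self.ai), dtype=bool)
        for c in (0, 1):
            cc = cols[yv == c]
            n_c = self.valid[:, cc].sum(axis=1)
            ok &= n_c > 0
            safe = np.maximum(n_c, 1)
            f[c] = self.less[:, cc].sum(axis=1) / safe
            g[c] = np.nansum(self.gap[:, cc], axis=1) / safe
        delta = np.abs(f[0] - f[1])
        flip = f[1] > f[0]
        gamma = np.where(flip, g[1] - g[0], g[0] - g[1])
        delta = np.where(ok, delta, -1.0)
        order = np.lexsort((np.arange(len(delta)), -gamma, -delta))
        out = []
        for k in order[: max(top_n, 0)]:
            if delta[k] < 0:
                break
            a, b = self.pair_names[k]
            pair = PairTest(b, a, True) if flip[k] else PairTest(a, b, True)
            out.append((int(k), bool(flip[k]), pair, float(delta[k]), float(gamma[k])))
        return out

    def _route_stored(self, k: int, flip: bool, cols: np.ndarray) -> np.ndarray:
        """Branch vector (+1 left / -1 right / 0 abstain) for a stored pair."""
        less, eq, valid = self.less[k, cols], self.eq[k, cols], self.valid[k, cols]
        holds = (~less & ~eq) if flip else less
        return np.where(valid, np.where(holds, 1, -1), 0)

    def build_multitest(self, primary_entry, candidates, cols: np.ndarray,
                        rng: np.random.Generator | None = None) -> MultiTest:
        """Surrogate selection among pre-scored candidate pairs at a node.

        When an ``rng`` is given the surrogate cap is drawn uniformly from
        0..max_surrogates, so the population explores cluster sizes from bare
        pairs to full multi-tests.
        """
        cfg = self.cfg
        cap = cfg.max_surrogates if rng is None else int(rng.integers(0, cfg.max_surrogates + 1))
        k0, flip0, primary, _, _ = primary_entry
        r0 = self._route_stored(k0, flip0, cols)
        chosen = []
        seen = {primary.proteins}
        for k, flipk, pair, delta, _ in candidates:
            if pair.proteins in seen or len(pair.proteins & primary.proteins) > 1:
                continue
            rk = self._route_stored(k, flipk, cols)
            both = (r0 != 0) & (rk != 0)
            sim = float((r0[both] == rk[both]).mean()) if both.any() else 0.0
            if sim >= cfg.theta:
                chosen.append((pair, sim, delta, k))
                seen.add(pair.proteins)
        chosen.sort(key=lambda t: (-t[1], -t[2], t[3]))
        chosen = chosen[:cap]
        yv = self.yv[cols]
        maj = 0 if (yv == 0).sum() >= (yv == 1).sum() else 1
        maj_routes = r0[(yv == maj) & (r0 != 0)]
        fallback = "left" if (maj_routes == 1).sum() >= (maj_routes == -1).sum() else "right"
        return MultiTest(
            primary=primary,
            surrogates=[c[0] for c in chosen],
            similarities=[c[1] for c in chosen],
            fallback_branch=fallback,
        )

    # -- routing / fitness -------------------------------------------------

    def route_multitest(self, mt: MultiTest, cols: np.ndarray) -> np.ndarray:
        """Vectorized majority-vote routing (+1 left / -1 right) of samples."""
        total = np.zeros(len(cols), dtype=int)
        surr = np.zeros(len(cols), dtype=int)
        for t_i, test in enumerate(mt.tests):
            ia, ib = self.pidx[test.protein_a], self.pidx[test.protein_b]
            va, vb = self.values[ia, cols], self.values[ib, cols]
            ok = ~(self.mask[ia, cols] | self.mask[ib, cols])
            with np.errstate(invalid="ignore"):
                holds = (va < vb) if test.direction else ~(va < vb)
            v = np.where(ok, np.where(holds, 1, -1), 0)
            total += v
            if t_i > 0:
                surr += v
        fb = 1 if mt.fallback_branch == "left" else -1
        tie = np.where(surr > 0, 1, np.where(surr < 0, -1, fb))
        return np.where(total > 0, 1, np.where(total < 0, -1, tie))

    def predict_codes(self, tree: RehaTree, cols: np.ndarray) -> np.ndarray:
        code = {c: i for i, c in enumerate(self.classes)}
        out = np.empty(len(cols), dtype=int)

        def walk(node, cols, pos):
            if isinstance(node, Leaf):
                out[pos] = code[node.label]
                return
            r = self.route_multitest(node.test, cols)
            left = r == 1
            walk(node.left, cols[left], pos[left])
            walk(node.right, cols[~left], pos[~left])

        walk(tree.root, cols, np.arange(len(cols)))
        return out

    def refit_counts(self, tree: RehaTree) -> RehaTree:
        """Recompute leaf counts/labels from the full training matrix."""

        def rebuild(node, cols):
            if isinstance(node, Leaf):
                counts = {c: int((self.yv[cols] == i).sum()) for i, c in enumerate(self.classes)}
                if sum(counts.values()) == 0:
                    return Leaf(node.label, {node.label: 1})
                label = max(self.classes, key=lambda c: (counts[c], -self.classes.index(c)))
                return Leaf(label, counts)
            r = self.route_multitest(node.test, cols)
            return InternalNode(node.test, rebuild(node.left, cols[r == 1]),
                                rebuild(node.right, cols[r != 1]))

        cols = np.arange(len(self.yv))
        return RehaTree(rebuild(tree.root, cols), self.classes, tree.max_depth)

    def fitness(self, tree: RehaTree):
        acc = float((self.predict_codes(tree, np.arange(len(self.yv))) == self.yv).mean())
        internal = list(_iter_internal(tree.root))
        cons = float(np.mean([
            np.mean(n.test.similarities) if n.test.similarities else 1.0 for n in internal
        ])) if internal else 1.0
        proteins = set()
        for n in internal:
            proteins |= n.test.proteins
        if proteins and self.ranking is not None:
            rank_score = float(np.mean([self.ranking.weight(p) for p in proteins]))
        else:
            rank_score = 0.0
        cfg = self.cfg
        F = (cfg.w_acc * acc + cfg.w_cons * cons + cfg.w_rank * rank_score
             - cfg.w_comp * len(internal))
        return F, (acc, cons, rank_score, len(internal))

    def make_individual(self, tree: RehaTree) -> Individual:
        tree = self.refit_counts(tree)
        F, comps = self.fitness(tree)
        return Individual(tree=tree, fitness=F, fitness_components=comps)

    # -- initialization ----------------------------------------------------

    def _leaf(self, cols: np.ndarray) -> Leaf:
        counts = {c: int((self.yv[cols] == i).sum()) for i, c in enumerate(self.classes)}
        if sum(counts.values()) == 0:
            counts = {self.classes[0]: 1}
        label = max(self.classes, key=lambda c: (counts[c], -self.classes.index(c)))
        return Leaf(label, counts)

    def grow(self, cols: np.ndarray, depth: int, rng: np.random.Generator):
        cfg = self.cfg
        counts = np.bincount(self.yv[cols], minlength=2)
        purity = counts.max() / max(counts.sum(), 1)
        if (depth >= cfg.max_depth or len(cols) < cfg.min_node_samples
                or purity >= cfg.purity_stop or counts.min() == 0):
            return self._leaf(cols)
        top = self.top_pairs(cols, max(cfg.init_top_pairs, cfg.surrogate_candidates))
        if not top:
            return self._leaf(cols)
        pick = int(rng.integers(0, min(cfg.init_top_pairs, len(top))))
        mt = self.build_multitest(top[pick], top[:cfg.surrogate_candidates], cols, rng)
        r = self.route_multitest(mt, cols)
        left_cols, right_cols = cols[r == 1], cols[r != 1]
        if len(left_cols) == 0 or len(right_cols) == 0:
            return self._leaf(cols)
        return InternalNode(mt, self.grow(left_cols, depth + 1, rng),
                            self.grow(right_cols, depth + 1, rng))

    def init_population(self, rng: np.random.Generator) -> list[Individual]:
        n = len(self.yv)
        pop = []
        for _ in range(self.cfg.population_size):
            # stratified bootstrap keeps both classes present
            cols = []
            for c in (0, 1):
                cc = np.flatnonzero(self.yv == c)
                cols.append(rng.choice(cc, size=len(cc), replace=True))
            cols = np.sort(np.concatenate(cols))
            tree = RehaTree(self.grow(cols, 0, rng), self.classes, self.cfg.max_depth)
            pop.append(self.make_individual(tree))
        return pop

    # -- mutation ----------------------------------------------------------

    def _node_cols(self, tree: RehaTree):
        """Training columns reaching each node, keyed by root path (L/R)."""
        out = {}

        def walk(node, cols, path):
            out[path] = cols
            if isinstance(node, InternalNode):
                r = self.route_multitest(node.test, cols)
                walk(node.left, cols[r == 1], path + "L")
                walk(node.right, cols[r != 1], path + "R")

        walk(tree.root, np.arange(len(self.yv)), "")
        return out

    def _replace_at(self, tree: RehaTree, path: str, subtree) -> RehaTree:
        def rebuild(node, remaining):
            if not remaining:
                return subtree
            if remaining[0] == "L":
                return InternalNode(node.test, rebuild(node.left, remaining[1:]), node.right)
            return InternalNode(node.test, node.left, rebuild(node.right, remaining[1:]))

        return RehaTree(rebuild(tree.root, path), tree.classes, tree.max_depth)

    def _fresh_multitest(self, cols, rng, forced_primary: PairTest | None = None):
        cfg = self.cfg
        top = self.top_pairs(cols, max(cfg.init_top_pairs, cfg.surrogate_candidates))
        if forced_primary is not None:
            name_to_k = {frozenset(nm): k for k, nm in enumerate(self.pair_names)}
            k = name_to_k.get(forced_primary.proteins)
            if k is None:
                return None
            a, b = self.pair_names[k]
            flip = not ((forced_primary.protein_a == a) == forced_primary.direction)
            entry = (k, flip, forced_primary, 0.0, 0.0)
            return self.build_multitest(entry, top[:cfg.surrogate_candidates], cols, rng)
        if not top:
            return None
        pick = int(rng.integers(0, min(cfg.init_top_pairs, len(top))))
        return self.build_multitest(top[pick], top[:cfg.surrogate_candidates], cols, rng)

    def mutate_tree(self, tree: RehaTree, rng: np.random.Generator) -> RehaTree:
        """Two-level mutation; each level fires with prob ``mutation_prob``."""
        cfg = self.cfg
        # level 1: structural
        if rng.random() < cfg.mutation_prob:
            op = rng.integers(0, 3)
            node_cols = self._node_cols(tree)
            internal_paths = [p for p, _ in _walk_paths(tree.root) if p in node_cols
                              and isinstance(_at(tree.root, p), InternalNode)]
            leaf_paths = [p for p, _ in _walk_paths(tree.root)
                          if isinstance(_at(tree.root, p), Leaf)]
            if op == 0 and internal_paths:  # replace a node's multitest
                path = internal_paths[int(rng.integers(0, len(internal_paths)))]
                cols = node_cols[path]
                if len(cols) >= 2 and len(set(self.yv[cols])) == 2:
                    mt = self._fresh_multitest(cols, rng)
                    if mt is not None:
                        node = _at(tree.root, path)
                        tree = self._replace_at(tree, path, InternalNode(mt, node.left, node.right))
            elif op == 1 and internal_paths:  # collapse a node to a leaf
                path = internal_paths[int(rng.integers(0, len(internal_paths)))]
                node = _at(tree.root, path)
                tree = self._replace_at(tree, path, _majority_leaf(node, tree.classes))
            elif op == 2 and leaf_paths:  # expand a leaf into a node
                path = leaf_paths[int(rng.integers(0, len(leaf_paths)))]
                cols = node_cols.get(path, np.array([], dtype=int))
                if (len(path) < cfg.max_depth and len(cols) >= cfg.min_node_samples
                        and len(set(self.yv[cols])) == 2):
                    mt = self._fresh_multitest(cols, rng)
                    if mt is not None:
                        r = self.route_multitest(mt, cols)
                        if (r == 1).any() and (r != 1).any():
                            node = InternalNode(mt, self._leaf(cols[r == 1]),
                                                self._leaf(cols[r != 1]))
                            tree = self._replace_at(tree, path, node)
        # level 2: intra-cluster
        if rng.random() < cfg.mutation_prob:
            node_cols = self._node_cols(tree)
            internal_paths = [p for p, _ in _walk_paths(tree.root)
                              if isinstance(_at(tree.root, p), InternalNode)]
            if internal_paths:
                path = internal_paths[int(rng.integers(0, len(internal_paths)))]
                node = _at(tree.root, path)
                cols = node_cols.get(path, np.arange(len(self.yv)))
                mt = self._mutate_multitest(node.test, cols, rng)
                if mt is not None:
                    tree = self._replace_at(tree, path, InternalNode(mt, node.left, node.right))
        return tree

    def _mutate_multitest(self, mt: MultiTest, cols, rng) -> MultiTest | None:
        cfg = self.cfg
        op = rng.integers(0, 3)
        if op == 0:  # swap one primary protein, weighted by discrimination rank
            keep_a = bool(rng.integers(0, 2))
            fixed = mt.primary.protein_a if keep_a else mt.primary.protein_b
            options = [p for p in self.pool if p != fixed]
            if not options:
                return None
            if self.ranking is not None:
                w = np.array([self.ranking.weight(p) for p in options]) + 1e-6
                w = w / w.sum()
                new_p = options[int(rng.choice(len(options), p=w))]
            else:
                new_p = options[int(rng.integers(0, len(options)))]
            primary = (PairTest(fixed, new_p, mt.primary.direction) if keep_a
                       else PairTest(new_p, fixed, mt.primary.direction))
            if len(cols) >= 2 and len(set(self.yv[cols])) == 2:
                fresh = self._fresh_multitest(cols, rng, forced_primary=primary)
                if fresh is not None:
                    return fresh
            return MultiTest(primary, [], [], mt.fallback_branch)
        if op == 1:  # add / remove / replace one surrogate
            sub = rng.integers(0, 3)
            if sub in (0, 2) and len(cols) >= 2 and len(set(self.yv[cols])) == 2:
                fresh = self._fresh_multitest(cols, rng, forced_primary=mt.primary)
                if fresh is not None and (sub == 2 or len(fresh.surrogates) > len(mt.surrogates)):
                    return fresh
            if mt.surrogates:  # remove
                i = int(rng.integers(0, len(mt.surrogates)))
                surr = [s for j, s in enumerate(mt.surrogates) if j != i]
                sims = [s for j, s in enumerate(mt.similarities) if j != i]
                return MultiTest(mt.primary, surr, sims, mt.fallback_branch)
            return None
        # op == 2: flip a test's direction
        tests = mt.tests
        i = int(rng.integers(0, len(tests)))
        flipped = replace(tests[i], direction=not tests[i].direction)
        if i == 0:
            return MultiTest(flipped, list(mt.surrogates), list(mt.similarities),
                             mt.fallback_branch)
        surr = list(mt.surrogates)
        surr[i - 1] = flipped
        return MultiTest(mt.primary, surr, list(mt.similarities), mt.fallback_branch)


def _walk_paths(root, path=""):
    yield path, root
    if isinstance(root, InternalNode):
        yield from _walk_paths(root.left, path + "L")
        yield from _walk_paths(root.right, path + "R")


def _at(root, path):
    node = root
    for step in path:
        node = node.left if step == "L" else node.right
    return node


# ---------------------------------------------------------------------------
# genetic operators (module surface)


def initialize_population(m: ExpressionMatrix, y: SampleLabels,
                          ranking: ProteinRanking | None,
                          cfg: EvolutionConfig) -> list[Individual]:
    """Greedy-stochastic initialization on stratified bootstrap resamples."""
    engine = _Engine(m, y, cfg, ranking)
    rng = np.random.default_rng(cfg.seed)
    return engine.init_population(rng)


def select_parents(pop: list[Individual], cfg: EvolutionConfig,
                   rng: np.random.Generator) -> list[Individual]:
    """Linear-ranking selection with replacement.

    With pressure s, the individual of rank r (0 = worst, n-1 = best) is drawn
    with probability (2-s)/n + 2 r (s-1) / (n (n-1)); elites are handled by
    the caller and bypass selection.
    """
    n = len(pop)
    if n == 0:
        raise ValidationError("empty population")
    if n == 1:
        return [pop[0]] * max(cfg.population_size - cfg.elitism_count, 1)
    order = sorted(range(n), key=lambda i: (pop[i].fitness, -i))  # worst first
    s = cfg.selection_pressure
    r = np.arange(n, dtype=float)
    p = (2 - s) / n + 2 * r * (s - 1) / (n * (n - 1))
    p = p / p.sum()
    n_draw = max(cfg.population_size - cfg.elitism_count, 1)
    picks = rng.choice(n, size=n_draw, replace=True, p=p)
    return [pop[order[i]] for i in picks]


def crossover_trees(p1: Individual, p2: Individual,
                    rng: np.random.Generator) -> tuple[Individual, Individual]:
    """Exchange uniformly chosen subtrees; repair depth by truncation.

    Identical parents use the same (homologous) crossover point, so
    self-crossover is an exact no-op.
    """
    t1, t2 = copy.deepcopy(p1.tree), copy.deepcopy(p2.tree)
    paths1 = [p for p, _ in _walk_paths(t1.root)]
    paths2 = [p for p, _ in _walk_paths(t2.root)]
    c1 = paths1[int(rng.integers(0, len(paths1)))]
    if t1 == t2:
        c2 = c1
    else:
        c2 = paths2[int(rng.integers(0, len(paths2)))]
    sub1 = copy.deepcopy(_at(t1.root, c1))
    sub2 = copy.deepcopy(_at(t2.root, c2))
    r1 = _graft(t1.root, c1, sub2)
    r2 = _graft(t2.root, c2, sub1)
    o1 = RehaTree(_truncate(r1, t1.max_depth, t1.classes), t1.classes, t1.max_depth)
    o2 = RehaTree(_truncate(r2, t2.max_depth, t2.classes), t2.classes, t2.max_depth)
    return Individual(o1), Individual(o2)


def _graft(root, path, subtree):
    if not path:
        return subtree
    if path[0] == "L":
        return InternalNode(root.test, _graft(root.left, path[1:], subtree), root.right)
    return InternalNode(root.test, root.left, _graft(root.right, path[1:], subtree))


def _truncate(node, budget, classes):
    """Replace internal nodes past the depth budget with majority leaves."""
    if isinstance(node, Leaf):
        return node
    if budget <= 0:
        return _majority_leaf(node, classes)
    return InternalNode(node.test, _truncate(node.left, budget - 1, classes),
                        _truncate(node.right, budget - 1, classes))


def mutate_individual(ind: Individual, m: ExpressionMatrix, y: SampleLabels,
                      ranking: ProteinRanking | None, cfg: EvolutionConfig,
                      rng: np.random.Generator) -> Individual:
    """Apply the two-level mutation and re-evaluate fitness."""
    engine = _Engine(m, y, cfg, ranking)
    tree = engine.mutate_tree(copy.deepcopy(ind.tree), rng)
    return engine.make_individual(tree)


# ---------------------------------------------------------------------------
# main loop


def run_evolution(m: ExpressionMatrix, y: SampleLabels, cfg: EvolutionConfig,
                  ranking: ProteinRanking | None = None,
                  return_history: bool = False):
    """Evolve a relative-expression tree on a binary task.

    Returns the best individual after pruning (and, optionally, the history
    of generation-best fitness values).  Deterministic given ``cfg.seed``.
    """
    if len(y.classes) != 2:
        raise ValidationError("run_evolution supports binary tasks only")
    if ranking is None:
        counts = np.bincount(y.y(m.sample_ids), minlength=2)
        k = max(1, min(cfg.relief_k, int(counts.min()) - 1))
        ranking = relief_f_rank(m, y, k_neighbors=k, seed=cfg.seed)
    engine = _Engine(m, y, cfg, ranking)
    rng = np.random.default_rng(cfg.seed)
    pop = engine.init_population(rng)
    history = []
    best = max(pop, key=lambda ind: ind.fitness)
    history.append(best.fitness)
    stall = 0
    for _gen in range(cfg.max_generations):
        pop_sorted = sorted(pop, key=lambda ind: -ind.fitness)
        elites = pop_sorted[: cfg.elitism_count]
        parents = select_parents(pop, cfg, rng)
        children: list[Individual] = []
        i = 0
        n_children = cfg.population_size - cfg.elitism_count
        while len(children) < n_children:
            p1 = parents[i % len(parents)]
            p2 = parents[(i + 1) % len(parents)]
            i += 2
            if rng.random() < cfg.crossover_prob:
                c1, c2 = crossover_trees(p1, p2, rng)
            else:
                c1, c2 = Individual(copy.deepcopy(p1.tree)), Individual(copy.deepcopy(p2.tree))
            for c in (c1, c2):
                if len(children) >= n_children:
                    break
                tree = engine.mutate_tree(c.tree, rng)
                children.append(engine.make_individual(tree))
        pop = elites + children
        gen_best = max(pop, key=lambda ind: ind.fitness)
        if gen_best.fitness > best.fitness + 1e-12:
            best = gen_best
            stall = 0
        else:
            stall += 1
        history.append(max(best.fitness, gen_best.fitness))
        if stall >= cfg.stall_generations:
            break
    pruned = prune_tree(best.tree, m, y, cfg, ranking)
    final = engine.make_individual(pruned)
    if return_history:
        return final, history
    return final
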