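"""Hierarchical relative-expression classifier trees.

Internal nodes hold multi-tests (primary + surrogate order pairs voting by
majority), leaves hold a class label with training class counts.  Trees
serialize losslessly to JSON and render to Graphviz DOT text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io_model import ExpressionMatrix, SampleLabels, ValidationError
from .rxa_core import MultiTest, PairTest, apply_multitest


@dataclass
class Leaf:
    label: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.counts and sum(self.counts.values()) < 1:
            raise ValidationError("leaf class counts must sum to >= 1")


@dataclass
class InternalNode:
    test: MultiTest
    left: "InternalNode | Leaf"
    right: "InternalNode | Leaf"


@dataclass
class RehaTree:
    """Binary-task decision tree over order-relation multi-tests."""

    root: InternalNode | Leaf
    classes: tuple[str, ...]
    max_depth: int = 4

    def __post_init__(self):
        self.classes = tuple(self.classes)
        if len(self.classes) != 2:
            raise ValidationError("trees support binary tasks only")
        if _depth(self.root) > self.max_depth:
            raise ValidationError(
                f"tree depth {_depth(self.root)} exceeds limit {self.max_depth}"
            )


@dataclass(frozen=True)
class TreeSummary:
    n_internal_nodes: int
    n_tests_total: int
    distinct_proteins: frozenset
    depth: int


def _depth(node) -> int:
    if isinstance(node, Leaf):
        return 0
    return 1 + max(_depth(node.left), _depth(node.right))


def _iter_internal(node):
    if isinstance(node, InternalNode):
        yield node
        yield from _iter_internal(node.left)
        yield from _iter_internal(node.right)


def _iter_leaves(node):
    if isinstance(node, Leaf):
        yield node
    else:
        yield from _iter_leaves(node.left)
        yield from _iter_leaves(node.right)


def tree_summary(t: RehaTree) -> TreeSummary:
    """Complexity accounting: node/test counts, protein set, depth."""
    internal = list(_iter_internal(t.root))
    proteins: set[str] = set()
    n_tests = 0
    for node in internal:
        n_tests += len(node.test.tests)
        proteins |= node.test.proteins
    return TreeSummary(
        n_internal_nodes=len(internal),
        n_tests_total=n_tests,
        distinct_proteins=frozenset(proteins),
        depth=_depth(t.root),
    )


# ---------------------------------------------------------------------------
# prediction


def _descend(node, sample, protein_index):
    while isinstance(node, InternalNode):
        branch = apply_multitest(node.test, sample, protein_index)
        node = node.left if branch == "left" else node.right
    return node


def predict_sample(t: RehaTree, sample, protein_index=None) -> str:
    """Class label for one sample (mapping id -> value, or vector + index)."""
    return _descend(t.root, sample, protein_index).label


def predict_proba_sample(t: RehaTree, sample, protein_index=None) -> tuple[float, float]:
    """Laplace-smoothed leaf class frequencies, (count_c + 1) / (n + 2)."""
    leaf = _descend(t.root, sample, protein_index)
    n = sum(leaf.counts.values())
    return tuple((leaf.counts.get(c, 0) + 1) / (n + 2) for c in t.classes)


def predict_matrix(t: RehaTree, m: ExpressionMatrix) -> list[str]:
    """Labels for every sample (column) of an expression matrix."""
    idx = {p: i for i, p in enumerate(m.protein_ids)}
    return [predict_sample(t, m.values[:, j], idx) for j in range(m.n_samples)]


def predict_proba_matrix(t: RehaTree, m: ExpressionMatrix) -> np.ndarray:
    idx = {p: i for i, p in enumerate(m.protein_ids)}
    return np.array([predict_proba_sample(t, m.values[:, j], idx) for j in range(m.n_samples)])


def refit_leaf_counts(t: RehaTree, m: ExpressionMatrix, y: SampleLabels) -> RehaTree:
    """Recompute training class counts (and majority labels) at every leaf.

    A leaf reached by no training sample keeps its label with a pseudo-count
    of 1, preserving the counts-sum >= 1 invariant after crossover surgery.
    """
    idx = {p: i for i, p in enumerate(m.protein_ids)}
    yv = y.y(m.sample_ids)

    def rebuild(node, cols):
        if isinstance(node, Leaf):
            counts = {c: 0 for c in t.classes}
            for j in cols:
                counts[t.classes[yv[j]]] += 1
            if sum(counts.values()) == 0:
                return Leaf(node.label, {node.label: 1})
            label = max(t.classes, key=lambda c: (counts[c], -t.classes.index(c)))
            return Leaf(label, counts)
        lcols, rcols = [], []
        for j in cols:
            branch = apply_multitest(node.test, m.values[:, j], idx)
            (lcols if branch == "left" else rcols).append(j)
        return InternalNode(node.test, rebuild(node.left, lcols), rebuild(node.right, rcols))

    return RehaTree(rebuild(t.root, list(range(m.n_samples))), t.classes, t.max_depth)


def training_accuracy(t: RehaTree, m: ExpressionMatrix, y: SampleLabels) -> float:
    yv = y.y(m.sample_ids)
    pred = predict_matrix(t, m)
    code = {c: i for i, c in enumerate(t.classes)}
    return float(np.mean([code[p] == v for p, v in zip(pred, yv)]))


# ---------------------------------------------------------------------------
# pruning


def _majority_leaf(node, classes) -> Leaf:
    counts = {c: 0 for c in classes}
    for leaf in _iter_leaves(node):
        for c, n in leaf.counts.items():
            counts[c] = counts.get(c, 0) + n
    if sum(counts.values()) == 0:
        counts = {next(_iter_leaves(node)).label: 1}
    label = max(classes, key=lambda c: (counts.get(c, 0), -list(classes).index(c)))
    return Leaf(label, counts)


def prune_tree(t: RehaTree, m: ExpressionMatrix, y: SampleLabels, fitness_cfg,
               ranking=None) -> RehaTree:
    """Bottom-up cost-complexity pruning against the evolutionary fitness.

    Each internal node is replaced by its majority-class leaf whenever doing
    so does not decrease the tree's fitness on the training data; the pass is
    bottom-up and idempotent.
    """
    from .evolution import tree_fitness  # local import to avoid a cycle

    def fitness(tree: RehaTree) -> float:
        return tree_fitness(tree, m, y, ranking, fitness_cfg)[0]

    def postorder_paths(node, path):
        if isinstance(node, InternalNode):
            yield from postorder_paths(node.left, path + "L")
            yield from postorder_paths(node.right, path + "R")
            yield path

    work = t
    for path in list(postorder_paths(t.root, "")):
        node = _node_at(work, path)
        candidate = _rebuild_with(work, path, _majority_leaf(node, t.classes))
        if fitness(candidate) >= fitness(work):
            work = candidate
    return work


def _node_at(t: RehaTree, path: str):
    node = t.root
    for step in path:
        node = node.left if step == "L" else node.right
    return node


def _rebuild_with(t: RehaTree, path: str, subtree) -> RehaTree:
    """Copy of ``t`` with the node at root-path ``path`` (L/R string) replaced."""

    def rebuild(node, remaining):
        if not remaining:
            return subtree
        if isinstance(node, Leaf):
            raise ValidationError("path descends through a leaf")
        if remaining[0] == "L":
            return InternalNode(node.test, rebuild(node.left, remaining[1:]), node.right)
        return InternalNode(node.test, node.left, rebuild(node.right, remaining[1:]))

    return RehaTree(rebuild(t.root, path), t.classes, t.max_depth)


# ---------------------------------------------------------------------------
# serialization


def _pair_to_json(p: PairTest) -> dict:
    return {"a": p.protein_a, "b": p.protein_b, "direction": p.direction}


def _pair_from_json(d: dict) -> PairTest:
    return PairTest(d["a"], d["b"], bool(d["direction"]))


def _node_to_json(node) -> dict:
    if isinstance(node, Leaf):
        return {"kind": "leaf", "label": node.label, "counts": dict(node.counts)}
    return {
        "kind": "node",
        "primary": _pair_to_json(node.test.primary),
        "surrogates": [_pair_to_json(s) for s in node.test.surrogates],
        "similarities": list(node.test.similarities),
        "fallback": node.test.fallback_branch,
        "left": _node_to_json(node.left),
        "right": _node_to_json(node.right),
    }


def _node_from_json(d: dict):
    if d["kind"] == "leaf":
        return Leaf(d["label"], {k: int(v) for k, v in d["counts"].items()})
    test = MultiTest(
        primary=_pair_from_json(d["primary"]),
        surrogates=[_pair_from_json(s) for s in d["surrogates"]],
        similarities=[float(s) for s in d["similarities"]],
        fallback_branch=d["fallback"],
    )
    return InternalNode(test, _node_from_json(d["left"]), _node_from_json(d["right"]))


def serialize_tree(t: RehaTree, format: str = "json") -> str:
    """Serialize to lossless JSON or Graphviz DOT text."""
    if format == "json":
        doc = {
            "classes": list(t.classes),
            "max_depth": t.max_depth,
            "root": _node_to_json(t.root),
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":"))
    if format == "dot":
        lines = ["digraph reha_tree {", "  node [shape=box];"]
        counter = [0]

        def emit(node) -> str:
            name = f"n{counter[0]}"
            counter[0] += 1
            if isinstance(node, Leaf):
                counts = ", ".join(f"{c}:{n}" for c, n in sorted(node.counts.items()))
                lines.append(f'  {name} [label="{node.label}\\n({counts})", shape=ellipse];')
                return name
            p = node.test.primary
            rel = "<" if p.direction else ">="
            label = f"{p.protein_a} {rel} {p.protein_b}"
            if node.test.surrogates:
                label += f"\\n+{len(node.test.surrogates)} surrogates"
            lines.append(f'  {name} [label="{label}"];')
            ln, rn = emit(node.left), emit(node.right)
            lines.append(f'  {name} -> {ln} [label="yes"];')
            lines.append(f'  {name} -> {rn} [label="no"];')
            return name

        emit(t.root)
        lines.append("}")
        return "\n".join(lines)
    raise ValidationError(f"unknown serialization format {format!r}")


def deserialize_tree(text: str) -> RehaTree:
    doc = json.loads(text)
    return RehaTree(_node_from_json(doc["root"]), tuple(doc["classes"]), int(doc["max_depth"]))
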