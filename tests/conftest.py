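"""Shared fixtures: random matrices, random trees, tiny planted cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from reha.io_model import ExpressionMatrix, SampleLabels
from reha.rxa_core import MultiTest, PairTest
from reha.tree import InternalNode, Leaf, RehaTree


def make_matrix(values, protein_ids=None, sample_ids=None, source_tags=None):
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    protein_ids = protein_ids or [f"P{i}" for i in range(p)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n)]
    return ExpressionMatrix(
        protein_ids=list(protein_ids),
        sample_ids=list(sample_ids),
        values=values,
        missing_mask=np.isnan(values),
        source_tags=source_tags or ["d"] * n,
    )


def make_labels(sample_ids, y, classes=("A", "B")):
    return SampleLabels(
        labels={s: classes[c] for s, c in zip(sample_ids, y)},
        classes=tuple(classes),
    )


def random_dataset(rng, n_proteins=8, n_samples=16, missing_frac=0.0):
    """Tie-free random matrix with balanced binary labels."""
    values = rng.normal(20.0, 2.0, size=(n_proteins, n_samples))
    if missing_frac > 0:
        mask = rng.random(values.shape) < missing_frac
        values[mask] = np.nan
    m = make_matrix(values)
    y = np.array([0, 1] * (n_samples // 2) + [0] * (n_samples % 2))
    return m, make_labels(m.sample_ids, y)


def random_tree(protein_ids, classes, rng, max_depth=3, p_leaf=0.3):
    """Random valid tree; leaf labels match the majority of their counts."""

    def rand_pair(exclude=frozenset()):
        while True:
            i, j = rng.choice(len(protein_ids), size=2, replace=False)
            pair = PairTest(protein_ids[i], protein_ids[j], bool(rng.integers(2)))
            if pair.proteins not in exclude:
                return pair

    def leaf():
        c0, c1 = int(rng.integers(0, 5)), int(rng.integers(0, 5))
        if c0 + c1 == 0:
            c0 = 1
        counts = {classes[0]: c0, classes[1]: c1}
        label = classes[0] if c0 >= c1 else classes[1]
        return Leaf(label, counts)

    def grow(depth):
        if depth >= max_depth or rng.random() < p_leaf:
            return leaf()
        primary = rand_pair()
        seen = {primary.proteins}
        surrogates = []
        for _ in range(int(rng.integers(0, 3))):
            s = rand_pair(exclude=frozenset(seen))
            seen.add(s.proteins)
            surrogates.append(s)
        sims = sorted((float(x) for x in rng.random(len(surrogates))), reverse=True)
        mt = MultiTest(primary, surrogates, sims,
                       "left" if rng.random() < 0.5 else "right")
        return InternalNode(mt, grow(depth + 1), grow(depth + 1))

    root = grow(0)
    return RehaTree(root, tuple(classes), max_depth=max_depth)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy():
    from reha.synthetic import toy_fixture

    return toy_fixture()
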