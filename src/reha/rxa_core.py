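"""Relative-expression (order-relation) pair tests and multi-test clusters.

A pair test asks, within one sample, whether protein *a* is expressed below
protein *b*.  Because only the within-sample order matters, every decision
built from such tests is invariant to strictly increasing transforms of a
sample's values — the property that makes top-scoring-pair classifiers robust
to normalization and batch effects.

A multi-test groups a primary pair with surrogate pairs that split the
training data similarly; at prediction time all member tests vote with equal
weight, which stabilizes decisions when single measurements are missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_model import ExpressionMatrix, SampleLabels, ValidationError


@dataclass(frozen=True)
class PairTest:
    """Order test on one protein pair.

    ``direction=True`` asserts expression(a) < expression(b) within a sample;
    ``direction=False`` asserts the complement (a >= b).  A sample satisfying
    the assertion is routed left, otherwise right; a sample missing either
    value abstains.
    """

    protein_a: str
    protein_b: str
    direction: bool = True

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise ValidationError("pair test needs two distinct proteins")

    @property
    def proteins(self) -> frozenset:
        return frozenset((self.protein_a, self.protein_b))


@dataclass(frozen=True)
class PairScore:
    """TSP score of a pair: primary score delta, rank-gap tie-break gamma."""

    delta: float
    gamma: float
    n_valid_per_class: tuple[int, int]

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0 + 1e-12):
            raise ValidationError(f"delta {self.delta} outside [0,1]")


@dataclass
class ProteinRanking:
    """Discrimination weights per protein, scaled to [0, 1]."""

    weights: dict[str, float]

    def __post_init__(self):
        for p, w in self.weights.items():
            if not (0.0 <= w <= 1.0 + 1e-12):
                raise ValidationError(f"weight for {p!r} outside [0,1]")

    def weight(self, protein_id: str) -> float:
        return self.weights[protein_id]

    def top(self, k: int) -> list[str]:
        """Top-k protein ids by weight (ties broken by id for determinism)."""
        order = sorted(self.weights.items(), key=lambda t: (-t[1], t[0]))
        return [p for p, _ in order[:k]]


@dataclass
class MultiTest:
    """Internal-node test: primary pair plus similarity-ranked surrogates."""

    primary: PairTest
    surrogates: list[PairTest] = field(default_factory=list)
    similarities: list[float] = field(default_factory=list)
    fallback_branch: str = "left"

    def __post_init__(self):
        if len(self.surrogates) != len(self.similarities):
            raise ValidationError("one similarity per surrogate required")
        if self.fallback_branch not in ("left", "right"):
            raise ValidationError("fallback_branch must be 'left' or 'right'")
        if any(s.proteins == self.primary.proteins for s in self.surrogates):
            raise ValidationError("surrogate duplicates the primary pair")
        if any(b > a + 1e-12 for a, b in zip(self.similarities, self.similarities[1:])):
            raise ValidationError("surrogates must be sorted by similarity descending")

    @property
    def tests(self) -> list[PairTest]:
        return [self.primary, *self.surrogates]

    @property
    def proteins(self) -> set:
        out = set(self.primary.proteins)
        for s in self.surrogates:
            out |= s.proteins
        return out


# ---------------------------------------------------------------------------
# scoring


def _binary_y(m: ExpressionMatrix, y: SampleLabels) -> np.ndarray:
    if len(y.classes) != 2:
        raise ValidationError("pair scoring requires a binary task")
    missing = [s for s in m.sample_ids if s not in y.labels]
    if missing:
        raise ValidationError(f"samples without labels: {missing[:5]}")
    return y.y(m.sample_ids)


def _rank_matrix(values: np.ndarray) -> np.ndarray:
    """Within-sample ranks of proteins (columns), NaN kept for missing."""
    ranks = np.full(values.shape, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        ok = ~np.isnan(col)
        if ok.any():
            ranks[ok, j] = rankdata(col[ok])
    return ranks


def pair_order_score(m: ExpressionMatrix, y: SampleLabels, pair: PairTest) -> PairScore:
    """Score one pair: delta = |f0 - f1| with f_c the fraction of class-c
    samples (both values present) in which a < b strictly; gamma = between-
    class difference of the mean within-sample rank gap rank(b) - rank(a).
    """
    yv = _binary_y(m, y)
    ia, ib = m.protein_index(pair.protein_a), m.protein_index(pair.protein_b)
    va, vb = m.values[ia], m.values[ib]
    valid = ~(m.missing_mask[ia] | m.missing_mask[ib])
    less = (va < vb) & valid
    ranks = _rank_matrix(m.values)
    gap = ranks[ib] - ranks[ia]
    f = np.empty(2)
    gmean = np.empty(2)
    n_valid = [0, 0]
    for c in (0, 1):
        sel = (yv == c) & valid
        n_valid[c] = int(sel.sum())
        if n_valid[c] == 0:
            raise ValidationError(
                f"pair ({pair.protein_a}, {pair.protein_b}): class "
                f"{y.classes[c]!r} has no samples with both values present"
            )
        f[c] = less[sel].mean()
        gmean[c] = gap[sel].mean()
    return PairScore(
        delta=float(abs(f[0] - f[1])),
        gamma=float(gmean[0] - gmean[1]),
        n_valid_per_class=(n_valid[0], n_valid[1]),
    )


def _score_all_pairs(values, mask, ranks, yv, ai, bi):
    """Vectorized delta/gamma for pair index arrays (ai, bi).

    Returns (f0, f1, gamma) for the orientation "a < b"; caller canonicalizes
    direction.  Raises if a class has no co-measured sample for some pair.
    """
    va, vb = values[ai], values[bi]
    valid = ~(mask[ai] | mask[bi])
    with np.errstate(invalid="ignore"):
        less = (va < vb) & valid
    gap = ranks[bi] - ranks[ai]
    out_f = []
    out_g = []
    for c in (0, 1):
        cols = yv == c
        n_c = valid[:, cols].sum(axis=1)
        if np.any(n_c == 0):
            bad = int(np.flatnonzero(n_c == 0)[0])
            raise ValidationError(
                f"candidate pair index {bad}: class {c} has no co-measured samples"
            )
        out_f.append(less[:, cols].sum(axis=1) / n_c)
        g = np.where(valid[:, cols], gap[:, cols], np.nan)
        out_g.append(np.nansum(g, axis=1) / n_c)
    return out_f[0], out_f[1], out_g[0] - out_g[1]


def rank_candidate_pairs(
    m: ExpressionMatrix,
    y: SampleLabels,
    candidate_proteins: set[str] | list[str],
    top_n: int,
) -> list[tuple[PairTest, PairScore]]:
    """Evaluate every unordered candidate pair and return the ``top_n`` best.

    Directions are collapsed: each pair is oriented so that the class-0
    fraction satisfying a < b is at least the class-1 fraction.  Ordering is
    the total order (delta desc, gamma desc, ids asc), so results are
    reproducible across platforms.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    cand = sorted(set(candidate_proteins))
    if len(cand) < 2:
        raise ValidationError("need at least 2 candidate proteins")
    yv = _binary_y(m, y)
    idx = np.array([m.protein_index(p) for p in cand])
    ii, jj = np.triu_indices(len(cand), k=1)
    ai, bi = idx[ii], idx[jj]
    ranks = _rank_matrix(m.values)
    f0, f1, gamma = _score_all_pairs(m.values, m.missing_mask, ranks, yv, ai, bi)
    n_per_class = (int((yv == 0).sum()), int((yv == 1).sum()))
    records = []
    for k in range(len(ai)):
        a, b = cand[ii[k]], cand[jj[k]]
        if f0[k] >= f1[k]:
            pair, g = PairTest(a, b, True), gamma[k]
        else:
            pair, g = PairTest(b, a, True), -gamma[k]
        delta = abs(f0[k] - f1[k])
        records.append((pair, PairScore(float(delta), float(g), n_per_class)))
    records.sort(key=lambda t: (-t[1].delta, -t[1].gamma, t[0].protein_a, t[0].protein_b))
    return records[:top_n]


# ---------------------------------------------------------------------------
# ReliefF


def relief_f_rank(
    m: ExpressionMatrix,
    y: SampleLabels,
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> ProteinRanking:
    """ReliefF discrimination weights with rank-based neighbour search.

    Missing values are imputed per protein by the class median (for distance
    computation only) and neighbours are found under Manhattan distance on
    within-sample ranks — keeping the neighbourhood scale-free in the same
    spirit as the order tests.  Weight updates are the standard ReliefF
    hit/miss contrasts on the (imputed) values, normalized by each protein's
    observed range, so a protein with no contrast scores exactly 0.  Weights
    are clipped at zero and scaled to [0, 1].
    """
    if k_neighbors < 1:
        raise ValidationError("k_neighbors must be >= 1")
    yv = _binary_y(m, y)
    n = m.n_samples
    p = m.n_proteins
    for c in (0, 1):
        if (yv == c).sum() < k_neighbors + 1:
            raise ValidationError(
                f"class {y.classes[c]!r} needs at least k_neighbors+1 = {k_neighbors + 1} samples"
            )
    if n_iterations is None:
        n_iterations = n
    X = m.values.copy()
    for c in (0, 1):
        cols = yv == c
        med = np.nanmedian(np.where(cols, X, np.nan), axis=1)
        med = np.nan_to_num(med, nan=0.0)
        block = X[:, cols]
        miss = np.isnan(block)
        block[miss] = np.broadcast_to(med[:, None], block.shape)[miss]
        X[:, cols] = block
    R = np.empty_like(X)
    for j in range(n):
        R[:, j] = rankdata(X[:, j])
    span = X.max(axis=1) - X.min(axis=1)
    span = np.where(span > 0, span, 1.0)  # constant proteins contribute 0 anyway
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n, size=n_iterations)
    D = np.abs(R[:, :, None] - R[:, None, :]).sum(axis=0)  # sample x sample Manhattan
    w = np.zeros(p)
    for i in picks:
        for kind, sel in (("hit", yv == yv[i]), ("miss", yv != yv[i])):
            cand = np.flatnonzero(sel)
            cand = cand[cand != i]
            order = cand[np.argsort(D[i, cand], kind="stable")]
            nb = order[:k_neighbors]
            diff = (np.abs(X[:, nb] - X[:, [i]]) / span[:, None]).sum(axis=1)
            if kind == "hit":
                w -= diff / (n_iterations * k_neighbors)
            else:
                w += diff / (n_iterations * k_neighbors)
    w = np.clip(w, 0.0, None)
    top = w.max()
    if top > 0:
        w = w / top
    return ProteinRanking(weights={pid: float(w[i]) for i, pid in enumerate(m.protein_ids)})


# ---------------------------------------------------------------------------
# multi-tests


def _route(test: PairTest, va: float, vb: float) -> str | None:
    """Branch for one test on one sample; None = abstain (missing value)."""
    if np.isnan(va) or np.isnan(vb):
        return None
    holds = (va < vb) if test.direction else not (va < vb)
    return "left" if holds else "right"


def _route_matrix(test: PairTest, m: ExpressionMatrix) -> np.ndarray:
    """Vector of branches over samples: +1 left, -1 right, 0 abstain."""
    ia, ib = m.protein_index(test.protein_a), m.protein_index(test.protein_b)
    va, vb = m.values[ia], m.values[ib]
    valid = ~(m.missing_mask[ia] | m.missing_mask[ib])
    with np.errstate(invalid="ignore"):
        holds = (va < vb) if test.direction else ~(va < vb)
    out = np.where(holds, 1, -1)
    return np.where(valid, out, 0)


def split_similarity(t1: PairTest, t2: PairTest, m: ExpressionMatrix) -> float:
    """Fraction of co-evaluable samples routed to the same branch by t1, t2."""
    r1 = _route_matrix(t1, m)
    r2 = _route_matrix(t2, m)
    both = (r1 != 0) & (r2 != 0)
    if not both.any():
        return 0.0
    return float((r1[both] == r2[both]).mean())


def build_multitest(
    m: ExpressionMatrix,
    y: SampleLabels,
    primary: PairTest,
    max_surrogates: int,
    theta: float,
    candidate_pairs: list[PairTest],
) -> MultiTest:
    """Assemble a multi-test: the primary pair plus up to ``max_surrogates``
    candidates whose split agrees with the primary on a fraction >= ``theta``
    of co-evaluable training samples and which share at most one protein with
    the primary.  Surrogates are kept in similarity-descending order.
    """
    yv = _binary_y(m, y)
    scored = []
    seen: set[frozenset] = {primary.proteins}
    for cand in candidate_pairs:
        if cand.proteins in seen:
            continue
        if len(cand.proteins & primary.proteins) > 1:
            continue
        sim = split_similarity(primary, cand, m)
        if sim >= theta:
            try:
                delta = pair_order_score(m, y, cand).delta
            except ValidationError:
                continue
            scored.append((cand, sim, delta))
            seen.add(cand.proteins)
    scored.sort(key=lambda t: (-t[1], -t[2], t[0].protein_a, t[0].protein_b))
    kept = scored[:max_surrogates]

    # fallback branch: where the primary test sends most majority-class samples
    maj = 0 if (yv == 0).sum() >= (yv == 1).sum() else 1
    r = _route_matrix(primary, m)
    maj_routes = r[(yv == maj) & (r != 0)]
    fallback = "left" if (maj_routes == 1).sum() >= (maj_routes == -1).sum() else "right"
    return MultiTest(
        primary=primary,
        surrogates=[t for t, _, _ in kept],
        similarities=[s for _, s, _ in kept],
        fallback_branch=fallback,
    )


def apply_multitest(node: MultiTest, sample: dict[str, float] | np.ndarray, protein_index=None) -> str:
    """Route one sample through a multi-test by equal-weight majority vote.

    ``sample`` is either a mapping protein id -> value (NaN = missing) or a
    value vector with ``protein_index`` mapping ids to positions.  On an exact
    tie the surrogate votes alone decide; if still tied (or every test
    abstains) the training-majority fallback branch is used.
    """

    def value(pid: str) -> float:
        if protein_index is not None:
            return float(sample[protein_index[pid]])
        v = sample.get(pid, np.nan)
        return float(v) if v is not None else np.nan

    votes = []
    for test in node.tests:
        votes.append(_route(test, value(test.protein_a), value(test.protein_b)))
    left = sum(1 for v in votes if v == "left")
    right = sum(1 for v in votes if v == "right")
    if left != right:
        return "left" if left > right else "right"
    s_left = sum(1 for v in votes[1:] if v == "left")
    s_right = sum(1 for v in votes[1:] if v == "right")
    if s_left != s_right:
        return "left" if s_left > s_right else "right"
    return node.fallback_branch
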