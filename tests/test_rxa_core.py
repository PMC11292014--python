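import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from reha.io_model import ValidationError
from reha.rxa_core import (
    MultiTest,
    PairTest,
    apply_multitest,
    build_multitest,
    pair_order_score,
    rank_candidate_pairs,
    relief_f_rank,
    split_similarity,
)

from .conftest import make_labels, make_matrix, random_dataset

NA = np.nan


def brute_force_pair_ranking(m, y, candidates, top_n):
    """Independent re-scoring: explicit loops over samples and pairs."""
    yv = y.y(m.sample_ids)
    ranks = np.full(m.values.shape, np.nan)
    for j in range(m.n_samples):
        col = m.values[:, j]
        ok = ~np.isnan(col)
        ranks[ok, j] = rankdata(col[ok])
    records = []
    for a, b in itertools.combinations(sorted(candidates), 2):
        ia, ib = m.protein_ids.index(a), m.protein_ids.index(b)
        f = {0: [], 1: []}
        g = {0: [], 1: []}
        for j in range(m.n_samples):
            va, vb = m.values[ia, j], m.values[ib, j]
            if np.isnan(va) or np.isnan(vb):
                continue
            f[yv[j]].append(1.0 if va < vb else 0.0)
            g[yv[j]].append(ranks[ib, j] - ranks[ia, j])
        f0, f1 = np.mean(f[0]), np.mean(f[1])
        gamma = np.mean(g[0]) - np.mean(g[1])
        if f0 >= f1:
            pair = PairTest(a, b, True)
        else:
            pair, gamma = PairTest(b, a, True), -gamma
        records.append((pair, abs(f0 - f1), gamma))
    records.sort(key=lambda t: (-t[1], -t[2], t[0].protein_a, t[0].protein_b))
    return records[:top_n]


class TestPairOrderScore:
    def test_same_order_everywhere_gives_zero(self):
        m = make_matrix([[1, 1, 1, 1], [2, 2, 2, 2]])
        y = make_labels(m.sample_ids, [0, 0, 1, 1])
        assert pair_order_score(m, y, PairTest("P0", "P1")).delta == 0.0

    def test_perfect_reversal_gives_one(self):
        m = make_matrix([[1, 1, 3, 3], [2, 2, 2, 2]])
        y = make_labels(m.sample_ids, [0, 0, 1, 1])
        assert pair_order_score(m, y, PairTest("P0", "P1")).delta == 1.0

    def test_hand_enumeration(self):
        # class 0: a<b in 3 of 4 samples; class 1: a<b in 1 of 4
        a = [1, 1, 1, 3, 1, 3, 3, 3]
        b = [2, 2, 2, 2, 2, 2, 2, 2]
        m = make_matrix([a, b])
        y = make_labels(m.sample_ids, [0, 0, 0, 0, 1, 1, 1, 1])
        score = pair_order_score(m, y, PairTest("P0", "P1"))
        assert score.delta == pytest.approx(0.5)
        assert score.n_valid_per_class == (4, 4)

    def test_ties_count_as_not_less(self):
        m = make_matrix([[2, 2, 1, 1], [2, 2, 2, 2]])
        y = make_labels(m.sample_ids, [0, 0, 1, 1])
        assert pair_order_score(m, y, PairTest("P0", "P1")).delta == 1.0

    def test_missing_samples_excluded(self):
        m = make_matrix([[1, NA, 3, 3], [2, 2, NA, 2]])
        y = make_labels(m.sample_ids, [0, 0, 1, 1])
        s = pair_order_score(m, y, PairTest("P0", "P1"))
        assert s.n_valid_per_class == (1, 1)

    def test_empty_class_raises(self):
        m = make_matrix([[1, NA, NA], [2, 2, 2]])
        y = make_labels(m.sample_ids, [0, 1, 1])
        with pytest.raises(ValidationError, match="no samples"):
            pair_order_score(m, y, PairTest("P0", "P1"))

    def test_delta_direction_symmetric(self, rng):
        m, y = random_dataset(rng, 6, 14)
        for a, b in [("P0", "P3"), ("P2", "P5")]:
            d1 = pair_order_score(m, y, PairTest(a, b)).delta
            d2 = pair_order_score(m, y, PairTest(b, a)).delta
            assert d1 == pytest.approx(d2)


class TestRankCandidatePairs:
    def test_pair_count(self, rng):
        m, y = random_dataset(rng, 3, 10)
        out = rank_candidate_pairs(m, y, m.protein_ids, top_n=10)
        assert len(out) == 3  # C(3,2)

    def test_planted_pair_ranked_first(self):
        rng = np.random.default_rng(5)
        values = rng.normal(20, 1, size=(6, 12))
        values[0] = [10] * 6 + [12] * 6   # reversal vs P1 = 11
        values[1] = 11.0
        m = make_matrix(values)
        y = make_labels(m.sample_ids, [0] * 6 + [1] * 6)
        top = rank_candidate_pairs(m, y, m.protein_ids, top_n=1)[0]
        assert top[0].proteins == frozenset({"P0", "P1"})
        assert top[1].delta == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(20):
            p = int(rng.integers(3, 11))
            n = int(rng.integers(6, 21)) // 2 * 2
            m, y = random_dataset(rng, p, n, missing_frac=0.1 if trial % 2 else 0.0)
            try:
                fast = rank_candidate_pairs(m, y, m.protein_ids, top_n=p * p)
            except ValidationError:
                continue  # missingness emptied a class for some pair
            slow = brute_force_pair_ranking(m, y, m.protein_ids, top_n=p * p)
            assert [t[0] for t in fast] == [t[0] for t in slow]
            np.testing.assert_allclose([t[1].delta for t in fast],
                                       [t[1] for t in slow], atol=1e-12)

    def test_top_n_validation(self, rng):
        m, y = random_dataset(rng, 3, 8)
        with pytest.raises(ValidationError):
            rank_candidate_pairs(m, y, m.protein_ids, top_n=0)


class TestReliefF:
    def test_constant_protein_scores_zero(self, rng):
        m, y = random_dataset(rng, 5, 12)
        m.values[2] = 17.0
        w = relief_f_rank(m, y, k_neighbors=2, seed=3).weights
        assert w["P2"] == 0.0

    def test_separating_protein_scores_one(self):
        rng = np.random.default_rng(8)
        values = rng.normal(20, 0.5, size=(6, 16))
        values[0, :8] -= 5
        values[0, 8:] += 5
        m = make_matrix(values)
        y = make_labels(m.sample_ids, [0] * 8 + [1] * 8)
        w = relief_f_rank(m, y, k_neighbors=3, seed=3).weights
        assert w["P0"] == 1.0
        assert max(w, key=w.get) == "P0"

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(44)
        values = rng.normal(20, 1, size=(5, 12))
        m = make_matrix(values)
        y = make_labels(m.sample_ids, [0, 1] * 6)
        k, seed = 2, 99
        fast = relief_f_rank(m, y, k_neighbors=k, seed=seed).weights

        # naive recomputation with explicit loops: rank-based neighbours,
        # range-normalized raw-value weight updates
        yv = y.y(m.sample_ids)
        R = np.vstack([rankdata(values[:, j]) for j in range(12)]).T
        span = values.max(axis=1) - values.min(axis=1)
        picks = np.random.default_rng(seed).integers(0, 12, size=12)
        w = np.zeros(5)
        for i in picks:
            d = [sum(abs(R[p, i] - R[p, j]) for p in range(5)) for j in range(12)]
            for sign, sel in ((-1, yv == yv[i]), (+1, yv != yv[i])):
                cand = [j for j in np.flatnonzero(sel) if j != i]
                cand.sort(key=lambda j: d[j])
                for j in cand[:k]:
                    for p in range(5):
                        w[p] += sign * abs(values[p, i] - values[p, j]) / span[p] / (12 * k)
        w = np.clip(w, 0, None)
        w = w / w.max()
        for i, pid in enumerate(m.protein_ids):
            assert fast[pid] == pytest.approx(w[i], abs=1e-12)

    def test_deterministic_and_validated(self, rng):
        m, y = random_dataset(rng, 4, 10)
        a = relief_f_rank(m, y, k_neighbors=2, seed=5).weights
        b = relief_f_rank(m, y, k_neighbors=2, seed=5).weights
        assert a == b
        with pytest.raises(ValidationError):
            relief_f_rank(m, y, k_neighbors=0)
        with pytest.raises(ValidationError):
            relief_f_rank(m, y, k_neighbors=50)


class TestSplitSimilarity:
    def test_identity_is_one(self, rng):
        m, _ = random_dataset(rng, 4, 10)
        t = PairTest("P0", "P1")
        assert split_similarity(t, t, m) == 1.0

    def test_flipped_direction_is_zero_without_ties(self, rng):
        m, _ = random_dataset(rng, 4, 10)
        t = PairTest("P0", "P1", True)
        assert split_similarity(t, PairTest("P0", "P1", False), m) == 0.0

    def test_hand_count(self):
        # t1 splits by P0 vs P1; t2 by P2 vs P3; they agree on 9 of 12 samples
        a = np.zeros(12)
        b = np.where(np.arange(12) < 6, 1.0, -1.0)        # t1: left on first 6
        c = np.zeros(12)
        d = np.where(np.arange(12) < 9, 1.0, -1.0)        # t2: left on first 9
        m = make_matrix([a, b, c, d])
        sim = split_similarity(PairTest("P0", "P1"), PairTest("P2", "P3"), m)
        assert sim == pytest.approx(9 / 12)

    def test_no_coevaluable_samples(self):
        m = make_matrix([[1, NA], [2, NA], [NA, 1], [NA, 2]])
        assert split_similarity(PairTest("P0", "P1"), PairTest("P2", "P3"), m) == 0.0


class TestBuildMultitest:
    def setup_method(self):
        rng = np.random.default_rng(13)
        self.m, self.y = random_dataset(rng, 8, 16)
        self.primary = rank_candidate_pairs(self.m, self.y, self.m.protein_ids, 1)[0][0]
        self.candidates = [t for t, _ in
                           rank_candidate_pairs(self.m, self.y, self.m.protein_ids, 30)]

    def test_unreachable_theta_gives_bare_primary(self):
        mt = build_multitest(self.m, self.y, self.primary, 3, theta=1.01,
                             candidate_pairs=self.candidates)
        assert mt.surrogates == []
        assert mt.primary == self.primary

    def test_sorted_and_capped(self):
        mt = build_multitest(self.m, self.y, self.primary, 2, theta=0.0,
                             candidate_pairs=self.candidates)
        assert len(mt.surrogates) <= 2
        sims = mt.similarities
        assert sims == sorted(sims, reverse=True)
        for s in mt.surrogates:
            assert s.proteins != self.primary.proteins
            assert len(s.proteins & self.primary.proteins) <= 1

    def test_duplicate_of_primary_excluded(self):
        dup = PairTest(self.primary.protein_b, self.primary.protein_a, False)
        mt = build_multitest(self.m, self.y, self.primary, 5, theta=0.0,
                             candidate_pairs=[dup] + self.candidates)
        assert all(s.proteins != self.primary.proteins for s in mt.surrogates)


class TestApplyMultitest:
    def test_single_test_majority_of_one(self):
        mt = MultiTest(PairTest("A", "B", True))
        assert apply_multitest(mt, {"A": 1.0, "B": 2.0}) == "left"
        assert apply_multitest(mt, {"A": 2.0, "B": 1.0}) == "right"

    def test_tie_resolved_by_surrogates_then_fallback(self):
        # primary left; surrogates right, right, left -> 2-2 tie -> surrogate
        # votes split 1-2... use exact construction from voting rule:
        mt = MultiTest(
            PairTest("A", "B", True),
            [PairTest("C", "D", True), PairTest("E", "F", True),
             PairTest("G", "H", True)],
            [0.9, 0.8, 0.7],
            fallback_branch="right",
        )
        # votes: primary left; surrogates right, right, left -> 2-2 overall,
        # surrogates 1 left vs 2 right -> right wins via surrogate override
        sample = {"A": 1, "B": 2, "C": 2, "D": 1, "E": 2, "F": 1, "G": 1, "H": 2}
        assert apply_multitest(mt, sample) == "right"
        # surrogates split 1-1 after one abstains -> fallback branch
        sample2 = {"A": 1, "B": 2, "C": 2, "D": 1, "E": NA, "F": 1, "G": 1, "H": 2}
        # votes: left, right, abstain, left => 2-1 left majority, no tie
        assert apply_multitest(mt, sample2) == "left"
        sample3 = {"A": 1, "B": 2, "C": 2, "D": 1, "E": NA, "F": 1, "G": NA, "H": 2}
        # votes: left, right -> 1-1 tie; surrogates alone: right -> right
        assert apply_multitest(mt, sample3) == "right"

    def test_all_abstain_uses_fallback(self):
        mt = MultiTest(PairTest("A", "B", True), fallback_branch="right")
        assert apply_multitest(mt, {"A": NA, "B": 2.0}) == "right"

    def test_odd_voters_never_fall_back(self, rng):
        for _ in range(50):
            tree_rng = np.random.default_rng(int(rng.integers(1 << 30)))
            pids = [f"P{i}" for i in range(10)]
            prim = PairTest("P0", "P1", True)
            surr = [PairTest("P2", "P3", True), PairTest("P4", "P5", True)]
            mt = MultiTest(prim, surr, [0.9, 0.8], "left")
            vals = {p: float(tree_rng.normal()) for p in pids}
            left = sum(1 for t in mt.tests if vals[t.protein_a] < vals[t.protein_b])
            res = apply_multitest(mt, vals)
            assert res == ("left" if left >= 2 else "right")


def test_monotone_invariance_of_pair_decisions(rng):
    """Order tests are invariant to strictly increasing per-sample transforms."""
    m, _ = random_dataset(rng, 8, 12)
    mt = MultiTest(PairTest("P0", "P1"), [PairTest("P2", "P3")], [0.9], "left")
    transforms = [
        lambda v: 2.5 * v + 7,
        lambda v: np.log(v - v.min() + 1.0),
        lambda v: rankdata(v),
    ]
    for j in range(m.n_samples):
        base = {p: m.values[i, j] for i, p in enumerate(m.protein_ids)}
        expected = apply_multitest(mt, base)
        for g in transforms:
            col = g(m.values[:, j])
            sample = {p: col[i] for i, p in enumerate(m.protein_ids)}
            assert apply_multitest(mt, sample) == expected
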