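"""Column scoring, gap models and Smith-Waterman local alignment."""

import itertools

import numpy as np
import pytest

from profsig._alphabet import BACKGROUND
from profsig.alignment import (GapModel, ScorerConfig, build_score_matrix,
                               gap_costs_from_transitions, local_align,
                               substitution_score)
from profsig.profile import Profile, ProfileColumn
from profsig.simulate import make_synthetic_seed

TRANS = np.array([0.9, 0.05, 0.05, 0.4, 0.6, 0.4, 0.6])


def column(probs, ss=None):
    probs = np.asarray(probs, dtype=float)
    return ProfileColumn(target_probs=probs,
                         log_odds=np.log(probs / BACKGROUND),
                         trans_probs=TRANS.copy(), eff_count=1.0,
                         ss_probs=None if ss is None else np.asarray(ss, float))


def make_profile(cols, ss=None):
    cols = np.asarray(cols, dtype=float)
    l = cols.shape[0]
    return Profile(id="t", target_probs=cols,
                   log_odds=np.log(cols / BACKGROUND[None, :]),
                   trans_probs=np.tile(TRANS, (l, 1)),
                   eff_counts=np.ones(l), eno=1.0,
                   ss_probs=ss)


class TestSubstitutionScore:
    def test_background_columns_score_zero(self):
        c = column(BACKGROUND)
        assert substitution_score(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_matching_indicators_score_log20(self):
        p = np.full(20, 1e-12)
        p[0] = 1.0 - 19e-12
        c = column(p)
        uniform = np.full(20, 0.05)
        s = substitution_score(c, c, background=uniform)
        assert s == pytest.approx(np.log(20), abs=1e-6)

    def test_identical_ss_term(self):
        c1 = column(BACKGROUND, ss=[1.0, 0.0, 0.0])
        c2 = column(BACKGROUND, ss=[1.0, 0.0, 0.0])
        s = substitution_score(c1, c2, ss_weight=1.0)
        assert s == pytest.approx(np.log(3), abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = column(rng.dirichlet(np.ones(20)))
        b = column(rng.dirichlet(np.ones(20)))
        assert substitution_score(a, b) == pytest.approx(substitution_score(b, a))


class TestScoreMatrix:
    def test_shape(self):
        rng = np.random.default_rng(1)
        p1 = make_profile(rng.dirichlet(np.ones(20), size=3))
        p2 = make_profile(rng.dirichlet(np.ones(20), size=4))
        m = build_score_matrix(p1, p2)
        assert m.values.shape == (3, 4)

    def test_matches_columnwise_scorer(self):
        rng = np.random.default_rng(2)
        p1 = make_profile(rng.dirichlet(np.ones(20), size=5))
        cfg = ScorerConfig(score_scale=1.0, ss_weight=0.0)
        m = build_score_matrix(p1, p1, cfg)
        for i, j in itertools.product(range(5), repeat=2):
            expect = substitution_score(p1.column(i), p1.column(j))
            assert m.values[i, j] == pytest.approx(expect, abs=1e-10)
        # diagonal self-scores dominate the score against the background
        bg = make_profile(np.tile(BACKGROUND, (5, 1)))
        mb = build_score_matrix(p1, bg, cfg)
        assert np.all(np.diag(m.values) >= np.diag(mb.values) - 1e-9)

    def test_column_permutation_permutes_matrix(self):
        rng = np.random.default_rng(3)
        cols = rng.dirichlet(np.ones(20), size=4)
        p1 = make_profile(cols)
        perm = [2, 0, 3, 1]
        p2 = make_profile(cols[perm])
        m1 = build_score_matrix(p1, p1)
        m2 = build_score_matrix(p1, p2)
        assert np.allclose(m2.values, m1.values[:, perm])


class TestGapCosts:
    def test_summed_open_transition(self):
        prof = make_profile(np.tile(BACKGROUND, (3, 1)))
        prof.trans_probs[:] = [0.9, 0.05, 0.05, 0.4, 0.6, 0.4, 0.6]
        g = gap_costs_from_transitions(prof, scale=1.0, min_cost=0.0,
                                       max_cost=100.0)
        assert g.open_cost[0] == pytest.approx(-np.log(0.1), abs=1e-9)

    def test_clipping_at_bounds(self):
        prof = make_profile(np.tile(BACKGROUND, (2, 1)))
        prof.trans_probs[:] = [1.0 - 2e-12, 1e-12, 1e-12, 0.4, 0.6, 0.4, 0.6]
        g = gap_costs_from_transitions(prof, scale=1.0, min_cost=0.2, max_cost=8.0)
        assert np.all(g.open_cost == 8.0)

    def test_scale_linearity(self):
        prof = make_profile(np.tile(BACKGROUND, (2, 1)))
        g1 = gap_costs_from_transitions(prof, 1.0, min_cost=0.0, max_cost=1e9)
        g2 = gap_costs_from_transitions(prof, 2.5, min_cost=0.0, max_cost=1e9)
        assert np.allclose(g2.open_cost, 2.5 * g1.open_cost)

    def test_extend_never_exceeds_open(self):
        prof = make_synthetic_seed(20, rng=np.random.default_rng(0))
        g = gap_costs_from_transitions(prof, 0.6)
        assert np.all(g.extend_cost <= g.open_cost + 1e-12)


def brute_force_local(S, open_cost, extend_cost):
    """Exhaustive local alignment score: enumerate every monotone path with
    affine gap costs over all start cells (feasible for tiny matrices)."""
    l1, l2 = S.shape
    best = 0.0

    def extend(i, j, score, state):
        nonlocal best
        best = max(best, score)
        if i + 1 < l1 and j + 1 < l2:
            extend(i + 1, j + 1, score + S[i + 1, j + 1], "m")
        if i + 1 < l1:
            cost = extend_cost if state == "u" else open_cost
            extend(i + 1, j, score - cost, "u")
        if j + 1 < l2:
            cost = extend_cost if state == "l" else open_cost
            extend(i, j + 1, score - cost, "l")

    for i in range(l1):
        for j in range(l2):
            extend(i, j, S[i, j], "m")
    return best


class TestLocalAlign:
    def test_all_negative_matrix_scores_zero(self):
        rng = np.random.default_rng(5)
        p1 = make_profile(np.tile(BACKGROUND, (4, 1)))
        from profsig.alignment import ScoreMatrix
        m = ScoreMatrix(-np.abs(rng.normal(1, 0.2, (4, 4))))
        res = local_align(p1, p1, matrix=m, check_expectation=False)
        assert res.score == 0.0
        assert res.path == []
        assert res.omega == 0

    def test_single_cell_matrix(self):
        from profsig.alignment import ScoreMatrix
        p = make_profile(np.tile(BACKGROUND, (1, 1)))
        res = local_align(p, p, matrix=ScoreMatrix(np.array([[3.2]])),
                          gaps=GapModel.affine(10.0, 5.0),
                          check_expectation=False)
        assert res.score == pytest.approx(3.2)
        assert res.omega == 1
        assert res.path == [(0, 0)]

    def test_high_gap_costs_reduce_to_best_diagonal_run(self):
        from profsig.alignment import ScoreMatrix
        rng = np.random.default_rng(7)
        S = rng.normal(-0.5, 1.0, (8, 8))
        p = make_profile(np.tile(BACKGROUND, (8, 1)))
        res = local_align(p, p, matrix=ScoreMatrix(S),
                          gaps=GapModel.affine(1e3, 1e3),
                          check_expectation=False)
        best = 0.0
        for di in range(-7, 8):
            for start in range(8):
                total = 0.0
                i, j = (start, start + di) if di >= 0 else (start - di, start)
                run = 0.0
                while i < 8 and j < 8:
                    run = max(run + S[i, j], S[i, j])
                    best = max(best, run)
                    i += 1
                    j += 1
        assert res.score == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        from profsig.alignment import ScoreMatrix
        rng = np.random.default_rng(seed)
        l1, l2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        S = rng.normal(-0.3, 1.0, (l1, l2))
        go, ge = float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.1, 0.5))
        p1 = make_profile(np.tile(BACKGROUND, (l1, 1)))
        p2 = make_profile(np.tile(BACKGROUND, (l2, 1)))
        res = local_align(p1, p2, matrix=ScoreMatrix(S),
                          gaps=GapModel.affine(go, ge),
                          check_expectation=False)
        assert res.score == pytest.approx(brute_force_local(S, go, ge), abs=1e-9)

    def test_score_recomputes_from_path(self):
        rng = np.random.default_rng(11)
        p1 = make_synthetic_seed(30, rng=rng)
        p2 = make_synthetic_seed(30, rng=rng)
        cfg = ScorerConfig()
        m = build_score_matrix(p1, p2, cfg)
        res = local_align(p1, p2, cfg, matrix=m, check_expectation=False)
        # full path-cost recomputation is exercised via the brute-force
        # tests; here assert omega consistency and score positivity
        assert res.omega <= res.n_aligned_pairs
        assert res.omega == sum(
            1 for i, j in res.path if i >= 0 and j >= 0 and m.values[i, j] > 0)
        assert res.score >= 0

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(13)
        p1 = make_synthetic_seed(25, rng=rng)
        p2 = make_synthetic_seed(25, rng=rng)
        cfg = ScorerConfig()
        r12 = local_align(p1, p2, cfg, check_expectation=False)
        r21 = local_align(p2, p1, cfg, check_expectation=False)
        assert r12.score == pytest.approx(r21.score, abs=1e-9)
        assert r12.omega == r21.omega

    def test_monotone_in_matrix_entries(self):
        from profsig.alignment import ScoreMatrix
        rng = np.random.default_rng(17)
        S = rng.normal(-0.3, 1.0, (5, 5))
        p = make_profile(np.tile(BACKGROUND, (5, 1)))
        gaps = GapModel.affine(1.0, 0.3)
        base = local_align(p, p, matrix=ScoreMatrix(S.copy()), gaps=gaps,
                           check_expectation=False).score
        for _ in range(10):
            S2 = S.copy()
            i, j = rng.integers(5, size=2)
            S2[i, j] += float(rng.uniform(0.1, 2.0))
            bumped = local_align(p, p, matrix=ScoreMatrix(S2), gaps=gaps,
                                 check_expectation=False).score
            assert bumped >= base - 1e-12
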