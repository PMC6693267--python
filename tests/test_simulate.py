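"""Random profile generation: seeds, noisy MSAs, fragment pools, grids."""

import io

import numpy as np
import pytest
from scipy import stats

from profsig._alphabet import AA_INDEX, BACKGROUND, N_AA
from profsig.errors import GenerationError, InputError
from profsig.msa import Msa, compute_eno
from profsig.profile import Profile, write_profile
from profsig.simulate import (FragmentPool, GridSpec, SimulationConfig,
                              default_seeds, generate_noisy_msa,
                              generate_profile_grid, generate_random_profile,
                              make_source_msas, make_synthetic_seed,
                              sample_fragment_pool)


class TestSyntheticSeed:
    def test_deterministic_under_seed(self):
        a = make_synthetic_seed(40, rng=np.random.default_rng(9))
        b = make_synthetic_seed(40, rng=np.random.default_rng(9))
        assert a.allclose(b, atol=0)

    def test_high_concentration_approaches_background(self):
        seed = make_synthetic_seed(80, concentration=5e3,
                                   rng=np.random.default_rng(1))
        tv = 0.5 * np.abs(seed.target_probs - BACKGROUND[None, :]).sum(axis=1)
        assert tv.mean() < 0.05

    def test_mean_column_distribution_near_background(self):
        rng = np.random.default_rng(2)
        cols = np.vstack([
            make_synthetic_seed(30, concentration=3.0, rng=rng).target_probs
            for _ in range(100)])
        tv = 0.5 * np.abs(cols.mean(axis=0) - BACKGROUND).sum()
        assert tv < 0.02

    def test_profile_invariants(self):
        seed = make_synthetic_seed(25, rng=np.random.default_rng(3))
        seed.validate()


class TestNoisyMsa:
    def test_zero_noise_frequencies_converge(self):
        # sharp columns keep the multinomial sampling error of the
        # empirical frequencies well inside the 0.03 tolerance at n=2000
        rng = np.random.default_rng(4)
        seed = make_synthetic_seed(30, rng=rng)
        seed.target_probs = rng.dirichlet(np.full(N_AA, 0.05), size=30)
        seed.trans_probs[:, 2] = 0.0  # no deletions for a clean check
        seed.trans_probs[:, 0] = 1.0 - seed.trans_probs[:, 1]
        msa = generate_noisy_msa(seed, 2000, 0.0, np.random.default_rng(5))
        codes = msa.codes()
        for i in range(0, 30, 7):
            freq = np.bincount(codes[:, i][codes[:, i] < 20], minlength=20)[:20] / 2000
            assert 0.5 * np.abs(freq - seed.target_probs[i]).sum() < 0.03

    def test_full_noise_gives_background(self):
        seed = make_synthetic_seed(30, rng=np.random.default_rng(6))
        seed.trans_probs[:, 2] = 0.0
        seed.trans_probs[:, 0] = 1.0 - seed.trans_probs[:, 1]
        msa = generate_noisy_msa(seed, 3000, 1.0, np.random.default_rng(7))
        codes = msa.codes()
        freq = np.bincount(codes[codes < 20].ravel(), minlength=20)[:20]
        freq = freq / freq.sum()
        assert 0.5 * np.abs(freq - BACKGROUND).sum() < 0.02

    def test_replacement_fraction_matches_r(self):
        # one-hot seed columns: any emitted residue differing from the
        # column's residue must come from a noise replacement
        L, n, r = 40, 3000, 0.03
        one_hot = np.zeros((L, N_AA))
        picks = np.random.default_rng(8).integers(N_AA, size=L)
        one_hot[np.arange(L), picks] = 1.0
        seed = make_synthetic_seed(L, rng=np.random.default_rng(9))
        seed.target_probs = one_hot
        seed.trans_probs[:, 2] = 0.0
        seed.trans_probs[:, 0] = 1.0 - seed.trans_probs[:, 1]
        msa = generate_noisy_msa(seed, n, r, np.random.default_rng(10))
        codes = msa.codes()
        mismatch = (codes != picks[None, :]) & (codes < 20)
        observed = mismatch.mean()
        # a replacement lands on the seed residue with prob b_a, so the
        # expected mismatch fraction is r * (1 - mean b_pick)
        expected = r * (1 - BACKGROUND[picks].mean())
        assert observed == pytest.approx(expected, abs=3 * np.sqrt(r / (n * L)) + 2e-3)

    def test_n_sequences_validated(self):
        seed = make_synthetic_seed(10, rng=np.random.default_rng(11))
        with pytest.raises(InputError):
            generate_noisy_msa(seed, 0, 0.1)


class TestFragmentPool:
    def test_single_window_msa(self):
        msa = Msa(["ACDEFGHIK"] * 3, list("abc"))
        pool = sample_fragment_pool([msa], 9, pool_size=1,
                                    rng=np.random.default_rng(0))
        assert len(pool.fragments) == 1
        assert pool.fragments[0].shape == (3, 9)

    def test_all_fragments_have_s_columns(self, fragment_pool):
        assert all(f.shape[1] == fragment_pool.s
                   for f in fragment_pool.fragments)

    def test_start_positions_uniform_without_exclusion(self):
        # chi-square over start positions across many draws, with the
        # non-overlap constraint disabled
        seed = make_synthetic_seed(48, rng=np.random.default_rng(12))
        msas = [generate_noisy_msa(seed, 4, 0.0, np.random.default_rng(13))]
        pool = sample_fragment_pool(msas, 9, pool_size=10000,
                                    rng=np.random.default_rng(14),
                                    exclusive=False)
        counts = np.bincount(pool.source_ids, minlength=1)
        assert counts[0] == 10000
        # uniformity of window content positions: chi-square on the first
        # column code frequency against expectation from the MSA
        first_codes = np.array([f[0, 0] for f in pool.fragments])
        source = msas[0].codes()[0, :40]  # starts 0..39 for s=9, L=48
        expected_freq = np.bincount(source, minlength=22)[:22] / 40
        obs = np.bincount(first_codes, minlength=22)[:22]
        mask = expected_freq > 0
        chi2 = ((obs[mask] - 10000 * expected_freq[mask]) ** 2
                / (10000 * expected_freq[mask])).sum()
        dof = mask.sum() - 1
        assert stats.chi2.sf(chi2, dof) > 0.01

    def test_all_msas_too_short_raises(self):
        msa = Msa(["ACDEF"] * 2, ["a", "b"])
        with pytest.raises(InputError):
            sample_fragment_pool([msa], 9, pool_size=5)

    def test_exclusive_windows_do_not_overlap(self):
        seed = make_synthetic_seed(60, rng=np.random.default_rng(15))
        msas = [generate_noisy_msa(seed, 4, 0.0, np.random.default_rng(i))
                for i in range(8)]
        pool = sample_fragment_pool(msas, 9, pool_size=30,
                                    rng=np.random.default_rng(16))
        # reconstruct window identity by content match per source MSA
        for sid in set(pool.source_ids):
            blocks = [f for f, s in zip(pool.fragments, pool.source_ids)
                      if s == sid]
            codes = msas[sid].codes()
            found = []
            for f in blocks:
                for start in range(codes.shape[1] - 9 + 1):
                    if np.array_equal(codes[:, start:start + 9], f):
                        found.append(start)
                        break
            for a in range(len(found)):
                for b in range(a + 1, len(found)):
                    assert abs(found[a] - found[b]) >= 9


class TestRandomProfile:
    def test_length_always_matches(self, fragment_pool):
        rng = np.random.default_rng(20)
        for l in (9, 23, 50):
            p = generate_random_profile(fragment_pool, l, 4.0, rng)
            assert p.length == l

    def test_fragment_count_arithmetic(self, fragment_pool):
        # l=23, s=9 -> 3 fragments, 4 columns truncated
        pool = FragmentPool(fragments=list(fragment_pool.fragments),
                            source_ids=list(fragment_pool.source_ids),
                            ss_blocks=list(fragment_pool.ss_blocks),
                            s=fragment_pool.s)
        before = pool.remaining
        generate_random_profile(pool, 23, 4.0,
                                np.random.default_rng(21), consume=True)
        assert (before - pool.remaining) % 3 == 0 and before > pool.remaining

    def test_eno_within_tolerance(self, fragment_pool):
        rng = np.random.default_rng(22)
        for target in (2.0, 6.0, 10.0):
            p = generate_random_profile(fragment_pool, 60, target, rng)
            assert abs(p.eno - target) <= 0.5 + 1e-9

    def test_unreachable_eno_raises(self, fragment_pool):
        with pytest.raises(GenerationError, match="achieved"):
            generate_random_profile(fragment_pool, 60, 19.5,
                                    np.random.default_rng(23))

    def test_generated_profiles_satisfy_invariants(self, fragment_pool):
        p = generate_random_profile(fragment_pool, 40, 6.0,
                                    np.random.default_rng(24))
        p.validate()


class TestProfileGrid:
    def test_cell_counts(self, small_grid_sets):
        assert len(small_grid_sets) == 4
        assert all(len(v) == 12 for v in small_grid_sets.values())

    def test_cells_respect_length_and_eno(self, small_grid_sets):
        for (l, n), profiles in small_grid_sets.items():
            for p in profiles:
                assert p.length == l
                assert abs(p.eno - n) <= 0.5 + 1e-9

    def test_byte_identical_rerun(self, small_sim, seed_profiles):
        grid = GridSpec(lengths=(50,), enos=(2.0, 6.0))
        texts = []
        for _ in range(2):
            sets = generate_profile_grid(seed_profiles, grid, 4, small_sim)
            text = "".join(
                np.array2string(p.target_probs, precision=10)
                for cell in sorted(sets) for p in sets[cell])
            texts.append(text)
        assert texts[0] == texts[1]

    def test_per_cell_lower_bound(self, small_sim, seed_profiles):
        with pytest.raises(InputError):
            generate_profile_grid(seed_profiles, GridSpec(lengths=(50,),
                                                          enos=(2.0,)),
                                  1, small_sim)


class TestCorrelationTrends:
    def test_larger_s_increases_cross_profile_scores(self, seed_profiles):
        # fragment length preserves local structure: mean alignment score
        # among profiles built with s=9 exceeds that with s=1
        from profsig.alignment import ScorerConfig, local_align
        import itertools

        sc = ScorerConfig()
        means = {}
        for s in (1, 9):
            sim = SimulationConfig(rng_seed=31, s=s, S=24, M=8, pool_size=1500)
            sets = generate_profile_grid(seed_profiles,
                                         GridSpec(lengths=(60,), enos=(4.0,)),
                                         16, sim)
            profs = sets[(60, 4.0)]
            scores = [local_align(profs[i], profs[j], sc,
                                  check_expectation=False).score
                      for i, j in itertools.combinations(range(16), 2)]
            means[s] = np.mean(scores)
        assert means[9] > means[1]

    def test_larger_r_decreases_cross_profile_scores(self, seed_profiles):
        from profsig.alignment import ScorerConfig, local_align
        import itertools

        sc = ScorerConfig()
        means = {}
        for r in (0.03, 0.5):
            sim = SimulationConfig(rng_seed=33, r=r, S=24, M=8, pool_size=1500)
            sets = generate_profile_grid(seed_profiles,
                                         GridSpec(lengths=(60,), enos=(4.0,)),
                                         16, sim)
            profs = sets[(60, 4.0)]
            scores = [local_align(profs[i], profs[j], sc,
                                  check_expectation=False).score
                      for i, j in itertools.combinations(range(16), 2)]
            means[r] = np.mean(scores)
        assert means[0.03] > means[0.5]

    def test_s1_and_s9_score_distributions_differ(self, seed_profiles):
        from profsig.alignment import ScorerConfig, local_align
        from profsig.tailstats import ks_two_sample
        import itertools

        sc = ScorerConfig()
        samples = {}
        for s in (1, 9):
            sim = SimulationConfig(rng_seed=35, s=s, S=24, M=8, pool_size=1500)
            sets = generate_profile_grid(seed_profiles,
                                         GridSpec(lengths=(60,), enos=(4.0,)),
                                         20, sim)
            profs = sets[(60, 4.0)]
            samples[s] = [local_align(profs[i], profs[j], sc,
                                      check_expectation=False).score
                          for i, j in itertools.combinations(range(20), 2)]
        d = ks_two_sample(samples[1], samples[9])
        n = len(samples[1])
        crit = 1.63 * np.sqrt(2 / n)  # two-sample KS at alpha=0.01
        assert d > crit
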