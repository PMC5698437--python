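import numpy as np
import pytest

import trimorph as tm
from trimorph import game

M, P, S = 0, 1, 2
EQUAL = (1 / 3, 1 / 3, 1 / 3)


class TestPayoffMatrix:
    def test_default_table_values(self, payoff):
        assert payoff.value("P", "M") == 2.0
        assert payoff.value("P", "S") == 0.5
        assert payoff.value("M", "S") == 2.0
        assert payoff.value("S", "P") == 2.0
        assert all(payoff.value(s, s) == 1.0 for s in "MPS")

    def test_pms_round_trip(self, payoff):
        assert np.array_equal(tm.PayoffMatrix.from_pms(payoff.to_pms()).matrix, payoff.matrix)

    def test_validation(self):
        with pytest.raises(ValueError):
            tm.PayoffMatrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            tm.PayoffMatrix(-np.ones((3, 3)))
        bad_diag = np.ones((3, 3))
        bad_diag[0, 0] = 2.0
        with pytest.raises(ValueError):
            tm.PayoffMatrix(bad_diag)


class TestMeanPayoff:
    def test_equal_frequency_pairwise_term(self, payoff):
        assert tm.mean_payoff(payoff, EQUAL, "P", "M") == pytest.approx(2 / 9)

    def test_same_strategy_term(self, payoff):
        f = (0.5, 0.3, 0.2)
        assert tm.mean_payoff(payoff, f, "M", "M") == pytest.approx(0.25)

    def test_absent_opponent_contributes_nothing(self, payoff):
        assert tm.mean_payoff(payoff, (0.0, 0.6, 0.4), "P", "M") == 0.0

    def test_invalid_strategy_label(self, payoff):
        with pytest.raises(ValueError):
            tm.mean_payoff(payoff, EQUAL, "P", "X")


class TestWinProbability:
    @pytest.mark.parametrize("mode", ["eq1_additive", "ratio"])
    @pytest.mark.parametrize("freqs", [EQUAL, (0.7, 0.2, 0.1), (0.0, 0.5, 0.5)])
    def test_same_strategy_is_even_chance(self, payoff, mode, freqs):
        for s in "MPS":
            assert tm.win_probability(payoff, freqs, s, s, win_mode=mode) == 0.5

    def test_additive_equal_frequency_value(self, payoff):
        # 0.5 + (1/3)(1/3)(2 - 0.5) = 0.5 + 1/6
        expected = 0.5 + 1.5 / 9
        assert tm.win_probability(payoff, EQUAL, "P", "M") == pytest.approx(expected)

    def test_additive_gain_scales_with_frequency_product(self, payoff):
        """A polygynous male has a better-than-even chance against monogamous
        males when they are common, and the gain term scales with the product
        of the two strategies' frequencies."""
        common_m = tm.win_probability(payoff, (0.8, 0.1, 0.1), "P", "M")
        assert common_m == pytest.approx(0.5 + 0.8 * 0.1 * 1.5)
        assert common_m > 0.5
        balanced = tm.win_probability(payoff, (0.45, 0.45, 0.1), "P", "M")
        assert balanced > common_m

    def test_ratio_mode_reference_values(self, payoff):
        # (0.8*2) / (0.8*2 + 0.1*0.5) with M common
        skewed = tm.win_probability(payoff, (0.8, 0.1, 0.1), "P", "M", win_mode="ratio")
        assert skewed == pytest.approx(1.6 / 1.65, abs=1e-9)
        equal = tm.win_probability(payoff, EQUAL, "P", "M", win_mode="ratio")
        assert equal == pytest.approx(0.8)
        assert skewed > equal

    @pytest.mark.parametrize("mode", ["eq1_additive", "ratio"])
    def test_cyclic_symmetry_at_equal_frequencies(self, payoff, mode):
        probs = {
            pair: tm.win_probability(payoff, EQUAL, *pair, win_mode=mode)
            for pair in (("P", "M"), ("M", "S"), ("S", "P"))
        }
        assert len({round(v, 12) for v in probs.values()}) == 1

    def test_ratio_degenerate_weights_fall_back_to_even(self, payoff):
        # both contestants' weighted terms vanish when both strategies absent
        assert tm.win_probability(payoff, (0.0, 0.0, 1.0), "M", "P", win_mode="ratio") == 0.5

    def test_pure_beats_heterozygote_multiplicative(self, payoff):
        # base 0.5, pure side weighted by 1.2 then renormalized: 0.6/1.1
        p = tm.win_probability(payoff, EQUAL, "P", "P", focal_het=False, opp_het=True, c=0.2)
        assert p == pytest.approx(0.6 / 1.1)
        q = tm.win_probability(payoff, EQUAL, "P", "P", focal_het=True, opp_het=False, c=0.2)
        assert q == pytest.approx(1 - 0.6 / 1.1)

    def test_pure_beats_heterozygote_additive(self, payoff):
        p = tm.win_probability(
            payoff, EQUAL, "P", "P", opp_het=True, c=0.2, cost_mode="additive"
        )
        assert p == pytest.approx(0.7)

    def test_heterozygote_pair_uncosted(self, payoff):
        p = tm.win_probability(payoff, EQUAL, "P", "P", focal_het=True, opp_het=True, c=0.2)
        assert p == 0.5

    def test_invalid_inputs(self, payoff):
        with pytest.raises(ValueError):
            tm.win_probability(payoff, EQUAL, "P", "X")
        with pytest.raises(ValueError):
            tm.win_probability(payoff, EQUAL, "P", "M", c=1.5)


class TestAssignNeighbours:
    def test_single_male_has_no_neighbours(self, rng):
        focal, nbr = tm.assign_neighbours(np.array([P], dtype=np.int8), tm.GameParams(), rng)
        assert focal.size == 0 and nbr.size == 0

    def test_poisson_mean_three(self, rng):
        n = 10_000
        strategies = np.full(n, P, dtype=np.int8)
        focal, nbr = tm.assign_neighbours(strategies, tm.GameParams(), rng)
        counts = np.bincount(focal, minlength=n)
        assert counts.mean() == pytest.approx(3.0, abs=0.1)
        assert np.all(focal != nbr)

    def test_capped_at_population_minus_one(self, rng):
        strategies = np.full(3, S, dtype=np.int8)
        for _ in range(50):
            focal, nbr = tm.assign_neighbours(strategies, tm.GameParams(), rng)
            counts = np.bincount(focal, minlength=3)
            assert counts.max() <= 2  # without replacement among the other two

    def test_strategy_specific_means(self, rng):
        params = tm.GameParams(neighbour_means=(1.0, 5.0, 3.0))
        strategies = np.repeat([M, P], 5000).astype(np.int8)
        focal, _ = tm.assign_neighbours(strategies, params, rng)
        counts = np.bincount(focal, minlength=10_000)
        assert counts[:5000].mean() == pytest.approx(1.0, abs=0.1)
        assert counts[5000:].mean() == pytest.approx(5.0, abs=0.15)


class TestAssembleHarems:
    def test_conservation_when_targets_exceed_females(self, rng):
        strategies = np.repeat([P, M, S], 20).astype(np.int8)
        het = np.zeros(60, bool)
        owner = tm.assemble_harems(strategies, het, 30, tm.GameParams(), 0.0, rng)
        assert owner.shape == (30,)
        assert np.all(owner >= 0)  # total target far exceeds 30 females
        assert np.all(np.bincount(owner).sum() == 30)

    def test_zero_females(self, rng):
        owner = tm.assemble_harems(
            np.array([P, M], dtype=np.int8), np.zeros(2, bool), 0, tm.GameParams(), 0.0, rng
        )
        assert owner.size == 0

    def test_heterozygote_mean_reduced_by_cost(self, rng):
        n = 20_000
        strategies = np.full(n, P, dtype=np.int8)
        het = np.ones(n, bool)
        # abundant females so targets are never truncated
        owner = tm.assemble_harems(strategies, het, 8 * n, tm.GameParams(), 0.2, rng)
        sizes = np.bincount(owner[owner >= 0], minlength=n)
        assert sizes.mean() == pytest.approx(3.0 * 0.8, abs=0.05)

    def test_assembly_order_p_males_first(self, rng):
        """With scarce females, polygynous males fill their harems first."""
        strategies = np.array([P, M, S, M, S], dtype=np.int8)
        got_p = 0
        for seed in range(200):
            owner = tm.assemble_harems(
                strategies, np.zeros(5, bool), 2, tm.GameParams(), 0.0,
                np.random.default_rng(seed),
            )
            got_p += np.count_nonzero(owner == 0)
        # the single P male (Poisson mean 3 > 2 females available most draws)
        # takes the clear majority of assignments
        assert got_p > 250


class TestRunContests:
    def run(self, state, freqs, rng, c=0.0, method="vectorized", rounds="cyclic_sym",
            scope="assembled", pairs=None, record=False, win_mode="eq1_additive"):
        males = np.flatnonzero(state.adult_sex == 1)
        strategies = state.adult_strategy[males]
        het = state.adult_alleles[males, 0] != state.adult_alleles[males, 1]
        n_f = int(np.count_nonzero(state.adult_sex == 0))
        owner = np.full(n_f, -1, dtype=np.int64)
        owner[:] = 0  # all females start with male 0
        if pairs is None:
            pairs = (np.array([1]), np.array([0]))  # male 1 has male 0 as neighbour
        return tm.run_contests(
            strategies, het, owner, pairs[0].astype(np.int64), pairs[1].astype(np.int64),
            tm.PayoffMatrix.default(), freqs, c, rng, contest_rounds=rounds,
            steal_scope=scope, method=method, record=record, win_mode=win_mode,
        )

    def test_empty_loser_harem_no_transfers(self, two_male_population, rng):
        # all females sit with the P male; under the default rounds only P
        # attacks M, whose harem is empty, so nothing can move
        out = self.run(two_male_population, EQUAL, rng)
        assert np.all(out == 0)

    def test_expected_transfers_match_bernoulli_enumeration(self, two_male_population):
        """P male holds 3 females; the M rival contests under the
        every-directed-pair reading.  Expected gain is 3 * p_win(M, P)."""
        p_win = tm.win_probability(tm.PayoffMatrix.default(), EQUAL, "M", "P")
        total = 0
        n_rep = 4000
        for seed in range(n_rep):
            out = self.run(
                two_male_population, EQUAL, np.random.default_rng(seed), rounds="all"
            )
            total += np.count_nonzero(out == 1)
        assert total / n_rep == pytest.approx(3 * p_win, abs=0.05)

    def test_same_strategy_transfer_probability_half(self):
        """In a monomorphic population each contested female moves with
        probability one half."""
        spec = tm.MiniPopulationSpec(
            members=(
                (2, "male", "adult", "pp", "P"),
                (4, "female", "adult", "mm", None),
            )
        )
        state = tm.make_population(spec)
        moved = 0
        n_rep = 3000
        for seed in range(n_rep):
            out = self.run(state, (0.0, 1.0, 0.0), np.random.default_rng(seed))
            moved += np.count_nonzero(out == 1)
        assert moved / (4 * n_rep) == pytest.approx(0.5, abs=0.03)

    def test_female_conservation_and_unmated_untouched(self, rng):
        spec = tm.MiniPopulationSpec(
            members=(
                (3, "male", "adult", "pp", "P"),
                (3, "male", "adult", "ss", "S"),
                (2, "male", "adult", "mm", "M"),
                (10, "female", "adult", "mm", None),
            )
        )
        state = tm.make_population(spec)
        males = np.flatnonzero(state.adult_sex == 1)
        strategies = state.adult_strategy[males]
        het = np.zeros(8, bool)
        owner = np.array([0, 0, 1, 3, 3, 4, 7, -1, -1, -1], dtype=np.int64)
        focal, nbr = tm.assign_neighbours(strategies, tm.GameParams(), rng)
        for method in ("vectorized", "sequential"):
            out = tm.run_contests(
                strategies, het, owner, focal, nbr, tm.PayoffMatrix.default(),
                (0.25, 0.375, 0.375), 0.0, rng, method=method,
            )
            assert out.shape == owner.shape
            assert np.count_nonzero(out >= 0) == 7  # mated count invariant
            assert np.all(out[owner == -1] == -1)  # unmated females untouched

    @pytest.mark.parametrize("c", [0.0, 0.3])
    def test_vectorized_matches_sequential_distribution(self, c):
        """The batch contest resolution is distributionally equivalent to the
        one-at-a-time reference on a cross-strategy population."""
        spec = tm.MiniPopulationSpec(
            members=(
                (2, "male", "adult", "pp", "P"),
                (1, "male", "adult", "ps", "P"),
                (2, "male", "adult", "ss", "S"),
                (1, "male", "adult", "mm", "M"),
                (9, "female", "adult", "mm", None),
            )
        )
        state = tm.make_population(spec)
        males = np.flatnonzero(state.adult_sex == 1)
        strategies = state.adult_strategy[males]
        het = state.adult_alleles[males, 0] != state.adult_alleles[males, 1]
        owner0 = np.array([0, 0, 0, 1, 1, 2, 2, 3, 5], dtype=np.int64)
        focal = np.array([3, 3, 4, 5, 0, 1, 2], dtype=np.int64)
        nbr = np.array([0, 1, 0, 3, 3, 4, 5], dtype=np.int64)
        freqs = (1 / 6, 3 / 6, 2 / 6)
        means = {}
        n_rep = 4000
        for method in ("vectorized", "sequential"):
            holder = np.zeros(6)
            for seed in range(n_rep):
                out = tm.run_contests(
                    strategies, het, owner0, focal, nbr, tm.PayoffMatrix.default(),
                    freqs, c, np.random.default_rng(seed), method=method,
                )
                holder += np.bincount(out, minlength=6)
            means[method] = holder / n_rep
        assert np.allclose(means["vectorized"], means["sequential"], atol=0.07)

    def test_cost_zero_makes_heterozygotes_indistinguishable(self):
        """With c = 0 a heterozygote attacker wins at the same rate as a
        homozygote attacker of the same strategy (10,000 contests each)."""
        rates = {}
        for attacker_genotype in ("pp", "ps"):
            spec = tm.MiniPopulationSpec(
                members=(
                    (1, "male", "adult", "pp", "P"),
                    (1, "male", "adult", attacker_genotype, "P"),
                    (4, "female", "adult", "mm", None),
                )
            )
            state = tm.make_population(spec)
            moved = 0
            for seed in range(10_000):
                out = self.run(state, (0.0, 1.0, 0.0), np.random.default_rng(seed))
                moved += np.count_nonzero(out == 1)
            rates[attacker_genotype] = moved / 40_000
        assert rates["pp"] == pytest.approx(rates["ps"], abs=0.02)

    def test_record_tracks_transfers(self, two_male_population):
        """Recorded outcomes list females that left the loser's harem for the
        winner's."""
        rng = np.random.default_rng(5)
        out, outcomes = self.run(
            two_male_population, EQUAL, rng, rounds="all", method="sequential", record=True
        )
        for outcome in outcomes:
            for female in outcome.transferred:
                assert out[female] == outcome.winner
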