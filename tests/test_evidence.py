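"""Likelihood-ratio calculus, checked against enumeration oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

import mtmix as M


def ordered_pair_probability(freqs: dict, pair) -> Fraction:
    """Brute-force probability that two iid draws form the given unordered
    pair: sum p_i * p_j over all ordered pairs matching it."""
    target = sorted(pair)
    total = Fraction(0)
    for a, b in itertools.product(freqs, repeat=2):
        if sorted((a, b)) == target:
            total += freqs[a] * freqs[b]
    return total


class TestKnownContributorLR:
    def test_frequency_one_eleventh(self):
        result = M.lr_known_contributor(suspect_frequency=Fraction(1, 11))
        assert result.lr == 11
        assert isinstance(result.lr, Fraction)

    def test_unseen_in_large_database_add_one(self):
        big = M.HaplotypeDatabase.from_counts(
            [(M.parse_profile("16093"), 2575)]
        )
        suspect = M.parse_profile("16126 16292 16294")
        result = M.lr_known_contributor(
            big, suspect, unseen_policy=M.UnseenPolicy.ADD_ONE
        )
        assert result.lr == 2576

    def test_only_profile_in_database(self):
        db1 = M.HaplotypeDatabase.from_counts([(M.parse_profile("16093"), 1)])
        result = M.lr_known_contributor(
            db1, M.parse_profile("16093"),
            unseen_policy=M.UnseenPolicy.ERROR,
        )
        assert result.lr == 1

    def test_unseen_error_policy(self, db):
        with pytest.raises(M.ProfileNotFoundError):
            M.lr_known_contributor(
                db, M.parse_profile("16069"),
                unseen_policy=M.UnseenPolicy.ERROR,
            )


class TestTwoUnknownLR:
    def test_equifrequent_eleven(self):
        result = M.lr_two_unknown(
            pair_frequencies=(Fraction(1, 11), Fraction(1, 11))
        )
        assert result.lr == Fraction(121, 2)  # 60.5
        # matches the enumeration oracle over 11 equifrequent haplotypes
        freqs = {i: Fraction(1, 11) for i in range(11)}
        assert ordered_pair_probability(freqs, (0, 1)) == result.likelihood_den

    def test_twelve_and_one_of_2575(self):
        result = M.lr_two_unknown(
            pair_frequencies=(Fraction(12, 2575), Fraction(1, 2575))
        )
        assert result.lr == Fraction(2575**2, 24)
        assert float(result.lr) == pytest.approx(276276.04, abs=0.01)

    def test_single_profile_database_identical_pair(self):
        prof = M.parse_profile("16093")
        db1 = M.HaplotypeDatabase.from_counts([(prof, 1)])
        result = M.lr_two_unknown(db1, (prof, prof))
        assert result.lr == 1

    def test_matches_oracle_on_random_databases(self, db, rng):
        profiles = db.distinct_profiles()
        freqs = db.frequencies()
        keyed = {p.key(): f for p, f in freqs.items()}
        for _ in range(10):
            i, j = rng.integers(0, len(profiles), size=2)
            pair = (profiles[i], profiles[j])
            result = M.lr_two_unknown(db, pair)
            expected = ordered_pair_probability(
                keyed, (pair[0].key(), pair[1].key())
            )
            assert result.likelihood_den == expected
            assert result.lr == 1 / expected

    def test_invariant_under_database_duplication(self, db, profs):
        doubled = M.HaplotypeDatabase(db.entries + db.entries)
        pair = (profs["H21"], profs["H22"])
        assert M.lr_two_unknown(db, pair).lr == M.lr_two_unknown(doubled, pair).lr
        # counting-proportion frequencies are duplication-invariant (the
        # add-one convention deliberately is not: it always adds one copy)
        assert (
            M.lr_known_contributor(
                db, profs["H21"], unseen_policy=M.UnseenPolicy.ERROR
            ).lr
            == M.lr_known_contributor(
                doubled, profs["H21"], unseen_policy=M.UnseenPolicy.ERROR
            ).lr
        )


class TestProbInformative:
    def test_single_profile(self):
        assert M.prob_informative([Fraction(1)], 2) == 0
        assert M.prob_informative([Fraction(1)], 5) == 0

    def test_two_equifrequent(self):
        assert M.prob_informative([Fraction(1, 2)] * 2, 2) == Fraction(1, 2)

    def test_eleven_equifrequent_matches_enumeration(self):
        p = M.prob_informative([Fraction(1, 11)] * 11, 2)
        assert p == Fraction(10, 11)
        informative = sum(
            1 for a, b in itertools.product(range(11), repeat=2) if a != b
        )
        assert p == Fraction(informative, 121)

    @pytest.mark.parametrize("k,m", [(2, 2), (3, 2), (3, 3), (4, 3), (5, 4)])
    def test_enumeration_oracle(self, k, m, rng):
        weights = rng.integers(1, 10, size=k)
        freqs = [Fraction(int(w), int(weights.sum())) for w in weights]
        closed = M.prob_informative(freqs, m)
        enumerated = Fraction(0)
        for draw in itertools.product(range(k), repeat=m):
            if len(set(draw)) > 1:
                enumerated += math.prod(freqs[i] for i in draw)
        assert closed == enumerated

    def test_nondecreasing_in_m(self, rng):
        weights = rng.integers(1, 10, size=6)
        freqs = [Fraction(int(w), int(weights.sum())) for w in weights]
        values = [M.prob_informative(freqs, m) for m in range(2, 7)]
        assert all(0 <= v <= 1 for v in values)
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_normalization_enforced(self):
        with pytest.raises(M.NormalizationError):
            M.prob_informative([0.5, 0.6], 2)


class TestProbInformativeMC:
    def test_two_equifrequent_converges(self):
        db2 = M.HaplotypeDatabase.from_counts(
            [(M.parse_profile("rCRS"), 1), (M.parse_profile("16093"), 1)]
        )
        mc = M.prob_informative_mc(db2, 2, n_sims=100_000, seed=1)
        assert abs(mc.estimate - 0.5) < 3 * mc.se

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_closed_form(self, db, m):
        closed = float(
            M.prob_informative(list(db.frequencies().values()), m)
        )
        mc = M.prob_informative_mc(db, m, n_sims=50_000, seed=2)
        assert abs(mc.estimate - closed) < 4 * max(mc.se, 1e-12)

    def test_single_profile_database(self):
        db1 = M.HaplotypeDatabase.from_counts([(M.parse_profile("16093"), 3)])
        mc = M.prob_informative_mc(db1, 2, n_sims=1000, seed=3)
        assert mc.estimate == 0.0


class TestContamination:
    def test_uniform_site_model_likelihood(self):
        sc = M.ContaminationScenario(S=100, x=8)
        assert M.mutation_likelihood(sc) == Fraction(1, 10**16)

    def test_single_mutation_both_models(self):
        for model in M.SiteModel:
            sc = M.ContaminationScenario(S=50, x=1, site_model=model)
            assert M.mutation_likelihood(sc) == Fraction(1, 50)

    def test_two_sites_two_mutations(self):
        uniform = M.ContaminationScenario(
            S=2, x=2, site_model=M.SiteModel.INDEPENDENT_UNIFORM
        )
        distinct = M.ContaminationScenario(
            S=2, x=2, site_model=M.SiteModel.DISTINCT_SITES
        )
        assert M.mutation_likelihood(uniform) == Fraction(1, 4)
        assert M.mutation_likelihood(distinct) == 1

    def test_reference_contaminant_lr(self):
        sc = M.ContaminationScenario(S=100, x=8, p_c=Fraction(1, 100))
        result = M.contamination_lr(sc)
        assert result.lr == 10**14

    def test_equipoise(self):
        sc = M.ContaminationScenario(S=10, x=3, p_c=Fraction(1, 1000))
        assert M.contamination_lr(sc).lr == 1

    def test_candidate_list_sums(self):
        sc = M.ContaminationScenario(
            S=100, x=2,
            candidate_frequencies=[Fraction(1, 100), Fraction(1, 50)],
        )
        assert M.contamination_lr(sc).lr == Fraction(3, 100) * 100**2

    def test_no_candidate_dismisses_contamination(self):
        sc = M.ContaminationScenario(S=100, x=2, candidate_frequencies=[])
        result = M.contamination_lr(sc)
        assert result.lr == 0
        assert "dismissed" in result.status

    def test_monotonic_in_pc_s_and_x(self):
        def lr(S, x, pc):
            return M.contamination_lr(
                M.ContaminationScenario(S=S, x=x, p_c=pc)
            ).lr

        assert lr(100, 3, Fraction(1, 50)) > lr(100, 3, Fraction(1, 100))
        assert lr(200, 3, Fraction(1, 100)) > lr(100, 3, Fraction(1, 100))
        assert lr(100, 4, Fraction(1, 100)) > lr(100, 3, Fraction(1, 100))

    def test_site_model_consistency_identity(self):
        """(1/S)^x vs 1/C(S,x): the ratio of the two likelihoods is exactly
        C(S,x)/S^x, so the distinct-sites likelihood is never smaller."""
        for S, x in [(10, 2), (100, 8), (7, 7)]:
            uniform = M.mutation_likelihood(
                M.ContaminationScenario(S=S, x=x)
            )
            distinct = M.mutation_likelihood(
                M.ContaminationScenario(
                    S=S, x=x, site_model=M.SiteModel.DISTINCT_SITES
                )
            )
            assert uniform / distinct == Fraction(math.comb(S, x), S**x)
            assert distinct >= uniform

    def test_scenario_validation(self):
        with pytest.raises(M.ParameterError):
            M.ContaminationScenario(S=5, x=6)
        with pytest.raises(M.ParameterError):
            M.ContaminationScenario(S=5, x=0)
        with pytest.raises(M.ParameterError):
            M.ContaminationScenario(S=5, x=2, p_c=1.5)
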