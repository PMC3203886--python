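"""Quantitative deconvolution: the closed-form fraction estimate, model fit,
hypothesis ranking and the no-contribution test."""

import numpy as np
import pytest

import mtmix as M
from mtmix import fixtures as fx
from mtmix.simulate import _simulate_y  # generator internals for power studies


@pytest.fixture(scope="module")
def true_model():
    profs = fx.table1_profiles()
    return M.TwoContributorModel.build(
        profs["H22"], profs["H23"], sites=fx.table2_sites()
    )


@pytest.fixture(scope="module")
def false_model():
    profs = fx.table1_profiles()
    return M.TwoContributorModel.build(
        profs["H1263"], profs["H2135"], sites=fx.table2_sites()
    )


class TestEstimateFraction:
    def test_printed_column(self, true_model, table2):
        _, y = table2
        est = M.estimate_fraction(y, true_model)
        # informative sites contribute (0.30+0.32+0.29+0.27)/4
        assert est.beta_hat == pytest.approx(0.295, abs=1e-12)
        assert est.n_sites == 11
        assert not est.out_of_range

    def test_noise_free_exact_recovery(self, true_model):
        y = 0.3 * true_model.x1 + 0.7 * true_model.x2
        est = M.estimate_fraction(y, true_model)
        assert est.beta_hat == pytest.approx(0.3, abs=1e-15)
        assert est.r_squared == 1.0

    def test_swap_symmetry(self, true_model, table2):
        _, y = table2
        a = M.estimate_fraction(y, true_model).beta_hat
        b = M.estimate_fraction(y, true_model.swapped()).beta_hat
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_identical_pair_degenerate(self, profs):
        model = M.TwoContributorModel.build(profs["H22"], profs["H22"])
        with pytest.raises(M.DegenerateModelError):
            M.estimate_fraction(np.zeros(len(model.sites)), model)

    def test_observation_input(self, true_model):
        obs = fx.table2_observation()
        est = M.estimate_fraction(obs, true_model)
        assert est.beta_hat == pytest.approx(0.295, abs=1e-12)

    def test_missing_peak_raises(self, true_model):
        obs = fx.table2_observation()
        del obs.peaks[16311]
        with pytest.raises(M.ParameterError):
            M.estimate_fraction(obs, true_model)

    def test_closed_form_matches_generic_least_squares(self, rng):
        """Eq-style closed form vs an unconstrained linear solver, 1e-10."""
        profs = fx.table1_profiles()
        names = list(profs)
        for _ in range(50):
            i, j = rng.choice(len(names), size=2, replace=False)
            model = M.TwoContributorModel.build(
                profs[names[i]], profs[names[j]], sites=fx.table2_sites()
            )
            w = model.x1 - model.x2
            if not w.any():
                continue
            y = rng.random(len(model.sites))
            beta = M.estimate_fraction(y, model).beta_hat
            lstsq = np.linalg.lstsq(
                w.reshape(-1, 1), y - model.x2, rcond=None
            )[0][0]
            assert beta == pytest.approx(lstsq, abs=1e-10)

    def test_inference_matches_reference_ols(self, true_model, table2):
        """se and p-value agree with a reference OLS fit of the rewritten
        one-parameter no-intercept regression."""
        sm = pytest.importorskip("statsmodels.api")
        _, y = table2
        w = true_model.x1 - true_model.x2
        fit = sm.OLS(y - true_model.x2, w).fit()
        est = M.estimate_fraction(y, true_model)
        assert est.beta_hat == pytest.approx(fit.params[0], abs=1e-12)
        assert est.se == pytest.approx(fit.bse[0], abs=1e-12)
        assert est.p_value_beta0 == pytest.approx(fit.pvalues[0], rel=1e-9)


class TestModelFit:
    def test_true_pair_fits_better_than_false(
        self, true_model, false_model, table2
    ):
        _, y = table2
        assert M.model_fit(y, true_model) > M.model_fit(y, false_model)

    def test_constant_y_flagged(self, true_model):
        est = M.estimate_fraction(np.full(11, 0.5), true_model)
        assert "degenerate_fit" in est.flags
        assert est.r_squared == 0.0

    def test_r_squared_bounds(self, true_model, rng):
        for _ in range(20):
            y = rng.random(11)
            r2 = M.model_fit(y, true_model)
            assert 0.0 <= r2 <= 1.0


class TestRanking:
    def test_correct_pair_first_on_printed_column(
        self, true_model, false_model, table2
    ):
        _, y = table2
        ranking = M.rank_hypotheses(y, [false_model, true_model])
        assert ranking.best.model is true_model
        assert not ranking.unresolved

    def test_single_candidate_unchanged(self, true_model, table2):
        _, y = table2
        ranking = M.rank_hypotheses(y, [true_model])
        assert ranking.best.model is true_model

    def test_pair_order_irrelevant(self, true_model, table2):
        _, y = table2
        r1 = M.model_fit(y, true_model)
        r2 = M.model_fit(y, true_model.swapped())
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_empty_candidates(self, table2):
        _, y = table2
        with pytest.raises(M.ParameterError):
            M.rank_hypotheses(y, [])


class TestNoContributionTest:
    def test_absent_contributor_gives_p_one(self, true_model):
        y = true_model.x2.astype(float)  # beta = 0 exactly, no noise
        est = M.estimate_fraction(y, true_model)
        assert est.beta_hat == 0.0
        assert M.test_no_contribution(y, true_model, 1) == 1.0

    def test_power_at_moderate_noise(self, true_model):
        """H0: beta=0 rejected at alpha=0.05 in >99% of replicates when the
        true fraction is 0.3 with sd 0.02 over the 11-site design."""
        noise = M.NoiseModel(sigma=0.02)
        streams = np.random.SeedSequence(7).spawn(1000)
        rejections = 0
        for stream in streams:
            rng = np.random.default_rng(stream)
            y = _simulate_y(true_model, 0.3, noise, None, rng)
            if M.test_no_contribution(y, true_model, 1) < 0.05:
                rejections += 1
        assert rejections / 1000 > 0.99

    def test_type_i_error_calibrated(self, true_model):
        """With beta=0 and untruncated normal errors the t-test size is 0.05;
        the empirical rejection rate stays within binomial 99% bounds."""
        noise = M.NoiseModel(sigma=0.02, truncate=False)
        streams = np.random.SeedSequence(11).spawn(2000)
        rejections = 0
        for stream in streams:
            rng = np.random.default_rng(stream)
            y = _simulate_y(true_model, 0.0, noise, None, rng)
            if M.test_no_contribution(y, true_model, 1) < 0.05:
                rejections += 1
        rate = rejections / 2000
        bound = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < bound

    def test_contributor_two_null(self, true_model):
        y = true_model.x1.astype(float)  # beta = 1: contributor 2 absent
        assert M.test_no_contribution(y, true_model, 2) == 1.0
        with pytest.raises(M.ParameterError):
            M.test_no_contribution(y, true_model, 3)


class TestSimulationProperties:
    def test_parameter_recovery_at_default_noise(self, db, profs):
        """Mean fraction estimate within 0.01 of the generating 0.3 and the
        central 95% interval near [0.22, 0.37] at the calibrated noise sd."""
        summary = M.run_study(
            db,
            (profs["H22"], profs["H23"]),
            [(profs["H1263"], profs["H2135"])],
            beta=0.3,
            n_sims=1000,
            seed=3,
        )
        assert summary.beta_mean == pytest.approx(0.3, abs=0.01)
        assert summary.beta_q025 == pytest.approx(0.22, abs=0.02)
        assert summary.beta_q975 == pytest.approx(0.37, abs=0.02)

    def test_wrong_model_estimate_is_biased(self, true_model, false_model):
        """Fitting the wrong pair biases the fraction estimate away from the
        generating value."""
        noise = M.NoiseModel()
        streams = np.random.SeedSequence(5).spawn(300)
        bt, bf = [], []
        for stream in streams:
            rng = np.random.default_rng(stream)
            y = _simulate_y(true_model, 0.3, noise, None, rng)
            bt.append(M.estimate_fraction(y, true_model).beta_hat)
            bf.append(M.estimate_fraction(y, false_model).beta_hat)
        assert abs(np.mean(bf) - 0.3) > abs(np.mean(bt) - 0.3)
        assert abs(np.mean(bf) - 0.3) > 0.05

    def test_noise_never_helps_discrimination(self, db, profs):
        """The correct-identification rate is non-increasing in sigma
        (common random numbers, small Monte-Carlo slack)."""
        rates = []
        for sigma in (0.02, 0.06, 0.10, 0.16, 0.25):
            summary = M.run_study(
                db,
                (profs["H22"], profs["H23"]),
                [(profs["H1263"], profs["H2135"])],
                beta=0.3,
                noise=M.NoiseModel(sigma=sigma),
                n_sims=300,
                seed=13,
            )
            rates.append(summary.correct_rate)
        for lo, hi in zip(rates[1:], rates[:-1]):
            assert lo <= hi + 0.02
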