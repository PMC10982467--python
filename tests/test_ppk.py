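"""Clearance model, random-effect sampling and the HMC kernel."""

import math

import numpy as np
import pytest
from scipy import stats

import vancoml as v
from vancoml.errors import ConfigurationError, DomainError, StateError


class TestClearance:
    def test_zero_clcr_reduces_to_base(self, params):
        assert v.clearance(0.0, 72.0) == pytest.approx(params.theta_base)

    def test_typical_patient_oracle(self):
        # independent arithmetic: 1.71 + 8.31*(1 - e^{-0.0113*100})*0.475^(72/72)
        expected = 1.71 + 8.31 * (1 - math.exp(-1.13)) * 0.475
        assert v.clearance(100.0, 72.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(4.382156978587263)

    def test_saturates_below_asymptote(self, params):
        asymptote = 1.71 + 8.31 * 0.475  # age 72, eta 0
        values = [v.clearance(c, 72.0) for c in (10, 100, 500, 1000)]
        assert values == sorted(values)
        assert values[-1] < asymptote
        assert values[-1] == pytest.approx(asymptote, rel=1e-4)

    def test_monotone_increasing_in_clcr(self):
        grid = np.linspace(0, 300, 50)
        cl = v.clearance(grid, 60.0)
        assert np.all(np.diff(cl) > 0)

    def test_monotone_decreasing_in_age(self):
        ages = np.linspace(20, 90, 40)
        cl = v.clearance(80.0, ages)
        assert np.all(np.diff(cl) < 0)

    def test_eta_scaling(self, params):
        eta = v.RandomEffects(eta1=0.3, eta2=-0.2)
        cl = v.clearance(50.0, 40.0, eta, params)
        base = params.theta_base * math.exp(0.3)
        renal = 8.31 * (1 - math.exp(-0.0113 * math.exp(-0.2) * 50.0))
        assert cl == pytest.approx(base + renal * 0.475 ** (40 / 72), rel=1e-12)
        assert cl > base

    def test_negative_clcr_rejected(self):
        with pytest.raises(DomainError):
            v.clearance(-1.0, 40.0)

    def test_bounded_above(self, params):
        # CL <= theta_base*e^eta1 + theta_renal_max*age_factor for any clcr
        eta = v.RandomEffects(0.5, 0.9)
        bound = params.theta_base * math.exp(0.5) + params.theta_renal_max * params.age_factor(30.0)
        assert v.clearance(1e7, 30.0, eta, params) <= bound

    def test_alternative_age_parses(self):
        p_ratio = v.PPKParams(age_term="ratio_power")
        p_lin = v.PPKParams(age_term="linear")
        assert v.clearance(100, 36, None, p_ratio) == pytest.approx(
            1.71 + 8.31 * (1 - math.exp(-1.13)) * 0.5**0.475
        )
        assert v.clearance(100, 36, None, p_lin) == pytest.approx(
            1.71 + 8.31 * (1 - math.exp(-1.13)) * 0.475 * 0.5
        )


class TestPopulationPrediction:
    def test_matches_clearance_at_zero_eta(self, small_cohort, params):
        pred = v.population_prediction(small_cohort, params)
        expected = v.clearance(
            small_cohort["clcr_mL_min"].to_numpy(), small_cohort["age_years"].to_numpy()
        )
        np.testing.assert_allclose(pred, expected)

    def test_single_record(self, params):
        rec = v.PatientRecord(0, "male", 72.0, 70.0, 100.0, clcr_mL_min=100.0)
        assert v.population_prediction(rec, params) == pytest.approx(4.382156978587263)

    def test_missing_clcr_raises(self, params):
        import pandas as pd

        df = pd.DataFrame({"age_years": [50.0], "clcr_mL_min": [np.nan]})
        with pytest.raises(StateError):
            v.population_prediction(df, params)

    def test_zero_omega_means_no_individual_deviation(self):
        p0 = v.PPKParams(omega1=0.0, omega2=0.0)
        cohort = v.generate_cohort(v.CohortSpec(n=40, seed=8))
        etas = v.sample_etas(40, seed=9, params=p0)
        cohort = v.simulate_individual_cl(cohort, etas, p0)
        np.testing.assert_allclose(
            cohort["cl_true_L_h"], v.population_prediction(cohort, p0)
        )

    def test_older_patient_has_smaller_prediction(self, params):
        young = v.PatientRecord(0, "male", 40.0, 70.0, 100.0, clcr_mL_min=80.0)
        old = v.PatientRecord(1, "male", 75.0, 70.0, 100.0, clcr_mL_min=80.0)
        assert v.population_prediction(old, params) < v.population_prediction(young, params)


class TestDirectSampling:
    def test_marginal_sds(self, params):
        sample = v.sample_etas(100_000, method="direct", seed=123)
        sd = sample.draws.std(axis=0)
        assert abs(sd[0] - params.omega1) < 0.02 * params.omega1
        assert abs(sd[1] - params.omega2) < 0.02 * params.omega2
        assert abs(np.corrcoef(sample.draws.T)[0, 1]) < 0.02

    def test_lognormal_mean_identity(self, params):
        # E[e^eta] = e^{omega^2/2} for lognormal
        sample = v.sample_etas(200_000, seed=7)
        for j, omega in enumerate([params.omega1, params.omega2]):
            emp = np.exp(sample.draws[:, j]).mean()
            assert emp == pytest.approx(math.exp(omega**2 / 2), rel=0.02)

    def test_zero_omega_degenerate(self):
        sample = v.sample_etas(100, seed=1, params=v.PPKParams(omega1=0.0, omega2=0.0))
        assert np.all(sample.draws == 0.0)

    def test_seeded_reproducibility(self):
        a = v.sample_etas(1000, seed=5)
        b = v.sample_etas(1000, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_invalid_requests(self):
        with pytest.raises(ConfigurationError):
            v.sample_etas(10, method="gibbs")
        with pytest.raises(ConfigurationError):
            v.sample_etas(-1)


class TestHMC:
    def test_transition_deterministic(self, params):
        state = v.RandomEffects(0.1, -0.1)
        out1 = v.hmc_transition(state, params, 0.2, 5, rng=99)
        out2 = v.hmc_transition(state, params, 0.2, 5, rng=99)
        assert out1 == out2

    def test_tiny_step_always_accepts(self, params):
        # Hamiltonian nearly conserved => Metropolis acceptance -> 1
        rng = np.random.default_rng(4)
        accepted = [
            v.hmc_transition(v.RandomEffects(0.2, 0.2), params, 1e-6, 1, rng)[1]
            for _ in range(200)
        ]
        assert all(accepted)

    def test_invalid_options(self, params):
        with pytest.raises(ConfigurationError):
            v.hmc_transition(v.RandomEffects(), params, -0.1, 5, rng=0)
        with pytest.raises(ConfigurationError):
            v.hmc_transition(v.RandomEffects(), params, 0.1, 0, rng=0)
        with pytest.raises(ConfigurationError):
            v.sample_etas(10, method="hmc", params=v.PPKParams(omega1=0.0))
        with pytest.raises(ConfigurationError):
            v.HMCOptions(step_size=-1.0)

    def test_chain_matches_target_sd(self, params):
        sample = v.sample_etas(10_000, method="hmc", seed=17)
        sd = sample.draws.std(axis=0)
        assert abs(sd[0] - params.omega1) < 0.05 * params.omega1
        assert abs(sd[1] - params.omega2) < 0.05 * params.omega2
        assert 0.5 < sample.acceptance_rate <= 1.0

    def test_hmc_agrees_with_direct_in_distribution(self):
        hmc = v.sample_etas(10_000, method="hmc", seed=31)
        direct = v.sample_etas(10_000, method="direct", seed=32)
        for j in range(2):
            p = stats.ks_2samp(hmc.draws[:, j], direct.draws[:, j]).pvalue
            assert p > 0.01


class TestSimulateIndividualCL:
    def test_matches_scalar_clearance(self, small_cohort, params):
        etas = v.sample_etas(len(small_cohort), seed=3)
        out = v.simulate_individual_cl(small_cohort, etas, params)
        for i in (0, 17, 59):
            row = out.iloc[i]
            expected = v.clearance(
                row["clcr_mL_min"],
                row["age_years"],
                v.RandomEffects(etas.draws[i, 0], etas.draws[i, 1]),
                params,
            )
            assert row["cl_true_L_h"] == pytest.approx(expected, rel=1e-12)

    def test_exceeds_base_term(self, small_cohort, params):
        etas = v.sample_etas(len(small_cohort), seed=3)
        out = v.simulate_individual_cl(small_cohort, etas, params)
        base = params.theta_base * np.exp(etas.draws[:, 0])
        assert (out["cl_true_L_h"].to_numpy() > base).all()

    def test_draw_count_mismatch(self, small_cohort):
        with pytest.raises(StateError):
            v.simulate_individual_cl(small_cohort, v.sample_etas(10, seed=1))

    def test_termwise_median_ratio_near_one(self):
        # e^eta has median 1, so each additive term's realized/typical ratio
        # has median ~1 across a large cohort
        cohort = v.generate_cohort(v.CohortSpec(n=20_000, seed=2))
        etas = v.sample_etas(20_000, seed=3)
        base_ratio = np.exp(etas.draws[:, 0])
        assert abs(np.median(base_ratio) - 1.0) < 0.02
        clcr = cohort["clcr_mL_min"].to_numpy()
        renal_real = 1 - np.exp(-0.0113 * np.exp(etas.draws[:, 1]) * clcr)
        renal_pop = 1 - np.exp(-0.0113 * clcr)
        assert abs(np.median(renal_real / renal_pop) - 1.0) < 0.02
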