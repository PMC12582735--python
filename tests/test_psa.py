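"""Probabilistic sensitivity analysis: samplers, engine, plane, CEAC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohortcea import (
    InfeasibleMomentsError,
    PSAConfig,
    PSAResult,
    TransitionProfile,
    beta_from_mean_se,
    ceac,
    gamma_from_mean_se,
    icer_plane_quadrants,
    run_psa,
    sample_transition_profile,
    se_from_pct_range,
)
from cohortcea.psa import draw_beta, draw_gamma, draw_scaled_beta
from cohortcea.synthetic import zero_se_config


def cloud_result(delta_effect, delta_cost, base_cost=1000.0, base_effect=0.5):
    """Wrap pairwise deltas as a two-treatment PSA iteration table."""
    n = len(delta_effect)
    frames = pd.DataFrame(
        {
            "iteration": np.tile(np.arange(n), 2),
            "treatment": np.repeat(["A", "B"], n),
            "cost": np.concatenate([base_cost + np.asarray(delta_cost),
                                    np.full(n, base_cost)]),
            "effect": np.concatenate([base_effect + np.asarray(delta_effect),
                                      np.full(n, base_effect)]),
        }
    )
    return PSAResult(iterations=frames, reference="A", seed=0)


class TestMomentMatching:
    def test_beta_reproduces_moments(self):
        mean, se = 0.065, 0.003
        alpha, beta = beta_from_mean_se(mean, se)
        assert alpha / (alpha + beta) == pytest.approx(mean)
        var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert np.sqrt(var) == pytest.approx(se)

    def test_beta_against_scipy(self):
        from scipy import stats

        alpha, beta = beta_from_mean_se(0.355, 0.018)
        m, v = stats.beta.stats(alpha, beta, moments="mv")
        assert m == pytest.approx(0.355)
        assert np.sqrt(v) == pytest.approx(0.018)

    def test_beta_variance_bound(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_mean_se(0.5, 0.5)

    def test_gamma_closed_form(self):
        shape, scale = gamma_from_mean_se(100, 25)
        assert (shape, scale) == (16.0, 6.25)

    @given(mean=st.floats(0.1, 1000), se=st.floats(0.01, 100))
    def test_gamma_mean_identity(self, mean, se):
        shape, scale = gamma_from_mean_se(mean, se)
        assert shape * scale == pytest.approx(mean)
        assert np.sqrt(shape) * scale == pytest.approx(se)

    def test_pct_range_to_se(self):
        assert se_from_pct_range(100) == pytest.approx(12.755, abs=1e-3)
        assert se_from_pct_range(200) == pytest.approx(2 * se_from_pct_range(100))

    def test_degenerate_draws_return_mean(self):
        rng = np.random.default_rng(0)
        assert draw_beta(0.3, 0.0, rng) == 0.3
        assert draw_gamma(100.0, 0.0, rng) == 100.0

    @pytest.mark.parametrize(
        "sampler,args",
        [
            (draw_beta, (0.065, 0.003)),
            (draw_gamma, (100.0, 25.0)),
            (draw_scaled_beta, (0.035, 0.00625, 0.0, 0.05)),
        ],
    )
    def test_sampler_moment_recovery(self, sampler, args):
        """Empirical mean/SD of 1e5 draws match the target within 3 SE."""
        rng = np.random.default_rng(42)
        n = 100_000
        draws = sampler(*args, rng, size=n)
        mean, se = args[0], args[1]
        assert abs(draws.mean() - mean) < 3 * se / np.sqrt(n)
        # SD of the sample SD is ~ se/sqrt(2n) for near-normal draws
        assert abs(draws.std(ddof=1) - se) < 5 * se / np.sqrt(2 * n)


class TestProfileSampling:
    def test_zero_se_returns_input_unchanged(self, brv_profile):
        rng = np.random.default_rng(0)
        fixed = TransitionProfile("BRV", 0.065, 0.355, 0.370, 0.210)
        assert sample_transition_profile(fixed, rng) is fixed

    def test_sampled_mean_recovers_published_value(self, brv_profile):
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_transition_profile(brv_profile, rng).p_sf for _ in range(20_000)]
        )
        assert abs(draws.mean() - 0.065) < 3 * 0.003 / np.sqrt(len(draws))

    def test_all_draws_on_simplex_even_with_large_ses(self):
        profile = TransitionProfile(
            "WIDE", 0.40, 0.35, 0.05, 0.20,
            se_sf=0.15, se_pr=0.15, se_nr=0.01, se_disc=0.12,
        )
        rng = np.random.default_rng(3)
        for _ in range(500):
            drawn = sample_transition_profile(profile, rng)
            assert drawn.probabilities.min() >= 0
            assert drawn.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def degenerate_run():
    config = zero_se_config()
    return config, run_psa(
        config.transition_profiles(),
        config.cost_models(),
        config.model_spec(),
        config.discount_spec(),
        config.psa_config(seed=11, n_iterations=50),
        cost_ses=config.drug_cost_ses(),
        ae_cost_ses=config.ae_drug_cost_ses(),
    )


class TestEngine:
    def test_zero_se_reproduces_deterministic(self, degenerate_run):
        from cohortcea import run_deterministic

        config, result = degenerate_run
        det = run_deterministic(config)
        for name, res in det.items():
            sub = result.iterations[result.iterations["treatment"] == name]
            assert (sub["cost"] == res.cost).all()
            assert (sub["effect"] == res.effect).all()

    def test_same_seed_bit_identical(self, config):
        kwargs = dict(
            profiles=config.transition_profiles(),
            cost_models=config.cost_models(),
            model_spec=config.model_spec(),
            discount=config.discount_spec(),
            cost_ses=config.drug_cost_ses(),
            ae_cost_ses=config.ae_drug_cost_ses(),
        )
        a = run_psa(psa=config.psa_config(seed=5, n_iterations=40), **kwargs)
        b = run_psa(psa=config.psa_config(seed=5, n_iterations=40), **kwargs)
        pd.testing.assert_frame_equal(a.iterations, b.iterations)

    def test_small_ses_concentrate_on_deterministic(self, config):
        """Shrinking all SEs tenfold pins iteration means near the base case."""
        from cohortcea import run_deterministic

        shrunk = {}
        for name, t in config.treatments.items():
            tr = t.transitions
            shrunk[name] = t.model_copy(update={
                "transitions": tr.model_copy(update={
                    "se_sf": tr.se_sf / 10, "se_pr": tr.se_pr / 10,
                    "se_nr": tr.se_nr / 10, "se_disc": tr.se_disc / 10,
                }),
                "drug_cost_se": t.drug_cost_se / 10,
            })
        small = config.model_copy(update={
            "treatments": shrunk,
            "services": config.services.model_copy(update={"cost_variation": 0.025}),
            "psa": config.psa.model_copy(update={
                "ae_probability_pct": 0.025, "discount_rate_se": 0.000625,
            }),
        })
        result = run_psa(
            small.transition_profiles(), small.cost_models(), small.model_spec(),
            small.discount_spec(), small.psa_config(seed=2, n_iterations=2000),
            cost_ses=small.drug_cost_ses(), ae_cost_ses=small.ae_drug_cost_ses(),
        )
        det = run_deterministic(small)
        for _, row in result.summary().iterrows():
            assert row["cost"] == pytest.approx(det[row["treatment"]].cost, rel=0.01)
            assert row["effect"] == pytest.approx(det[row["treatment"]].effect, rel=0.01)


class TestPlaneAndCEAC:
    def test_all_dominant_cloud(self):
        result = cloud_result(np.full(100, 0.1), np.full(100, -50.0))
        fractions = icer_plane_quadrants(result, "A", "B")
        assert fractions["SE"] == 1.0

    def test_fractions_sum_to_one(self, cases):
        cloud = cases["symmetric_cloud"]
        result = cloud_result(cloud[:, 0], cloud[:, 1])
        fractions = icer_plane_quadrants(result, "A", "B")
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_symmetric_cloud_quarters(self, cases):
        cloud = cases["symmetric_cloud"]
        result = cloud_result(cloud[:, 0], cloud[:, 1])
        fractions = icer_plane_quadrants(result, "A", "B")
        n = len(cloud)
        for share in fractions.values():
            assert share == pytest.approx(0.25, abs=3 * 0.5 / np.sqrt(n))

    def test_ceac_at_zero_wtp_is_cost_saving_share(self, cases):
        cloud = cases["symmetric_cloud"]
        result = cloud_result(cloud[:, 0], cloud[:, 1])
        table = ceac(result, [0.0])
        assert table["probability"].iloc[0] == pytest.approx(
            np.mean(cloud[:, 1] < 0)
        )

    def test_dominant_everywhere_gives_one(self):
        result = cloud_result(np.full(50, 0.2), np.full(50, -10.0))
        table = ceac(result, [0, 1000, 9000])
        assert (table["probability"] == 1.0).all()

    def test_two_point_cloud_mixture_weight(self):
        # 30% of iterations lie below the WTP line, 70% above
        de = np.full(100, 0.1)
        dc = np.where(np.arange(100) < 30, 50.0, 2000.0)  # icer 500 vs 20000
        result = cloud_result(de, dc)
        table = ceac(result, [1000.0])
        assert table["probability"].iloc[0] == pytest.approx(0.30)

    def test_ceac_monotone_for_positive_gains(self, config):
        result = run_psa(
            config.transition_profiles(), config.cost_models(), config.model_spec(),
            config.discount_spec(), config.psa_config(seed=3, n_iterations=300),
            cost_ses=config.drug_cost_ses(), ae_cost_ses=config.ae_drug_cost_ses(),
        )
        table = ceac(result, np.linspace(0, 12000, 25), comparators=["LCM"])
        pair = result.pair("BRV", "LCM")
        if (pair["delta_effect"] > 0).all():
            assert (np.diff(table["probability"]) >= -1e-12).all()
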