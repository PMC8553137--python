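import math

import numpy as np
import pytest
from scipy.stats import kstest

from conesens.mcmc_fit import (
    FlashResponseModel,
    MCMCConfig,
    interval_distance,
    log_density,
    metropolis_hastings,
    rms_error,
    run_chain,
)
from conesens.parameters import mcmc_hard_constraints, mcmc_soft_ranges
from conesens.synthetic_data import generate_experiment


@pytest.fixture(scope="module")
def clean_target(table10):
    return generate_experiment(table10, intensities=(940,), noise_sd=0.0, seed=0)


@pytest.fixture(scope="module")
def noisy_target(table10):
    return generate_experiment(table10, intensities=(940,), noise_sd=0.5, seed=3, dt=1e-4)


class TestRmsError:
    def test_self_target_is_zero(self, table10, clean_target):
        assert rms_error(table10, clean_target, rtol=1e-8) < 1e-4

    def test_constant_offset_recovered(self, table10, clean_target):
        shifted = generate_experiment(table10, intensities=(940,), noise_sd=0.0, seed=0)
        shifted.drops[940] += 0.7
        assert rms_error(table10, shifted, rtol=1e-8) == pytest.approx(0.7, abs=1e-3)

    def test_noise_floor_matches_noise_sd(self, table10, noisy_target):
        # rms against truth ≈ noise sd (5001 samples ⇒ ±5%)
        assert rms_error(table10, noisy_target, rtol=1e-8) == pytest.approx(0.5, rel=0.05)

    def test_nonexistent_dark_state_is_infinite(self, table10, clean_target):
        p = table10.replace(Jex_sat=3138 * 0.26 / 2 + 1, alpha_min=10.0)
        assert rms_error(p, clean_target) == math.inf


class TestDensity:
    def test_no_penalty_inside_all_intervals(self, table10):
        cfg = MCMCConfig()
        soft = mcmc_soft_ranges()
        inside = table10.replace(G_sigma=700.0, PDE_sigma=80.0, m_cG=2.9)
        lp_pen, _ = log_density(inside, None, soft, cfg)
        assert lp_pen == 0.0

    def test_best_fit_point_pays_for_its_two_excursions(self, table10):
        # the best-fit transducin and PDE densities sit outside their expected
        # intervals; the penalty is exactly γ·ln2 times the summed excursions
        cfg = MCMCConfig(gamma=5.0)
        soft = mcmc_soft_ranges()
        dist = (500 - 253.82) / (1500 - 500) + (115 - 100) / (100 - 10)
        lp_pen, _ = log_density(table10, None, soft, cfg)
        assert lp_pen == pytest.approx(-cfg.gamma * math.log(2) * dist)

    def test_one_interval_width_excursion_halves_density_gamma_times(self, table10):
        cfg = MCMCConfig(gamma=5.0)
        soft = mcmc_soft_ranges()
        r = soft["k_R"]
        inside, _ = log_density(table10, None, soft, cfg, draw={"k_R": r.hi})
        outside, _ = log_density(table10, None, soft, cfg, draw={"k_R": r.hi + r.width()})
        assert inside - outside == pytest.approx(cfg.gamma * math.log(2.0))

    def test_derived_dark_current_outside_K_kills_density(self, table10, clean_target):
        cfg = MCMCConfig()
        # scaling the CNG maximum current pushes J_dark above the allowed 27 pA
        p = table10.replace(JcG_max=table10.JcG_max * 1.3)
        lp, err = log_density(p, clean_target, mcmc_soft_ranges(), cfg, hard=mcmc_hard_constraints())
        assert lp == -math.inf

    def test_best_fit_point_satisfies_K(self, table10, clean_target):
        cfg = MCMCConfig()
        lp, err = log_density(
            table10, clean_target, mcmc_soft_ranges(), cfg, hard=mcmc_hard_constraints()
        )
        assert math.isfinite(lp)

    def test_interval_distance_normalization(self):
        assert interval_distance(5.0, 0.0, 10.0) == 0.0
        assert interval_distance(20.0, 0.0, 10.0) == 1.0
        assert interval_distance(-5.0, 0.0, 10.0) == 0.5


class TestKernel:
    def test_uniform_target_on_box_is_sampled_uniformly(self):
        """MH with a flat in-box density accepts every in-box proposal; the
        1-D marginal must pass a KS uniformity test at the 1% level."""

        def logpi(x):
            return (0.0, 1.0) if 0.0 <= x[0] <= 1.0 else (-math.inf, math.inf)

        rng = np.random.default_rng(11)
        states, _, _, acc = metropolis_hastings(
            logpi, np.array([0.5]), np.array([0.25]), 20_000, rng
        )
        # thin to reduce autocorrelation before the KS test
        sample = states[::20, 0]
        assert kstest(sample, "uniform").pvalue > 0.01

    def test_reversible_pair_acceptance_product_is_one(self):
        # symmetric proposal: a(x→y)·a(y→x) = min(1, r)·min(1, 1/r) = min(r, 1/r)...
        # for the MH ratio r = π(y)/π(x) the product of the two Hastings
        # ratios is exactly 1 (detailed balance of the underlying densities)
        def lp(x):
            return -0.5 * float(x[0]) ** 2

        x, y = np.array([0.3]), np.array([1.1])
        assert math.exp(lp(y) - lp(x)) * math.exp(lp(x) - lp(y)) == pytest.approx(1.0)

    def test_identical_seeds_identical_chains(self, table10, clean_target):
        cfg = MCMCConfig(n_steps=40, seed=9)
        start = {"k_R": 95.0, "k_E": 75.0}
        c1 = run_chain(clean_target, cfg, free_names=("k_R", "k_E"), start=start)
        c2 = run_chain(clean_target, cfg, free_names=("k_R", "k_E"), start=start)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        np.testing.assert_array_equal(c1.accepted, c2.accepted)

    def test_infeasible_start_rejected(self, table10, clean_target):
        cfg = MCMCConfig(n_steps=10)
        with pytest.raises(ValueError):
            run_chain(clean_target, cfg, free_names=("beta_dark",), start={"beta_dark": 900.0})


@pytest.fixture(scope="module")
def short_fit(table10, clean_target):
    cfg = MCMCConfig(n_steps=150, seed=4, proposal_scale=0.005)
    model = FlashResponseModel(clean_target, config=cfg, free_names=("k_R", "k_E", "nu_RG"))
    start = {"k_R": table10.k_R * 1.2, "k_E": table10.k_E * 0.85, "nu_RG": table10.nu_RG * 1.1}
    return model, model.fit(start=start)


class TestChainContracts:
    def test_every_retained_sample_satisfies_K(self, short_fit, table10):
        from conesens.mcmc_fit import _satisfies_hard
        from conesens.parameters import parameter_set_from_draw

        model, res = short_fit
        hard = mcmc_hard_constraints()
        for row in res.chain.samples[::10]:
            draw = dict(zip(res.chain.free_names, row))
            assert _satisfies_hard(draw, parameter_set_from_draw(draw), hard)

    def test_best_error_is_chain_minimum(self, short_fit):
        _, res = short_fit
        assert res.rms == res.chain.errors.min()
        assert res.rms <= res.chain.errors[0]

    def test_summary_reports_fit(self, short_fit):
        _, res = short_fit
        text = res.summary()
        assert "rms error" in text and "k_R" in text and "dark state" in text

    def test_missing_fit_intensity_rejected(self, table10):
        target = generate_experiment(table10, intensities=(40,), noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            FlashResponseModel(target)
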