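"""Mixture engine: truncated priors, likelihood, sampler contract, PPO."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from torpormix import (
    MetabolicDataset,
    MixtureModel,
    PriorSpec,
    RunConfig,
    ThermoParams,
    build_priors,
    log_likelihood,
    ppo,
    run_mcmc,
)
from torpormix.engine import FREE, PriorError, TNZ


def spec23(m_tnz=1.0, tlc=30.0, l95=29.5):
    return PriorSpec(stage="step23", m_tnz=m_tnz, tlc_low=29.0, ta_max=38.0,
                     tlc_fixed=tlc, tlc_l95=l95)


def spec1(m_tnz=1.0):
    return PriorSpec(stage="step1", m_tnz=m_tnz, tlc_low=29.0, ta_max=38.0)


class TestPriors:
    def test_joint_draws_respect_every_truncation(self):
        for spec in (spec1(), spec23()):
            rng = np.random.default_rng(0)
            d = spec.sample(10_000, rng)
            assert np.all(d["tmr"] > 0) and np.all(d["tmr"] <= 0.8 * spec.m_tnz)
            assert np.all(d["tmr"] <= d["m_r"]) and np.all(d["m_r"] <= spec.m_tnz)
            assert np.all(d["t_bt"] >= -5.0)
            assert np.all(d["sd_r"] < 3.0)
            assert np.all(d["sd_c"] >= d["sd_r"] / 5) and np.all(d["sd_c"] <= d["sd_r"])
            assert np.all(d["sd_tnz"] >= d["sd_r"] / 2) and np.all(d["sd_tnz"] <= d["sd_r"])
            # implied conforming Q10 never exceeds 5 on any draw
            tlc = d.get("tlc", np.full(10_000, spec.tlc_fixed or 0.0))
            beta = spec.m_tnz / (d["t_be"] - tlc)
            t_t = d["t_bt"] - d["tmr"] / beta
            q10 = np.exp(10 * np.log(d["m_r"] / d["tmr"]) / (tlc - t_t))
            assert np.all(q10 <= 5.0 + 1e-9)

    def test_step1_tlc_support(self):
        d = spec1().sample(5_000, np.random.default_rng(1))
        assert np.all(d["tlc"] >= 29.0) and np.all(d["tlc"] <= 38.0)

    def test_invalid_configuration_raises(self):
        with pytest.raises(PriorError):
            PriorSpec(stage="step23", m_tnz=1.0, tlc_low=29.0, ta_max=38.0)
        with pytest.raises(PriorError):
            PriorSpec(stage="step1", m_tnz=-1.0, tlc_low=29.0, ta_max=38.0)
        with pytest.raises(PriorError):
            PriorSpec(stage="step1", m_tnz=1.0, tlc_low=40.0, ta_max=38.0)

    def test_build_priors_uses_dataset_ta_max(self):
        data = MetabolicDataset(np.linspace(0, 37.5, 20), np.ones(20))
        spec = build_priors(data, 1.0, "step1", tlc_low=30.0)
        assert spec.ta_max == pytest.approx(37.5)


class TestLogLikelihood:
    P = ThermoParams(m_tnz=1.0, t_lc=30.0, t_be=38.0, t_bt=2.0, tmr=0.05,
                     m_r=0.4, sd_tnz=0.05, sd_r=0.07, sd_c=0.03)

    def test_mode_value_on_the_curve(self):
        from torpormix import predict_euthermic

        ta = 20.0
        m = predict_euthermic(ta, self.P)
        ll = log_likelihood((ta, m), self.P, "euthermy")
        assert ll == pytest.approx(-math.log(self.P.sd_r * math.sqrt(2 * math.pi)))

    @pytest.mark.parametrize("state,ta", [
        ("tnz", 33.0), ("euthermy", 20.0), ("torpor", 10.0), ("torpor", -1.0),
    ])
    def test_density_normalizes(self, state, ta):
        from torpormix import predict_euthermic, predict_torpor

        mu = {"tnz": self.P.m_tnz,
              "euthermy": predict_euthermic(ta, self.P),
              "torpor": predict_torpor(ta, self.P)}[state]
        total, _ = quad(
            lambda m: math.exp(log_likelihood((ta, m), self.P, state)),
            mu - 3, mu + 3, points=[mu], limit=200,
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_state_discrimination(self):
        from torpormix import predict_euthermic

        ta = 15.0
        m = predict_euthermic(ta, self.P)  # far above the torpor curve
        assert log_likelihood((ta, m), self.P, "euthermy") > log_likelihood(
            (ta, m), self.P, "torpor"
        )


class TestRunMcmc:
    def _model(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        ta = rng.uniform(0, 38, n)
        p = ThermoParams(m_tnz=1.0, t_lc=30.0, t_be=38.0, t_bt=2.0, tmr=0.05,
                         m_r=0.4, sd_tnz=0.05, sd_r=0.07, sd_c=0.03)
        from torpormix import predict_euthermic, predict_torpor

        below = ta <= 30.0
        torpid = below & (rng.random(n) < 0.5)
        m = np.where(
            torpid, predict_torpor(ta, p),
            np.where(below, predict_euthermic(ta, p), 1.0),
        ) + rng.normal(0, 0.04, n)
        m = np.abs(m) + 1e-9
        clamped = np.where(ta > 30.0, TNZ, FREE)
        return MixtureModel(ta, m / m.mean(), spec23(m_tnz=float(np.mean(m[ta > 30]) / m.mean())), clamped)

    def test_bookkeeping_and_truncation_soundness(self, quick_mcmc):
        config = RunConfig(**quick_mcmc)
        model = self._model()
        post = run_mcmc(model, config, seed=11)
        expected = (config.iterations - config.burn_in) // config.thinning
        for name, arr in post.draws.items():
            assert arr.shape == (3, expected)
        assert post.state_draws.shape == (3, expected, model.n_below)
        spec = model.spec
        for chain in range(3):
            for i in range(0, expected, 97):
                theta = {k: post.draws[k][chain, i] for k in spec.sampled_names}
                assert spec.in_support(theta)

    def test_chain_order_does_not_change_summaries(self, quick_mcmc):
        config = RunConfig(**quick_mcmc)
        post = run_mcmc(self._model(), config, seed=11)
        med = post.median("t_be")
        post.draws = {k: v[::-1].copy() for k, v in post.draws.items()}
        assert post.median("t_be") == med

    def test_prior_only_run_recovers_prior(self, quick_mcmc):
        """With no data the posterior is the prior and the overlap is total."""
        spec = spec23()
        model = MixtureModel(np.empty(0), np.empty(0), spec, np.empty(0, int))
        post = run_mcmc(model, RunConfig(**quick_mcmc), seed=5)
        prior = spec.sample(6_000, np.random.default_rng(6))
        assert ppo(prior["tmr"], post.stacked("tmr")) > 85.0


class TestPpo:
    def test_identical_samples_fully_overlap(self):
        x = np.random.default_rng(0).normal(0, 1, 20_000)
        assert ppo(x, x.copy()) == pytest.approx(100.0, abs=2.0)

    def test_disjoint_supports_do_not_overlap(self):
        rng = np.random.default_rng(0)
        assert ppo(rng.normal(0, 0.1, 5_000), rng.normal(100, 0.1, 5_000)) < 2.0

    def test_unit_gaussians_match_closed_form(self):
        # overlap of N(0,1) and N(1,1) is 2*Phi(-1/2)
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 50_000)
        b = rng.normal(1, 1, 50_000)
        closed = 200.0 * norm.cdf(-0.5)
        assert ppo(a, b) == pytest.approx(closed, abs=2.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 5_000), rng.normal(0.5, 2, 5_000)
        assert ppo(a, b) == pytest.approx(ppo(b, a), abs=1e-9)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            ppo(np.ones(100), np.random.default_rng(0).normal(size=100))
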