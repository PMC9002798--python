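"""Three-step pipeline wrapped as a scikit-learn style estimator.

``TorporClassifier.fit`` takes paired (T_a, M) measurements and runs:

1. the rolling-regression screen for ``T_lc_low`` followed by a Bayesian run
   estimating T_lc (and M_TNZ as the mean M above it);
2. a mixture run over the full dataset producing state membership
   probabilities and the automatic euthermy/torpor overrides;
3. a final mixture run with the automatic assignments clamped, yielding the
   reported thermoregulatory parameters, per-measurement confidence and
   validity, and identifiability diagnostics.

The estimator composes with sklearn tooling (``get_params``/``set_params``,
``fit_predict``); fitted results live in trailing-underscore attributes.
"""

from __future__ import annotations

from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import assign as assign_mod
from .boundary import BoundaryResult, estimate_tlc, find_tlc_low
from .engine import (
    EUTHERMY,
    FREE,
    TNZ,
    TORPOR,
    MixtureModel,
    PosteriorSamples,
    build_priors,
    ppo_report,
    run_mcmc,
)
from .io import MetabolicDataset, RunConfig
from .model import ThermoParams

__all__ = ["TorporClassifier", "fit_pipeline"]

#: parameters reported with prior-posterior overlap diagnostics
_PPO_PARAMS = ["t_be", "t_bt", "tmr", "m_r"]
_METABOLIC = {"tmr", "m_r", "sd_tnz", "sd_r", "sd_c"}  # rescaled to input units


def _as_dataset(X, y=None) -> MetabolicDataset:
    if isinstance(X, MetabolicDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return MetabolicDataset.from_frame(X)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("X must be a (n, 2) array of (ta, m) pairs")
    labels = None if y is None else np.asarray(y, dtype=object)
    return MetabolicDataset(arr[:, 0], arr[:, 1], labels)


class TorporClassifier(BaseEstimator):
    """Assign metabolic-rate measurements to torpor, euthermy or the TNZ.

    Parameters
    ----------
    chains, iterations, burn_in, thinning :
        MCMC run protocol (defaults: 3 chains of 50,000 iterations, 30,000
        burn-in, thinning 10 — 2,000 retained draws per chain).
    bp_alpha, slope_alpha :
        Significance levels of the step-1 Breusch-Pagan and slope tests.
    validity_threshold, validity_alpha :
        Confidence threshold and binomial-test level for assignment validity.
    ppo_threshold :
        Prior-posterior overlap (percent) at or above which a parameter is
        reported unidentifiable.
    rhat_threshold :
        Convergence bound on R-hat.
    random_state :
        Seed for every source of randomness in the fit.

    Attributes
    ----------
    boundary_ : step-1 screen result (``tlc_low`` plus window diagnostics).
    tlc_low_, tlc_, tlc_ci_ : boundary underestimate, posterior-median T_lc
        and its 95% credible interval (deg C).
    mtnz_ : plateau metabolic rate, input units.
    posterior_step1_, posterior_step2_, posterior_ : retained draws of the
        three runs (final run last).
    assignment_ : per-measurement table (state, membership, confidence,
        validity, predicted M with credible interval), input units.
    labels_ : the ``state`` column of ``assignment_`` as an array.
    params_ : posterior-median ThermoParams in input units.
    ppo_ : parameter -> prior-posterior overlap percent.
    identifiable_ : parameter -> bool (overlap below threshold).
    rhat_ : final-run R-hat per parameter (plus ``tlc`` from step 1).
    converged_ : all R-hat below threshold in every run.
    """

    def __init__(
        self,
        chains: int = 3,
        iterations: int = 50_000,
        burn_in: int = 30_000,
        thinning: int = 10,
        bp_alpha: float = 0.05,
        slope_alpha: float = 0.01,
        validity_threshold: float = 0.8,
        validity_alpha: float = 0.05,
        ppo_threshold: float = 75.0,
        rhat_threshold: float = 1.1,
        random_state: Optional[int] = None,
    ):
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.bp_alpha = bp_alpha
        self.slope_alpha = slope_alpha
        self.validity_threshold = validity_threshold
        self.validity_alpha = validity_alpha
        self.ppo_threshold = ppo_threshold
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # -- configuration ------------------------------------------------------

    def _run_config(self) -> RunConfig:
        return RunConfig(
            chains=self.chains,
            iterations=self.iterations,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=self.random_state,
            bp_alpha=self.bp_alpha,
            slope_alpha=self.slope_alpha,
            validity_threshold=self.validity_threshold,
            validity_alpha=self.validity_alpha,
            ppo_threshold=self.ppo_threshold,
            rhat_threshold=self.rhat_threshold,
        )

    def _seeds(self) -> np.ndarray:
        root = 0 if self.random_state is None else int(self.random_state)
        return np.random.SeedSequence(root).generate_state(4) % (2**31)

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y=None) -> "TorporClassifier":
        """Run the full three-step pipeline on (T_a, M) data."""
        data = _as_dataset(X, y)
        config = self._run_config()
        s1, s2, s3, s_ppo = (int(s) for s in self._seeds())

        # step 1: boundary screen, then Bayesian T_lc
        self.boundary_ = find_tlc_low(data, self.bp_alpha, self.slope_alpha)
        self.tlc_low_ = self.boundary_.tlc_low
        post1, m_tnz_norm, m_mean = estimate_tlc(
            data, self.tlc_low_, config, seed=s1
        )
        self.posterior_step1_ = post1
        self.m_mean_ = m_mean
        self.tlc_ = post1.median("tlc")
        self.tlc_ci_ = post1.ci("tlc")
        self.tlc_draws_ = post1.stacked("tlc")
        self.mtnz_ = m_tnz_norm * m_mean

        # step 2: pre-assignment over the full dataset
        m_norm = data.m / m_mean
        spec2 = build_priors(
            data, m_tnz_norm, "step23",
            tlc_fixed=self.tlc_, tlc_l95=self.tlc_ci_[0],
        )
        clamped2 = np.where(data.ta > self.tlc_, TNZ, FREE)
        model2 = MixtureModel(data.ta, m_norm, spec2, clamped2)
        post2 = run_mcmc(model2, config, seed=s2)
        post2.m_mean = m_mean
        self.posterior_step2_ = post2
        pre = assign_mod.preassign(data, post2, self.tlc_, m_tnz_norm, m_mean)
        self.preassignment_ = pre

        # step 3: final run with automatic assignments clamped
        self.assignment_, post3 = assign_mod.final_assign(
            data, pre, spec2, self.tlc_, m_mean, self.tlc_draws_, config,
            seed=s3, validity_threshold=self.validity_threshold,
            validity_alpha=self.validity_alpha,
        )
        self.posterior_ = post3
        self.labels_ = self.assignment_["state"].to_numpy()

        # diagnostics
        reports = ppo_report(
            spec2, post3, _PPO_PARAMS, seed=s_ppo,
            threshold=self.ppo_threshold,
        )
        self.ppo_ = {r.parameter: r.overlap_percent for r in reports}
        self.identifiable_ = {r.parameter: r.identifiable for r in reports}
        self.rhat_ = dict(post3.rhat)
        self.rhat_["tlc"] = post1.rhat["tlc"]
        self.converged_ = post1.converged and post2.converged and post3.converged
        self.messages_ = post1.messages + post2.messages + post3.messages

        self.params_ = self._median_params()
        self.n_features_in_ = 2
        return self

    def _median_params(self) -> ThermoParams:
        p = self.posterior_
        mm = self.m_mean_
        return ThermoParams(
            m_tnz=self.mtnz_,
            t_lc=self.tlc_,
            t_be=p.median("t_be"),
            t_bt=p.median("t_bt"),
            tmr=p.median("tmr") * mm,
            m_r=p.median("m_r") * mm,
            sd_tnz=p.median("sd_tnz") * mm,
            sd_r=p.median("sd_r") * mm,
            sd_c=p.median("sd_c") * mm,
            p_t=p.median("p_t"),
            p_e=1.0 - p.median("p_t"),
        )

    # -- inference on new data ----------------------------------------------

    def predict_proba(self, X) -> pd.DataFrame:
        """Posterior state probabilities for new (T_a, M) pairs.

        Averages the conditional state probability over the retained final
        draws; records above the fitted T_lc are assigned to the plateau with
        probability one, mirroring the pipeline's hard split.
        """
        self._check_fitted()
        data = _as_dataset(X)
        post = self.posterior_
        ta, m_norm = data.ta, data.m / self.m_mean_
        n = len(data)
        out = np.zeros((n, 3))
        above = ta > self.tlc_
        out[above, 0] = 1.0
        idx = np.flatnonzero(~above)
        if idx.size:
            spec = post.spec
            t_be = post.stacked("t_be")[:, None]
            beta_e = -spec.m_tnz / (t_be - self.tlc_)
            mu_e = spec.m_tnz + beta_e * (ta[idx][None, :] - self.tlc_)
            sd_r = post.stacked("sd_r")[:, None]
            tmr = post.stacked("tmr")[:, None]
            m_r = post.stacked("m_r")[:, None]
            t_bt = post.stacked("t_bt")[:, None]
            t_t = t_bt + tmr / beta_e
            beta_c = np.where(m_r > tmr, np.log(m_r / tmr) / (self.tlc_ - t_t), 0.0)
            reg = ta[idx][None, :] < t_t
            mu_t = np.where(
                reg, beta_e * (ta[idx][None, :] - t_bt),
                m_r * np.exp(beta_c * (ta[idx][None, :] - self.tlc_)),
            )
            sd_t = np.where(reg, sd_r, post.stacked("sd_c")[:, None])
            p_t = post.stacked("p_t")[:, None]
            log_e = (
                np.log(1 - p_t) - np.log(sd_r)
                - 0.5 * ((m_norm[idx][None, :] - mu_e) / sd_r) ** 2
            )
            log_t = (
                np.log(p_t) - np.log(sd_t)
                - 0.5 * ((m_norm[idx][None, :] - mu_t) / sd_t) ** 2
            )
            hi = np.maximum(log_e, log_t)
            we, wt = np.exp(log_e - hi), np.exp(log_t - hi)
            prob_t = (wt / (we + wt)).mean(axis=0)
            out[idx, 1] = 1.0 - prob_t
            out[idx, 2] = prob_t
        return pd.DataFrame(out, columns=["tnz", "euthermy", "torpor"])

    def predict(self, X) -> np.ndarray:
        """Most probable state for new (T_a, M) pairs."""
        proba = self.predict_proba(X)
        return proba.columns.to_numpy(dtype=object)[
            proba.to_numpy().argmax(axis=1)
        ]

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_

    def predict_metabolic_rate(
        self, ta, state: str = "euthermy", level: float = 0.95
    ) -> pd.DataFrame:
        """Posterior median and credible band of a state curve, input units."""
        self._check_fitted()
        ta = np.atleast_1d(np.asarray(ta, float))
        code = {"tnz": TNZ, "euthermy": EUTHERMY, "torpor": TORPOR}[state]
        draws = assign_mod.predicted_curve_draws(
            self.posterior_, ta, code, self.tlc_, self.posterior_.spec.m_tnz
        ) * self.m_mean_
        lo = (1 - level) / 2
        return pd.DataFrame(
            {
                "ta": ta,
                "median": np.median(draws, axis=0),
                "lo": np.quantile(draws, lo, axis=0),
                "hi": np.quantile(draws, 1 - lo, axis=0),
            }
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> Dict:
        """JSON-ready summary: parameters (input units), CIs, R-hat, PPO."""
        self._check_fitted()
        post = self.posterior_
        mm = self.m_mean_
        params = {}
        for name in post.draws:
            scale = mm if name in _METABOLIC else 1.0
            lo, hi = post.ci(name)
            params[name] = dict(
                median=post.median(name) * scale,
                lo95=lo * scale,
                hi95=hi * scale,
                rhat=self.rhat_.get(name),
                ppo=self.ppo_.get(name),
                identifiable=self.identifiable_.get(name),
            )
        # derived torpor breakpoint
        t_be = post.stacked("t_be")
        beta_e = -post.spec.m_tnz / (t_be - self.tlc_)
        t_t = post.stacked("t_bt") + post.stacked("tmr") / beta_e
        q = np.quantile(t_t, [0.5, 0.025, 0.975])
        params["t_t"] = dict(median=float(q[0]), lo95=float(q[1]),
                             hi95=float(q[2]))
        lo1, hi1 = self.tlc_ci_
        return dict(
            tlc_low=self.tlc_low_,
            tlc=dict(median=self.tlc_, lo95=lo1, hi95=hi1,
                     rhat=self.rhat_["tlc"]),
            m_tnz=self.mtnz_,
            m_mean=mm,
            parameters=params,
            converged=self.converged_,
            messages=self.messages_,
            n_valid=int(self.assignment_["valid"].sum()),
            n_records=int(len(self.assignment_)),
        )

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise RuntimeError("this TorporClassifier instance is not fitted")


def fit_pipeline(
    data: Union[MetabolicDataset, pd.DataFrame],
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> TorporClassifier:
    """Functional entry point: run the three-step pipeline and return the
    fitted estimator."""
    config = config or RunConfig()
    clf = TorporClassifier(
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        thinning=config.thinning,
        bp_alpha=config.bp_alpha,
        slope_alpha=config.slope_alpha,
        validity_threshold=config.validity_threshold,
        validity_alpha=config.validity_alpha,
        ppo_threshold=config.ppo_threshold,
        rhat_threshold=config.rhat_threshold,
        random_state=seed if seed is not None else config.seed,
    )
    return clf.fit(data)
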