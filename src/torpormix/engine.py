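"""Bayesian mixture engine shared by all three pipeline steps.

The model: every measurement below T_lc belongs to one of two latent states —
euthermic rest or torpor — with dataset-level mixing fractions under a flat
Dirichlet prior; measurements above T_lc belong to the thermoneutral plateau.
Conditional on its state, M is Gaussian around the state's thermoregulatory
curve with a state-specific scatter (``sd_tnz`` on the plateau, ``sd_r`` on
the linear euthermic/regulated branches, ``sd_c`` on the conforming branch).
All computation happens on mean-normalized M (measurements divided by their
mean), which puts every dataset on a common scale; results are rescaled to
input units downstream.

Priors are truncated Gaussians with mean 0 and precision 0.001 (location
parameters) or uniforms (scatter parameters), with biologically motivated
truncations; the T_bt upper bound is *parameter dependent*, enforcing both
that the torpor breakpoint T_t stays below the (lower 95% bound of the)
T_lc and that the conforming branch's Q10 never exceeds 5.

Sampling is adaptive random-walk Metropolis on the *collapsed* target: the
latent state indicators are marginalized out of the likelihood (a
two-component mixture density per record), proposals outside the joint
truncated support are rejected outright, and the indicators are re-drawn
from their exact conditional at each retained iteration — the joint
posterior is identical to sampling the indicators explicitly, but the chain
can cross between mixture labellings that per-record Gibbs updates lock in.
The run protocol is 3 chains of 50,000 iterations, 30,000 burn-in, thinning
10 (2,000 retained draws per chain); convergence is judged by R-hat < 1.1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import gaussian_kde, truncnorm

from .io import MetabolicDataset, RunConfig
from .model import (
    MAX_Q10,
    TBT_FLOOR,
    TMR_FRACTION_OF_MTNZ,
    ThermoParams,
    predict_euthermic,
    predict_torpor,
)

__all__ = [
    "PriorSpec",
    "PriorError",
    "MixtureModel",
    "PosteriorSamples",
    "build_priors",
    "log_likelihood",
    "run_mcmc",
    "ppo",
    "PpoReport",
]

#: Prior scale of the location parameters: precision 0.001 => SD = sqrt(1000).
PRIOR_SIGMA = math.sqrt(1000.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
#: Euthermic-line upper anchor for T_be (deg C).
TBE_CEILING = 50.0
#: Upper bound of the uniform prior on sd_r (mean-normalized scale).
SDR_CEILING = 3.0

# latent state codes used throughout
TNZ, EUTHERMY, TORPOR = 0, 1, 2
STATE_NAMES = {TNZ: "tnz", EUTHERMY: "euthermy", TORPOR: "torpor"}
FREE = -1


class PriorError(ValueError):
    """A prior support is empty or a prior argument inadmissible."""


def _log_truncnorm(x: float, lo: float, hi: float) -> float:
    """Log density of N(0, PRIOR_SIGMA^2) truncated to [lo, hi]."""
    z = ndtr(hi / PRIOR_SIGMA) - ndtr(lo / PRIOR_SIGMA)
    if z <= 0:
        return -np.inf
    return (
        -0.5 * (x / PRIOR_SIGMA) ** 2
        - math.log(PRIOR_SIGMA)
        - _LOG_SQRT_2PI
        - math.log(z)
    )


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-prior specification for one sampling stage.

    ``stage="step1"`` samples T_lc itself (truncated between ``tlc_low`` and
    the warmest T_a in the dataset); ``stage="step23"`` holds T_lc fixed at
    the step-1 posterior median and uses the step-1 lower 95% credible bound
    ``tlc_l95`` inside the T_bt truncation.  ``m_tnz`` is on the
    mean-normalized scale.
    """

    stage: str
    m_tnz: float
    tlc_low: float
    ta_max: float
    tlc_fixed: Optional[float] = None
    tlc_l95: Optional[float] = None

    def __post_init__(self):
        if self.stage not in ("step1", "step23"):
            raise PriorError(f"unknown stage {self.stage!r}")
        if self.m_tnz <= 0:
            raise PriorError("m_tnz must be positive")
        if self.stage == "step1":
            if self.ta_max < self.tlc_low:
                raise PriorError(
                    "empty T_lc support: max T_a below T_lc_low"
                )
        else:
            if self.tlc_fixed is None or self.tlc_l95 is None:
                raise PriorError("step23 needs tlc_fixed and tlc_l95")

    # -- supports -----------------------------------------------------------

    @property
    def sampled_names(self) -> List[str]:
        names = ["t_be", "t_bt", "tmr", "m_r", "sd_tnz", "sd_r", "sd_c", "p_t"]
        if self.stage == "step1":
            names = ["tlc"] + names
        return names

    @property
    def tmr_upper(self) -> float:
        return TMR_FRACTION_OF_MTNZ * self.m_tnz

    def tlc_of(self, theta: Dict[str, float]) -> float:
        return theta["tlc"] if self.stage == "step1" else self.tlc_fixed

    def tbt_upper(self, theta: Dict[str, float]) -> float:
        """Parameter-dependent T_bt ceiling.

        Enforces (i) the torpor breakpoint T_t below the lower 95% credible
        bound of T_lc and (ii) conforming-branch Q10 <= 5.
        Condition (i) is imposed on T_bt itself, which implies it for
        T_t < T_bt: keeping the regulated line's zero-metabolism intercept —
        the torpid body-temperature setpoint — below the TNZ prevents the
        regulated-torpor line from impersonating the euthermic line whenever
        the T_lc anchor is slightly misplaced, and holds for every
        heterotherm the model describes.  In step 1 the screen's T_lc_low —
        the only lower bound on T_lc available before the run — stands in
        for the credible bound.
        """
        tlc = self.tlc_of(theta)
        abs_beta = self.m_tnz / (theta["t_be"] - tlc)
        shift = theta["tmr"] / abs_beta
        u1 = self.tlc_low if self.stage == "step1" else self.tlc_l95
        u2 = tlc - 10.0 * math.log(theta["m_r"] / theta["tmr"]) / math.log(MAX_Q10) + shift
        return min(u1, u2)

    def in_support(self, theta: Dict[str, float]) -> bool:
        """Joint admissibility of a full parameter dictionary."""
        if self.stage == "step1":
            if not (self.tlc_low <= theta["tlc"] <= self.ta_max):
                return False
        tlc = self.tlc_of(theta)
        if not (tlc < theta["t_be"] <= TBE_CEILING):
            return False
        if not (0.0 < theta["tmr"] <= self.tmr_upper):
            return False
        if not (theta["tmr"] <= theta["m_r"] <= self.m_tnz):
            return False
        if not (TBT_FLOOR <= theta["t_bt"] <= self.tbt_upper(theta)):
            return False
        if not (0.0 < theta["sd_r"] < SDR_CEILING):
            return False
        if not (theta["sd_r"] / 5.0 <= theta["sd_c"] <= theta["sd_r"]):
            return False
        if not (theta["sd_r"] / 2.0 <= theta["sd_tnz"] <= theta["sd_r"]):
            return False
        if not (0.0 <= theta["p_t"] <= 1.0):
            return False
        return True

    def log_prior(self, theta: Dict[str, float]) -> float:
        """Joint log prior density (normalization constants included, since
        several truncation bounds depend on other parameters)."""
        if not self.in_support(theta):
            return -np.inf
        lp = 0.0
        if self.stage == "step1":
            lp += _log_truncnorm(theta["tlc"], self.tlc_low, self.ta_max)
        tlc = self.tlc_of(theta)
        lp += _log_truncnorm(theta["t_be"], tlc, TBE_CEILING)
        lp += _log_truncnorm(theta["tmr"], 0.0, self.tmr_upper)
        lp += _log_truncnorm(theta["m_r"], theta["tmr"], self.m_tnz)
        lp += _log_truncnorm(theta["t_bt"], TBT_FLOOR, self.tbt_upper(theta))
        lp += -math.log(SDR_CEILING)                       # sd_r ~ U(0, 3)
        lp += -math.log(0.8 * theta["sd_r"])               # sd_c ~ U(sd_r/5, sd_r)
        lp += -math.log(0.5 * theta["sd_r"])               # sd_tnz ~ U(sd_r/2, sd_r)
        return lp                                          # p_t ~ Beta(1,1): 0

    # -- prior sampling -----------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        """Draw ``n`` joint prior vectors (sequential conditional sampling,
        rejecting the rare draws whose T_bt support is empty)."""

        def tn(lo, hi, size):
            a, b = np.asarray(lo) / PRIOR_SIGMA, np.asarray(hi) / PRIOR_SIGMA
            return truncnorm.rvs(a, b, scale=PRIOR_SIGMA, size=size, random_state=rng)

        out = {k: np.empty(n) for k in self.sampled_names}
        todo = np.arange(n)
        for _ in range(1000):
            k = todo.size
            if k == 0:
                break
            if self.stage == "step1":
                tlc = tn(self.tlc_low, self.ta_max, k)
            else:
                tlc = np.full(k, self.tlc_fixed)
            t_be = tn(tlc, TBE_CEILING, k)
            tmr = tn(1e-12, self.tmr_upper, k)
            m_r = tn(tmr, self.m_tnz, k)
            sd_r = rng.uniform(1e-9, SDR_CEILING, k)
            sd_c = rng.uniform(sd_r / 5.0, sd_r)
            sd_tnz = rng.uniform(sd_r / 2.0, sd_r)
            p_t = rng.uniform(0.0, 1.0, k)
            abs_beta = self.m_tnz / (t_be - tlc)
            shift = tmr / abs_beta
            tlc_ref = self.tlc_low if self.stage == "step1" else self.tlc_l95
            upper = np.minimum(
                np.full(k, tlc_ref),
                tlc - 10.0 * np.log(m_r / tmr) / math.log(MAX_Q10) + shift,
            )
            ok = upper > TBT_FLOOR
            idx = todo[ok]
            if self.stage == "step1":
                out["tlc"][idx] = tlc[ok]
            out["t_be"][idx] = t_be[ok]
            out["tmr"][idx] = tmr[ok]
            out["m_r"][idx] = m_r[ok]
            out["sd_r"][idx] = sd_r[ok]
            out["sd_c"][idx] = sd_c[ok]
            out["sd_tnz"][idx] = sd_tnz[ok]
            out["p_t"][idx] = p_t[ok]
            out["t_bt"][idx] = tn(TBT_FLOOR, upper[ok], int(ok.sum()))
            todo = todo[~ok]
        if todo.size:
            raise PriorError(
                "could not draw from the joint prior: the T_bt support "
                "(Q10 and T_t constraints) is almost surely empty"
            )
        return out


def build_priors(
    data: MetabolicDataset,
    m_tnz: float,
    stage: str,
    tlc_low: Optional[float] = None,
    tlc_fixed: Optional[float] = None,
    tlc_l95: Optional[float] = None,
) -> PriorSpec:
    """Construct the stage-appropriate prior specification.

    ``m_tnz`` must already be on the mean-normalized scale used for sampling.
    """
    if stage == "step1" and tlc_low is None:
        raise PriorError("step1 priors need tlc_low")
    return PriorSpec(
        stage=stage,
        m_tnz=m_tnz,
        tlc_low=tlc_low if tlc_low is not None else -np.inf,
        ta_max=float(np.max(data.ta)),
        tlc_fixed=tlc_fixed,
        tlc_l95=tlc_l95,
    )


def log_likelihood(
    record: tuple[float, float], params: ThermoParams, state: str
) -> float:
    """Gaussian log density of one normalized (T_a, M) record given a state.

    Scatter is ``sd_tnz`` on the plateau, ``sd_r`` on the euthermic line and
    the regulated-torpor branch, ``sd_c`` on the conforming branch.
    """
    ta, m = record
    if state == "tnz":
        mu, sd = params.m_tnz, params.sd_tnz
    elif state == "euthermy":
        mu, sd = predict_euthermic(ta, params), params.sd_r
    elif state == "torpor":
        mu = predict_torpor(ta, params)
        sd = params.sd_r if ta < params.t_t else params.sd_c
    else:
        raise ValueError(f"unknown state {state!r}")
    return -math.log(sd) - _LOG_SQRT_2PI - 0.5 * ((m - mu) / sd) ** 2


@dataclass
class PosteriorSamples:
    """Retained draws of one MCMC run.

    ``draws[name]`` has shape ``(chains, retained)``; ``state_draws`` has
    shape ``(chains, retained, n_below)`` with codes 1 (euthermy) and
    2 (torpor) for the records below T_lc, in ``below_index`` order.
    All scalars are on the mean-normalized M scale; ``m_mean`` converts back.
    """

    draws: Dict[str, np.ndarray]
    state_draws: np.ndarray
    below_index: np.ndarray
    clamped: np.ndarray
    rhat: Dict[str, float]
    converged: bool
    messages: List[str]
    m_mean: float
    spec: PriorSpec

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(np.median(self.stacked(name)))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.stacked(name), [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            lo, hi = self.ci(name)
            rows.append(
                dict(parameter=name, median=self.median(name), lo95=lo,
                     hi95=hi, rhat=self.rhat.get(name, np.nan))
            )
        return pd.DataFrame(rows)


class MixtureModel:
    """Likelihood bookkeeping for one run of the mixture sampler.

    Parameters
    ----------
    ta, m_norm : full-length arrays (M already divided by the dataset mean).
    spec : the stage's PriorSpec.
    clamped : full-length int array with codes ``0`` (plateau record, fixed),
        ``1``/``2`` (record clamped to euthermy/torpor by an automatic
        assignment rule), ``-1`` (free: latent state to be sampled).
    """

    def __init__(
        self,
        ta: np.ndarray,
        m_norm: np.ndarray,
        spec: PriorSpec,
        clamped: np.ndarray,
    ):
        self.spec = spec
        self.ta = np.asarray(ta, float)
        self.m = np.asarray(m_norm, float)
        clamped = np.asarray(clamped, int)
        if clamped.shape != self.ta.shape:
            raise ValueError("clamped must match data length")
        tnz_mask = clamped == TNZ
        # plateau likelihood only depends on sd_tnz: cache sufficient stats
        self.n_tnz = int(tnz_mask.sum())
        self.ss_tnz = float(np.sum((self.m[tnz_mask] - spec.m_tnz) ** 2))
        self.below_index = np.flatnonzero(~tnz_mask)
        self.ta_b = self.ta[self.below_index]
        self.m_b = self.m[self.below_index]
        self.clamped_b = clamped[self.below_index]
        self.free_mask = self.clamped_b == FREE
        self.n_below = self.below_index.size
        self.n_clamped_e = int((self.clamped_b == EUTHERMY).sum())
        self.n_clamped_t = int((self.clamped_b == TORPOR).sum())

    # -- likelihood ---------------------------------------------------------

    def loglik(self, theta: Dict[str, float], states: np.ndarray) -> float:
        """Total log likelihood given continuous params and below-T_lc states."""
        sd_r, sd_c = theta["sd_r"], theta["sd_c"]
        tlc = self.spec.tlc_of(theta)
        beta_e = -self.spec.m_tnz / (theta["t_be"] - tlc)
        total = 0.0
        if self.n_tnz:
            sd = theta["sd_tnz"]
            total += (
                -self.n_tnz * (math.log(sd) + _LOG_SQRT_2PI)
                - self.ss_tnz / (2.0 * sd * sd)
            )
        if self.n_below == 0:
            return total
        e_mask = states == EUTHERMY
        if e_mask.any():
            mu = self.spec.m_tnz + beta_e * (self.ta_b[e_mask] - tlc)
            r = self.m_b[e_mask] - mu
            total += (
                -e_mask.sum() * (math.log(sd_r) + _LOG_SQRT_2PI)
                - float(r @ r) / (2.0 * sd_r * sd_r)
            )
        t_mask = states == TORPOR
        if t_mask.any():
            mu, sd = self._torpor_mu_sd(self.ta_b[t_mask], theta, beta_e, tlc)
            r = (self.m_b[t_mask] - mu) / sd
            total += float(
                -np.log(sd).sum() - t_mask.sum() * _LOG_SQRT_2PI - 0.5 * (r @ r)
            )
        return total

    def _torpor_mu_sd(self, ta, theta, beta_e, tlc):
        tmr, m_r, t_bt = theta["tmr"], theta["m_r"], theta["t_bt"]
        t_t = t_bt + tmr / beta_e
        if m_r > tmr:
            beta_c = math.log(m_r / tmr) / (tlc - t_t)
        else:
            beta_c = 0.0
        reg = ta < t_t
        mu = np.where(
            reg,
            -beta_e * t_bt + beta_e * ta,
            m_r * np.exp(beta_c * (ta - tlc)),
        )
        sd = np.where(reg, theta["sd_r"], theta["sd_c"])
        return mu, sd

    def state_logdensities(self, theta: Dict[str, float]) -> np.ndarray:
        """Per-record log densities under each below-T_lc state: shape (n, 2)
        with columns (euthermy, torpor), mixing fractions *not* included."""
        tlc = self.spec.tlc_of(theta)
        beta_e = -self.spec.m_tnz / (theta["t_be"] - tlc)
        sd_r = theta["sd_r"]
        mu_e = self.spec.m_tnz + beta_e * (self.ta_b - tlc)
        le = (
            -math.log(sd_r) - _LOG_SQRT_2PI
            - 0.5 * ((self.m_b - mu_e) / sd_r) ** 2
        )
        mu_t, sd_t = self._torpor_mu_sd(self.ta_b, theta, beta_e, tlc)
        lt = (
            -np.log(sd_t) - _LOG_SQRT_2PI
            - 0.5 * ((self.m_b - mu_t) / sd_t) ** 2
        )
        return np.column_stack([le, lt])

    def loglik_collapsed(self, theta: Dict[str, float]) -> float:
        """Log likelihood with the latent state indicators marginalized out.

        Free records contribute the two-component mixture density
        ``p_e N_e + p_t N_t``; clamped records contribute their own state's
        density together with its mixing-fraction mass (clamped states count
        toward the dataset-level fractions).  Marginalizing the indicators
        decouples the continuous parameters from the current labelling and
        lets the chain cross between mixture modes that per-record Gibbs
        updates cannot reach.
        """
        total = 0.0
        if self.n_tnz:
            sd = theta["sd_tnz"]
            total += (
                -self.n_tnz * (math.log(sd) + _LOG_SQRT_2PI)
                - self.ss_tnz / (2.0 * sd * sd)
            )
        if self.n_below == 0:
            return total
        ld = self.state_logdensities(theta)
        log_pt = math.log(max(theta["p_t"], 1e-300))
        log_pe = math.log(max(1.0 - theta["p_t"], 1e-300))
        free = self.free_mask
        if free.any():
            total += float(
                np.logaddexp(log_pe + ld[free, 0], log_pt + ld[free, 1]).sum()
            )
        if self.n_clamped_e:
            total += float(ld[self.clamped_b == EUTHERMY, 0].sum())
            total += self.n_clamped_e * log_pe
        if self.n_clamped_t:
            total += float(ld[self.clamped_b == TORPOR, 1].sum())
            total += self.n_clamped_t * log_pt
        return total

    def sample_states(
        self, theta: Dict[str, float], rng: np.random.Generator
    ) -> np.ndarray:
        """Draw the below-T_lc state indicators from their exact conditional."""
        states = self.clamped_b.copy().astype(np.int8)
        free = self.free_mask
        if free.any():
            ld = self.state_logdensities(theta)
            a = math.log(max(1.0 - theta["p_t"], 1e-300)) + ld[free, 0]
            b = math.log(max(theta["p_t"], 1e-300)) + ld[free, 1]
            p_torp = expit(b - a)
            states[free] = np.where(
                rng.random(p_torp.size) < p_torp, TORPOR, EUTHERMY
            )
        return states


# proposal scales by parameter kind (normalized-M units / deg C)
_INIT_SCALES = {
    "tlc": 1.0, "t_be": 1.0, "t_bt": 1.0,
    "tmr": 0.05, "m_r": 0.05, "sd_tnz": 0.03, "sd_r": 0.03, "sd_c": 0.03,
    "p_t": 0.1,
}


def _init_theta(spec: PriorSpec, rng: np.random.Generator) -> Dict[str, float]:
    draw = spec.sample(1, rng)
    theta = {k: float(v[0]) for k, v in draw.items()}
    # temper extreme prior draws of the scatter: start inside a plausible range
    theta["sd_r"] = min(theta["sd_r"], 1.0)
    theta["sd_c"] = float(np.clip(theta["sd_c"], theta["sd_r"] / 5, theta["sd_r"]))
    theta["sd_tnz"] = float(np.clip(theta["sd_tnz"], theta["sd_r"] / 2, theta["sd_r"]))
    return theta


def _run_chain(
    model: MixtureModel,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[Dict[str, np.ndarray], np.ndarray]:
    spec = model.spec
    names = list(spec.sampled_names)  # p_t updated by Metropolis like the rest
    for _ in range(200):
        theta = _init_theta(spec, rng)
        if spec.in_support(theta):
            break
    else:
        raise PriorError("could not initialize a chain inside the prior support")

    scales = {k: _INIT_SCALES[k] for k in names}
    acc = {k: 0 for k in names}
    tries = {k: 0 for k in names}

    cur_ll = model.loglik_collapsed(theta)
    cur_lp = spec.log_prior(theta)

    n_keep = config.retained_per_chain
    keep = {k: np.empty(n_keep) for k in names + ["p_e"]}
    keep_states = np.empty((n_keep, model.n_below), dtype=np.int8)
    k_out = 0

    normal = rng.standard_normal
    uniform = rng.random
    for it in range(config.iterations):
        # random-walk Metropolis on each scalar against the collapsed target
        # (state indicators marginalized out; they are re-drawn from their
        # exact conditional at retention time)
        for name in names:
            tries[name] += 1
            prop = dict(theta)
            prop[name] = theta[name] + scales[name] * normal()
            lp = spec.log_prior(prop)
            if lp == -np.inf:
                continue
            ll = model.loglik_collapsed(prop)
            if math.log(uniform()) < (ll + lp) - (cur_ll + cur_lp):
                theta, cur_ll, cur_lp = prop, ll, lp
                acc[name] += 1

        # adapt proposal scales during burn-in, frozen afterwards
        if it < config.burn_in and (it + 1) % 50 == 0:
            for name in names:
                rate = acc[name] / max(tries[name], 1)
                scales[name] = float(
                    np.clip(scales[name] * math.exp(0.6 * (rate - 0.35)),
                            1e-4, 50.0)
                )
                acc[name] = 0
                tries[name] = 0

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
            if k_out < n_keep:
                for name in names:
                    keep[name][k_out] = theta[name]
                keep["p_e"][k_out] = 1.0 - theta["p_t"]
                keep_states[k_out] = model.sample_states(theta, rng)
                k_out += 1
    return keep, keep_states


def _compute_rhat(draws: Dict[str, np.ndarray]) -> Dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        out = {}
        for name, arr in draws.items():
            if np.ptp(arr) == 0:  # degenerate: identical draws everywhere
                out[name] = 1.0
                continue
            out[name] = float(az.rhat(az.convert_to_dataset(arr))["x"])
    return out


def run_mcmc(
    model: MixtureModel,
    config: RunConfig,
    seed: Optional[int] = None,
) -> PosteriorSamples:
    """Run the full multi-chain protocol on one MixtureModel.

    Returns retained draws per chain plus R-hat for every scalar parameter;
    non-convergence (any R-hat at or above the threshold) is reported as a
    message on the result, never as an exception.
    """
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    ss = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(config.chains)]

    per_chain = []
    per_chain_states = []
    for rng in chain_rngs:
        keep, keep_states = _run_chain(model, config, rng)
        per_chain.append(keep)
        per_chain_states.append(keep_states)

    names = list(per_chain[0].keys())
    draws = {
        name: np.stack([c[name] for c in per_chain]) for name in names
    }
    state_draws = np.stack(per_chain_states)

    rhat = _compute_rhat(draws)
    messages = []
    converged = all(r < config.rhat_threshold for r in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items()
               if v >= config.rhat_threshold}
        messages.append(f"non-convergence: R-hat at or above threshold for {bad}")

    return PosteriorSamples(
        draws=draws,
        state_draws=state_draws,
        below_index=model.below_index,
        clamped=model.clamped_b,
        rhat=rhat,
        converged=converged,
        messages=messages,
        m_mean=1.0,
        spec=model.spec,
    )


# ---------------------------------------------------------------------------
# prior-posterior overlap


@dataclass(frozen=True)
class PpoReport:
    """Per-parameter prior-posterior overlap and identifiability verdict."""

    parameter: str
    overlap_percent: float
    identifiable: bool


def ppo(
    prior_draws: np.ndarray,
    posterior_draws: np.ndarray,
    grid_size: int = 512,
) -> float:
    """Percent overlap of two kernel-density estimates.

    Gaussian kernels with the standard plug-in bandwidth on a shared grid
    spanning both samples; overlap is 100 times the integral of the pointwise
    minimum of the two densities.  Symmetric in its arguments, in [0, 100].
    """
    a = np.asarray(prior_draws, float).ravel()
    b = np.asarray(posterior_draws, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("ppo needs at least two draws from each density")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("ppo is undefined for a zero-variance sample")
    kde_a = gaussian_kde(a)
    kde_b = gaussian_kde(b)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    overlap = np.trapezoid(np.minimum(kde_a(grid), kde_b(grid)), grid)
    return float(100.0 * min(overlap, 1.0))


def ppo_report(
    spec: PriorSpec,
    posterior: PosteriorSamples,
    parameters: List[str],
    seed: int = 0,
    n_prior: int = 10_000,
    threshold: float = 75.0,
) -> List[PpoReport]:
    """Overlap of each parameter's posterior with its own sampling prior."""
    rng = np.random.default_rng(seed)
    prior = spec.sample(n_prior, rng)
    out = []
    for name in parameters:
        overlap = ppo(prior[name], posterior.stacked(name))
        out.append(PpoReport(name, overlap, overlap < threshold))
    return out
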