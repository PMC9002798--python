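"""Measurement assignment: pre-assignment, automatic rules, confidence.

Step 2 samples latent state indicators for every measurement below T_lc and
turns the retained draws into state membership probabilities.  Two automatic
rules then override the probabilistic result where the data leave no room for
doubt: a measurement *above* the predicted euthermic curve is euthermic, one
*below* the predicted torpor curve is torpid (both with membership one).  The
override pass only runs when the probabilistic pass assigned at least one
measurement to torpor — otherwise there is no evidence the species uses
torpor at all.  Measurements above T_lc are always assigned to the plateau.

Step 3 re-runs the mixture with the automatically assigned states clamped, so
only measurements lying between the two predicted curves keep a sampled
indicator; the thermoregulatory parameters reported to the user come from
this final run.

Assignment confidence multiplies the winning membership probability by the
probability that the measurement sits on the correct side of T_lc (from the
step-1 T_lc posterior CDF); an exact one-sided binomial test against the
confidence threshold decides validity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .engine import EUTHERMY, FREE, TNZ, TORPOR, PosteriorSamples
from .io import MetabolicDataset

__all__ = [
    "membership_probabilities",
    "predicted_curve_draws",
    "preassign",
    "apply_overrides",
    "final_assign",
    "confidence",
    "validity",
    "build_assignment_table",
]

_STATE_LABEL = {TNZ: "tnz", EUTHERMY: "euthermy", TORPOR: "torpor"}


def membership_probabilities(posterior: PosteriorSamples) -> np.ndarray:
    """Fraction of retained draws in each state, per below-T_lc record.

    Returns an array of shape ``(n_below, 2)`` with columns
    (euthermy, torpor); rows sum to one.  Clamped records trivially have
    probability one for their clamped state.
    """
    n_below = posterior.state_draws.shape[-1]
    if n_below == 0:
        return np.empty((0, 2))
    flat = posterior.state_draws.reshape(-1, n_below)
    p_torp = (flat == TORPOR).mean(axis=0)
    return np.column_stack([1.0 - p_torp, p_torp])


def predicted_curve_draws(
    posterior: PosteriorSamples,
    ta: np.ndarray,
    state: int,
    tlc: float,
    m_tnz: float,
) -> np.ndarray:
    """Draw-wise state-curve values at the given temperatures.

    Shape ``(total_draws, len(ta))``, on the normalized M scale.  The plateau
    "curve" is the constant ``m_tnz`` (not a sampled quantity, so its
    credible band is degenerate).
    """
    ta = np.atleast_1d(np.asarray(ta, float))
    if state == TNZ:
        n = posterior.stacked("t_be").size
        return np.full((n, ta.size), m_tnz)
    t_be = posterior.stacked("t_be")[:, None]
    beta_e = -m_tnz / (t_be - tlc)
    if state == EUTHERMY:
        return m_tnz + beta_e * (ta[None, :] - tlc)
    tmr = posterior.stacked("tmr")[:, None]
    m_r = posterior.stacked("m_r")[:, None]
    t_bt = posterior.stacked("t_bt")[:, None]
    t_t = t_bt + tmr / beta_e
    beta_c = np.where(m_r > tmr, np.log(m_r / tmr) / (tlc - t_t), 0.0)
    reg = ta[None, :] < t_t
    return np.where(
        reg,
        beta_e * (ta[None, :] - t_bt),
        m_r * np.exp(beta_c * (ta[None, :] - tlc)),
    )


@dataclass
class Preassignment:
    """Step-2 outcome: per-record state, membership, and clamp codes.

    ``clamped`` is full-length with engine codes (0 plateau, 1/2 overridden
    euthermy/torpor, -1 still free) and feeds the step-3 run directly.
    """

    state: np.ndarray          # full-length int codes
    membership: np.ndarray     # full-length winning-state probability
    auto: np.ndarray           # full-length bool, True where overridden/plateau
    clamped: np.ndarray        # full-length engine clamp codes
    overrides_applied: bool


def preassign(
    data: MetabolicDataset,
    posterior: PosteriorSamples,
    tlc: float,
    m_tnz: float,
    m_mean: float,
) -> Preassignment:
    """Turn the step-2 posterior into states, memberships and clamp codes."""
    n = len(data)
    state = np.full(n, TNZ, dtype=int)
    membership = np.ones(n)
    below = np.asarray(posterior.below_index, dtype=int)
    probs = membership_probabilities(posterior)
    state[below] = np.where(probs[:, 1] > probs[:, 0], TORPOR, EUTHERMY)
    membership[below] = probs.max(axis=1)

    any_torpor = bool((state[below] == TORPOR).any())
    auto = np.ones(n, dtype=bool)
    auto[below] = False
    clamped = np.full(n, TNZ, dtype=int)
    clamped[below] = FREE

    if any_torpor and below.size:
        m_norm = data.m[below] / m_mean
        pred_e = np.median(
            predicted_curve_draws(posterior, data.ta[below], EUTHERMY, tlc, m_tnz),
            axis=0,
        )
        pred_t = np.median(
            predicted_curve_draws(posterior, data.ta[below], TORPOR, tlc, m_tnz),
            axis=0,
        )
        above_e = m_norm > pred_e
        below_t = m_norm < pred_t
        state[below[above_e]] = EUTHERMY
        state[below[below_t]] = TORPOR
        membership[below[above_e | below_t]] = 1.0
        auto[below[above_e | below_t]] = True
        clamped[below[above_e]] = EUTHERMY
        clamped[below[below_t]] = TORPOR
    return Preassignment(
        state=state,
        membership=membership,
        auto=auto,
        clamped=clamped,
        overrides_applied=any_torpor,
    )


# kept as a named operation for symmetry with the written method description
apply_overrides = preassign


def confidence(
    ta: np.ndarray,
    state: np.ndarray,
    membership: np.ndarray,
    tlc_draws: np.ndarray,
) -> np.ndarray:
    """Assignment confidence: membership times the correct-side probability.

    The side probability is the empirical T_lc posterior CDF at the record's
    T_a for plateau assignments and one minus it for euthermy/torpor; a
    record sitting exactly at the posterior median therefore caps at half its
    membership probability.
    """
    ta = np.atleast_1d(np.asarray(ta, float))
    state = np.atleast_1d(np.asarray(state, int))
    membership = np.atleast_1d(np.asarray(membership, float))
    draws = np.sort(np.asarray(tlc_draws, float))
    below = np.searchsorted(draws, ta, side="left")
    above = np.searchsorted(draws, ta, side="right")
    # midpoint convention for ties, so the posterior median sits at CDF 1/2
    cdf = (below + above) / (2.0 * draws.size)
    side = np.where(state == TNZ, cdf, 1.0 - cdf)
    return membership * side


def validity(
    record_confidence: float,
    posterior_draw_count: int,
    threshold: float = 0.8,
    alpha: float = 0.05,
) -> bool:
    """Exact one-sided binomial test of the confidence against the threshold.

    The retained draws act as Bernoulli trials whose success count is the
    confidence times the number of draws; the assignment is valid when the
    hypothesis "success probability <= threshold" is rejected at ``alpha``.
    A confidence exactly at the threshold can never be valid.
    """
    if posterior_draw_count <= 0:
        raise ValueError("need a positive number of posterior draws")
    successes = int(round(record_confidence * posterior_draw_count))
    res = binomtest(
        successes, posterior_draw_count, p=threshold, alternative="greater"
    )
    return bool(res.pvalue < alpha)


def build_assignment_table(
    data: MetabolicDataset,
    posterior: PosteriorSamples,
    pre: Preassignment,
    tlc: float,
    m_tnz: float,
    m_mean: float,
    tlc_draws: np.ndarray,
    validity_threshold: float = 0.8,
    validity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Final per-measurement table in input units.

    Columns: ``ta, m, state, membership, auto, confidence, valid,
    pred_median, pred_lo95, pred_hi95``.  States of clamped records come from
    the step-2 clamp; free records take the majority state of the final run's
    indicator draws.
    """
    n = len(data)
    state = pre.state.copy()
    membership = pre.membership.copy()
    below = np.asarray(posterior.below_index, dtype=int)
    if below.size:
        probs = membership_probabilities(posterior)
        free = pre.clamped[below] == FREE
        state[below[free]] = np.where(
            probs[free, 1] > probs[free, 0], TORPOR, EUTHERMY
        )
        membership[below[free]] = probs[free].max(axis=1)
        # clamped records keep membership one by construction
        membership[below[~free]] = 1.0

    conf = confidence(data.ta, state, membership, tlc_draws)
    n_draws = posterior.stacked("t_be").size
    valid = np.array([
        validity(c, n_draws, validity_threshold, validity_alpha) for c in conf
    ])

    pred = np.empty((n, 3))
    for code in (TNZ, EUTHERMY, TORPOR):
        mask = state == code
        if not mask.any():
            continue
        draws = predicted_curve_draws(posterior, data.ta[mask], code, tlc, m_tnz)
        pred[mask, 0] = np.median(draws, axis=0)
        pred[mask, 1] = np.quantile(draws, 0.025, axis=0)
        pred[mask, 2] = np.quantile(draws, 0.975, axis=0)
    pred *= m_mean

    table = pd.DataFrame(
        {
            "ta": data.ta,
            "m": data.m,
            "state": [_STATE_LABEL[s] for s in state],
            "membership": membership,
            "auto": pre.auto,
            "confidence": conf,
            "valid": valid,
            "pred_median": pred[:, 0],
            "pred_lo95": pred[:, 1],
            "pred_hi95": pred[:, 2],
        }
    )
    return table


def final_assign(
    data: MetabolicDataset,
    pre: Preassignment,
    spec,
    tlc: float,
    m_mean: float,
    tlc_draws: np.ndarray,
    config,
    seed: Optional[int] = None,
    validity_threshold: float = 0.8,
    validity_alpha: float = 0.05,
) -> Tuple[pd.DataFrame, PosteriorSamples]:
    """Step 3: re-run the mixture with automatic assignments clamped.

    Only measurements between the predicted curves keep a sampled state
    indicator; the returned posterior carries the reported parameter draws
    and the returned table the final per-measurement states, confidence and
    validity in input units.
    """
    from .engine import MixtureModel, run_mcmc

    model = MixtureModel(data.ta, data.m / m_mean, spec, pre.clamped)
    posterior = run_mcmc(model, config, seed=seed)
    posterior.m_mean = m_mean
    table = build_assignment_table(
        data, posterior, pre, tlc, spec.m_tnz, m_mean, tlc_draws,
        validity_threshold, validity_alpha,
    )
    return table, posterior
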