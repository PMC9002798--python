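"""Step 1 screen: locate a conservative underestimate of T_lc.

Working downward from the warmest measurements, ordinary least-squares
regressions of M on T_a are fit on growing windows.  While the window stays
inside the thermoneutral zone the regression should be flat and
homoscedastic; the first window showing either a significantly negative slope
(homeotherm signature: the euthermic line has entered) or heteroscedasticity
by the studentized Breusch-Pagan test (heterotherm signature: euthermic and
torpid values start to diverge) marks the crossing.  ``T_lc_low`` is the
minimum T_a of the last clean window, guaranteed (up to test error) to
underestimate the true lower critical temperature; the Bayesian step then
estimates T_lc itself on the data at or below ``T_lc_low``.

A significantly *positive* slope means the dataset lacks euthermic-rest
measurements below the TNZ and the analysis is aborted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .io import MetabolicDataset

__all__ = [
    "BoundaryResult",
    "BoundaryError",
    "UndefinableBoundaryError",
    "breusch_pagan",
    "find_tlc_low",
]

#: Initial rolling-regression window size.
INITIAL_WINDOW = 10


class BoundaryError(ValueError):
    """The step-1 screen cannot run on this dataset."""


class UndefinableBoundaryError(BoundaryError):
    """Significantly positive slope: no euthermic data below the TNZ."""


@dataclass(frozen=True)
class BoundaryResult:
    """Outcome of the rolling screen.

    ``diagnostics`` has one row per window: ``ta_min``, ``n``, ``slope``,
    ``slope_p`` (one-sided, negative direction), ``bp_stat``, ``bp_p`` and
    ``trigger`` in {"", "slope", "bp"}.
    """

    tlc_low: float
    diagnostics: pd.DataFrame


def breusch_pagan(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Studentized (Koenker) Breusch-Pagan heteroscedasticity test.

    Statistic is n * R-squared of the auxiliary regression of squared OLS
    residuals on ``x``; p-value from chi-square with one degree of freedom.
    Returns ``(statistic, p_value)``.  With numerically zero residual
    variance the test is reported as non-significant with a warning —
    heteroscedasticity is not detectable on an exact fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise BoundaryError("Breusch-Pagan needs at least 3 observations")
    if np.ptp(x) == 0:
        raise BoundaryError("Breusch-Pagan needs non-constant x")
    exog = sm.add_constant(x)
    resid = sm.OLS(y, exog).fit().resid
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, float(np.abs(y).max()))):
        warnings.warn(
            "zero residual variance: heteroscedasticity not detectable",
            stacklevel=2,
        )
        return 0.0, 1.0
    stat, pval, _, _ = het_breuschpagan(resid, exog, robust=True)
    return float(stat), float(pval)


def _tie_group_sizes(ta_desc: np.ndarray) -> list[int]:
    """Sizes of consecutive equal-T_a groups of the descending-sorted array."""
    _, counts = np.unique(-ta_desc, return_counts=True)
    return counts.tolist()


def find_tlc_low(
    data: MetabolicDataset,
    alpha_bp: float = 0.05,
    alpha_slope: float = 0.01,
) -> BoundaryResult:
    """Run the rolling screen and return ``T_lc_low`` with diagnostics.

    Records sharing a T_a enter a window together, so a window boundary never
    splits a tie and ``T_lc_low`` is always the T_a of an actual record.
    Slope significance is one-sided (negative for the trigger, positive for
    the abort) at ``alpha_slope``; the Breusch-Pagan trigger uses
    ``alpha_bp``.
    """
    data.require_min_size()
    order = np.argsort(-data.ta, kind="stable")
    ta = data.ta[order]
    m = data.m[order]

    sizes = _tie_group_sizes(ta)
    ends = np.cumsum(sizes)  # window end indices at tie-group boundaries
    ends = ends[ends >= INITIAL_WINDOW]

    rows = []
    last_clean_min: Optional[float] = None
    for end in ends:
        xw, yw = ta[:end], m[:end]
        if np.ptp(xw) == 0:
            # window is one big tie: no slope, no heteroscedasticity signal
            rows.append(
                dict(ta_min=float(xw.min()), n=int(end), slope=0.0,
                     slope_p=1.0, bp_stat=0.0, bp_p=1.0, trigger="")
            )
            last_clean_min = float(xw.min())
            continue
        exog = sm.add_constant(xw)
        fit = sm.OLS(yw, exog).fit()
        slope = float(fit.params[1])
        p_two = float(fit.pvalues[1])
        p_neg = p_two / 2 if slope < 0 else 1 - p_two / 2
        p_pos = p_two / 2 if slope > 0 else 1 - p_two / 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bp_stat, bp_p = breusch_pagan(xw, yw)

        if p_pos < alpha_slope:
            raise UndefinableBoundaryError(
                "significantly positive M-vs-T_a slope: insufficient euthermic "
                "data below the TNZ, T_lc_low is undefinable"
            )
        trigger = ""
        if p_neg < alpha_slope:
            trigger = "slope"
        elif bp_p < alpha_bp:
            trigger = "bp"
        rows.append(
            dict(ta_min=float(xw.min()), n=int(end), slope=slope,
                 slope_p=p_neg, bp_stat=bp_stat, bp_p=bp_p, trigger=trigger)
        )
        if trigger:
            break
        last_clean_min = float(xw.min())

    diagnostics = pd.DataFrame(rows)
    if last_clean_min is None:
        raise BoundaryError(
            "the initial window already shows a trigger: the thermoneutral "
            "segment is too small or too noisy to anchor T_lc_low"
        )
    return BoundaryResult(tlc_low=last_clean_min, diagnostics=diagnostics)


def estimate_tlc(
    data: MetabolicDataset,
    tlc_low: float,
    config=None,
    seed: Optional[int] = None,
):
    """Step-1 Bayesian run: estimate T_lc and recompute M_TNZ.

    Runs the mixture model on the records at or below ``tlc_low`` with T_lc as
    a free parameter truncated to ``[tlc_low, max T_a]``.  The plateau level
    supplied to the run is the mean normalized M above ``tlc_low``; once the
    posterior is in hand, M_TNZ is recomputed as the mean of M above the
    posterior-median T_lc (a superset-or-equal set of records, since the
    prior forbids T_lc below ``tlc_low``).

    Returns ``(posterior, m_tnz_norm, m_mean)`` with ``m_tnz_norm`` on the
    mean-normalized scale and ``m_mean`` the normalization constant.
    """
    from .engine import FREE, MixtureModel, build_priors, run_mcmc
    from .io import RunConfig

    if config is None:
        config = RunConfig()
    m_mean = float(np.mean(data.m))
    m_norm = data.m / m_mean
    above_low = data.ta > tlc_low
    if not above_low.any():
        raise BoundaryError("no records above T_lc_low to anchor M_TNZ")
    m_tnz_initial = float(np.mean(m_norm[above_low]))

    spec = build_priors(data, m_tnz_initial, "step1", tlc_low=tlc_low)
    mask = data.ta <= tlc_low
    model = MixtureModel(
        data.ta[mask], m_norm[mask], spec,
        clamped=np.full(int(mask.sum()), FREE),
    )
    posterior = run_mcmc(model, config, seed=seed)
    posterior.m_mean = m_mean

    tlc = posterior.median("tlc")
    above = data.ta > tlc
    m_tnz = float(np.mean(m_norm[above])) if above.any() else m_tnz_initial
    return posterior, m_tnz, m_mean
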