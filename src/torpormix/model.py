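"""Extended Scholander-Irving model of resting metabolism.

The classical Scholander-Irving model describes resting metabolic rate (M) of
an endotherm as a function of ambient temperature (T_a): flat within the
thermoneutral zone (TNZ) and increasing linearly as T_a drops below the lower
critical temperature T_lc.  The extension adds a torpor curve below T_lc with
two branches: *regulated* torpor (linear, defending a torpid body-temperature
setpoint, for T_a below the breakpoint T_t) and *conforming* torpor
(exponential in T_a, between T_t and T_lc).

Every curve is pinned down by anchor conditions rather than free intercepts:

* euthermic line through ``(T_lc, M_TNZ)`` and ``(T_be, 0)``;
* regulated-torpor line through ``(T_bt, 0)`` with the *same slope* as the
  euthermic line (empirically the two slopes are indistinguishable);
* conforming exponential through ``(T_t, TMR)`` and ``(T_lc, M_r)``.

``T_be`` and ``T_bt`` are the extrapolated T_a at which the euthermic and
regulated-torpor lines reach zero metabolism; under constant conductance they
proxy euthermic and minimal torpid body temperature.  ``M_r <= M_TNZ`` allows
for additional metabolic inhibition in torpor beyond suppressed thermogenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Union

import numpy as np

__all__ = [
    "InvalidParameterError",
    "ThermoParams",
    "derive_euthermic_line",
    "derive_tt",
    "predict_euthermic",
    "predict_torpor",
    "q10_conforming",
    "MAX_Q10",
    "TMR_FRACTION_OF_MTNZ",
    "TBT_FLOOR",
]

ArrayLike = Union[float, np.ndarray]

#: Maximal admissible Q10 of the conforming-torpor branch.
MAX_Q10 = 5.0
#: TMR may not exceed this fraction of M_TNZ.
TMR_FRACTION_OF_MTNZ = 0.8
#: Hard lower bound on T_bt (deg C).
TBT_FLOOR = -5.0


class InvalidParameterError(ValueError):
    """A parameter vector violates the model's admissibility constraints."""


@dataclass(frozen=True)
class ThermoParams:
    """One coherent parameter vector of the extended model.

    Metabolic quantities (``m_tnz``, ``tmr``, ``m_r``, the SDs) share the unit
    of the data they describe; temperatures are degrees Celsius.  Slopes,
    intercepts and the torpor breakpoint ``t_t`` are derived, never stored.

    Parameters
    ----------
    m_tnz : mean resting metabolic rate within the TNZ.
    t_lc : lower critical temperature of the TNZ.
    t_be : extrapolated T_a where the euthermic line reaches zero.
    t_bt : extrapolated T_a where the regulated-torpor line reaches zero.
    tmr : minimal torpid metabolic rate, attained at ``t_t``.
    m_r : torpid metabolic rate at ``t_lc`` (``m_r < m_tnz`` signals
        additional metabolic inhibition).
    sd_tnz, sd_r, sd_c : Gaussian scatter of M in the TNZ, on the linear
        (euthermic / regulated-torpor) branches, and on the conforming branch.
    p_t, p_e : dataset-level fractions of below-T_lc measurements in torpor
        and euthermic rest (sum to one).
    """

    m_tnz: float
    t_lc: float
    t_be: float
    t_bt: float
    tmr: float
    m_r: float
    sd_tnz: float = 0.0
    sd_r: float = 0.0
    sd_c: float = 0.0
    p_t: float = 0.5
    p_e: float = 0.5

    # -- derived quantities -------------------------------------------------

    @property
    def beta_e(self) -> float:
        """Slope of the euthermic line (negative)."""
        if self.t_be <= self.t_lc:
            raise InvalidParameterError(
                f"degenerate euthermic line: t_be={self.t_be} <= t_lc={self.t_lc}"
            )
        return -self.m_tnz / (self.t_be - self.t_lc)

    @property
    def alpha_e(self) -> float:
        """Intercept of the euthermic line."""
        return self.m_tnz - self.beta_e * self.t_lc

    @property
    def beta_r(self) -> float:
        """Slope of the regulated-torpor line; equals ``beta_e`` by assumption."""
        return self.beta_e

    @property
    def alpha_r(self) -> float:
        """Intercept of the regulated-torpor line (zero at ``t_bt``)."""
        return -self.beta_r * self.t_bt

    @property
    def t_t(self) -> float:
        """Breakpoint between regulated and conforming torpor."""
        return derive_tt(self)

    @property
    def beta_c(self) -> float:
        """Exponent coefficient of the conforming branch (>= 0)."""
        if self.m_r < self.tmr:
            raise InvalidParameterError(
                f"m_r={self.m_r} < tmr={self.tmr}: conforming branch undefined"
            )
        if self.m_r == self.tmr:
            return 0.0  # flat conforming segment, exact limit
        span = self.t_lc - self.t_t
        if span <= 0:
            raise InvalidParameterError(
                f"t_t={self.t_t} >= t_lc={self.t_lc}: conforming branch has no support"
            )
        return math.log(self.m_r / self.tmr) / span

    @property
    def alpha_c(self) -> float:
        """Prefactor of the conforming exponential (anchored at ``t_lc``)."""
        return self.m_r * math.exp(-self.beta_c * self.t_lc)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ThermoParams":
        """Check every admissibility constraint; return self or raise."""
        if not np.isfinite(
            [self.m_tnz, self.t_lc, self.t_be, self.t_bt, self.tmr, self.m_r]
        ).all():
            raise InvalidParameterError("non-finite parameter")
        if self.m_tnz <= 0:
            raise InvalidParameterError(f"m_tnz={self.m_tnz} must be positive")
        if self.t_be <= self.t_lc:
            raise InvalidParameterError(
                f"t_be={self.t_be} must exceed t_lc={self.t_lc}"
            )
        if self.t_bt < TBT_FLOOR:
            raise InvalidParameterError(f"t_bt={self.t_bt} below floor {TBT_FLOOR}")
        if not (0 < self.tmr <= TMR_FRACTION_OF_MTNZ * self.m_tnz):
            raise InvalidParameterError(
                f"tmr={self.tmr} outside (0, {TMR_FRACTION_OF_MTNZ}*m_tnz]"
            )
        if not (self.tmr <= self.m_r <= self.m_tnz):
            raise InvalidParameterError(
                f"m_r={self.m_r} outside [tmr={self.tmr}, m_tnz={self.m_tnz}]"
            )
        if self.t_t >= self.t_lc:
            raise InvalidParameterError(
                f"t_t={self.t_t} must lie below t_lc={self.t_lc}"
            )
        if q10_conforming(self) > MAX_Q10 * (1 + 1e-12):
            raise InvalidParameterError(
                f"conforming Q10={q10_conforming(self):.3f} exceeds {MAX_Q10}"
            )
        if abs(self.p_t + self.p_e - 1.0) > 1e-9 or self.p_t < 0 or self.p_e < 0:
            raise InvalidParameterError("state fractions must be >=0 and sum to 1")
        for name in ("sd_tnz", "sd_r", "sd_c"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        return self

    def replace(self, **changes) -> "ThermoParams":
        return replace(self, **changes)


def derive_euthermic_line(params: ThermoParams) -> tuple[float, float]:
    """Intercept and slope of the euthermic line below the TNZ.

    The line passes through ``(t_lc, m_tnz)`` (euthermic M meets the TNZ
    plateau at the lower critical temperature) and ``(t_be, 0)``.

    Returns
    -------
    (alpha_e, beta_e)
    """
    if params.t_be <= params.t_lc:
        raise InvalidParameterError(
            f"t_be={params.t_be} must exceed t_lc={params.t_lc}"
        )
    if params.m_tnz <= 0:
        raise InvalidParameterError("m_tnz must be positive")
    return params.alpha_e, params.beta_e


def predict_euthermic(t_a: ArrayLike, params: ThermoParams) -> ArrayLike:
    """Euthermic resting metabolic rate at ambient temperature ``t_a``.

    Linear, strictly decreasing in T_a; equals ``m_tnz`` at ``t_lc`` and zero
    at ``t_be``.  Extrapolates outside that range — callers enforce
    ``t_a <= t_lc`` where physiologically required.
    """
    alpha_e, beta_e = derive_euthermic_line(params)
    return alpha_e + beta_e * np.asarray(t_a, dtype=float) if np.ndim(t_a) else (
        alpha_e + beta_e * float(t_a)
    )


def derive_tt(params: ThermoParams) -> float:
    """Breakpoint T_t where the regulated-torpor line reaches TMR.

    Solves ``alpha_r + beta_r * T_t = TMR`` with ``alpha_r = -beta_r * t_bt``,
    giving ``T_t = t_bt + TMR / beta_r``; since ``beta_r < 0`` the breakpoint
    lies below ``t_bt``.
    """
    if params.tmr <= 0:
        raise InvalidParameterError("tmr must be positive")
    beta_r = params.beta_r
    if beta_r == 0:
        raise InvalidParameterError("beta_r must be non-zero")
    return params.t_bt + params.tmr / beta_r


def predict_torpor(t_a: ArrayLike, params: ThermoParams) -> ArrayLike:
    """Torpid metabolic rate at ``t_a``: regulated below T_t, conforming above.

    The regulated branch is the line ``alpha_r + beta_r * T_a``; the conforming
    branch is ``alpha_c * exp(beta_c * T_a)``.  Both equal ``tmr`` at ``t_t``
    and the conforming branch equals ``m_r`` at ``t_lc``.
    """
    if params.m_r < params.tmr:
        raise InvalidParameterError(
            f"m_r={params.m_r} < tmr={params.tmr}: torpor curve undefined"
        )
    t_t = params.t_t
    ta = np.asarray(t_a, dtype=float)
    regulated = params.alpha_r + params.beta_r * ta
    conforming = params.alpha_c * np.exp(params.beta_c * ta)
    out = np.where(ta < t_t, regulated, conforming)
    if np.ndim(t_a) == 0:
        return float(out)
    return out


def q10_conforming(params: ThermoParams) -> float:
    """Q10 of the conforming branch: factor of M per 10 deg C of T_a."""
    return math.exp(10.0 * params.beta_c)
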