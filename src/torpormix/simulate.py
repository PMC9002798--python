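"""Synthetic respirometry-like datasets with known ground truth.

Generates (T_a, M) pairs from the extended Scholander-Irving model: records
above T_lc scatter around the TNZ plateau; below T_lc each record is first
assigned a true state (torpor with probability ``p_t``, else euthermic rest)
and M is drawn Gaussian around that state's curve with the state's scatter —
``sd_tnz`` on the plateau, ``sd_r`` on the linear branches (euthermy and
regulated torpor), ``sd_c`` on the conforming branch.  Negative draws are
redrawn rather than truncated, which keeps the generating density essentially
identical to the fitted likelihood at realistic noise levels.

What this emulates: steady-state resting/torpid measurements spread over a
temperature gradient, the design the method assumes.  What it does not:
torpor-bout time structure, transitions, circadian variation, body-mass
effects — so recovery on these fixtures demonstrates correctness of the
inference, not robustness to every feature of real traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .io import MetabolicDataset
from .model import ThermoParams, predict_euthermic, predict_torpor

__all__ = ["GeneratorConfig", "generate", "default_fixtures"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and sampling design for one synthetic dataset.

    ``mode="homeotherm"`` forces the torpor fraction to zero while keeping the
    (then-unused) torpor parameters admissible, mimicking a species that never
    enters torpor.  The default T_a range ``[t_bt - 5, t_lc + 8]`` keeps a
    generous TNZ segment so the step-1 screen always has its initial window.
    """

    params: ThermoParams
    n: int = 120
    ta_range: Optional[Tuple[float, float]] = None
    scheme: str = "uniform"  # or "grid"
    mode: str = "heterotherm"
    seed: int = 0

    def __post_init__(self):
        self.params.validate()
        if self.mode not in ("heterotherm", "homeotherm"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scheme not in ("uniform", "grid"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.mode == "homeotherm" and self.params.p_t != 0.0:
            object.__setattr__(
                self, "params", self.params.replace(p_t=0.0, p_e=1.0)
            )

    @property
    def resolved_ta_range(self) -> Tuple[float, float]:
        if self.ta_range is not None:
            return self.ta_range
        return (self.params.t_bt - 5.0, self.params.t_lc + 8.0)


def _state_curve(state: str, ta: np.ndarray, p: ThermoParams) -> np.ndarray:
    if state == "tnz":
        return np.full_like(ta, p.m_tnz)
    if state == "euthermy":
        return np.asarray(predict_euthermic(ta, p))
    return np.asarray(predict_torpor(ta, p))


def _state_sd(state: str, ta: np.ndarray, p: ThermoParams) -> np.ndarray:
    if state == "tnz":
        return np.full_like(ta, p.sd_tnz)
    if state == "euthermy":
        return np.full_like(ta, p.sd_r)
    return np.where(ta < p.t_t, p.sd_r, p.sd_c)


def generate(config: GeneratorConfig) -> MetabolicDataset:
    """Draw one dataset; true state labels are kept in ``label_ref``."""
    rng = np.random.default_rng(config.seed)
    p = config.params
    lo, hi = config.resolved_ta_range
    if config.scheme == "uniform":
        ta = rng.uniform(lo, hi, size=config.n)
    else:
        ta = np.linspace(lo, hi, config.n)

    below = ta <= p.t_lc
    labels = np.full(config.n, "tnz", dtype=object)
    torpid = below & (rng.random(config.n) < p.p_t)
    labels[below] = "euthermy"
    labels[torpid] = "torpor"

    m = np.empty(config.n)
    for state in ("tnz", "euthermy", "torpor"):
        mask = labels == state
        if not mask.any():
            continue
        mu = _state_curve(state, ta[mask], p)
        sd = _state_sd(state, ta[mask], p)
        draw = rng.normal(mu, sd)
        # redraw non-positive values (positivity of metabolic rate)
        bad = draw <= 0
        while bad.any():
            draw[bad] = rng.normal(mu[bad], sd[bad])
            bad = draw <= 0
        m[mask] = draw
    return MetabolicDataset(ta=ta, m=m, label_ref=labels)


def default_fixtures() -> dict[str, GeneratorConfig]:
    """Named study designs spanning the method's intended range.

    * ``deep_hibernator`` — large euthermy-torpor separation, torpid
      setpoint near 2 deg C: the easy, classical hibernation pattern.
    * ``shallow_daily`` — torpid setpoint only a few degrees below euthermic
      levels (T_bt near 25 deg C) and small separation: the hard case of
      daily heterotherms.
    * ``homeotherm`` — no torpor at all; the torpor parameters exist only as
      admissible placeholders and should come out unidentifiable.
    * ``inhibited`` — strong additional metabolic inhibition
      (M_r well below half of M_TNZ).
    """
    deep = ThermoParams(
        m_tnz=1.0, t_lc=30.0, t_be=38.0, t_bt=2.0, tmr=0.05, m_r=0.40,
        sd_tnz=0.05, sd_r=0.07, sd_c=0.03, p_t=0.5, p_e=0.5,
    )
    shallow = ThermoParams(
        m_tnz=1.0, t_lc=30.0, t_be=36.0, t_bt=25.0, tmr=0.30, m_r=0.60,
        sd_tnz=0.05, sd_r=0.08, sd_c=0.05, p_t=0.5, p_e=0.5,
    )
    homeo = ThermoParams(
        m_tnz=1.0, t_lc=30.0, t_be=38.0, t_bt=2.0, tmr=0.05, m_r=0.40,
        sd_tnz=0.05, sd_r=0.07, sd_c=0.03, p_t=0.0, p_e=1.0,
    )
    inhib = ThermoParams(
        m_tnz=1.0, t_lc=32.0, t_be=40.0, t_bt=5.0, tmr=0.10, m_r=0.35,
        sd_tnz=0.05, sd_r=0.07, sd_c=0.03, p_t=0.5, p_e=0.5,
    )
    return {
        "deep_hibernator": GeneratorConfig(params=deep, n=120, seed=11),
        "shallow_daily": GeneratorConfig(params=shallow, n=120, seed=12),
        "homeotherm": GeneratorConfig(
            params=homeo, n=100, mode="homeotherm", seed=13
        ),
        "inhibited": GeneratorConfig(params=inhib, n=120, seed=14),
    }
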