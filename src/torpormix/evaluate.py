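"""Method-evaluation utilities: corroboration, inhibition, comparisons.

These quantify how well the pipeline's assignments and parameter estimates
agree with an independent reference — the labels of the original
investigators, generator ground truth, or parameter values reported
elsewhere.  Only *valid* assignments (confidence passing the binomial test)
enter the corroboration index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "corroboration_index",
    "inhibition_fraction",
    "compare_parameters",
    "EvaluationError",
]


class EvaluationError(ValueError):
    pass


def corroboration_index(
    model_states: Sequence[str],
    reference_states: Sequence[str],
    valid_mask: Sequence[bool],
    mode: str = "strict",
) -> float:
    """Fraction of validly assigned records whose state matches the reference.

    ``mode="strict"`` compares the three states as labelled; ``mode="binary"``
    collapses plateau and euthermic rest into a single non-torpor class,
    isolating the torpor/euthermy decision from disagreements about where
    T_lc sits.  Records flagged invalid are excluded from numerator and
    denominator alike.
    """
    model_states = np.asarray(model_states, dtype=object)
    reference_states = np.asarray(reference_states, dtype=object)
    valid = np.asarray(valid_mask, dtype=bool)
    if not (len(model_states) == len(reference_states) == len(valid)):
        raise EvaluationError("state vectors and valid mask must align")
    if not valid.any():
        raise EvaluationError("corroboration is undefined with no valid record")
    a, b = model_states[valid], reference_states[valid]
    if mode == "binary":
        a = np.where(a == "torpor", "torpor", "rest")
        b = np.where(b == "torpor", "torpor", "rest")
    elif mode != "strict":
        raise EvaluationError(f"unknown mode {mode!r}")
    return float(np.mean(a == b))


def inhibition_fraction(
    m_r_posterior: np.ndarray,
    m_tnz: float,
    ppo_m_r: Optional[float] = None,
    ppo_threshold: float = 75.0,
) -> tuple[float, bool]:
    """Additional metabolic inhibition in torpor, as posterior-median M_r/M_TNZ.

    One means no inhibition beyond suppressed thermogenesis.  The returned
    flag marks the estimate unreliable whenever M_r's prior-posterior overlap
    reaches the identifiability threshold (too few conforming-torpor values
    to pin M_r down).
    """
    if m_tnz <= 0:
        raise EvaluationError("m_tnz must be positive")
    frac = float(np.median(np.asarray(m_r_posterior, float)) / m_tnz)
    unreliable = ppo_m_r is not None and ppo_m_r >= ppo_threshold
    return frac, bool(unreliable)


def compare_parameters(
    estimates: pd.DataFrame,
    references: pd.DataFrame,
    ta_range: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Pearson correlation of estimated vs reference parameters across datasets.

    ``estimates`` and ``references`` are aligned frames with one row per
    dataset and one column per parameter.  When ``ta_range`` (columns
    ``ta_min``/``ta_max``) is given, ``t_t`` pairs whose *estimate* falls
    outside the measured temperature range are dropped before testing —
    a breakpoint outside the data is unidentifiable.  Parameters with fewer
    than 3 usable pairs get NaN correlation.
    """
    if not estimates.columns.equals(references.columns):
        raise EvaluationError("estimate and reference columns must match")
    rows = []
    for name in estimates.columns:
        x = estimates[name].to_numpy(float)
        y = references[name].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y)
        if name == "t_t" and ta_range is not None:
            inside = (x >= ta_range["ta_min"].to_numpy(float)) & (
                x <= ta_range["ta_max"].to_numpy(float)
            )
            keep &= inside
        n = int(keep.sum())
        if n < 3:
            rows.append(dict(parameter=name, n=n, r=np.nan, p=np.nan))
            continue
        r, p = pearsonr(x[keep], y[keep])
        rows.append(dict(parameter=name, n=n, r=float(r), p=float(p)))
    return pd.DataFrame(rows)
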