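"""Dataset container, run configuration and CSV/JSON I/O.

The exchange format is a headed CSV with columns ``ta`` (ambient temperature,
deg C) and ``m`` (metabolic rate in any consistent unit), plus an optional
``state_ref`` column carrying the reference labels used for method evaluation
(values among ``torpor``, ``euthermy``, ``tnz``, ``none``).  The tool is
unit-agnostic: all modelling happens on mean-normalized M and results are
reported back in input units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STATES",
    "MetabolicDataset",
    "RunConfig",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "load_config",
]

STATES = ("tnz", "euthermy", "torpor")
#: Minimal dataset size: the step-1 rolling regression starts on 10 records.
MIN_RECORDS = 10


class DatasetError(ValueError):
    """Malformed or inadmissible input data."""


@dataclass(frozen=True)
class MetabolicDataset:
    """Paired (T_a, M) measurements of resting or torpid animals.

    Measurements above the upper critical temperature must be excluded by the
    caller before analysis; the model does not describe heat stress.
    """

    ta: np.ndarray
    m: np.ndarray
    label_ref: Optional[np.ndarray] = None

    def __post_init__(self):
        ta = np.asarray(self.ta, dtype=float)
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "ta", ta)
        object.__setattr__(self, "m", m)
        if ta.ndim != 1 or m.ndim != 1 or ta.shape != m.shape:
            raise DatasetError("ta and m must be 1-d arrays of equal length")
        if not np.isfinite(ta).all():
            rows = np.flatnonzero(~np.isfinite(ta))
            raise DatasetError(f"non-finite ta at rows {rows.tolist()}")
        if not np.isfinite(m).all():
            rows = np.flatnonzero(~np.isfinite(m))
            raise DatasetError(f"non-finite m at rows {rows.tolist()}")
        if (m <= 0).any():
            rows = np.flatnonzero(m <= 0)
            raise DatasetError(f"non-positive m at rows {rows.tolist()}")
        if self.label_ref is not None:
            lab = np.asarray(self.label_ref, dtype=object)
            if lab.shape != ta.shape:
                raise DatasetError("label_ref length mismatch")
            bad = [l for l in np.unique(lab) if l not in STATES + ("none",)]
            if bad:
                raise DatasetError(f"unknown reference labels: {bad}")
            object.__setattr__(self, "label_ref", lab)

    def __len__(self) -> int:
        return self.ta.size

    def require_min_size(self) -> "MetabolicDataset":
        if len(self) < MIN_RECORDS:
            raise DatasetError(
                f"need at least {MIN_RECORDS} records, got {len(self)}"
            )
        return self

    def subset(self, mask: np.ndarray) -> "MetabolicDataset":
        lab = None if self.label_ref is None else self.label_ref[mask]
        return MetabolicDataset(self.ta[mask], self.m[mask], lab)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"ta": self.ta, "m": self.m})
        if self.label_ref is not None:
            df["state_ref"] = self.label_ref
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetabolicDataset":
        missing = {"ta", "m"} - set(df.columns)
        if missing:
            raise DatasetError(f"missing required columns: {sorted(missing)}")
        bad = df.index[df[["ta", "m"]].isna().any(axis=1)]
        if len(bad):
            raise DatasetError(f"missing ta/m values at rows {bad.tolist()}")
        lab = df["state_ref"].to_numpy() if "state_ref" in df.columns else None
        return cls(df["ta"].to_numpy(float), df["m"].to_numpy(float), lab)


def read_dataset(path: Union[str, Path]) -> MetabolicDataset:
    """Read a (ta, m[, state_ref]) CSV into a validated dataset."""
    df = pd.read_csv(path)
    try:
        return MetabolicDataset.from_frame(df)
    except DatasetError as exc:
        raise DatasetError(f"{path}: {exc}") from None


def write_dataset(data: MetabolicDataset, path: Union[str, Path]) -> None:
    data.to_frame().to_csv(path, index=False)


@dataclass
class RunConfig:
    """All tunable settings of the three-step pipeline.

    Defaults are the method's canonical values: 3 chains of 50,000 iterations,
    30,000 burn-in, thinning 10; Breusch-Pagan alpha 0.05 and slope alpha 0.01
    for the step-1 screen; assignment-validity threshold 0.8; prior-posterior
    overlap threshold 75%; R-hat convergence bound 1.1.
    """

    chains: int = 3
    iterations: int = 50_000
    burn_in: int = 30_000
    thinning: int = 10
    seed: Optional[int] = None
    bp_alpha: float = 0.05
    slope_alpha: float = 0.01
    validity_threshold: float = 0.8
    validity_alpha: float = 0.05
    ppo_threshold: float = 75.0
    rhat_threshold: float = 1.1
    reference_column: str = "state_ref"

    def __post_init__(self):
        if not (0 < self.validity_threshold < 1):
            raise ValueError("validity_threshold must lie in (0, 1)")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**load_config(path))


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON mapping of RunConfig fields."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
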