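"""Per-bin result containers: diversity curves and rate series.

Both containers align to a :class:`~paleodiv.bins.BinScheme` and allow
undefined bins (NaN) — e.g. zero-coverage intervals where subsampled
richness cannot be computed, or edge bins where rate corrections are
unavailable.  They serialize to tidy CSV (bin label, age midpoint, value,
dispersion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bins import BinScheme

__all__ = ["DiversitySeries", "RateSeries"]


@dataclass
class DiversitySeries:
    """A per-bin diversity estimate (TDE, SQS or PDE variants).

    Parameters
    ----------
    scheme : BinScheme
        Time bins the values align to (oldest first).
    values : ndarray
        Per-bin diversity; NaN where undefined.
    dispersion : ndarray, optional
        Per-bin standard deviation (e.g. across subsampling trials).
    label : str
        Metric name, e.g. ``"tde"``, ``"sqs"``, ``"pde_mean"``.
    meta : dict
        Free-form provenance (quorum, trials, seed, dating method...).
    """

    scheme: BinScheme
    values: np.ndarray
    dispersion: np.ndarray | None = None
    label: str = "diversity"
    meta: dict = field(default_factory=dict)
    #: centred anomaly series (e.g. simulated driver responses) may dip
    #: below zero; true diversity metrics never do
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.scheme),):
            raise ValueError(
                f"values length {self.values.shape} does not match scheme "
                f"with {len(self.scheme)} bins"
            )
        if self.dispersion is not None:
            self.dispersion = np.asarray(self.dispersion, dtype=float)
            if self.dispersion.shape != self.values.shape:
                raise ValueError("dispersion length must match values")
        defined = self.values[~np.isnan(self.values)]
        if not self.allow_negative and (defined < 0).any():
            raise ValueError("diversity values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": self.scheme.labels,
                "midpoint": [b.midpoint for b in self.scheme],
                "value": self.values,
            }
        )
        df["sd"] = self.dispersion if self.dispersion is not None else np.nan
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def value_for(self, label: str) -> float:
        return float(self.values[self.scheme.index_of(label)])


@dataclass
class RateSeries:
    """Per-bin origination (lambda) and extinction (mu) rates.

    ``clamped`` flags bins whose raw estimate was negative (possible under
    the three-timer sampling correction) and was clamped to zero.
    """

    scheme: BinScheme
    extinction: np.ndarray
    origination: np.ndarray
    method: str = "rates"
    per_myr: bool = False
    clamped: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        self.origination = np.asarray(self.origination, dtype=float)
        n = len(self.scheme)
        if self.extinction.shape != (n,) or self.origination.shape != (n,):
            raise ValueError("rate arrays must match the scheme length")
        for arr in (self.extinction, self.origination):
            defined = arr[~np.isnan(arr)]
            if (defined < 0).any():
                raise ValueError("rates must be non-negative where defined")
        if self.clamped is None:
            self.clamped = np.zeros(n, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.scheme.labels,
                "midpoint": [b.midpoint for b in self.scheme],
                "mu": self.extinction,
                "lambda": self.origination,
                "clamped": self.clamped,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
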