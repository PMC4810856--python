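"""Geological time-bin schemes.

A :class:`BinScheme` is an ordered sequence of contiguous, non-overlapping
time bins running from older to younger, with ages in Ma.  Each bin is the
half-open age interval ``[older_bound, younger_bound)``: the older bound is
inclusive and the younger bound exclusive, so an age lying exactly on a
boundary belongs to the bin whose *older* bound it equals.  This convention
prevents double counting of occurrences dated exactly to a stage boundary.

Two built-in schemes covering the Jurassic--Cretaceous (201--66 Ma) ship
with the package: a 23-bin stage-level scheme with GTS2012 stage ages, and
a 14-bin composite of roughly 10-Myr bins (J1--J6, K1--K8).  The composite
boundaries are an approximation assembled from whole GTS2012 stages; every
analysis takes the scheme as an argument, so alternative bin tables load
as drop-in replacements via :func:`read_bin_scheme`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

__all__ = [
    "Bin",
    "BinScheme",
    "stage_bins",
    "tenmyr_bins",
    "read_bin_scheme",
    "write_bin_scheme",
]


@dataclass(frozen=True)
class Bin:
    """One time bin: half-open age interval [older, younger), ages in Ma."""

    label: str
    older: float
    younger: float

    def __post_init__(self) -> None:
        if not self.older > self.younger:
            raise ValueError(
                f"bin {self.label!r}: older bound ({self.older}) must exceed "
                f"younger bound ({self.younger})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.older + self.younger)

    @property
    def duration(self) -> float:
        """Bin length in Myr."""
        return self.older - self.younger

    def contains_age(self, age: float) -> bool:
        """True if a point age falls in [older, younger)."""
        return self.younger < age <= self.older

    def contains_range(self, age_max: float, age_min: float) -> bool:
        """True if the whole age range [age_min, age_max] lies in this bin."""
        return age_max <= self.older and age_min > self.younger

    def overlaps_range(self, age_max: float, age_min: float) -> bool:
        """True if the age range intersects this bin's half-open interval."""
        return age_max > self.younger and age_min <= self.older


@dataclass(frozen=True)
class BinScheme:
    """Ordered time bins, oldest first; contiguity is enforced."""

    name: str
    bins: tuple[Bin, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("a BinScheme needs at least one bin")
        for older_bin, younger_bin in zip(self.bins, self.bins[1:]):
            if older_bin.younger != younger_bin.older:
                raise ValueError(
                    f"scheme {self.name!r}: bins {older_bin.label!r} and "
                    f"{younger_bin.label!r} are not contiguous "
                    f"({older_bin.younger} != {younger_bin.older})"
                )

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self) -> Iterator[Bin]:
        return iter(self.bins)

    def __getitem__(self, i: int) -> Bin:
        return self.bins[i]

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]

    @property
    def older_bound(self) -> float:
        return self.bins[0].older

    @property
    def younger_bound(self) -> float:
        return self.bins[-1].younger

    def index_of(self, label: str) -> int:
        for i, b in enumerate(self.bins):
            if b.label == label:
                return i
        raise KeyError(f"no bin labelled {label!r} in scheme {self.name!r}")

    def bin_for_age(self, age: float) -> Bin | None:
        """Bin containing a point age, or None if outside the scheme span."""
        for b in self.bins:
            if b.contains_age(age):
                return b
        return None

    def bins_overlapping(self, age_max: float, age_min: float) -> list[Bin]:
        """All bins whose interval intersects [age_min, age_max]."""
        return [b for b in self.bins if b.overlaps_range(age_max, age_min)]

    def single_bin_for_range(self, age_max: float, age_min: float) -> Bin | None:
        """The unique bin wholly containing [age_min, age_max], else None."""
        for b in self.bins:
            if b.contains_range(age_max, age_min):
                return b
        return None

    def durations(self) -> list[float]:
        return [b.duration for b in self.bins]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.labels,
                "older": [b.older for b in self.bins],
                "younger": [b.younger for b in self.bins],
                "midpoint": [b.midpoint for b in self.bins],
            }
        )


def _scheme(name: str, rows: Sequence[tuple[str, float, float]]) -> BinScheme:
    return BinScheme(name, tuple(Bin(*r) for r in rows))


# GTS2012 stage boundaries, Hettangian through Maastrichtian.
_STAGES: list[tuple[str, float, float]] = [
    ("Hettangian", 201.3, 199.3),
    ("Sinemurian", 199.3, 190.8),
    ("Pliensbachian", 190.8, 182.7),
    ("Toarcian", 182.7, 174.1),
    ("Aalenian", 174.1, 170.3),
    ("Bajocian", 170.3, 168.3),
    ("Bathonian", 168.3, 166.1),
    ("Callovian", 166.1, 163.5),
    ("Oxfordian", 163.5, 157.3),
    ("Kimmeridgian", 157.3, 152.1),
    ("Tithonian", 152.1, 145.0),
    ("Berriasian", 145.0, 139.8),
    ("Valanginian", 139.8, 132.9),
    ("Hauterivian", 132.9, 129.4),
    ("Barremian", 129.4, 125.0),
    ("Aptian", 125.0, 113.0),
    ("Albian", 113.0, 100.5),
    ("Cenomanian", 100.5, 93.9),
    ("Turonian", 93.9, 89.8),
    ("Coniacian", 89.8, 86.3),
    ("Santonian", 86.3, 83.6),
    ("Campanian", 83.6, 72.1),
    ("Maastrichtian", 72.1, 66.0),
]

# Approximately-10-Myr composite bins built from whole stages.  J6 is the
# Tithonian, K2 the Hauterivian-Barremian and K3 the Aptian, matching the
# usual usage of these labels for this interval.
_TENMYR: list[tuple[str, float, float]] = [
    ("J1", 201.3, 190.8),  # Hettangian-Sinemurian
    ("J2", 190.8, 182.7),  # Pliensbachian
    ("J3", 182.7, 174.1),  # Toarcian
    ("J4", 174.1, 163.5),  # Aalenian-Callovian
    ("J5", 163.5, 152.1),  # Oxfordian-Kimmeridgian
    ("J6", 152.1, 145.0),  # Tithonian
    ("K1", 145.0, 132.9),  # Berriasian-Valanginian
    ("K2", 132.9, 125.0),  # Hauterivian-Barremian
    ("K3", 125.0, 113.0),  # Aptian
    ("K4", 113.0, 100.5),  # Albian
    ("K5", 100.5, 93.9),   # Cenomanian
    ("K6", 93.9, 86.3),    # Turonian-Coniacian
    ("K7", 86.3, 72.1),    # Santonian-Campanian
    ("K8", 72.1, 66.0),    # Maastrichtian
]


def stage_bins() -> BinScheme:
    """The 23-bin stage-level scheme, 201.3--66 Ma (GTS2012 ages)."""
    return _scheme("stage", _STAGES)


def tenmyr_bins() -> BinScheme:
    """The 14-bin approximately-10-Myr composite scheme (J1--J6, K1--K8)."""
    return _scheme("tenmyr", _TENMYR)


def read_bin_scheme(path: str | Path, name: str | None = None) -> BinScheme:
    """Load a scheme from a CSV with columns label, older, younger."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"label", "older", "younger"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bin scheme CSV {path} lacks columns: {sorted(missing)}")
    rows = [
        (str(r.label), float(r.older), float(r.younger))
        for r in df.itertuples(index=False)
    ]
    return _scheme(name or path.stem, rows)


def write_bin_scheme(scheme: BinScheme, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": scheme.labels,
            "older": [b.older for b in scheme.bins],
            "younger": [b.younger for b in scheme.bins],
        }
    ).to_csv(path, index=False)
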