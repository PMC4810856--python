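"""Fossil occurrence tables: ingest, filtering, subsetting, binning, and
raw (uncorrected) diversity.

An occurrence is a body-fossil record of a taxon from one collection
(locality), published in one reference, dated to an age range
``[age_min, age_max]`` in Ma.  Only occurrences identifiable at least to
genus are retained: indeterminate material carries no taxonomic signal for
genus-level diversity.  Occurrences are assigned to time bins under one of
two policies:

``constrained``
    an occurrence is kept only if its whole age range lies inside a single
    bin (half-open ``[older, younger)`` intervals, older bound inclusive);
    range-spanning occurrences are dropped.  Required for raw counts.
``unconstrained``
    every occurrence is kept with the full set of candidate bins its range
    overlaps; downstream subsamplers resolve the ambiguity per trial.

The raw taxonomic diversity estimate (TDE) is the per-bin count of
distinct taxa, with duplicate records of the same taxon in the same
collection collapsed to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bins import BinScheme
from .series import DiversitySeries

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceTable",
    "BinnedOccurrences",
    "TaxonRange",
    "REALMS",
    "CONTINENTS",
    "read_occurrences",
    "apply_filters",
    "subset",
    "assign_to_bins",
    "tde",
    "taxon_ranges",
]

REALMS = ("marine", "nonmarine")
CONTINENTS = ("Europe", "Asia", "Africa", "SouthAmerica", "NorthAmerica", "Other")

#: canonical column order for occurrence tables
COLUMNS = [
    "occurrence_id",
    "taxon",
    "genus",
    "species",
    "collection_id",
    "publication_id",
    "age_max",
    "age_min",
    "realm",
    "continent",
]

Rank = Literal["genus", "species"]


class OccurrenceError(ValueError):
    """Raised for invalid occurrence rows or configuration."""


@dataclass
class OccurrenceTable:
    """A validated table of occurrences (one row each).

    ``meta`` records ingest/filter provenance such as dropped-row counts.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise OccurrenceError(f"occurrence table lacks columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        bad_age = self.df[self.df.age_min > self.df.age_max]
        if len(bad_age):
            ids = bad_age.occurrence_id.tolist()[:5]
            raise OccurrenceError(
                f"age_min > age_max for occurrence id(s) {ids}"
            )
        nonpos = self.df[self.df.age_min <= 0]
        if len(nonpos):
            ids = nonpos.occurrence_id.tolist()[:5]
            raise OccurrenceError(f"non-positive ages for occurrence id(s) {ids}")
        bad_realm = set(self.df.realm.unique()) - set(REALMS)
        if bad_realm:
            raise OccurrenceError(f"unknown realm value(s): {sorted(bad_realm)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_genera(self) -> int:
        return self.df.genus.nunique()

    @property
    def n_collections(self) -> int:
        return self.df.collection_id.nunique()

    def taxon_column(self, rank: Rank) -> pd.Series:
        """Taxon identity at the requested rank.

        Genus rank uses every row; species rank drops rows whose species
        field is empty (material identified only to genus).
        """
        if rank == "genus":
            return self.df.genus
        mask = self.df.species.astype(str).str.len() > 0
        return (self.df.genus + " " + self.df.species)[mask]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class TaxonRange:
    """Observed stratigraphic range of one taxon (ages in Ma)."""

    taxon: str
    fad: float
    lad: float
    fad_bin: str
    lad_bin: str

    def __post_init__(self) -> None:
        if self.fad < self.lad:
            raise OccurrenceError(
                f"taxon {self.taxon!r}: fad ({self.fad}) < lad ({self.lad})"
            )


@dataclass
class BinnedOccurrences:
    """Occurrences with their bin assignment under a stated policy.

    Under the constrained policy ``table`` holds only single-bin
    occurrences and ``assignment`` maps each row to one bin label; under
    the unconstrained policy all in-span occurrences are retained and
    ``candidates`` lists each row's overlapping bins.
    """

    scheme: BinScheme
    table: OccurrenceTable
    policy: Literal["constrained", "unconstrained"]
    assignment: pd.Series | None = None
    candidates: list[list[str]] | None = None
    n_dropped_spanning: int = 0
    n_dropped_out_of_span: int = 0

    def occurrences_in_bin(self, label: str) -> pd.DataFrame:
        if self.policy != "constrained":
            raise OccurrenceError(
                "fixed per-bin occurrence lists require the constrained "
                "policy; unconstrained candidate sets are resolved per trial"
            )
        return self.table.df[self.assignment == label]


def _load_column_map(column_map: Mapping[str, str] | str | Path | None) -> dict:
    if column_map is None:
        return {c: c for c in COLUMNS}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh)
    return dict(column_map)


def read_occurrences(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> OccurrenceTable:
    """Read an occurrence CSV (PaleoDB-style export) into a table.

    Parameters
    ----------
    path : path to CSV
    column_map : mapping from canonical field names to CSV column names,
        or a YAML file holding one.  Unmapped fields default to their
        canonical names; ``species`` and ``publication_id`` may be absent
        from the CSV and are filled with empty strings.

    Rows lacking a genus are rejected with a logged count (recorded in
    ``meta["n_dropped_no_genus"]``); an unparseable or inverted age range
    raises an error naming the offending occurrence id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = _load_column_map(column_map)
    raw = pd.read_csv(path, dtype=str).fillna("")
    out = {}
    for field_name in COLUMNS:
        col = cmap.get(field_name, field_name)
        if col in raw.columns:
            out[field_name] = raw[col]
        elif field_name in ("species", "publication_id"):
            out[field_name] = pd.Series([""] * len(raw))
        elif field_name == "occurrence_id":
            out[field_name] = pd.Series([str(i) for i in range(len(raw))])
        else:
            raise OccurrenceError(
                f"column {col!r} (field {field_name!r}) missing from {path}"
            )
    df = pd.DataFrame(out)
    for age_col in ("age_max", "age_min"):
        try:
            df[age_col] = df[age_col].astype(float)
        except ValueError as exc:
            bad = df[pd.to_numeric(df[age_col], errors="coerce").isna()]
            ids = bad.occurrence_id.tolist()[:5]
            raise OccurrenceError(
                f"unparseable {age_col} for occurrence id(s) {ids}"
            ) from exc
    no_genus = df.genus.str.strip() == ""
    n_dropped = int(no_genus.sum())
    if n_dropped:
        logger.info("dropped %d occurrence(s) lacking a genus", n_dropped)
    df = df[~no_genus]
    table = OccurrenceTable(df, meta={"n_dropped_no_genus": n_dropped})
    return table


def apply_filters(
    table: OccurrenceTable,
    rules: Sequence[Mapping],
) -> OccurrenceTable:
    """Remove occurrences matching any exclusion rule.

    Each rule is a mapping with a ``genus`` key and optionally
    ``age_older``/``age_younger`` (Ma) restricting the rule to occurrences
    whose range intersects that window, e.g. stripping out-of-epoch records
    of extant genera or reassigned clades.  Returns a filtered copy;
    per-rule removal counts land in ``meta["filter_report"]``.
    """
    allowed = {"genus", "age_older", "age_younger", "clade", "label"}
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    report: list[dict] = []
    for rule in rules:
        unknown = set(rule) - allowed
        if unknown:
            raise OccurrenceError(f"exclusion rule has unknown field(s): {sorted(unknown)}")
        if "genus" not in rule:
            raise OccurrenceError(f"exclusion rule lacks a genus: {rule}")
        m = (df.genus == rule["genus"]).to_numpy()
        if "age_older" in rule:
            m &= (df.age_min < float(rule["age_older"])).to_numpy()
        if "age_younger" in rule:
            m &= (df.age_max > float(rule["age_younger"])).to_numpy()
        n_removed = int((m & keep).sum())
        keep &= ~m
        report.append({**rule, "n_removed": n_removed})
        if n_removed:
            logger.info("filter rule %s removed %d occurrence(s)", rule, n_removed)
    meta = dict(table.meta)
    meta["filter_report"] = report
    return OccurrenceTable(df[keep], meta=meta)


def subset(
    table: OccurrenceTable,
    realm: str | None = None,
    continent: str | None = None,
) -> OccurrenceTable:
    """Filtered copy by realm (marine/nonmarine) and/or palaeocontinent.

    The two realm subsets partition the table; continents likewise.
    """
    df = table.df
    if realm is not None:
        if realm not in REALMS:
            raise OccurrenceError(f"unknown realm {realm!r}; expected one of {REALMS}")
        df = df[df.realm == realm]
    if continent is not None:
        if continent not in CONTINENTS:
            raise OccurrenceError(
                f"unknown continent {continent!r}; expected one of {CONTINENTS}"
            )
        df = df[df.continent == continent]
    return OccurrenceTable(df, meta=dict(table.meta))


def assign_to_bins(
    table: OccurrenceTable,
    scheme: BinScheme,
    policy: Literal["constrained", "unconstrained"] = "constrained",
) -> BinnedOccurrences:
    """Assign occurrences to time bins.

    Constrained: keep an occurrence only if its full age range sits inside
    one bin; occurrences straddling a boundary are dropped (count logged).
    Unconstrained: keep every occurrence whose range overlaps the scheme,
    with its list of candidate bins.  Occurrences wholly outside the
    scheme span are excluded under both policies.
    """
    df = table.df
    if policy == "constrained":
        labels: list[str] = []
        keep_idx: list[int] = []
        n_spanning = 0
        n_outside = 0
        for i, row in enumerate(df.itertuples(index=False)):
            b = scheme.single_bin_for_range(row.age_max, row.age_min)
            if b is not None:
                labels.append(b.label)
                keep_idx.append(i)
            elif scheme.bins_overlapping(row.age_max, row.age_min):
                n_spanning += 1
            else:
                n_outside += 1
        if n_spanning or n_outside:
            logger.info(
                "constrained binning dropped %d spanning and %d out-of-span occurrence(s)",
                n_spanning,
                n_outside,
            )
        kept = OccurrenceTable(df.iloc[keep_idx], meta=dict(table.meta))
        assignment = pd.Series(labels, index=range(len(keep_idx)))
        return BinnedOccurrences(
            scheme=scheme,
            table=kept,
            policy="constrained",
            assignment=assignment,
            n_dropped_spanning=n_spanning,
            n_dropped_out_of_span=n_outside,
        )
    if policy == "unconstrained":
        cand: list[list[str]] = []
        keep_idx = []
        n_outside = 0
        for i, row in enumerate(df.itertuples(index=False)):
            bins = scheme.bins_overlapping(row.age_max, row.age_min)
            if bins:
                cand.append([b.label for b in bins])
                keep_idx.append(i)
            else:
                n_outside += 1
        kept = OccurrenceTable(df.iloc[keep_idx], meta=dict(table.meta))
        return BinnedOccurrences(
            scheme=scheme,
            table=kept,
            policy="unconstrained",
            candidates=cand,
            n_dropped_out_of_span=n_outside,
        )
    raise OccurrenceError(f"unknown binning policy {policy!r}")


def _dedup(df: pd.DataFrame, taxa: pd.Series) -> pd.DataFrame:
    """Collapse duplicate (taxon, collection) records for counting."""
    work = df.loc[taxa.index].copy()
    work["_taxon"] = taxa
    return work.drop_duplicates(subset=["_taxon", "collection_id"])


def tde(binned: BinnedOccurrences, rank: Rank = "genus") -> DiversitySeries:
    """Raw taxonomic diversity: per-bin count of distinct taxa.

    Requires constrained binning — a raw count needs each occurrence in
    exactly one bin.
    """
    if binned.policy != "constrained":
        raise OccurrenceError(
            "tde requires constrained binning; re-bin with policy='constrained' "
            "or resolve multi-bin occurrences first"
        )
    taxa = binned.table.taxon_column(rank)
    work = _dedup(binned.table.df, taxa)
    work["_bin"] = binned.assignment.loc[work.index]
    counts = work.groupby("_bin")["_taxon"].nunique()
    values = np.array([float(counts.get(lbl, 0)) for lbl in binned.scheme.labels])
    return DiversitySeries(binned.scheme, values, label=f"tde_{rank}")


def taxon_ranges(binned: BinnedOccurrences, rank: Rank = "genus") -> list[TaxonRange]:
    """Observed first/last appearance (fad/lad) per taxon.

    fad is the oldest ``age_max`` over the taxon's occurrences and lad the
    youngest ``age_min``; the corresponding bins come from the binning
    assignment of the range-end occurrences.
    """
    if binned.policy != "constrained":
        raise OccurrenceError("taxon_ranges requires constrained binning")
    taxa = binned.table.taxon_column(rank)
    df = binned.table.df.loc[taxa.index]
    out: list[TaxonRange] = []
    assignment = binned.assignment.loc[taxa.index]
    for taxon, grp in df.groupby(taxa):
        fad = float(grp.age_max.max())
        lad = float(grp.age_min.min())
        fad_bin = assignment.loc[grp.age_max.idxmax()]
        lad_bin = assignment.loc[grp.age_min.idxmin()]
        out.append(TaxonRange(str(taxon), fad, lad, fad_bin, lad_bin))
    out.sort(key=lambda r: r.taxon)
    return out
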