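"""Shareholder quorum subsampling (SQS): coverage-standardized richness.

Raw per-bin taxon counts confound diversity with sampling effort.  SQS
standardizes bins not to a fixed number of draws but to a fixed *coverage*
of the underlying taxon frequency distribution: collections are drawn in
random order and each newly encountered taxon contributes its occurrence
frequency as a "share"; drawing stops once the accumulated share reaches
the quorum ``q``.  Coverage of the sampled frequency distribution is
estimated by Good's u (one minus the proportion of occurrences that are
singletons), and the stopping target is ``q / u`` so that the quorum is
expressed on the scale of the *true* frequency distribution.  The
subsampled richness, averaged over many trials, is comparable across bins
with very different sampling intensities.

Two dialects are provided:

``throttled``
    at most ``pubs_cap`` collections per publication enter a trial
    (collections beyond the cap are skipped in draw order), damping the
    leverage of monographic treatments that publish many collections;
``plain``
    no publication cap.

The two dialects coincide exactly whenever every publication contributes
at most ``pubs_cap`` collections.

Bins whose coverage is zero (all taxa singletons) or below the quorum
return an undefined estimate rather than a downward-biased number.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bins import BinScheme
from .occdata import BinnedOccurrences, OccurrenceError, Rank
from .series import DiversitySeries

__all__ = [
    "AbundanceDistribution",
    "SQSConfig",
    "SQSResult",
    "BinCollections",
    "goods_u",
    "sqs_trial",
    "run_draw_order",
    "sqs_estimate",
]

_EPS = 1e-12


@dataclass(frozen=True)
class AbundanceDistribution:
    """Per-taxon occurrence counts within one bin."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        """Total occurrence count O."""
        return sum(self.counts.values())

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.counts.values() if c == 1)

    @property
    def dominant(self) -> str | None:
        """Most frequent taxon (lexicographic tie-break)."""
        if not self.counts:
            return None
        return min(self.counts, key=lambda t: (-self.counts[t], t))

    @property
    def dominant_count(self) -> int:
        d = self.dominant
        return 0 if d is None else self.counts[d]


def goods_u(ab: AbundanceDistribution, correct_dominant: bool = False) -> float:
    """Good's u coverage estimate for one bin.

    ``u = 1 - s1/O`` where s1 is the number of singleton taxa and O the
    total occurrence count.  With ``correct_dominant`` the dominant
    taxon's occurrences are removed from the denominator
    (``u = 1 - s1/(O - n_dominant)``), discounting coverage apparently
    contributed by a single overwhelmingly common taxon.  Returns NaN for
    an empty bin; clamped to [0, 1].
    """
    O = ab.total
    if O == 0:
        return float("nan")
    s1 = ab.n_singletons
    if s1 == 0:
        return 1.0
    denom = O - ab.dominant_count if correct_dominant else O
    if denom <= 0:
        return 0.0
    return float(min(1.0, max(0.0, 1.0 - s1 / denom)))


@dataclass(frozen=True)
class SQSConfig:
    """Subsampling parameters.

    quorum : target coverage fraction in (0, 1]; 0.4 is a robust baseline.
    trials : subsampling trials per bin (per replicate if replicates set).
    dialect : 'throttled' caps collections per publication at pubs_cap;
        'plain' does not.
    exclude_singletons : singleton taxa do not count toward the richness
        tally (they still shape coverage via Good's u).
    include_dominant : the bin's dominant taxon is always tallied once
        drawn, even when it would otherwise be excluded.
    count_dominant_share : the dominant taxon's frequency counts toward
        the quorum (on by default; switch off to diff against dialects
        that exclude it from coverage accumulation).
    correct_dominant : use the dominance-corrected Good's u.
    replicates : optional outer replicate count; total trials become
        replicates * trials with per-replicate means retained.
    """

    quorum: float = 0.4
    trials: int = 1000
    dialect: Literal["throttled", "plain"] = "throttled"
    pubs_cap: int = 3
    exclude_singletons: bool = True
    include_dominant: bool = True
    count_dominant_share: bool = True
    correct_dominant: bool = False
    replicates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.quorum <= 1.0:
            raise ValueError(f"quorum must be in (0, 1], got {self.quorum}")
        if self.trials < 1:
            raise ValueError("trials must be positive")
        if self.dialect not in ("throttled", "plain"):
            raise ValueError(f"unknown dialect {self.dialect!r}")


@dataclass(frozen=True)
class Collection:
    """One fossil collection: its publication and the taxa it contains."""

    collection_id: str
    publication_id: str
    taxa: tuple[str, ...]


@dataclass
class BinCollections:
    """All collections of one bin plus the bin's abundance distribution."""

    collections: list[Collection]
    abundance: AbundanceDistribution

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str, str]]) -> "BinCollections":
        """Build from (taxon, collection_id, publication_id) records.

        Duplicate (taxon, collection) records collapse to one.
        """
        seen: set[tuple[str, str]] = set()
        counts: Counter[str] = Counter()
        coll_taxa: dict[str, list[str]] = {}
        coll_pub: dict[str, str] = {}
        for taxon, coll, pub in records:
            if (taxon, coll) in seen:
                continue
            seen.add((taxon, coll))
            counts[taxon] += 1
            coll_taxa.setdefault(coll, []).append(taxon)
            coll_pub.setdefault(coll, pub)
        collections = [
            Collection(cid, coll_pub[cid], tuple(taxa))
            for cid, taxa in sorted(coll_taxa.items())
        ]
        return cls(collections, AbundanceDistribution(dict(counts)))


def run_draw_order(
    bin_data: BinCollections,
    order: Sequence[int],
    cfg: SQSConfig,
) -> int | None:
    """Run one deterministic subsampling pass over a given collection order.

    Returns the subsampled richness, or None when the bin's coverage
    cannot meet the quorum.  Exposed separately from :func:`sqs_trial` so
    that exhaustive enumeration over draw orders can serve as an oracle.
    """
    ab = bin_data.abundance
    O = ab.total
    u = goods_u(ab, correct_dominant=cfg.correct_dominant)
    if not np.isfinite(u) or u <= 0.0 or u < cfg.quorum - _EPS:
        return None
    target = min(1.0, cfg.quorum / u)
    dominant = ab.dominant
    freq = {t: c / O for t, c in ab.counts.items()}
    seen: set[str] = set()
    coverage = 0.0
    pub_drawn: Counter[str] = Counter()
    for idx in order:
        coll = bin_data.collections[idx]
        if cfg.dialect == "throttled":
            if pub_drawn[coll.publication_id] >= cfg.pubs_cap:
                continue
            pub_drawn[coll.publication_id] += 1
        for taxon in coll.taxa:
            if taxon not in seen:
                seen.add(taxon)
                if cfg.count_dominant_share or taxon != dominant:
                    coverage += freq[taxon]
        if coverage >= target - _EPS:
            break
    tally = 0
    for taxon in seen:
        if cfg.exclude_singletons and ab.counts[taxon] == 1:
            if cfg.include_dominant and taxon == dominant:
                tally += 1
            continue
        tally += 1
    return tally


def sqs_trial(
    bin_data: BinCollections,
    cfg: SQSConfig,
    rng: np.random.Generator,
) -> int | None:
    """One subsampling trial: shuffle the collection order and draw."""
    order = rng.permutation(len(bin_data.collections))
    return run_draw_order(bin_data, order, cfg)


@dataclass
class SQSResult:
    """Per-bin subsampled richness: mean, sd, coverage, defined flag."""

    scheme: BinScheme
    mean: np.ndarray
    sd: np.ndarray
    coverage: np.ndarray
    n_trials: np.ndarray
    config: SQSConfig
    replicate_means: pd.DataFrame | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.mean)

    def to_series(self) -> DiversitySeries:
        return DiversitySeries(
            self.scheme,
            self.mean,
            dispersion=self.sd,
            label=f"sqs_{self.config.dialect}",
            meta={
                "quorum": self.config.quorum,
                "trials": self.config.trials,
                "dialect": self.config.dialect,
                "seed": self.config.seed,
            },
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.scheme.labels,
                "u": self.coverage,
                "mean": self.mean,
                "sd": self.sd,
                "n_trials": self.n_trials,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _bin_records(
    df: pd.DataFrame, taxa: pd.Series
) -> list[tuple[str, str, str]]:
    sub = df.loc[taxa.index]
    return list(zip(taxa, sub.collection_id, sub.publication_id))


def bin_collections_constrained(
    binned: BinnedOccurrences, rank: Rank = "genus"
) -> dict[str, BinCollections]:
    """Per-bin collection lists from a constrained binning."""
    taxa = binned.table.taxon_column(rank)
    df = binned.table.df.loc[taxa.index]
    assignment = binned.assignment.loc[taxa.index]
    out: dict[str, BinCollections] = {}
    for label in binned.scheme.labels:
        mask = assignment == label
        out[label] = BinCollections.from_records(
            _bin_records(df[mask], taxa[mask])
        )
    return out


def _realize_unconstrained(
    binned: BinnedOccurrences, rank: Rank, rng: np.random.Generator
) -> dict[str, BinCollections]:
    """Randomly resolve each multi-bin occurrence to one candidate bin."""
    taxa = binned.table.taxon_column(rank)
    df = binned.table.df
    chosen: list[str] = []
    for cands in binned.candidates:
        if len(cands) == 1:
            chosen.append(cands[0])
        else:
            chosen.append(cands[rng.integers(len(cands))])
    assignment = pd.Series(chosen, index=df.index)
    out: dict[str, BinCollections] = {}
    sub_assignment = assignment.loc[taxa.index]
    sub_df = df.loc[taxa.index]
    for label in binned.scheme.labels:
        mask = sub_assignment == label
        out[label] = BinCollections.from_records(
            _bin_records(sub_df[mask], taxa[mask])
        )
    return out


def sqs_estimate(
    binned: BinnedOccurrences,
    cfg: SQSConfig | None = None,
    rank: Rank = "genus",
) -> SQSResult:
    """Coverage-standardized richness for every bin of a binned table.

    Under the constrained policy the per-bin occurrence pools are fixed
    and each trial shuffles the draw order.  Under the unconstrained
    policy each trial first resolves every multi-bin occurrence to one of
    its candidate bins uniformly at random, then draws — retaining
    temporally uncertain occurrences without double counting.  Seeded
    runs are reproducible.
    """
    cfg = cfg or SQSConfig()
    scheme = binned.scheme
    n_bins = len(scheme)
    n_rep = cfg.replicates or 1
    total_trials = n_rep * cfg.trials
    rng = np.random.default_rng(cfg.seed)

    results: list[list[int]] = [[] for _ in range(n_bins)]
    cov_sums = np.zeros(n_bins)
    cov_n = np.zeros(n_bins)
    rep_means = np.full((n_rep, n_bins), np.nan)

    if binned.policy == "constrained":
        per_bin = bin_collections_constrained(binned, rank)
        bin_list = [per_bin[lbl] for lbl in scheme.labels]
        for i, bd in enumerate(bin_list):
            u = goods_u(bd.abundance, correct_dominant=cfg.correct_dominant)
            cov_sums[i] = 0.0 if not np.isfinite(u) else u
            cov_n[i] = 1.0
        for rep in range(n_rep):
            rep_vals: list[list[int]] = [[] for _ in range(n_bins)]
            for _ in range(cfg.trials):
                for i, bd in enumerate(bin_list):
                    r = sqs_trial(bd, cfg, rng)
                    if r is not None:
                        results[i].append(r)
                        rep_vals[i].append(r)
            for i in range(n_bins):
                if rep_vals[i]:
                    rep_means[rep, i] = float(np.mean(rep_vals[i]))
    elif binned.policy == "unconstrained":
        for rep in range(n_rep):
            rep_vals = [[] for _ in range(n_bins)]
            for _ in range(cfg.trials):
                per_bin = _realize_unconstrained(binned, rank, rng)
                for i, lbl in enumerate(scheme.labels):
                    bd = per_bin[lbl]
                    u = goods_u(bd.abundance, correct_dominant=cfg.correct_dominant)
                    if np.isfinite(u):
                        cov_sums[i] += u
                        cov_n[i] += 1
                    r = sqs_trial(bd, cfg, rng)
                    if r is not None:
                        results[i].append(r)
                        rep_vals[i].append(r)
            for i in range(n_bins):
                if rep_vals[i]:
                    rep_means[rep, i] = float(np.mean(rep_vals[i]))
    else:  # pragma: no cover - BinnedOccurrences validates policy
        raise OccurrenceError(f"unknown policy {binned.policy!r}")

    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n_ok = np.zeros(n_bins)
    for i in range(n_bins):
        vals = results[i]
        n_ok[i] = len(vals)
        if vals:
            mean[i] = float(np.mean(vals))
            sd[i] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    coverage = np.where(cov_n > 0, cov_sums / np.maximum(cov_n, 1), np.nan)
    rep_df = None
    if cfg.replicates:
        rep_df = pd.DataFrame(rep_means, columns=scheme.labels)
    return SQSResult(
        scheme=scheme,
        mean=mean,
        sd=sd,
        coverage=coverage,
        n_trials=n_ok,
        config=cfg,
        replicate_means=rep_df,
    )
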