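"""Per-interval origination and extinction rates.

Two estimators operating on a taxon-by-bin range chart:

**Three-timer (3T) rates** correct for incomplete sampling.  With
``2T_bot(i)`` the taxa sampled in bins i-1 and i, ``2T_top(i)`` those
sampled in i and i+1, ``3T(i)`` those sampled in all three, and ``PT(i)``
the part-timers (sampled in the flanking bins but not i), the per-bin
sampling probability is ``Ps(i) = 3T(i) / (3T(i) + PT(i))`` and

    mu(i)     = ln(2T_bot(i) / 3T(i)) + ln(Ps(i+1))
    lambda(i) = ln(2T_top(i) / 3T(i)) + ln(Ps(i-1))

The ``ln Ps`` term removes the apparent extinction (origination) created
by taxa that survive into the next (previous) bin without being sampled
there — the Signor-Lipps smearing of turnover.  Sampling noise can push
the corrected estimate below zero; such values are clamped to 0 and
flagged.

**Boundary-crosser (Foote) rates** take the sampled record at face value
(ranges filled between first and last appearance).  With ``N_bt(i)`` the
taxa crossing both boundaries of bin i, ``N_bL(i)`` those crossing the
bottom boundary and ending within, and ``N_Ft(i)`` those starting within
and crossing the top:

    q(i) = -ln(N_bt / (N_bt + N_bL)),   p(i) = -ln(N_bt / (N_bt + N_Ft))

Single-interval taxa contribute to neither count.  Rates are
per-interval; both can be normalized per Myr by bin duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .bins import BinScheme
from .occdata import BinnedOccurrences, OccurrenceError, Rank, taxon_ranges
from .series import RateSeries

__all__ = [
    "RangeChart",
    "TimerCounts",
    "range_chart",
    "timer_counts",
    "three_timer_rates",
    "foote_rates",
]


@dataclass
class RangeChart:
    """Taxon-by-bin presence matrices.

    ``sampled`` marks bins with at least one in-bin occurrence;
    ``range_through`` fills every bin from the taxon's first-appearance
    bin to its last-appearance bin (so sampled is a subset of
    range-through).  Rows are taxa, columns bins ordered old to young.
    """

    scheme: BinScheme
    sampled: pd.DataFrame
    range_through: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.sampled.columns == self.range_through.columns).all():
            raise ValueError("sampled / range_through column mismatch")
        if ((self.sampled & ~self.range_through).to_numpy()).any():
            raise ValueError("sampled presence outside range-through span")

    @property
    def durations(self) -> np.ndarray:
        return np.array(self.scheme.durations())


def range_chart(binned: BinnedOccurrences, rank: Rank = "genus") -> RangeChart:
    """Build the range chart from a constrained binning."""
    if binned.policy != "constrained":
        raise OccurrenceError("range_chart requires constrained binning")
    labels = binned.scheme.labels
    taxa_col = binned.table.taxon_column(rank)
    assignment = binned.assignment.loc[taxa_col.index]
    taxa = sorted(taxa_col.unique())
    sampled = pd.DataFrame(False, index=taxa, columns=labels)
    for taxon, label in zip(taxa_col, assignment):
        sampled.loc[taxon, label] = True
    rt = sampled.copy()
    for r in taxon_ranges(binned, rank):
        i0 = binned.scheme.index_of(r.fad_bin)
        i1 = binned.scheme.index_of(r.lad_bin)
        rt.loc[r.taxon, labels[i0 : i1 + 1]] = True
    return RangeChart(binned.scheme, sampled, rt)


@dataclass
class TimerCounts:
    """Two-timer / three-timer / part-timer counts per bin.

    Edge bins (first and last) are undefined (NaN) since they lack a
    flanking neighbour.  ``Ps = 3T / (3T + PT)`` is the per-bin sampling
    probability, NaN where 3T + PT = 0.
    """

    scheme: BinScheme
    two_timer_bottom: np.ndarray
    two_timer_top: np.ndarray
    three_timer: np.ndarray
    part_timer: np.ndarray

    @property
    def ps(self) -> np.ndarray:
        denom = self.three_timer + self.part_timer
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.three_timer / denom, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.scheme.labels,
                "two_timer_bottom": self.two_timer_bottom,
                "two_timer_top": self.two_timer_top,
                "three_timer": self.three_timer,
                "part_timer": self.part_timer,
                "ps": self.ps,
            }
        )


def timer_counts(chart: RangeChart) -> TimerCounts:
    """Count two-timers, three-timers and part-timers from sampled bins."""
    S = chart.sampled.to_numpy(dtype=bool)
    n_bins = S.shape[1]
    if n_bins < 3:
        raise ValueError("timer counts need at least three bins")
    t2b = np.full(n_bins, np.nan)
    t2t = np.full(n_bins, np.nan)
    t3 = np.full(n_bins, np.nan)
    pt = np.full(n_bins, np.nan)
    for i in range(1, n_bins - 1):
        prev, cur, nxt = S[:, i - 1], S[:, i], S[:, i + 1]
        t2b[i] = np.sum(prev & cur)
        t2t[i] = np.sum(cur & nxt)
        t3[i] = np.sum(prev & cur & nxt)
        pt[i] = np.sum(prev & nxt & ~cur)
    return TimerCounts(chart.scheme, t2b, t2t, t3, pt)


def three_timer_rates(
    tc: TimerCounts,
    ps_mode: Literal["adjacent", "pooled"] = "adjacent",
    per_myr: bool = False,
) -> RateSeries:
    """Sampling-corrected per-interval extinction and origination rates.

    ``ps_mode='adjacent'`` corrects extinction with the following bin's
    sampling probability and origination with the preceding bin's (the
    standard formulation); ``'pooled'`` uses a single overall Ps computed
    from summed counts across bins.  Undefined wherever a needed count is
    zero or the correction Ps is undefined; negative corrected estimates
    clamp to zero with a flag.
    """
    n = len(tc.scheme)
    ps = tc.ps
    if ps_mode == "pooled":
        tot3 = np.nansum(tc.three_timer)
        totp = np.nansum(tc.part_timer)
        pooled = tot3 / (tot3 + totp) if (tot3 + totp) > 0 else np.nan
        ps_next = np.full(n, pooled)
        ps_prev = np.full(n, pooled)
    elif ps_mode == "adjacent":
        ps_next = np.concatenate([ps[1:], [np.nan]])
        ps_prev = np.concatenate([[np.nan], ps[:-1]])
    else:
        raise ValueError(f"unknown ps_mode {ps_mode!r}")
    mu = np.full(n, np.nan)
    lam = np.full(n, np.nan)
    clamped = np.zeros(n, dtype=bool)
    for i in range(n):
        t3 = tc.three_timer[i]
        if np.isfinite(t3) and t3 > 0:
            if tc.two_timer_bottom[i] > 0 and np.isfinite(ps_next[i]) and ps_next[i] > 0:
                mu[i] = np.log(tc.two_timer_bottom[i] / t3) + np.log(ps_next[i])
            if tc.two_timer_top[i] > 0 and np.isfinite(ps_prev[i]) and ps_prev[i] > 0:
                lam[i] = np.log(tc.two_timer_top[i] / t3) + np.log(ps_prev[i])
        for arr in (mu, lam):
            if np.isfinite(arr[i]) and arr[i] < 0:
                arr[i] = 0.0
                clamped[i] = True
    if per_myr:
        dur = np.array(tc.scheme.durations())
        mu, lam = mu / dur, lam / dur
    return RateSeries(
        tc.scheme,
        extinction=mu,
        origination=lam,
        method="three_timer",
        per_myr=per_myr,
        clamped=clamped,
        meta={"ps_mode": ps_mode},
    )


def foote_rates(chart: RangeChart, per_myr: bool = False) -> RateSeries:
    """Boundary-crosser per-capita rates from the range-through matrix.

    Undefined where no taxon crosses both boundaries of a bin
    (``N_bt = 0``); single-interval taxa are ignored by construction.
    """
    R = chart.range_through.to_numpy(dtype=bool)
    n_taxa, n_bins = R.shape
    first = np.array([np.argmax(row) for row in R])
    last = np.array([n_bins - 1 - np.argmax(row[::-1]) for row in R])
    has = R.any(axis=1)
    q = np.full(n_bins, np.nan)
    p = np.full(n_bins, np.nan)
    for i in range(n_bins):
        n_bt = np.sum(has & (first < i) & (last > i))
        n_bl = np.sum(has & (first < i) & (last == i))
        n_ft = np.sum(has & (first == i) & (last > i))
        if n_bt > 0:
            q[i] = -np.log(n_bt / (n_bt + n_bl))
            p[i] = -np.log(n_bt / (n_bt + n_ft))
    if per_myr:
        dur = np.array(chart.scheme.durations())
        q, p = q / dur, p / dur
    return RateSeries(
        chart.scheme,
        extinction=q,
        origination=p,
        method="foote",
        per_myr=per_myr,
    )
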