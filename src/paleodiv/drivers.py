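"""Environmental-driver model fitting and comparison.

Palaeo-environmental covariates (sea level, stable-isotope series,
sampling proxies...) are strongly autocorrelated, so raw correlations with
diversity series are spurious-prone.  Each predictor is therefore
detrended by fitting a first-order autoregressive model by (conditional)
maximum likelihood,

    x_t = c + phi * x_{t-1} + eps_t,

and keeping the residuals ``e_t = x_t - c_hat - phi_hat * x_{t-1}``.  The
detrended predictors are compared as Gaussian linear models of the
diversity response; candidate models (intercept-only null, every single
predictor and optionally every pair) are ranked by the small-sample
Akaike information criterion

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1),

with k counting intercept, slopes and the residual variance, and by
Akaike weights ``w_i = exp(-dAICc_i/2) / sum_j exp(-dAICc_j/2)``.
Pearson and Spearman correlations with two-sided p-values accompany each
single-predictor fit; a result is flagged "strong" when it carries the
top Akaike weight and both correlation p-values clear a significance
threshold (0.05 by default, configurable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bins import BinScheme
from .series import DiversitySeries

logger = logging.getLogger(__name__)

__all__ = [
    "EnvSeries",
    "AR1Fit",
    "ModelFit",
    "ModelTable",
    "CorrelationResult",
    "ar1_residuals",
    "fit_models",
    "correlate",
    "driver_report",
    "read_env_series",
]


@dataclass
class EnvSeries:
    """One environmental or sampling-proxy time series, aligned to bins."""

    name: str
    values: np.ndarray
    scheme: BinScheme | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scheme is not None and len(self.values) != len(self.scheme):
            raise ValueError(
                f"series {self.name!r}: {len(self.values)} values for "
                f"{len(self.scheme)}-bin scheme"
            )


def read_env_series(
    path: str | Path, scheme: BinScheme, name: str | None = None
) -> EnvSeries:
    """Load a covariate CSV (columns: ``bin`` or ``midpoint``, ``value``).

    Bin-labelled rows align by label; midpoint-aged rows align to the bin
    containing the age.  Bins without a row are missing (NaN).
    """
    path = Path(path)
    df = pd.read_csv(path)
    values = np.full(len(scheme), np.nan)
    if "bin" in df.columns:
        for _, row in df.iterrows():
            try:
                values[scheme.index_of(str(row["bin"]))] = float(row["value"])
            except KeyError:
                logger.warning("env series %s: unknown bin %r", path, row["bin"])
    elif "midpoint" in df.columns:
        for _, row in df.iterrows():
            b = scheme.bin_for_age(float(row["midpoint"]))
            if b is not None:
                values[scheme.index_of(b.label)] = float(row["value"])
    else:
        raise ValueError(f"{path}: need a 'bin' or 'midpoint' column")
    return EnvSeries(name or path.stem, values, scheme, source=str(path))


@dataclass
class AR1Fit:
    """Conditional-ML AR(1) fit and its residuals."""

    residuals: np.ndarray
    phi: float
    intercept: float
    sigma2: float
    constant: bool = False  # input had zero variance


def ar1_residuals(series: EnvSeries | np.ndarray) -> AR1Fit:
    """Detrend a series by removing its fitted AR(1) structure.

    The model ``x_t = c + phi x_{t-1} + eps`` is fitted by conditional
    maximum likelihood (least squares over the lagged pairs, conditioning
    on the first observation).  Residuals are NaN at the first position
    and wherever either member of the lag pair is missing.  A constant
    series has no autoregressive structure: phi is reported as 0 with all
    residuals zero and the ``constant`` flag set.
    """
    x = series.values if isinstance(series, EnvSeries) else np.asarray(series, float)
    n = len(x)
    resid = np.full(n, np.nan)
    prev, cur = x[:-1], x[1:]
    ok = np.isfinite(prev) & np.isfinite(cur)
    if ok.sum() < 3:
        raise ValueError(
            "AR(1) fit needs at least four consecutive non-missing values"
        )
    xp, xc = prev[ok], cur[ok]
    if np.ptp(x[np.isfinite(x)]) == 0.0:
        resid[np.isfinite(x)] = 0.0
        resid[0] = np.nan
        return AR1Fit(resid, 0.0, float(x[np.isfinite(x)][0]), 0.0, constant=True)
    X = np.column_stack([np.ones_like(xp), xp])
    beta, *_ = np.linalg.lstsq(X, xc, rcond=None)
    c, phi = float(beta[0]), float(beta[1])
    fitted = c + phi * prev
    r = cur - fitted
    resid[1:][ok] = r[ok]
    sigma2 = float(np.mean((xc - (c + phi * xp)) ** 2))
    return AR1Fit(resid, phi, c, sigma2)


@dataclass
class ModelFit:
    """One candidate Gaussian linear model of the response."""

    predictors: tuple[str, ...]
    n: int
    k: int
    loglik: float
    aicc: float
    slopes: dict[str, float] = field(default_factory=dict)
    delta_aicc: float = np.nan
    weight: float = np.nan


@dataclass
class ModelTable:
    """All candidate fits for one response, with Akaike weights."""

    response_label: str
    fits: list[ModelFit]

    def best(self) -> ModelFit:
        return min(self.fits, key=lambda f: f.aicc)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append(
                {
                    "predictors": "+".join(f.predictors) or "(null)",
                    "n": f.n,
                    "k": f.k,
                    "loglik": f.loglik,
                    "aicc": f.aicc,
                    "delta_aicc": f.delta_aicc,
                    "weight": f.weight,
                    **{f"slope_{p}": s for p, s in f.slopes.items()},
                }
            )
        return pd.DataFrame(rows)


def _gaussian_ols(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """ML Gaussian linear fit: returns (logL, coefficients)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    sigma2 = float(np.mean(resid**2))
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return float(loglik), beta


def aicc(loglik: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    a = np.asarray(aiccs, float)
    delta = a - np.nanmin(a)
    w = np.exp(-0.5 * delta)
    return w / np.nansum(w)


def fit_models(
    response: DiversitySeries | np.ndarray,
    predictors: Sequence[EnvSeries],
    combos: int = 2,
    detrend: bool = True,
    detrend_response: bool = False,
    include_null: bool = True,
) -> ModelTable:
    """Fit and rank candidate driver models of a diversity series.

    Candidates are the intercept-only null, every single predictor, and
    (when ``combos >= 2``) every predictor pair.  Predictors are AR(1)
    detrended by default; the response is used as-is unless
    ``detrend_response`` is set (sensitivity runs).  Bins where the
    response or any of a candidate's predictors are undefined are dropped
    listwise per candidate, so n can vary across candidates and is
    reported per fit.  Candidates with too few bins for the AICc
    correction are skipped with a warning.
    """
    if isinstance(response, DiversitySeries):
        y_full = response.values.copy()
        label = response.label
    else:
        y_full = np.asarray(response, float)
        label = "response"
    if detrend_response:
        y_full = ar1_residuals(y_full).residuals
    detrended: dict[str, np.ndarray] = {}
    for p in predictors:
        detrended[p.name] = (
            ar1_residuals(p).residuals if detrend else p.values.copy()
        )
    names = [p.name for p in predictors]
    candidates: list[tuple[str, ...]] = []
    if include_null:
        candidates.append(())
    candidates += [(nm,) for nm in names]
    if combos >= 2:
        candidates += list(itertools.combinations(names, 2))

    # the intercept-only null is the baseline for the drivers under
    # comparison: restrict it to bins at least one predictor covers, or
    # its larger sample would make its likelihood non-comparable (the
    # detrended predictors all lose the first bin, the null would not)
    if names:
        any_pred = np.zeros(len(y_full), dtype=bool)
        for nm in names:
            any_pred |= np.isfinite(detrended[nm])
    else:
        any_pred = np.ones(len(y_full), dtype=bool)

    fits: list[ModelFit] = []
    for cand in candidates:
        cols = [detrended[nm] for nm in cand]
        mask = np.isfinite(y_full)
        if not cand:
            mask &= any_pred
        for c in cols:
            mask &= np.isfinite(c)
        n = int(mask.sum())
        k = len(cand) + 2  # intercept + slopes + residual variance
        if n - k - 1 <= 0:
            logger.warning(
                "skipping candidate %s: n=%d too small for k=%d",
                "+".join(cand) or "(null)", n, k,
            )
            continue
        y = y_full[mask]
        X = np.column_stack([np.ones(n)] + [c[mask] for c in cols])
        loglik, beta = _gaussian_ols(y, X)
        fits.append(
            ModelFit(
                predictors=cand,
                n=n,
                k=k,
                loglik=loglik,
                aicc=aicc(loglik, n, k),
                slopes={nm: float(b) for nm, b in zip(cand, beta[1:])},
            )
        )
    if not fits:
        return ModelTable(label, [])
    w = akaike_weights([f.aicc for f in fits])
    best = min(f.aicc for f in fits)
    for f, wi in zip(fits, w):
        f.delta_aicc = f.aicc - best
        f.weight = float(wi)
    return ModelTable(label, fits)


@dataclass
class CorrelationResult:
    """Pearson and Spearman correlations on pairwise-complete data."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    degenerate: bool = False  # zero variance in either variable


def correlate(
    response: np.ndarray | DiversitySeries,
    predictor: np.ndarray | EnvSeries,
) -> CorrelationResult:
    """Pearson r and Spearman rho between two per-bin series."""
    y = response.values if isinstance(response, DiversitySeries) else np.asarray(response, float)
    x = predictor.values if isinstance(predictor, EnvSeries) else np.asarray(predictor, float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("correlation needs at least three paired values")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, n, degenerate=True)
    pr = stats.pearsonr(xs, ys)
    sr = stats.spearmanr(xs, ys)
    return CorrelationResult(
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue), n,
    )


def driver_report(
    response: DiversitySeries,
    predictors: Sequence[EnvSeries],
    combos: int = 2,
    detrend: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-predictor summary: likelihood, Akaike weight and correlations.

    One row per (response metric, predictor): the single-predictor
    candidate's log-likelihood and Akaike weight (computed over the full
    candidate set), plus Pearson/Spearman correlations between the
    response and the detrended predictor.  ``strong`` flags predictors
    holding the top weight with both correlation p-values below
    ``alpha``.
    """
    table = fit_models(response, predictors, combos=combos, detrend=detrend)
    if not table.fits:
        return pd.DataFrame(
            columns=[
                "metric", "parameter", "loglik", "weight", "slope",
                "spearman_rho", "spearman_p", "pearson_r", "pearson_p",
                "n", "strong",
            ]
        )
    top_weight = max(f.weight for f in table.fits)
    rows = []
    for p in predictors:
        fit = next(
            (f for f in table.fits if f.predictors == (p.name,)), None
        )
        if fit is None:
            continue
        x = ar1_residuals(p).residuals if detrend else p.values
        try:
            corr = correlate(response, x)
        except ValueError:
            corr = CorrelationResult(np.nan, np.nan, np.nan, np.nan, 0, True)
        strong = (
            fit.weight >= top_weight - 1e-12
            and np.isfinite(corr.pearson_p)
            and corr.pearson_p < alpha
            and corr.spearman_p < alpha
        )
        rows.append(
            {
                "metric": response.label,
                "parameter": p.name,
                "loglik": fit.loglik,
                "weight": fit.weight,
                "slope": fit.slopes.get(p.name, np.nan),
                "spearman_rho": corr.spearman_rho,
                "spearman_p": corr.spearman_p,
                "pearson_r": corr.pearson_r,
                "pearson_p": corr.pearson_p,
                "n": fit.n,
                "strong": bool(strong),
            }
        )
    return pd.DataFrame(rows)
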