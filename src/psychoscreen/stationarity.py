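"""ACF-based stationarity gate for mood-factor and taxon time series.

Before correlating microbial abundances with mood, both kinds of series are
required to look like stationary stochastic processes: no sample
autocorrelation outside the white-noise confidence band and a non-significant
portmanteau (Ljung-Box) Q statistic. This module provides the sample ACF,
the Ljung-Box test and a per-(subject, variable) panel assessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ACFResult:
    subject: str
    variable: str
    lags: np.ndarray
    acf: np.ndarray
    conf_bound: float
    q_stat: Optional[float]
    q_pvalue: Optional[float]
    stationary_flag: Optional[bool]
    status: str = "ok"  # "ok" or "insufficient"


def sample_acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation r_0..r_max_lag with the common-denominator
    (biased) estimator:

        r_k = sum_{t=1..n-k} (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if n < max_lag + 2:
        raise ValueError(f"series of length {n} too short for max_lag={max_lag}")
    d = x - x.mean()
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("constant series: autocorrelation undefined (zero variance)")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(d[:-k] @ d[k:]) / denom
    return r


def ljung_box(acf: np.ndarray, n: int, h: int) -> tuple[float, float]:
    """Ljung-Box portmanteau statistic over lags 1..h and its chi-square
    upper-tail probability (h degrees of freedom):

        Q = n (n + 2) sum_{k=1..h} r_k^2 / (n - k)
    """
    if h >= n:
        raise ValueError(f"h={h} must be < n={n}")
    if h < 1:
        raise ValueError("h must be >= 1")
    r = np.asarray(acf, dtype=float)
    if r.size < h + 1:
        raise ValueError(f"need acf values up to lag {h}; got {r.size - 1}")
    k = np.arange(1, h + 1)
    q = float(n * (n + 2) * np.sum(r[1 : h + 1] ** 2 / (n - k)))
    p = float(stats.chi2.sf(q, df=h))
    return q, p


def default_max_lag(n: int) -> int:
    return max(1, min(10, n // 2 - 1))


def assess_series(
    series: np.ndarray,
    subject: str = "",
    variable: str = "",
    max_lag: Optional[int] = None,
    alpha: float = 0.05,
) -> ACFResult:
    """Assess one subject's series: stationary iff every lag-1..L sample
    autocorrelation lies inside +-z_{1-alpha/2}/sqrt(n) AND the Ljung-Box
    p-value exceeds alpha. Series shorter than 4 points (or constant) are
    flagged ``insufficient`` rather than raising."""
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 4 or np.ptp(x) == 0.0:
        return ACFResult(subject, variable, np.arange(1), np.array([1.0]),
                         np.nan, None, None, None, status="insufficient")
    lag = default_max_lag(n) if max_lag is None else min(max_lag, n - 2)
    r = sample_acf(x, lag)
    bound = float(stats.norm.ppf(1 - alpha / 2) / np.sqrt(n))
    q, p = ljung_box(r, n, lag)
    inside = bool(np.all(np.abs(r[1:]) <= bound))
    flag = inside and (p > alpha)
    return ACFResult(subject, variable, np.arange(lag + 1), r, bound, q, p, flag)


def assess_panel_stationarity(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    max_lag: Optional[int] = None,
    alpha: float = 0.05,
) -> list[ACFResult]:
    """Per-(subject, variable) stationarity assessment.

    ``table`` is samples x variables; ``metadata`` (index sample_id) supplies
    ``subject_id`` and ``timepoint``. Each subject's series is assessed
    separately, in timepoint order — series are never pooled across subjects.
    """
    missing = table.index.difference(metadata.index)
    if len(missing):
        raise ValueError(f"samples without metadata: {missing.tolist()}")
    results: list[ACFResult] = []
    meta = metadata.loc[table.index]
    for subject, sub in meta.groupby("subject_id", sort=True):
        ordered = sub.sort_values("timepoint").index
        block = table.loc[ordered]
        for variable in table.columns:
            results.append(
                assess_series(block[variable].to_numpy(), str(subject),
                              str(variable), max_lag=max_lag, alpha=alpha)
            )
    return results


def results_to_frame(results: list[ACFResult]) -> pd.DataFrame:
    """Long-format table: one row per (subject, variable, lag)."""
    rows = []
    for res in results:
        if res.status == "insufficient":
            rows.append({"subject": res.subject, "variable": res.variable,
                         "lag": 0, "acf": 1.0, "conf_bound": np.nan,
                         "q_stat": np.nan, "q_pvalue": np.nan,
                         "stationary": "", "status": res.status})
            continue
        for lag, r in zip(res.lags, res.acf):
            rows.append({"subject": res.subject, "variable": res.variable,
                         "lag": int(lag), "acf": float(r),
                         "conf_bound": res.conf_bound, "q_stat": res.q_stat,
                         "q_pvalue": res.q_pvalue,
                         "stationary": bool(res.stationary_flag),
                         "status": res.status})
    return pd.DataFrame(rows)
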