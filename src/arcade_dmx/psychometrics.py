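"""Distributional summaries and bivariate correlation tables.

Conventions (documented so golden values are stable):

* sd uses the n-1 denominator;
* skewness / excess kurtosis are the bias-corrected sample statistics used
  by mainstream statistics software;
* quartiles use the common linear-interpolation rule;
* the coefficient of variation is sd/mean; the adjusted variant divides by
  (mean - scale_min) so scales that do not start at zero stay comparable;
* correlation p-values are two-sided, from the t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DescribeError(ValueError):
    pass


def coefficient_of_variation(mean: float, sd: float) -> float:
    """sd / mean — relative variability for zero-based scales."""
    if mean <= 0:
        raise DescribeError(f"cv undefined for mean <= 0 (mean={mean})")
    if sd < 0:
        raise DescribeError("sd must be >= 0")
    return sd / mean


def adjusted_coefficient_of_variation(mean: float, sd: float, scale_min: float) -> float:
    """sd / (mean - scale_min) — cv with the scale minimum subtracted first."""
    if mean <= scale_min:
        raise DescribeError(
            f"adjusted cv undefined: mean ({mean}) must exceed scale minimum ({scale_min})"
        )
    if sd < 0:
        raise DescribeError("sd must be >= 0")
    return sd / (mean - scale_min)


@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sd: float
    q25: float
    median: float
    q75: float
    skewness: float | None
    excess_kurtosis: float | None
    cv: float | None
    adjusted_cv: float | None
    shapiro_w: float | None
    shapiro_p: float | None


def describe(values, scale_min: float | None = None) -> Descriptives:
    """Full distributional summary of a sample of at least 3 finite values.

    ``adjusted_cv`` is populated only when ``scale_min`` is supplied.
    Degenerate (constant) samples get sd 0, cv 0, and undefined
    skewness/kurtosis/normality fields (``None``).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 3:
        raise DescribeError(f"describe requires >= 3 values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise DescribeError("describe requires finite values")

    n = int(arr.size)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    q25, median, q75 = (float(q) for q in np.percentile(arr, [25, 50, 75]))

    constant = sd == 0.0
    skewness = None if constant else float(stats.skew(arr, bias=False))
    kurtosis = None if constant else float(stats.kurtosis(arr, bias=False, fisher=True))
    if constant:
        shapiro_w = shapiro_p = None
    else:
        w_stat = stats.shapiro(arr)
        shapiro_w, shapiro_p = float(w_stat.statistic), float(w_stat.pvalue)

    cv = sd / mean if mean > 0 else None
    adjusted_cv = None
    if scale_min is not None:
        adjusted_cv = adjusted_coefficient_of_variation(mean, sd, scale_min)

    return Descriptives(
        n=n, mean=mean, sd=sd, q25=q25, median=median, q75=q75,
        skewness=skewness, excess_kurtosis=kurtosis,
        cv=cv, adjusted_cv=adjusted_cv,
        shapiro_w=shapiro_w, shapiro_p=shapiro_p,
    )


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise-complete Pearson correlations with two-sided p-values."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def pair(self, a: str, b: str) -> tuple[float, float, int]:
        return float(self.r.loc[a, b]), float(self.p.loc[a, b]), int(self.n.loc[a, b])


def correlation_table(data, variables: list[str] | None = None) -> CorrelationTable:
    """Pairwise Pearson correlation matrix over participant records.

    ``data`` is a DataFrame or anything convertible to one (e.g. a list of
    record dicts or dataclasses). Pairs with fewer than 4 complete cases are
    reported as NaN.
    """
    if not isinstance(data, pd.DataFrame):
        try:
            data = pd.DataFrame([vars(rec) if hasattr(rec, "__dataclass_fields__") else rec for rec in data])
        except TypeError:
            data = pd.DataFrame(data)
    if variables is None:
        variables = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise KeyError(f"variables not in data: {missing}")

    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    cols = [pd.to_numeric(data[v], errors="coerce").to_numpy(dtype=float) for v in variables]
    for i in range(k):
        for j in range(i, k):
            mask = np.isfinite(cols[i]) & np.isfinite(cols[j])
            m = int(mask.sum())
            n[i, j] = n[j, i] = m
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            if m < 4:
                continue
            res = stats.pearsonr(cols[i][mask], cols[j][mask])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)

    idx = list(variables)
    return CorrelationTable(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )
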