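"""Cohort-level statistics: aggregation, age regressions, sex comparison.

Specimens — not individual imaged regions — are the statistical units:
each metric is first averaged across a specimen's imaged areas, then
regressed on age by ordinary least squares, reporting slope, intercept,
Pearson R and its two-sided p-value.  Relative-change statements
("X% larger by age 80") are evaluated on the fitted line; for
negative-valued indices "larger" means growth in absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AgeRegression:
    """Ordinary least-squares fit of one metric against age."""

    metric_name: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    residual_sd: float

    def predict(self, age: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(age, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        return {"metric": self.metric_name, "slope": self.slope,
                "intercept": self.intercept, "r": self.pearson_r,
                "p": self.p_value, "n": self.n,
                "residual_sd": self.residual_sd}


def aggregate_specimen(regions: Sequence[Mapping[str, float]] | pd.DataFrame
                       ) -> pd.Series:
    """Unweighted per-specimen mean and sd of each metric across regions.

    With a single region the sd is reported as 0 and flagged through the
    ``n_regions`` field.
    """
    df = pd.DataFrame(regions)
    if df.empty:
        raise ValueError("cannot aggregate an empty region list")
    num = df.select_dtypes("number")
    out = {}
    for col in num.columns:
        vals = num[col].dropna()
        out[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
        out[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["n_regions"] = int(len(df))
    return pd.Series(out)


def fit_age_regression(ages: Sequence[float], values: Sequence[float],
                       metric_name: str = "metric") -> AgeRegression:
    """Least-squares line of a specimen-level metric against age.

    Pearson R and the two-sided t-test p-value come with the fit; at
    least three specimens with non-constant ages and values are needed.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ages and values must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 specimens for a regression")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant: regression undefined")
    if np.ptp(y) == 0:
        raise ValueError("metric is constant: Pearson r undefined")
    res = sps.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return AgeRegression(metric_name=metric_name, slope=float(res.slope),
                         intercept=float(res.intercept),
                         pearson_r=float(res.rvalue),
                         p_value=float(res.pvalue), n=int(len(x)),
                         residual_sd=float(np.std(resid, ddof=2)) if len(x) > 2
                         else 0.0)


def relative_change(reg: AgeRegression, age_from: float, age_to: float,
                    signed: bool = False) -> dict:
    """Percent change of the fitted line between two ages.

    By default the change in *magnitude*,
    100·(|line(age_to)| − |line(age_from)|)/|line(age_from)| — the natural
    reading of "larger" for a negative-valued index; ``signed=True`` uses
    the raw values instead.  A line crossing zero between the two ages is
    flagged.
    """
    y0 = float(reg.predict(age_from))
    y1 = float(reg.predict(age_to))
    if y0 == 0:
        raise ValueError(f"line({age_from}) = 0: relative change undefined")
    crosses = (y0 < 0) != (y1 < 0) and y1 != 0
    if signed:
        pct = 100.0 * (y1 - y0) / y0
    else:
        pct = 100.0 * (abs(y1) - abs(y0)) / abs(y0)
    return {"percent": pct, "from": y0, "to": y1,
            "crosses_zero": bool(crosses), "signed": signed}


def sex_comparison(ages_by_sex: Mapping[str, Sequence[float]]) -> dict:
    """Two-sided Mann–Whitney U comparison of ages between the sexes.

    The exact null distribution is used for small samples without ties,
    the normal approximation (tie-corrected) otherwise; the method chosen
    is recorded in the result.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in ages_by_sex.items()}
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    (ka, a), (kb, b) = groups.items()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(a), len(b)) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"groups": (ka, kb), "n": (len(a), len(b)),
            "U": float(res.statistic), "p": float(res.pvalue),
            "method": method}
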