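"""Impact of inconsistent observations on long-term onset trends.

The temporal trend in flowering-onset DOY is modeled by ordinary least
squares on calendar year, once on all resolved observations ("full") and once
on the consistent subset only ("clean").  An analysis of covariance
(DOY ~ year + consistency + year x consistency) tests whether the two groups
share a slope: the interaction term is the slope-difference test.  Slopes are
in days per year; multiplying by ten gives the days-per-decade rate usually
quoted for phenological advancement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import Observation
from .outlier_flag import ConsistencyFlag

__all__ = [
    "TrendResult",
    "AncovaResult",
    "fit_trend",
    "compare_trends",
    "decadal_rate",
]


@dataclass(frozen=True)
class TrendResult:
    slope: float  # days/year
    intercept: float  # DOY at year 0
    se_slope: float
    p_slope: float
    n: int
    r2: float

    def intercept_at(self, year0: int) -> float:
        """Fitted DOY at a reference year (readability; the slope is
        invariant to centering)."""
        return self.intercept + self.slope * year0


@dataclass(frozen=True)
class AncovaResult:
    slope_full: float
    slope_clean: float
    interaction_estimate: float  # inconsistent-group slope minus consistent-group slope
    se_interaction: float
    p_interaction: float
    p_group: float
    n: int


def fit_trend(years: Sequence[float], doys: Sequence[float]) -> TrendResult:
    """OLS of onset DOY on calendar year with a two-sided slope t-test."""
    years = np.asarray(years, dtype=float)
    doys = np.asarray(doys, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(years) == 0:
        raise ValueError("all years identical; trend is undefined")
    res = sm.OLS(doys, sm.add_constant(years)).fit()
    return TrendResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        se_slope=float(res.bse[1]),
        p_slope=float(res.pvalues[1]),
        n=len(years),
        r2=float(res.rsquared),
    )


def compare_trends(
    observations: Sequence[Observation],
    flags: Sequence[ConsistencyFlag],
) -> tuple[TrendResult, TrendResult, AncovaResult | None]:
    """Trends with and without the flagged observations, plus the ANCOVA.

    Unresolved observations enter neither fit.  When no observation is
    flagged inconsistent the two trends coincide and the ANCOVA is skipped
    (returned as None).
    """
    if len(flags) != len(observations):
        raise ValueError("one flag per observation required")
    years = np.array([o.year for o in observations], dtype=float)
    doys = np.array([o.onset_doy for o in observations], dtype=float)
    verdicts = np.array([f.verdict for f in flags])
    resolved = verdicts != "unresolved"
    inconsistent = np.isin(verdicts, ("inconsistent_early", "inconsistent_late"))
    clean = verdicts == "consistent"

    full = fit_trend(years[resolved], doys[resolved])
    clean_trend = fit_trend(years[clean], doys[clean])
    if not inconsistent.any():
        return full, clean_trend, None

    # ANCOVA on the resolved observations: DOY ~ year * consistency
    y = doys[resolved]
    yr = years[resolved]
    grp = inconsistent[resolved].astype(float)
    Xd = sm.add_constant(np.column_stack([yr, grp, yr * grp]))
    res = sm.OLS(y, Xd).fit()
    ancova = AncovaResult(
        slope_full=full.slope,
        slope_clean=clean_trend.slope,
        interaction_estimate=float(res.params[3]),
        se_interaction=float(res.bse[3]),
        p_interaction=float(res.pvalues[3]),
        p_group=float(res.pvalues[2]),
        n=int(resolved.sum()),
    )
    return full, clean_trend, ancova


def decadal_rate(trend: TrendResult | float) -> float:
    """Convert a days-per-year slope to days per decade."""
    slope = trend.slope if isinstance(trend, TrendResult) else float(trend)
    return slope * 10.0
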