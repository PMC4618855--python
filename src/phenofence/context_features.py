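"""Contextual variables: 3 geographic + 8 cumulative-climate features.

Phenological onsets are driven by the climate an individual plant has
experienced since the start of the year, so each observation is described by
its location (latitude, longitude, elevation) plus eight climatic parameters
accumulated from 1 January to the reported onset DOY: maximum, minimum and
average daily temperature, day length, precipitation, solar radiation, snow
water equivalent and water vapor pressure — 11 contextual variables in all.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXT_COLUMNS",
    "CLIMATE_COLUMNS",
    "read_climate",
    "cumulative_context",
    "assemble_context_matrix",
    "standardize",
]

#: canonical context-matrix column order
CONTEXT_COLUMNS = [
    "latitude",
    "longitude",
    "elevation",
    "cum_tmax",
    "cum_tmin",
    "cum_tavg",
    "cum_dayl",
    "cum_prcp",
    "cum_srad",
    "cum_swe",
    "cum_vp",
]

#: daily-climate CSV columns (one row per location-day)
CLIMATE_COLUMNS = [
    "location_id",
    "year",
    "doy",
    "tmax",
    "tmin",
    "prcp",
    "vp",
    "srad",
    "dayl",
    "swe",
]

_CUM_MAP = {
    "cum_tmax": "tmax",
    "cum_tmin": "tmin",
    "cum_dayl": "dayl",
    "cum_prcp": "prcp",
    "cum_srad": "srad",
    "cum_swe": "swe",
    "cum_vp": "vp",
}


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read a daily-climate CSV and validate its basic structure."""
    df = pd.read_csv(path, dtype={"location_id": str})
    missing = [c for c in CLIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"climate table missing columns: {missing}")
    bad = df["tmax"] < df["tmin"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"tmax < tmin at location {df['location_id'].iloc[i]!r} "
            f"year {df['year'].iloc[i]} doy {df['doy'].iloc[i]}"
        )
    return df


def cumulative_context(series: pd.DataFrame, onset_doy: int) -> dict[str, float]:
    """Accumulate climatic parameters from 1 January to the onset DOY.

    ``series`` holds the daily rows for one location-year.  Each cumulative
    value is the plain sum of the daily parameter over doys 1..onset_doy;
    daily average temperature (tmax+tmin)/2 is summed the same way.  A gap in
    the daily coverage is a hard error listing the missing doys.
    """
    doys = series["doy"].to_numpy()
    wanted = np.arange(1, onset_doy + 1)
    present = np.isin(wanted, doys)
    if not present.all():
        missing = wanted[~present].tolist()
        raise ValueError(f"climate series has gaps; missing doys {missing}")
    window = series[series["doy"] <= onset_doy]
    out = {k: float(window[v].sum()) for k, v in _CUM_MAP.items()}
    out["cum_tavg"] = float(((window["tmax"] + window["tmin"]) / 2.0).sum())
    return out


def assemble_context_matrix(
    observations: Sequence,
    climate: pd.DataFrame,
) -> tuple[np.ndarray, list[str]]:
    """Build the n x 11 context matrix, one row per observation.

    Climate is matched on the observation's ``location_id`` and ``year``
    exactly (no spatial interpolation); a missing series is a hard error
    naming the observation.  Row order follows the observation order and
    column order is :data:`CONTEXT_COLUMNS`.
    """
    groups = dict(tuple(climate.groupby(["location_id", "year"], sort=False)))
    rows = np.empty((len(observations), len(CONTEXT_COLUMNS)))
    for i, obs in enumerate(observations):
        key = (obs.location_id, obs.year)
        if key not in groups:
            raise ValueError(
                f"no climate series for obs_id {obs.obs_id!r} "
                f"(location {obs.location_id!r}, year {obs.year})"
            )
        cum = cumulative_context(groups[key], obs.onset_doy)
        rows[i] = [obs.latitude, obs.longitude, obs.elevation] + [
            cum[c] for c in CONTEXT_COLUMNS[3:]
        ]
    return rows, list(CONTEXT_COLUMNS)


def standardize(
    matrix: np.ndarray,
    columns: Sequence[str] | None = None,
    drop_constant: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Z-score each column (sample standard deviation, ddof=1).

    Raw context variables span seven orders of magnitude (cumulative day
    length ~5e6 s vs latitude ~42 deg), which would let a single column
    dominate any Euclidean embedding; standardization puts the 11 variables
    on a common scale.  Returns ``(z, means, sds, dropped_columns)``; the
    transform is invertible from the stored means and sds.  A constant column
    is an error unless ``drop_constant`` is set, in which case it is removed
    and reported.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize needs a 2-D matrix with n >= 2 rows")
    names = list(columns) if columns is not None else [f"x{j}" for j in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    constant = sds == 0
    dropped: list[str] = []
    if constant.any():
        if not drop_constant:
            bad = [names[j] for j in np.flatnonzero(constant)]
            raise ValueError(f"constant column(s) {bad}; pass drop_constant=True to remove")
        dropped = [names[j] for j in np.flatnonzero(constant)]
        keep = ~constant
        X, means, sds = X[:, keep], means[keep], sds[keep]
    return (X - means) / sds, means, sds, dropped
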