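"""Cumulative-climate feature construction and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenofence.context_features import (
    CONTEXT_COLUMNS,
    assemble_context_matrix,
    cumulative_context,
    standardize,
)
from phenofence.data_model import Observation


def _series(days, tmax=10.0, tmin=0.0, **kw):
    n = len(days)
    base = {
        "location_id": "L1",
        "year": 2000,
        "doy": days,
        "tmax": np.full(n, tmax),
        "tmin": np.full(n, tmin),
        "prcp": np.full(n, kw.get("prcp", 1.0)),
        "vp": np.full(n, kw.get("vp", 500.0)),
        "srad": np.full(n, kw.get("srad", 200.0)),
        "dayl": np.full(n, kw.get("dayl", 40000.0)),
        "swe": np.full(n, kw.get("swe", 2.0)),
    }
    return pd.DataFrame(base)


def test_constant_series_closed_form():
    s = _series(np.arange(1, 41))
    cum = cumulative_context(s, 10)
    assert cum["cum_tmax"] == pytest.approx(100.0)
    assert cum["cum_tmin"] == pytest.approx(0.0)
    assert cum["cum_tavg"] == pytest.approx(50.0)
    assert cum["cum_prcp"] == pytest.approx(10.0)


def test_single_day_and_zero_series():
    s = _series(np.arange(1, 10))
    cum = cumulative_context(s, 1)
    assert cum["cum_tmax"] == pytest.approx(10.0)
    z = _series(np.arange(1, 10), tmax=0, tmin=0, prcp=0, vp=0, srad=0, dayl=0, swe=0)
    assert all(v == 0 for v in cumulative_context(z, 5).values())


def test_gap_in_series_is_hard_error():
    s = _series(np.array([1, 2, 4, 5]))
    with pytest.raises(ValueError, match=r"missing doys \[3\]"):
        cumulative_context(s, 5)


@given(st.integers(2, 60), st.integers(0, 10_000))
@settings(deadline=None, max_examples=30)
def test_cumulative_matches_brute_force_and_is_monotone(onset, seed):
    """Vectorized accumulation agrees with an explicit per-day loop to 1e-9
    relative, and is non-decreasing in onset DOY for nonnegative parameters."""
    rng = np.random.default_rng(seed)
    n = 70
    df = _series(np.arange(1, n + 1))
    for c in ("tmax", "tmin", "prcp", "vp", "srad", "dayl", "swe"):
        df[c] = rng.uniform(0, 10, n)
    df["tmax"] = df["tmin"] + rng.uniform(0, 5, n)
    cum = cumulative_context(df, onset)
    # independent oracle: plain python loop over rows
    acc = {k: 0.0 for k in cum}
    for _, row in df[df["doy"] <= onset].iterrows():
        for name, src in [
            ("cum_tmax", "tmax"), ("cum_tmin", "tmin"), ("cum_prcp", "prcp"),
            ("cum_vp", "vp"), ("cum_srad", "srad"), ("cum_dayl", "dayl"),
            ("cum_swe", "swe"),
        ]:
            acc[name] += row[src]
        acc["cum_tavg"] += (row["tmax"] + row["tmin"]) / 2
    for k in cum:
        assert cum[k] == pytest.approx(acc[k], rel=1e-9)
    assert cum["cum_tavg"] == pytest.approx((cum["cum_tmax"] + cum["cum_tmin"]) / 2)
    prev = cumulative_context(df, onset - 1)
    for k in ("cum_prcp", "cum_srad", "cum_dayl", "cum_swe", "cum_vp"):
        assert cum[k] >= prev[k]


def _obs(obs_id="o1", year=2000, doy=10):
    return Observation(obs_id, year, doy, 42.0, -79.0, 200.0, location_id="L1")


def test_assemble_matrix_composition_and_order():
    climate = _series(np.arange(1, 30))
    X, names = assemble_context_matrix([_obs()], climate)
    assert names == CONTEXT_COLUMNS and X.shape == (1, 11)
    assert X[0, :3] == pytest.approx([42.0, -79.0, 200.0])
    cum = cumulative_context(climate, 10)
    assert X[0, 3:] == pytest.approx([cum[c] for c in CONTEXT_COLUMNS[3:]])
    # empty input
    X0, _ = assemble_context_matrix([], climate)
    assert X0.shape == (0, 11)
    # permutation equivariance
    o2 = Observation("o2", 2000, 20, 41.0, -80.0, 100.0, location_id="L1")
    Xa, _ = assemble_context_matrix([_obs(), o2], climate)
    Xb, _ = assemble_context_matrix([o2, _obs()], climate)
    assert np.allclose(Xa, Xb[::-1])


def test_assemble_matrix_missing_series():
    climate = _series(np.arange(1, 30))
    bad = Observation("ghost", 1999, 10, 42.0, -79.0, 200.0, location_id="L9")
    with pytest.raises(ValueError, match="ghost"):
        assemble_context_matrix([bad], climate)


def test_standardize_sample_sd_convention():
    Z, mean, sd, dropped = standardize(np.array([[1.0], [2.0], [3.0]]))
    assert Z[:, 0] == pytest.approx([-1.0, 0.0, 1.0])  # sample sd (ddof=1)
    assert mean[0] == pytest.approx(2.0) and sd[0] == pytest.approx(1.0)
    # idempotence within tolerance
    Z2, _, _, _ = standardize(Z)
    assert np.allclose(Z, Z2)
    # columns re-centered and unit-scaled
    rng = np.random.default_rng(0)
    M = rng.normal(5, 3, size=(50, 4))
    Zm, means, sds, _ = standardize(M)
    assert np.allclose(Zm.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(Zm.std(axis=0, ddof=1), 1, atol=1e-10)
    assert np.allclose(Zm * sds + means, M)


def test_standardize_constant_column():
    M = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(ValueError, match="constant"):
        standardize(M)
    Z, _, _, dropped = standardize(M, columns=["c", "x"], drop_constant=True)
    assert dropped == ["c"] and Z.shape == (10, 1)
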