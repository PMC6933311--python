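"""ARGOS quality/speed filtering, hourly interpolation, habitat grids."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sealflux.tracks import (
    GridField,
    _speeds,
    classify_positions,
    haversine_m,
    interpolate_hourly,
    quality_filter,
    speed_filter,
)


def track(times_h, lats, lons, quality="1"):
    q = [quality] * len(lats) if isinstance(quality, str) else quality
    return pd.DataFrame(
        {"time": np.asarray(times_h) / 24.0, "lat": lats, "lon": lons, "quality": q}
    )


# -- quality filter ---------------------------------------------------------


def test_all_bad_quality_removed():
    t = track([0, 1, 2], [57.0] * 3, [-170.0] * 3, quality=["B", "Z", "B"])
    assert len(quality_filter(t)) == 0


def test_mixed_quality_keeps_good_in_order(rng):
    n = 40
    quals = rng.choice(list("3210ABZ"), size=n)
    t = track(np.arange(n), 57 + rng.normal(0, 0.01, n), -170 + rng.normal(0, 0.01, n),
              quality=list(quals))
    out = quality_filter(t)
    assert len(out) == int(np.sum(~np.isin(quals, ["B", "Z"])))
    assert (out["time"].diff().dropna() > 0).all()


# -- speed filter -----------------------------------------------------------


def test_slow_straight_transit_unchanged():
    # ~1 m/s eastward at 57N: 3.6 km/h ~ 0.059 deg lon/h
    lons = -170 + np.arange(10) * 0.059
    t = track(np.arange(10), [57.0] * 10, lons)
    out = speed_filter(t, vmax=3.0)
    assert len(out) == 10


def test_single_spike_removed():
    lons = -170 + np.arange(9) * 0.01
    lats = np.full(9, 57.0)
    lats[4] = 58.0  # ~111 km excursion within an hour
    t = track(np.arange(9), lats, lons)
    out = speed_filter(t, vmax=3.0)
    assert len(out) == 8
    assert 58.0 not in out["lat"].values
    assert (_speeds(out) <= 3.0).all()


def test_two_points_never_touched():
    t = track([0, 1], [57.0, 60.0], [-170.0, -160.0])
    out = speed_filter(t, vmax=3.0)
    assert len(out) == 2


def test_output_is_subsequence_and_speed_admissible(rng):
    for _ in range(20):
        n = int(rng.integers(4, 12))
        lats = 57 + np.cumsum(rng.normal(0, 0.01, n))
        lons = -170 + np.cumsum(rng.normal(0, 0.01, n))
        spikes = rng.random(n) < 0.25
        lats = np.where(spikes, lats + rng.normal(0, 0.5, n), lats)
        t = track(np.arange(n), lats, lons)
        out = speed_filter(t, vmax=3.0)
        # subsequence of the input
        merged = t.merge(out, on=["time", "lat", "lon"], how="inner")
        assert len(merged) == len(out)
        assert (out["time"].diff().dropna() > 0).all()
        if len(out) > 2:
            assert (_speeds(out) <= 3.0).all()


def brute_force_minimal_removal(t, vmax):
    """Smallest interior subset whose removal makes all speeds admissible."""
    n = len(t)
    interior = list(range(1, n - 1))
    for k in range(len(interior) + 1):
        for drop in itertools.combinations(interior, k):
            sub = t.drop(index=list(drop)).reset_index(drop=True)
            if len(sub) < 2 or (_speeds(sub) <= vmax).all():
                return k
    return len(interior)


def test_matches_minimal_removal_cardinality_on_small_tracks(rng):
    for _ in range(10):
        n = int(rng.integers(5, 9))
        lats = np.full(n, 57.0) + rng.normal(0, 0.005, n)
        lons = -170 + np.arange(n) * 0.01
        for i in rng.choice(np.arange(1, n - 1), size=2, replace=False):
            lats[i] += rng.choice([-1, 1]) * rng.uniform(0.4, 0.9)
        t = track(np.arange(n), lats, lons)
        out = speed_filter(t, vmax=3.0)
        k_min = brute_force_minimal_removal(t, 3.0)
        assert len(t) - len(out) == k_min


# -- interpolation ----------------------------------------------------------


def test_fix_exactly_on_hour_returned_unchanged():
    t = track([0, 1, 2], [57.0, 57.5, 58.0], [-170.0, -170.0, -170.0])
    out = interpolate_hourly(t, 0.0, 2 / 24.0)
    assert out["lat"].tolist() == pytest.approx([57.0, 57.5, 58.0])
    assert not out["extrapolated"].any()


def test_midpoint_of_two_fixes_is_geodesic_midpoint():
    t = track([0, 2], [57.0, 57.0], [-170.0, -169.0])
    out = interpolate_hourly(t, 0.0, 2 / 24.0)
    mid = out.iloc[1]
    # geodesic midpoint of same-latitude points: halfway in lon, slightly poleward
    assert mid["lon"] == pytest.approx(-169.5, abs=1e-6)
    assert mid["lat"] >= 57.0
    d1 = haversine_m(57.0, -170.0, mid["lat"], mid["lon"])
    d2 = haversine_m(57.0, -169.0, mid["lat"], mid["lon"])
    assert d1 == pytest.approx(d2, rel=1e-6)


@pytest.mark.parametrize("method", ["linear", "ctcrw_lite"])
def test_interpolation_error_shrinks_with_fix_density(method, rng):
    # smooth correlated-velocity truth over 2 days
    hours = np.arange(0, 49)
    vel = np.cumsum(rng.normal(0, 0.004, (49, 2)), axis=0)
    pos = np.cumsum(vel, axis=0)
    lat_true = 57 + pos[:, 0]
    lon_true = -170 + pos[:, 1]
    errs = []
    for step in (8, 2):  # sparse then dense fixes
        sel = np.arange(0, 49, step)
        if 48 not in sel:
            sel = np.append(sel, 48)
        t = track(hours[sel], lat_true[sel], lon_true[sel])
        out = interpolate_hourly(t, 0.0, 2.0, method=method)
        err = haversine_m(out["lat"].values, out["lon"].values, lat_true, lon_true)
        errs.append(np.sqrt(np.mean(err**2)))
    assert errs[1] < errs[0]


# -- habitat classification -------------------------------------------------


def flat_grid(value):
    lon = np.linspace(-171, -169, 11)
    lat = np.linspace(56, 58, 11)
    return GridField(lon, lat, np.full((11, 11), value))


def test_flat_shallow_grid_all_shelf():
    pos = pd.DataFrame({"lat": [56.5, 57.5], "lon": [-170.5, -169.5]})
    out = classify_positions(pos, flat_grid(50.0))
    assert (out["habitat"] == "shelf").all()


def test_dive_below_mld():
    pos = pd.DataFrame({"lat": [57.0], "lon": [-170.0]})
    out = classify_positions(pos, flat_grid(3000.0), mld=flat_grid(20.0), dive_depths=[30.0])
    assert out.loc[0, "habitat"] == "pelagic"
    assert out.loc[0, "mld_position"] == "below_mld"


def test_position_outside_grid_is_unknown():
    pos = pd.DataFrame({"lat": [40.0], "lon": [-120.0]})
    out = classify_positions(pos, flat_grid(50.0))
    assert out.loc[0, "habitat"] == "unknown"


def test_grid_lookup_matches_brute_force(rng):
    lon = np.linspace(-171, -169, 15)
    lat = np.linspace(56, 58, 13)
    vals = rng.uniform(10, 400, (13, 15))
    g = GridField(lon, lat, vals)
    plat = rng.uniform(56, 58, 50)
    plon = rng.uniform(-171, -169, 50)
    got = g.lookup(plat, plon)
    for k in range(50):
        i = np.abs(lat - plat[k]).argmin()
        j = np.abs(lon - plon[k]).argmin()
        assert got[k] == vals[i, j]


def test_grid_round_trip_from_table(rng):
    lon = np.linspace(-171, -169, 5)
    lat = np.linspace(56, 58, 4)
    rows = [{"lon": lo, "lat": la, "value": 100 * la + lo} for la in lat for lo in lon]
    g = GridField.from_table(pd.DataFrame(rows))
    assert g.lookup([lat[1]], [lon[3]])[0] == pytest.approx(100 * lat[1] + lon[3])
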