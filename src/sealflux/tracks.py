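"""ARGOS track filtering, hourly interpolation and habitat classification.

Satellite-derived locations carry a quality class (3, 2, 1, 0, A, B, Z, best
to worst).  Processing follows the standard at-sea workflow: drop the two
unusable classes (B, Z), remove positions implying unrealistic transit
speeds, then interpolate to a regular hourly time base.  Positions can be
classified against user-supplied bathymetry and mixed-layer-depth grids.

Tracks are pandas DataFrames with columns ``time`` (decimal days), ``lat``,
``lon`` (degrees) and ``quality`` (str).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "haversine_m",
    "quality_filter",
    "speed_filter",
    "interpolate_hourly",
    "GridField",
    "classify_positions",
]

EARTH_RADIUS_M = 6_371_000.0
BAD_QUALITY = frozenset({"B", "Z"})


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on a spherical Earth (R = 6371 km)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def _speeds(df: pd.DataFrame) -> np.ndarray:
    """Adjacent-pair speeds (m/s); times in decimal days."""
    d = haversine_m(
        df["lat"].values[:-1], df["lon"].values[:-1], df["lat"].values[1:], df["lon"].values[1:]
    )
    dt_s = np.diff(df["time"].values) * 86_400.0
    with np.errstate(divide="ignore"):
        return np.where(dt_s > 0, d / np.maximum(dt_s, 1e-12), np.inf)


def quality_filter(locs: pd.DataFrame) -> pd.DataFrame:
    """Drop unusable ARGOS quality classes (B and Z), preserving order."""
    keep = ~locs["quality"].astype(str).str.upper().isin(BAD_QUALITY)
    return locs[keep].reset_index(drop=True)


def speed_filter(locs: pd.DataFrame, vmax: float = 3.0) -> pd.DataFrame:
    """Remove locations implying transit speeds above ``vmax`` (m s⁻¹).

    Iteratively deletes the interior point with the worst implied speed to
    either neighbour until all adjacent-pair speeds are admissible, then
    drops an endpoint if only its own segment still violates.  With two
    points nothing is removed (their mutual speed cannot identify the bad
    fix); this degenerate case is left to the caller.  The output is always
    an order-preserving subsequence of the input.
    """
    df = locs.reset_index(drop=True)
    if len(df) <= 2:
        return df
    while len(df) > 2:
        v = _speeds(df)
        if (v <= vmax).all():
            break
        hi = np.maximum(v[:-1], v[1:])  # worst adjacent speed per interior point
        if hi.max() <= vmax:
            # only an endpoint segment violates; drop the offending endpoint
            drop = 0 if v[0] > vmax else len(df) - 1
        else:
            # among violating interior points, drop the one whose removal most
            # reduces its local speed: a genuine spike bridges to a slow
            # segment, an innocent point between two spikes does not
            lat, lon, t = df["lat"].values, df["lon"].values, df["time"].values
            idx = np.flatnonzero(hi > vmax)  # interior points 1..n-2, offset -1
            d_bridge = haversine_m(lat[idx], lon[idx], lat[idx + 2], lon[idx + 2])
            dt_s = np.maximum((t[idx + 2] - t[idx]) * 86_400.0, 1e-12)
            benefit = hi[idx] - d_bridge / dt_s
            drop = int(idx[np.argmax(benefit)]) + 1
        df = df.drop(index=drop).reset_index(drop=True)
    return df


def interpolate_hourly(
    locs: pd.DataFrame,
    t_depart: float,
    t_arrive: float,
    method: str = "linear",
) -> pd.DataFrame:
    """Estimate positions at each whole hour in ``[t_depart, t_arrive]``.

    ``linear`` interpolates along the great circle between bracketing fixes
    (spherical linear interpolation of the position vectors).  ``ctcrw_lite``
    runs a correlated-velocity Kalman smoother on local planar coordinates —
    a light-weight stand-in for a continuous-time correlated random walk —
    and evaluates the smoothed mean at the hourly times.  Hours outside the
    span of the fixes are extrapolated and flagged.

    Returns columns ``time, lat, lon, extrapolated``.
    """
    df = locs.sort_values("time").reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least 2 locations to interpolate")
    hours = np.arange(np.ceil(t_depart * 24.0), np.floor(t_arrive * 24.0) + 1) / 24.0
    t = df["time"].values
    extrap = (hours < t[0]) | (hours > t[-1])
    if method == "linear":
        lat, lon = _slerp_track(df, hours)
    elif method == "ctcrw_lite":
        lat, lon = _ctcrw_lite(df, hours)
    else:
        raise ValueError(f"unknown interpolation method: {method!r}")
    return pd.DataFrame({"time": hours, "lat": lat, "lon": lon, "extrapolated": extrap})


def _to_unit(lat, lon):
    la, lo = np.radians(lat), np.radians(lon)
    return np.stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1)


def _from_unit(v):
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1, 1)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lat, lon


def _slerp_track(df: pd.DataFrame, hours: np.ndarray):
    t = df["time"].values
    u = _to_unit(df["lat"].values, df["lon"].values)
    idx = np.clip(np.searchsorted(t, hours, side="right") - 1, 0, len(t) - 2)
    t0, t1 = t[idx], t[idx + 1]
    frac = np.where(t1 > t0, (hours - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
    a, b = u[idx], u[idx + 1]
    dot = np.clip((a * b).sum(axis=1), -1.0, 1.0)
    omega = np.arccos(dot)
    small = omega < 1e-9
    so = np.where(small, 1.0, np.sin(np.where(small, 1.0, omega)))
    w0 = np.where(small, 1.0 - frac, np.sin((1.0 - frac) * omega) / so)
    w1 = np.where(small, frac, np.sin(frac * omega) / so)
    v = w0[:, None] * a + w1[:, None] * b
    return _from_unit(v)


def _ctcrw_lite(df: pd.DataFrame, hours: np.ndarray, sigma_obs_m: float = 1500.0,
                sigma_vel: float = 0.15):
    """Correlated-velocity Kalman smoother on a local equirectangular plane.

    State (x, vx, y, vy); constant-velocity transitions with white
    acceleration noise ``sigma_vel`` (m s⁻² scaled), observation noise
    ``sigma_obs_m``.  A fixed-interval RTS smoother is run on the union of
    fix and output times.
    """
    lat0 = float(df["lat"].mean())
    mx = EARTH_RADIUS_M * np.cos(np.radians(lat0)) * np.pi / 180.0  # m per deg lon
    my = EARTH_RADIUS_M * np.pi / 180.0  # m per deg lat
    obs_t = df["time"].values * 86_400.0
    obs = np.stack([df["lon"].values * mx, df["lat"].values * my], axis=1)
    all_t = np.union1d(obs_t, hours * 86_400.0)
    is_obs = np.isin(all_t, obs_t)
    obs_map = {ti: i for i, ti in enumerate(obs_t)}

    H = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])
    R = np.eye(2) * sigma_obs_m**2
    x = np.array([obs[0, 0], 0.0, obs[0, 1], 0.0])
    P = np.diag([sigma_obs_m**2, 1.0, sigma_obs_m**2, 1.0])
    xs_pred, Ps_pred, xs_filt, Ps_filt, Fs = [], [], [], [], []
    prev_t = all_t[0]
    for ti, has in zip(all_t, is_obs):
        dt = ti - prev_t
        F = np.eye(4)
        F[0, 1] = F[2, 3] = dt
        q = sigma_vel**2
        Qb = q * np.array([[dt**3 / 3, dt**2 / 2], [dt**2 / 2, dt]])
        Q = np.zeros((4, 4))
        Q[:2, :2], Q[2:, 2:] = Qb, Qb
        xp, Pp = F @ x, F @ P @ F.T + Q
        if has:
            z = obs[obs_map[ti]]
            S = H @ Pp @ H.T + R
            K = Pp @ H.T @ np.linalg.inv(S)
            x = xp + K @ (z - H @ xp)
            P = (np.eye(4) - K @ H) @ Pp
        else:
            x, P = xp, Pp
        xs_pred.append(xp); Ps_pred.append(Pp); xs_filt.append(x); Ps_filt.append(P); Fs.append(F)
        prev_t = ti
    # RTS backward pass
    n = len(all_t)
    xs = [None] * n
    xs[-1] = xs_filt[-1]
    Ps = Ps_filt[-1]
    for i in range(n - 2, -1, -1):
        C = Ps_filt[i] @ Fs[i + 1].T @ np.linalg.pinv(Ps_pred[i + 1])
        xs[i] = xs_filt[i] + C @ (xs[i + 1] - xs_pred[i + 1])
        Ps = Ps_filt[i] + C @ (Ps - Ps_pred[i + 1]) @ C.T
    sm = np.array(xs)
    out_idx = np.searchsorted(all_t, hours * 86_400.0)
    lon = sm[out_idx, 0] / mx
    lat = sm[out_idx, 2] / my
    return lat, lon


class GridField:
    """Regular lon/lat grid of a scalar field (bathymetry, MLD) with
    nearest-cell lookup; plain-text friendly."""

    def __init__(self, lon: np.ndarray, lat: np.ndarray, values: np.ndarray):
        self.lon = np.asarray(lon, dtype=float)
        self.lat = np.asarray(lat, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.lat), len(self.lon)):
            raise ValueError("values must have shape (n_lat, n_lon)")

    def lookup(self, lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
        """Nearest-cell values; nan outside the grid's bounding box."""
        lat, lon = np.atleast_1d(lat).astype(float), np.atleast_1d(lon).astype(float)
        out = np.full(lat.shape, np.nan)
        half_dlon = 0.5 * (np.diff(self.lon).max() if len(self.lon) > 1 else 1.0)
        half_dlat = 0.5 * (np.diff(self.lat).max() if len(self.lat) > 1 else 1.0)
        inside = (
            (lon >= self.lon.min() - half_dlon) & (lon <= self.lon.max() + half_dlon)
            & (lat >= self.lat.min() - half_dlat) & (lat <= self.lat.max() + half_dlat)
        )
        i = np.abs(lat[inside, None] - self.lat[None, :]).argmin(axis=1)
        j = np.abs(lon[inside, None] - self.lon[None, :]).argmin(axis=1)
        out[inside] = self.values[i, j]
        return out

    @classmethod
    def from_table(cls, df: pd.DataFrame, value_col: str = "value") -> "GridField":
        """Build from a long-format (lon, lat, value) table covering a full grid."""
        lons = np.sort(df["lon"].unique())
        lats = np.sort(df["lat"].unique())
        piv = df.pivot_table(index="lat", columns="lon", values=value_col)
        return cls(lons, lats, piv.reindex(index=lats, columns=lons).values)


def classify_positions(
    positions: pd.DataFrame,
    bathy: GridField,
    mld: GridField | None = None,
    dive_depths: np.ndarray | None = None,
    shelf_isobath_m: float = 200.0,
) -> pd.DataFrame:
    """Label positions shelf vs pelagic, and dives above vs below the MLD.

    A position is ``shelf`` when the local water depth (positive-down
    bathymetry, metres) is shallower than the configured isobath, else
    ``pelagic``; positions outside the grid get ``unknown``.  When an MLD
    field and per-position dive depths are supplied, a dive is ``below_mld``
    when its maximum depth exceeds the local mixed layer depth.
    """
    depth = bathy.lookup(positions["lat"].values, positions["lon"].values)
    habitat = np.where(np.isnan(depth), "unknown",
                       np.where(depth < shelf_isobath_m, "shelf", "pelagic"))
    out = positions.copy()
    out["habitat"] = habitat
    if mld is not None and dive_depths is not None:
        local_mld = mld.lookup(positions["lat"].values, positions["lon"].values)
        dd = np.asarray(dive_depths, dtype=float)
        out["mld_position"] = np.where(
            np.isnan(local_mld), "unknown", np.where(dd > local_mld, "below_mld", "above_mld")
        )
    return out
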