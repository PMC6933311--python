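"""ARGOS track processing: quality and speed filtering, hourly positions,
habitat classification.

Simulates a foraging-trip track observed through satellite telemetry with
class-dependent location error, removes unusable quality classes (B, Z) and
positions implying transit speeds above 3 m/s, interpolates to hourly
positions, and classifies them against a synthetic bathymetry grid.
"""

import numpy as np

from sealflux.simulate import _simulate_track
from sealflux.tracks import (
    GridField,
    classify_positions,
    interpolate_hourly,
    quality_filter,
    speed_filter,
)

rng = np.random.default_rng(11)
raw = _simulate_track(trip_days=5.0, rng=rng)
print(f"raw locations        : {len(raw)}")

good = quality_filter(raw)
print(f"after quality filter : {len(good)}  (B and Z classes removed)")

clean = speed_filter(good, vmax=3.0)
print(f"after speed filter   : {len(clean)}  (max transit rate 3 m/s)")

hourly = interpolate_hourly(clean, clean["time"].min(), clean["time"].max())
print(f"hourly positions     : {len(hourly)}")

# synthetic shelf: shallow (80 m) east of the colony longitude, deep west
lon = np.linspace(-175, -165, 41)
lat = np.linspace(54, 60, 25)
depth = np.where(lon[None, :] > -170.3, 80.0, 2500.0) * np.ones((25, 1))
bathy = GridField(lon, lat, depth)
labelled = classify_positions(hourly, bathy, shelf_isobath_m=200.0)
counts = labelled["habitat"].value_counts()
print(f"habitat of positions : {counts.to_dict()}")
print()
print("Shelf positions overlie water shallower than the 200 m isobath;")
print("the rest are pelagic.")
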