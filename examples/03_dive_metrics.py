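"""From a raw depth trace to trip-level dive metrics.

Generates a two-day depth series with nocturnal dive bouts and a drifting
pressure sensor, applies zero-offset correction, detects dives deeper than
3 m, and summarizes the trip.
"""

import numpy as np

from sealflux.dives import detect_dives, trip_summary, zero_offset_correct
from sealflux.simulate import SimulationConfig, _simulate_depths
from sealflux.dives import DepthSeries

rng = np.random.default_rng(7)
config = SimulationConfig(seed=7)
series = _simulate_depths(trip_days=2.0, depth_target=26.0, pct_dive_target=13.0,
                          config=config, rng=rng)

# add slow sensor drift of +2.5 m over the record
drifted = DepthSeries(
    series.seal_id, series.t0, series.dt,
    series.depth + np.linspace(0.0, 2.5, len(series.depth)),
)

corrected = zero_offset_correct(drifted)
dives = detect_dives(corrected, threshold=3.0)
# night windows: 21:00 to 06:00 the next morning, for each day, in seconds
night = [(d * 86400 - 10800, d * 86400 + 21600) for d in range(3)]
summary = trip_summary(dives, trip_duration_days=2.0, night_windows_s=night)

print(f"dives detected      : {summary.n_dives}")
print(f"mean max dive depth : {summary.mean_max_depth:.1f} m")
print(f"percent time diving : {summary.pct_time_diving:.1f} %")
print(f"percent dives night : {summary.pct_dives_night:.1f} %")
print()
print("A dive is a maximal run of samples strictly deeper than 3 m after")
print("the surface baseline (sensor drift) has been removed.")
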