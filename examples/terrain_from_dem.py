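"""Slope, aspect and aspect sectors from a synthetic DEM.

Builds an inclined-plane DEM with a known gradient, derives terrain layers
and checks them against the closed form.
"""

import numpy as np

import terroirgrid as tg

cfg = tg.FixtureConfig(dem_kind="plane", gradient=(0.03, 0.04), shape=(20, 20))
dem = tg.make_dem(cfg)
slope = tg.compute_slope(dem)
aspect = tg.compute_aspect(dem)
sectors = tg.classify_aspect(aspect)

print(f"interior slope:  {slope.values[10, 10]:.3f} % rise (closed form: 5.000)")
print(f"interior aspect: {aspect.values[10, 10]:.2f} deg (downslope azimuth)")
code = int(sectors.values[10, 10])
from terroirgrid.terrain import ASPECT_NAMES

print(f"aspect sector:   {ASPECT_NAMES[code]}")
print("A plane rising to the north-east faces south-west: vineyards on it get")
print("afternoon sun, which is why aspect sectors matter for site selection.")
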