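"""Standardized PCA of the seven-layer environmental stack.

Builds the stack (elevation, AWC, pH, depth, GDD, FFD, precipitation) on a
synthetic landscape, z-scores it and reports variance fractions and loadings.
"""

import numpy as np

import terroirgrid as tg

cfg = tg.FixtureConfig(seed=3, dem_kind="composite", n_mapunits=8, shape=(40, 60),
                       noise_sd_t=0.3, noise_sd_ppt=3.0, noise_sd_frost=2.0)
dem, normals, survey, _ = tg.make_fixture(cfg)
surfaces = tg.compute_climate_surfaces(normals)
extent = dem.transform.extent(dem.shape)
layers = {
    "elevation": dem,
    "awc": tg.rasterize_attribute(survey, "awc", cell=cfg.cell, extent=extent),
    "ph": tg.rasterize_attribute(survey, "ph", cell=cfg.cell, extent=extent),
    "depth": tg.rasterize_attribute(survey, "depth", cell=cfg.cell, extent=extent),
    "gdd": surfaces.gdd, "ffd": surfaces.ffd, "gsp": surfaces.gsp,
}
stack = tg.standardize_layers(tg.build_stack(layers))
result = tg.principal_components(stack, k=2)

print("variance fractions:",
      np.round(result.variance_fractions, 3), "(first two components)")
print("cumulative:        ", np.round(result.cumulative_fractions, 3))
print("\nloadings (eigenvector components):")
print(result.loadings_table().round(3).to_string())
print("\nElevation, GDD, FFD and precipitation load together with opposite")
print("signs on PC1: the elevation-climate axis that dominates terrain-driven")
print("appellations. Soil attributes separate on the next component.")
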