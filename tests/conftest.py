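import numpy as np
import pytest

import terroirgrid as tg


@pytest.fixture
def small_transform():
    return tg.GridTransform(500_000.0, 5_150_000.0, 30.0, -30.0)


@pytest.fixture
def constant_grid(small_transform):
    def _make(value, shape=(5, 5)):
        return tg.Grid(np.full(shape, float(value)), small_transform, "EPSG:32611")

    return _make


@pytest.fixture
def constant_normals(constant_grid):
    """Monthly normals with the same mean temperature every month."""

    def _make(tavg, diurnal=12.0, ppt=10.0, spring=120.0, fall=290.0, shape=(5, 5)):
        months = range(4, 11)
        return tg.MonthlyNormals(
            tmax={m: constant_grid(tavg + diurnal / 2, shape) for m in months},
            tmin={m: constant_grid(tavg - diurnal / 2, shape) for m in months},
            ppt={m: constant_grid(ppt, shape) for m in months},
            last_spring_frost=constant_grid(spring, shape),
            first_fall_frost=constant_grid(fall, shape),
        )

    return _make


@pytest.fixture
def plane_dem():
    def _make(gx, gy, shape=(10, 12), cell=30.0, base=200.0):
        cfg = tg.FixtureConfig(dem_kind="plane", gradient=(gx, gy), shape=shape,
                               cell=cell, base_elevation=base)
        return tg.make_dem(cfg)

    return _make
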