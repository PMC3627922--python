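"""Published reference summaries of the 13 inland Pacific Northwest AVAs.

Two small tables ship with the package as worked-example fixtures:

* ``load_ava_site_means()`` — mean site characteristics per appellation
  (elevation m, slope %, insolation kWh/m^2, AWC cm/cm, depth cm, pH,
  GDD C-degrees, BEDD C-degrees, FFD days, growing-season precipitation mm),
* ``load_ava_drainage_classes()`` — drainage-class area percentages per
  appellation (columns ``drainage_ED`` .. ``drainage_VPD``; classes absent
  from an appellation are missing values, and trace shares below 0.01% are
  stored as 0.005).

Both frames are indexed by appellation name and use the same column names as
:func:`terroirgrid.zonal_summary.summarize_zones`, so the contrast and
column-average operations run on them directly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("terroirgrid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col="zone")


def load_ava_site_means() -> pd.DataFrame:
    """Mean site characteristics of the 13 inland Pacific Northwest AVAs."""
    return _load("ava_site_means.csv")


def load_ava_drainage_classes() -> pd.DataFrame:
    """Drainage-class area percentages of the 13 AVAs (percent units)."""
    return _load("ava_drainage_classes.csv")
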