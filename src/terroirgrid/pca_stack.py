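"""Standardized PCA over the seven-layer environmental raster stack.

The stack holds, in fixed order: elevation, soil AWC, soil pH, depth to
restrictive layer, GDD, FFD and growing-season precipitation.  Slope, aspect,
insolation (all DEM-derived), drainage class (categorical) and BEDD (derived
from the same normals as GDD) are deliberately excluded to avoid redundant or
non-numeric inputs.  Layers are z-scored over the common validity mask (cells
with data in every layer), so the eigen-decomposition of the covariance
matrix of the standardized stack equals the correlation matrix of the raw
layers.  Loadings are sign-fixed so each eigenvector's largest-magnitude
component is positive, making results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_io import Grid

#: Fixed layer order of the PCA stack.
LAYER_ORDER = ("elevation", "awc", "ph", "depth", "gdd", "ffd", "gsp")


@dataclass
class StackSpec:
    """Ordered layer grids plus the common validity mask."""

    grids: dict[str, Grid]
    mask: np.ndarray = None  # True where every layer has data

    def __post_init__(self) -> None:
        missing = [n for n in LAYER_ORDER if n not in self.grids]
        if missing:
            raise ValueError(f"stack missing layers: {missing}")
        ref = self.grids[LAYER_ORDER[0]]
        for name in LAYER_ORDER[1:]:
            ref.assert_aligned(self.grids[name])
        if self.mask is None:
            mask = np.ones(ref.shape, dtype=bool)
            for name in LAYER_ORDER:
                mask &= ~self.grids[name].nodata_mask
            self.mask = mask

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.mask))

    def matrix(self) -> np.ndarray:
        """(n_cells, 7) data matrix over the common mask, layer order fixed."""
        return np.column_stack([self.grids[n].values[self.mask] for n in LAYER_ORDER])


def build_stack(layers: dict[str, Grid]) -> StackSpec:
    """Assemble a :class:`StackSpec` from named layer grids."""
    return StackSpec({n: layers[n] for n in LAYER_ORDER})


def standardize_layers(stack: StackSpec, ddof: int = 0) -> StackSpec:
    """Z-score every layer over the common mask (subtract mean, divide by SD).

    ``ddof=0`` (population SD) is the default; at raster cell counts the
    sample/population distinction is negligible but is pinned for
    reproducibility.  A constant layer has no z-score and is rejected by name.
    """
    out: dict[str, Grid] = {}
    for name in LAYER_ORDER:
        g = stack.grids[name]
        cells = g.values[stack.mask]
        sd = float(np.std(cells, ddof=ddof))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"layer {name!r} is constant over the mask; cannot standardize")
        vals = (g.values - float(np.mean(cells))) / sd
        out[name] = Grid(vals, g.transform, g.crs_tag, g.nodata_mask.copy(), dict(g.meta))
    return StackSpec(out, stack.mask.copy())


@dataclass
class PCAResult:
    """Eigenvalues (descending), variance fractions, and per-layer loadings."""

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    cumulative_fractions: np.ndarray
    loadings: np.ndarray  # (7, k): column j = eigenvector of component j+1
    layers: tuple = LAYER_ORDER

    def loadings_table(self):
        import pandas as pd

        cols = [f"PC{j + 1}" for j in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=list(self.layers), columns=cols)


def principal_components(stack: StackSpec, k: int = len(LAYER_ORDER),
                         ddof: int = 0) -> PCAResult:
    """Eigen-decomposition of the standardized stack's covariance matrix.

    With a standardized stack this is the correlation matrix of the raw
    layers.  Returns the first ``k`` components; variance fractions are
    eigenvalue shares of the total (they sum to 1 over all 7).
    """
    p = len(LAYER_ORDER)
    if not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}]")
    if stack.n_cells < p:
        raise ValueError("fewer masked cells than layers")
    X = stack.matrix()
    C = np.cov(X, rowvar=False, ddof=ddof)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-|component| entry of each eigenvector positive
    for j in range(p):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    fractions = evals / evals.sum()
    return PCAResult(
        eigenvalues=evals[:k],
        variance_fractions=fractions[:k],
        cumulative_fractions=np.cumsum(fractions)[:k],
        loadings=evecs[:, :k],
    )


def cumulative_variance(result: PCAResult, j: int) -> float:
    """Total variance fraction explained by the first ``j`` components."""
    if not (1 <= j <= len(result.cumulative_fractions)):
        raise ValueError("j out of range")
    return float(result.cumulative_fractions[j - 1])
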