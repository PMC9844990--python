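"""Gaussian-convolved density maps and the median-centred density correlation.

Cell positions, once normalized into the idealized transverse frame, are
turned into a gridded density map: each cell contributes a truncated 2D
Gaussian kernel evaluated at the grid centres, and the map is normalized to
unit total mass. The kernel bandwidth is data-driven, per axis:

    sigma = SD(coordinates) * n ** (-1/5)

a Scott-type rule — the per-axis sample standard deviation shrunk by the
usual one-dimensional rate, so maps from large experiments sharpen while
small experiments stay smooth.

Two experiments' maps rho_n and rho_m on a shared grid are compared with a
*median*-centred correlation coefficient

    r_nm = sum_ij (rho_n(ij) - med rho_n)(rho_m(ij) - med rho_m)
           / sqrt( sum_ij (rho_n(ij) - med rho_n)^2
                 * sum_ij (rho_m(ij) - med rho_m)^2 )

where the median is taken over all grid entries of each matrix. Because
most grid cells of an anatomical map are (near-)empty, the median tracks
the empty background, making r_nm sensitive to where the labelled mass
sits rather than to the overall occupancy level. r_nm is symmetric, equals
1 for positive affine transforms of the same map, and is undefined when a
map has zero median-centred variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (EmptyInputError, ParameterError,
                     UndefinedCorrelationError)
from .normalization import IdealizedFrame

DEFAULT_GRID_UM = 25.0
DEFAULT_TRUNCATION_SIGMAS = 4.0
#: fallback bandwidth (μm) for degenerate samples; about one soma radius
MIN_BANDWIDTH_UM = 10.0


@dataclass(frozen=True)
class GridSpec:
    """Regular grid of cell centres covering the idealized frame."""

    x_centres: np.ndarray
    y_centres: np.ndarray
    spacing_um: float

    @classmethod
    def for_frame(cls, frame: IdealizedFrame = IdealizedFrame(),
                  spacing_um: float = DEFAULT_GRID_UM) -> "GridSpec":
        if spacing_um <= 0:
            raise ParameterError(f"grid spacing must be positive, got {spacing_um}")
        nx = int(round(frame.width_um / spacing_um))
        ny = int(round(frame.height_um / spacing_um))
        x = -frame.ml_halfwidth_um + spacing_um * (np.arange(nx) + 0.5)
        y = frame.dv_ventral_um + spacing_um * (np.arange(ny) + 0.5)
        return cls(x_centres=x, y_centres=y, spacing_um=spacing_um)

    def refined(self, factor: int = 2) -> "GridSpec":
        """Same extent with ``factor``-times finer spacing."""
        s = self.spacing_um / factor
        x0 = self.x_centres[0] - self.spacing_um / 2
        y0 = self.y_centres[0] - self.spacing_um / 2
        nx = len(self.x_centres) * factor
        ny = len(self.y_centres) * factor
        return GridSpec(x_centres=x0 + s * (np.arange(nx) + 0.5),
                        y_centres=y0 + s * (np.arange(ny) + 0.5),
                        spacing_um=s)


@dataclass
class DensityMatrix:
    """Unit-mass gridded density rho(x_i, y_j) of one (pooled) experiment.

    ``values`` is indexed [i, j] = (x, y); the total over all entries is 1.
    """

    grid: GridSpec
    values: np.ndarray
    bandwidth: tuple[float, float]
    n_cells: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid.x_centres), len(self.grid.y_centres)):
            raise ValueError("values shape does not match grid")
        if (self.values < -1e-12).any():
            raise ValueError("density values must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())


@dataclass
class MarginalDistribution:
    """1D convolved distribution along one axis; weights sum to 1."""

    axis: str
    centres: np.ndarray
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < -1e-12).any():
            raise ValueError("marginal weights must be non-negative")

    @property
    def total(self) -> float:
        return float(self.weights.sum())


def bandwidth_from_sd(coords: np.ndarray,
                      min_bandwidth_um: float = MIN_BANDWIDTH_UM) -> float:
    """Scott-type kernel bandwidth: sample SD times n^(-1/5).

    Degenerate samples (n < 2 or zero SD) fall back to ``min_bandwidth_um``
    with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.size
    if n < 2:
        warnings.warn("fewer than 2 coordinates; using minimum bandwidth")
        return min_bandwidth_um
    sd = float(np.std(coords, ddof=1))
    if sd <= 1e-9 * max(1.0, float(np.abs(coords).max())):
        warnings.warn("constant coordinate sample; using minimum bandwidth")
        return min_bandwidth_um
    return sd * n ** (-1.0 / 5.0)


def _kernel_1d(coords: np.ndarray, centres: np.ndarray, sigma: float,
               truncation: float) -> np.ndarray:
    """(n_cells, n_centres) truncated Gaussian weights, each row unit-sum."""
    d = coords[:, None] - centres[None, :]
    k = np.exp(-0.5 * (d / sigma) ** 2)
    k[np.abs(d) > truncation * sigma] = 0.0
    row = k.sum(axis=1, keepdims=True)
    # a cell whose 4-sigma window misses every grid centre gets its nearest cell
    dead = (row[:, 0] == 0.0)
    if dead.any():
        nearest = np.abs(d[dead]).argmin(axis=1)
        k[np.flatnonzero(dead), nearest] = 1.0
        row = k.sum(axis=1, keepdims=True)
    return k / row


def density_matrix(x: np.ndarray, y: np.ndarray,
                   grid: GridSpec | None = None,
                   bandwidth: tuple[float, float] | None = None,
                   truncation_sigmas: float = DEFAULT_TRUNCATION_SIGMAS) -> DensityMatrix:
    """Gaussian-convolved density map of normalized cell positions.

    Each cell contributes a separable truncated Gaussian, renormalized after
    truncation so the matrix sums to exactly 1. ``bandwidth`` defaults to the
    per-axis Scott-type rule.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("density_matrix needs at least one cell")
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if grid is None:
        grid = GridSpec.for_frame()
    if bandwidth is None:
        bandwidth = (bandwidth_from_sd(x), bandwidth_from_sd(y))
    sx, sy = bandwidth
    if sx <= 0 or sy <= 0:
        raise ParameterError(f"bandwidth must be positive, got {bandwidth}")
    kx = _kernel_1d(x, grid.x_centres, sx, truncation_sigmas)
    ky = _kernel_1d(y, grid.y_centres, sy, truncation_sigmas)
    values = kx.T @ ky / x.size
    return DensityMatrix(grid=grid, values=values, bandwidth=(sx, sy),
                         n_cells=int(x.size))


def marginal(source, axis: str,
             bandwidth: float | None = None,
             grid: GridSpec | None = None,
             truncation_sigmas: float = DEFAULT_TRUNCATION_SIGMAS) -> MarginalDistribution:
    """1D convolved distribution along ``axis`` ("x" or "y").

    ``source`` is either a :class:`DensityMatrix` (row/column sums) or a 1D
    coordinate array (direct 1D convolution). Weights sum to 1.
    """
    if axis not in ("x", "y"):
        raise ParameterError(f"axis must be 'x' or 'y', got {axis!r}")
    if isinstance(source, DensityMatrix):
        if axis == "x":
            return MarginalDistribution(axis=axis, centres=source.grid.x_centres,
                                        weights=source.values.sum(axis=1))
        return MarginalDistribution(axis=axis, centres=source.grid.y_centres,
                                    weights=source.values.sum(axis=0))
    coords = np.asarray(source, dtype=float).ravel()
    if coords.size == 0:
        raise EmptyInputError("marginal needs at least one coordinate")
    if grid is None:
        grid = GridSpec.for_frame()
    centres = grid.x_centres if axis == "x" else grid.y_centres
    if bandwidth is None:
        bandwidth = bandwidth_from_sd(coords)
    k = _kernel_1d(coords, centres, bandwidth, truncation_sigmas)
    return MarginalDistribution(axis=axis, centres=centres,
                                weights=k.sum(axis=0) / coords.size)


def density_correlation(rho_n: DensityMatrix | np.ndarray,
                        rho_m: DensityMatrix | np.ndarray) -> float:
    """Median-centred correlation r_nm between two density matrices.

    Both matrices must share a grid (same shape). Centring is on the median
    over all grid entries, not the mean — see the module docstring.
    """
    a = rho_n.values if isinstance(rho_n, DensityMatrix) else np.asarray(rho_n, float)
    b = rho_m.values if isinstance(rho_m, DensityMatrix) else np.asarray(rho_m, float)
    if a.shape != b.shape:
        raise ValueError(f"matrices must share a grid: {a.shape} vs {b.shape}")
    da = a - np.median(a)
    db = b - np.median(b)
    ssa = float((da * da).sum())
    ssb = float((db * db).sum())
    if ssa == 0.0 or ssb == 0.0:
        raise UndefinedCorrelationError(
            "zero median-centred variance; correlation undefined")
    return float((da * db).sum() / np.sqrt(ssa * ssb))


def correlation_matrix(densities: dict[str, DensityMatrix]) -> "pd.DataFrame":
    """Symmetric matrix of pairwise r_nm with unit diagonal.

    Pairs with undefined correlation are recorded as NaN.
    """
    import pandas as pd

    keys = list(densities)
    out = np.full((len(keys), len(keys)), np.nan)
    for i, ki in enumerate(keys):
        out[i, i] = 1.0
        for j in range(i + 1, len(keys)):
            try:
                r = density_correlation(densities[ki], densities[keys[j]])
            except UndefinedCorrelationError:
                r = np.nan
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=keys, columns=keys)


def pooled_density(experiments, grid: GridSpec | None = None,
                   which: str = "interneurons") -> DensityMatrix:
    """Density of a group of experiments, pooling cells by concatenation.

    Pooling concatenates normalized cells across the group before the
    convolution (it does not average per-experiment maps), so each animal
    contributes in proportion to its cell count.
    """
    xs, ys = [], []
    for exp in experiments:
        c = exp.coords(which=which)
        xs.append(c[:, 0])
        ys.append(c[:, 1])
    x = np.concatenate(xs) if xs else np.array([])
    y = np.concatenate(ys) if ys else np.array([])
    return density_matrix(x, y, grid=grid)
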