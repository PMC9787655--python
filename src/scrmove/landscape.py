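"""Discretized habitat state space and the movement potential surface.

The study region is a rectangle in projected km coordinates, discretized into
square habitat cells (1 km in the motivating polar bear study).  Each cell is
flagged as sea ice (1) or not (0).  Individuals start the season uniformly
distributed over ice cells; a "distance to sea ice" scalar field ``c`` and its
gradient supply the habitat drift term ``delta * grad(c)`` of the movement
kernels, attracting individuals back toward ice.

Conventions
-----------
* The coordinate origin is the lower-left corner of the raster; x increases
  with column index, y with row index.  Row 0 is the bottom row.
* Cells are indexed row-major from that corner: ``g = row * ncols + col``.
* Cell membership uses half-open intervals ``[lo, hi)`` in both axes, so
  points on a grid seam belong to exactly one cell and points on the top or
  right edge of the extent are *outside* the state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "StateSpace",
    "PotentialSurface",
    "SurveyRegion",
    "build_state_space",
    "distance_to_ice",
    "gradient_field",
    "build_potential",
    "eval_gradient",
    "synthetic_landscape",
]


class OutsideStateSpaceError(ValueError):
    """A continuous location fell outside the state-space extent."""


@dataclass(frozen=True)
class StateSpace:
    """Gridded habitat domain with the initial-distribution weights.

    Attributes
    ----------
    ice : (nrows, ncols) int array of {0, 1}
        Habitat mask; 1 marks sea-ice cells.
    resolution_km : float
        Cell edge length in km.
    pi : (G,) float array
        Initial-distribution probability per cell, uniform over ice cells and
        exactly zero elsewhere (row-major order).
    """

    ice: np.ndarray
    resolution_km: float
    pi: np.ndarray = field(repr=False)

    @property
    def nrows(self) -> int:
        return self.ice.shape[0]

    @property
    def ncols(self) -> int:
        return self.ice.shape[1]

    @property
    def n_cells(self) -> int:
        return self.ice.size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in km."""
        return (
            0.0,
            self.ncols * self.resolution_km,
            0.0,
            self.nrows * self.resolution_km,
        )

    @property
    def cell_centroids(self) -> np.ndarray:
        """(G, 2) centroid coordinates in km, row-major."""
        res = self.resolution_km
        cols = (np.arange(self.ncols) + 0.5) * res
        rows = (np.arange(self.nrows) + 0.5) * res
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    # -- continuous <-> discrete plumbing ---------------------------------

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Half-open membership test for continuous locations (..., 2)."""
        p = np.asarray(points, dtype=float)
        xmin, xmax, ymin, ymax = self.extent
        return (
            (p[..., 0] >= xmin)
            & (p[..., 0] < xmax)
            & (p[..., 1] >= ymin)
            & (p[..., 1] < ymax)
        )

    def cell_rowcol(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) indices of the cells containing ``points``.

        Raises
        ------
        OutsideStateSpaceError
            If any point lies outside the extent (half-open convention).
        """
        p = np.asarray(points, dtype=float)
        if not np.all(self.contains(p)):
            raise OutsideStateSpaceError("location outside state space")
        col = np.floor(p[..., 0] / self.resolution_km).astype(np.intp)
        row = np.floor(p[..., 1] / self.resolution_km).astype(np.intp)
        return row, col

    def cell_index(self, points: np.ndarray) -> np.ndarray:
        """Row-major cell index of each continuous location."""
        row, col = self.cell_rowcol(points)
        return row * self.ncols + col

    def cell_origin(self, g: np.ndarray) -> np.ndarray:
        """Lower-left corner (..., 2) of cells given row-major indices."""
        g = np.asarray(g)
        row, col = np.divmod(g, self.ncols)
        return np.stack([col, row], axis=-1) * self.resolution_km


def build_state_space(ice_raster: np.ndarray, resolution_km: float) -> StateSpace:
    """Build a :class:`StateSpace` from a binary habitat raster.

    The initial distribution ``pi`` is uniform over ice cells and zero
    elsewhere.

    Parameters
    ----------
    ice_raster : 2-D array-like of {0, 1}
        Habitat mask with row 0 interpreted as the *bottom* row.
    resolution_km : float
        Cell edge length, km.
    """
    ice = np.asarray(ice_raster)
    if ice.ndim != 2:
        raise ValueError("habitat raster must be a rectangular 2-D array")
    if not np.isin(ice, (0, 1)).all():
        raise ValueError("habitat raster values must be 0 or 1")
    if resolution_km <= 0:
        raise ValueError("resolution_km must be positive")
    ice = ice.astype(np.int8)
    n_ice = int(ice.sum())
    if n_ice == 0:
        raise ValueError("no habitat: raster contains no ice cells")
    pi = ice.ravel().astype(float) / n_ice
    return StateSpace(ice=ice, resolution_km=float(resolution_km), pi=pi)


@dataclass(frozen=True)
class PotentialSurface:
    """Scalar habitat potential ``c`` and its (signed) gradient field.

    ``c`` is the distance-to-ice covariate (km, zero on ice); ``grad`` holds
    the drift direction per cell, ``attraction_sign * gradient(c)``, as an
    (nrows, ncols, 2) array of (d/dx, d/dy) components per km.  With the
    default ``attraction_sign = -1`` the field points *toward* ice, so a
    positive potential coefficient attracts individuals to ice.
    """

    state_space: StateSpace
    c: np.ndarray
    grad: np.ndarray
    attraction_sign: int = -1

    def __post_init__(self):
        if self.c.shape != self.state_space.ice.shape:
            raise ValueError("potential surface shape mismatch")
        if not np.all(np.isfinite(self.grad)):
            raise ValueError("gradient field must be finite")


def distance_to_ice(state_space: StateSpace) -> np.ndarray:
    """Euclidean distance (km) from each cell centroid to the nearest
    ice-cell centroid; exactly zero on ice cells."""
    off_ice = state_space.ice == 0
    # exact Euclidean distance transform, in cell units, center-to-center
    d = ndimage.distance_transform_edt(off_ice)
    return d * state_space.resolution_km


def gradient_field(
    c: np.ndarray, resolution_km: float, attraction_sign: int = -1
) -> np.ndarray:
    """Signed finite-difference gradient of a cell-based scalar field.

    Central differences in the interior, one-sided at the borders, scaled per
    km.  Returns an (nrows, ncols, 2) array of (d/dx, d/dy) components
    multiplied by ``attraction_sign``.
    """
    if attraction_sign not in (-1, 1):
        raise ValueError("attraction_sign must be +1 or -1")
    dc_dy, dc_dx = np.gradient(np.asarray(c, dtype=float), resolution_km)
    return attraction_sign * np.stack([dc_dx, dc_dy], axis=-1)


def build_potential(state_space: StateSpace, attraction_sign: int = -1) -> PotentialSurface:
    """Distance-to-ice potential with its drift field, the default habitat
    covariate of the movement model."""
    c = distance_to_ice(state_space)
    grad = gradient_field(c, state_space.resolution_km, attraction_sign)
    return PotentialSurface(
        state_space=state_space, c=c, grad=grad, attraction_sign=attraction_sign
    )


def eval_gradient(surface: PotentialSurface, location: np.ndarray) -> np.ndarray:
    """Drift vector at continuous locations (..., 2).

    Piecewise-constant (nearest-cell) lookup: the value of the cell containing
    the point under the half-open convention.
    """
    row, col = surface.state_space.cell_rowcol(location)
    return surface.grad[row, col]


@dataclass(frozen=True)
class SurveyRegion:
    """The J surveyed trap cells (effective traps of the search-encounter
    observation model) and their union, region A.

    Trap cells are square, typically coarser than habitat cells (25 km in the
    case study), and must lie inside the state-space extent.
    """

    origins: np.ndarray  # (J, 2) lower-left corners, km
    resolution_km: float

    def __post_init__(self):
        org = np.asarray(self.origins, dtype=float)
        if org.ndim != 2 or org.shape[1] != 2:
            raise ValueError("origins must be (J, 2)")
        # disjointness: origins of equal-size axis-aligned squares must differ
        if len(np.unique(org, axis=0)) != len(org):
            raise ValueError("trap cells must be disjoint")
        object.__setattr__(self, "origins", org)

    @property
    def n_traps(self) -> int:
        return len(self.origins)

    @property
    def centroids(self) -> np.ndarray:
        return self.origins + self.resolution_km / 2.0

    def trap_of(self, points: np.ndarray) -> np.ndarray:
        """Index of the trap cell containing each point, -1 if outside A.

        Half-open cell convention; cells are disjoint so the match is unique.
        """
        p = np.asarray(points, dtype=float)
        rel = (p[..., None, :] - self.origins) / self.resolution_km
        inside = ((rel >= 0) & (rel < 1)).all(axis=-1)  # (..., J)
        idx = np.where(inside.any(axis=-1), inside.argmax(axis=-1), -1)
        return idx

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership of continuous points in region A (union of trap cells)."""
        return self.trap_of(points) >= 0

    @classmethod
    def from_grid(
        cls, origin: tuple[float, float], shape: tuple[int, int], resolution_km: float
    ) -> "SurveyRegion":
        """Contiguous ``shape = (nrows, ncols)`` block of trap cells whose
        lower-left corner sits at ``origin``."""
        nr, nc = shape
        ox, oy = origin
        xs = ox + np.arange(nc) * resolution_km
        ys = oy + np.arange(nr) * resolution_km
        xx, yy = np.meshgrid(xs, ys)
        return cls(
            origins=np.column_stack([xx.ravel(), yy.ravel()]),
            resolution_km=float(resolution_km),
        )


def synthetic_landscape(
    seed: int,
    nrows: int,
    ncols: int,
    resolution_km: float = 1.0,
    shore_fraction: float = 0.0,
    speckle: float = 0.0,
    margin_fraction: float = 0.0,
) -> StateSpace:
    """Seeded synthetic sea-ice landscape.

    A contiguous "shore" band of ice-free columns occupies the rightmost
    ``round(shore_fraction * ncols)`` columns (emulating the coastline of the
    study area); ``margin_fraction`` additionally strips ice from that
    fraction of rows/columns on *every* side, leaving an ice core surrounded
    by open water so that the habitat potential, not the state-space edge,
    confines movement.  The remaining ice may be pocked with a ``speckle``
    fraction of ice-free holes.  Deterministic given ``seed``.
    """
    if not 0 <= shore_fraction < 1:
        raise ValueError("shore_fraction must be in [0, 1)")
    if not 0 <= margin_fraction < 0.5:
        raise ValueError("margin_fraction must be in [0, 0.5)")
    if not 0 <= speckle < 1:
        raise ValueError("speckle must be in [0, 1)")
    n_shore = int(round(shore_fraction * ncols))
    ice = np.ones((nrows, ncols), dtype=np.int8)
    if n_shore:
        ice[:, ncols - n_shore :] = 0
    if margin_fraction:
        mr = int(round(margin_fraction * nrows))
        mc = int(round(margin_fraction * ncols))
        if mr:
            ice[:mr, :] = 0
            ice[nrows - mr :, :] = 0
        if mc:
            ice[:, :mc] = 0
            ice[:, ncols - mc :] = 0
    if speckle:
        rng = np.random.default_rng(seed)
        ice_flat = np.flatnonzero(ice.ravel())
        n_holes = int(np.floor(speckle * len(ice_flat)))
        if n_holes >= len(ice_flat):
            raise ValueError("speckle leaves no ice cells")
        holes = rng.choice(ice_flat, size=n_holes, replace=False)
        ice.ravel()[holes] = 0
    if ice.sum() == 0:
        raise ValueError("no habitat: shore_fraction leaves no ice cells")
    return build_state_space(ice, resolution_km)
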