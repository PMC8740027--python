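"""Conduction-velocity vector fields and divergence maps.

Given the fitted activation map f(x, y), the wavefront propagates along
the gradient of f, and the velocity vector is

    v = grad f / ||grad f||^2        (mm/ms; reported in cm/s)

so the speed is 1/||grad f||.  Focal sources are exposed by the
divergence of the *normalized* field v_hat = grad f / ||grad f||, which
isolates the angular structure of propagation:

    D = div v_hat = trace(H)/||g|| - (g' H g)/||g||^3

with g = grad f and H the Hessian of f, both available analytically
from the interpolant.  D is positive at centrifugal sources, negative
along wavefront collision lines, and ~0 for planar propagation.

Everything is sampled on uniform rectangular grids; by default nodes
outside the convex hull of the mapping sites are masked out, since the
interpolant extrapolates freely there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "EvalGrid",
    "VectorField",
    "ScalarField",
    "make_grid",
    "hull_mask",
    "velocity_field",
    "divergence_field",
    "median_speed",
    "GRADIENT_DEGENERACY",
    "MM_PER_MS_TO_CM_PER_S",
]

#: ||grad f|| (ms/mm) below this is treated as degenerate (speed -> inf)
GRADIENT_DEGENERACY = 1e-6
MM_PER_MS_TO_CM_PER_S = 100.0


@dataclass
class EvalGrid:
    """Uniform rectangular evaluation grid with a validity mask.

    x : (nx,) and y : (ny,) node coordinates, mm, uniformly spaced;
    mask : (ny, nx) boolean, True inside the region of interest.
    """

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        for c in (self.x, self.y):
            if c.size < 2:
                raise ValueError("grid needs at least 2 nodes per side")
            dc = np.diff(c)
            if not np.allclose(dc, dc[0], rtol=1e-9) or dc[0] <= 0:
                raise ValueError("grid coordinates must be uniformly increasing")
        if self.mask.shape != (self.y.size, self.x.size):
            raise ValueError("mask shape must be (ny, nx)")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y.size, self.x.size)

    def points(self) -> np.ndarray:
        """All grid nodes as (ny*nx, 2), row-major (y outer)."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class VectorField:
    """Grid-sampled CV vectors (cm/s) with unit vectors and validity."""

    grid: EvalGrid
    vx: np.ndarray
    vy: np.ndarray
    unit_vx: np.ndarray
    unit_vy: np.ndarray
    valid: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


@dataclass
class ScalarField:
    """Grid-sampled scalar values (divergence maps, mm^-1)."""

    grid: EvalGrid
    values: np.ndarray
    valid: np.ndarray


def hull_mask(grid_points: np.ndarray, sites: np.ndarray) -> np.ndarray:
    """Boolean flags for grid points inside the convex hull of sites."""
    try:
        tri = Delaunay(sites)
    except QhullError as exc:
        raise ValueError("sites are degenerate; cannot build convex hull") from exc
    return tri.find_simplex(grid_points) >= 0


def make_grid(layout_or_bounds, resolution: int = 100, mask_mode: str = "hull") -> EvalGrid:
    """Uniform grid over a layout's bounding box (padded by one spacing).

    ``layout_or_bounds`` is either an object with a ``points`` attribute
    (a catheter layout) or explicit bounds ((xmin, xmax), (ymin, ymax)).
    With ``mask_mode="hull"`` nodes outside the convex hull of the
    layout points are masked; ``"box"`` keeps every node.
    """
    if resolution < 8:
        raise ValueError("resolution must be at least 8")
    pts = getattr(layout_or_bounds, "points", None)
    if pts is None:
        pts = getattr(layout_or_bounds, "positions", None)
    if pts is not None:
        pts = np.asarray(pts, dtype=float)
        (xmin, ymin), (xmax, ymax) = pts.min(axis=0), pts.max(axis=0)
    else:
        (xmin, xmax), (ymin, ymax) = layout_or_bounds
        if mask_mode == "hull":
            raise ValueError("hull masking requires a layout with points")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("degenerate bounds")
    pad_x = (xmax - xmin) / (resolution - 1)
    pad_y = (ymax - ymin) / (resolution - 1)
    x = np.linspace(xmin - pad_x, xmax + pad_x, resolution)
    y = np.linspace(ymin - pad_y, ymax + pad_y, resolution)
    # keep spacing identical in x and y by using the larger of the two
    h = max(x[1] - x[0], y[1] - y[0])
    x = 0.5 * (x[0] + x[-1]) + h * (np.arange(resolution) - (resolution - 1) / 2)
    y = 0.5 * (y[0] + y[-1]) + h * (np.arange(resolution) - (resolution - 1) / 2)
    xx, yy = np.meshgrid(x, y)
    if mask_mode == "hull":
        mask = hull_mask(np.column_stack([xx.ravel(), yy.ravel()]), pts).reshape(xx.shape)
    elif mask_mode == "box":
        mask = np.ones(xx.shape, dtype=bool)
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    return EvalGrid(x=x, y=y, mask=mask)


def _masked_gradient(model, grid: EvalGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient at masked nodes: returns (g (ny,nx,2), norm, valid)."""
    pts = grid.points()
    idx = grid.mask.ravel()
    g = np.full((pts.shape[0], 2), np.nan)
    g[idx] = model.gradient(pts[idx])
    g = g.reshape(grid.shape + (2,))
    norm = np.hypot(g[..., 0], g[..., 1])
    valid = grid.mask & (norm >= GRADIENT_DEGENERACY)
    return g, norm, valid


def velocity_field(model, grid: EvalGrid) -> VectorField:
    """Analytic CV vector field of a fitted interpolant on a grid.

    Nodes where the gradient magnitude falls below the degeneracy
    threshold (isochrone extrema, the immediate focal origin) are
    flagged invalid rather than producing unbounded speeds.
    """
    g, norm, valid = _masked_gradient(model, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = g / norm[..., None] ** 2 * MM_PER_MS_TO_CM_PER_S
        u = g / norm[..., None]
    v[~valid] = np.nan
    u[~valid] = np.nan
    return VectorField(grid=grid, vx=v[..., 0], vy=v[..., 1],
                       unit_vx=u[..., 0], unit_vy=u[..., 1], valid=valid)


def divergence_field(model, grid: EvalGrid) -> ScalarField:
    """Divergence of the normalized CV field, analytically, in mm^-1."""
    g, norm, valid = _masked_gradient(model, grid)
    pts = grid.points()
    idx = valid.ravel()
    h = np.full((pts.shape[0], 2, 2), np.nan)
    h[idx] = model.hessian(pts[idx])
    h = h.reshape(grid.shape + (2, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        trace = h[..., 0, 0] + h[..., 1, 1]
        ghg = np.einsum("...i,...ij,...j->...", g, h, g)
        d = trace / norm - ghg / norm**3
    d[~valid] = np.nan
    return ScalarField(grid=grid, values=d, valid=valid)


def median_speed(vfield: VectorField) -> float:
    """Median CV magnitude (cm/s) over valid masked nodes."""
    speeds = vfield.speed[vfield.valid]
    if speeds.size == 0:
        raise ValueError("no valid nodes in the vector field")
    return float(np.median(speeds))
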