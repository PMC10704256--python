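"""Rigid, affine, and nodal-grid deformable transforms.

All transforms map *reference* physical coordinates to *template*
physical coordinates (backward warping): the registered template is
produced by sampling ``T(y(x))`` on the reference grid.  Points are
``(..., 2)`` arrays ordered ``(x, y)`` in micrometers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .imgio import Image

__all__ = [
    "RigidTransform",
    "AffineTransform",
    "DeformationGrid",
    "map_points",
    "interpolate_displacement",
    "warp_image",
    "promote",
    "count_folds",
    "sample_bilinear",
    "transform_to_json",
    "transform_from_json",
]


def _as_points(points) -> np.ndarray:
    p = np.asarray(points, dtype=np.float64)
    if p.shape[-1] != 2:
        raise ValueError(f"points must have trailing dimension 2, got {p.shape}")
    return p


@dataclass
class RigidTransform:
    """Rotation by ``phi`` about ``center`` followed by translation.

    ``y(x) = center + R(phi) (x - center) + (t1, t2)``.
    """

    phi: float = 0.0
    t1: float = 0.0
    t2: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        vals = (self.phi, self.t1, self.t2, *self.center)
        if not np.all(np.isfinite(vals)):
            raise ValueError("rigid parameters must be finite")

    @property
    def n_parameters(self) -> int:
        return 3

    def get_parameters(self) -> np.ndarray:
        return np.array([self.phi, self.t1, self.t2])

    def with_parameters(self, p) -> "RigidTransform":
        return RigidTransform(float(p[0]), float(p[1]), float(p[2]), self.center)

    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.phi), np.sin(self.phi)
        return np.array([[c, -s], [s, c]])

    def map_points(self, points) -> np.ndarray:
        p = _as_points(points)
        c = np.asarray(self.center)
        rel = p - c
        rot = rel @ self.rotation_matrix().T
        return rot + c + np.array([self.t1, self.t2])

    def parameter_jacobian(self, points) -> np.ndarray:
        """d y(x) / d(phi, t1, t2); shape ``points.shape + (3,)``."""
        p = _as_points(points)
        c, s = np.cos(self.phi), np.sin(self.phi)
        dr = np.array([[-s, -c], [c, -s]])  # d/dphi of R(phi)
        rel = p - np.asarray(self.center)
        jac = np.zeros(p.shape + (3,))
        jac[..., :, 0] = rel @ dr.T
        jac[..., 0, 1] = 1.0
        jac[..., 1, 2] = 1.0
        return jac


@dataclass
class AffineTransform:
    """``y(x) = A x + b`` with an invertible 2x2 matrix ``A``."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=np.float64).reshape(2)
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.offset))):
            raise ValueError("affine parameters must be finite")
        if np.linalg.det(self.matrix) == 0:
            raise ValueError("affine matrix must be invertible")

    @property
    def n_parameters(self) -> int:
        return 6

    def get_parameters(self) -> np.ndarray:
        return np.concatenate([self.matrix.ravel(), self.offset])

    def with_parameters(self, p) -> "AffineTransform":
        p = np.asarray(p, dtype=np.float64)
        return AffineTransform(p[:4].reshape(2, 2), p[4:6])

    def map_points(self, points) -> np.ndarray:
        p = _as_points(points)
        return p @ self.matrix.T + self.offset

    def parameter_jacobian(self, points) -> np.ndarray:
        """d y(x) / d(a11, a12, a21, a22, b1, b2)."""
        p = _as_points(points)
        jac = np.zeros(p.shape + (6,))
        jac[..., 0, 0] = p[..., 0]
        jac[..., 0, 1] = p[..., 1]
        jac[..., 1, 2] = p[..., 0]
        jac[..., 1, 3] = p[..., 1]
        jac[..., 0, 4] = 1.0
        jac[..., 1, 5] = 1.0
        return jac

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)


@dataclass
class DeformationGrid:
    """Nodal control-point grid of displacements over the reference domain.

    ``node_displacements`` has shape (m1, m2, 2): m1 node rows, m2 node
    columns, displacement components (ux, uy) in micrometers.  Nodes are
    uniformly spaced and include the domain corners; the dense deformation
    ``y(x) = x + u(x)`` interpolates the nodes bilinearly, clamping to the
    boundary cell's bilinear extension outside the node hull.
    """

    node_displacements: np.ndarray
    domain_extent: tuple[float, float]  # physical (width, height), um
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.node_displacements = np.asarray(self.node_displacements, dtype=np.float64)
        if self.node_displacements.ndim != 3 or self.node_displacements.shape[2] != 2:
            raise ValueError(
                f"node_displacements must have shape (m1, m2, 2), got "
                f"{self.node_displacements.shape}"
            )
        m1, m2 = self.node_displacements.shape[:2]
        if m1 < 2 or m2 < 2:
            raise ValueError(f"grid must be at least 2x2 nodes, got {m1}x{m2}")
        if not np.all(np.isfinite(self.node_displacements)):
            raise ValueError("node displacements must be finite")
        self.domain_extent = (float(self.domain_extent[0]), float(self.domain_extent[1]))
        if min(self.domain_extent) <= 0:
            raise ValueError("domain extent must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.node_displacements.shape[:2]

    @property
    def node_spacing(self) -> tuple[float, float]:
        """(dx, dy) between neighboring nodes, um."""
        m1, m2 = self.grid_shape
        return (self.domain_extent[0] / (m2 - 1), self.domain_extent[1] / (m1 - 1))

    @property
    def n_parameters(self) -> int:
        return self.node_displacements.size

    def get_parameters(self) -> np.ndarray:
        return self.node_displacements.ravel().copy()

    def with_parameters(self, p) -> "DeformationGrid":
        u = np.asarray(p, dtype=np.float64).reshape(self.node_displacements.shape)
        return DeformationGrid(u, self.domain_extent, self.origin)

    def _cell_coords(self, points: np.ndarray):
        """Cell indices and in-cell fractions for bilinear interpolation,
        clamped to the boundary cells (extrapolation = boundary-cell
        bilinear extension)."""
        m1, m2 = self.grid_shape
        dx, dy = self.node_spacing
        fx = (points[..., 0] - self.origin[0]) / dx
        fy = (points[..., 1] - self.origin[1]) / dy
        j0 = np.clip(np.floor(fx).astype(np.int64), 0, m2 - 2)
        i0 = np.clip(np.floor(fy).astype(np.int64), 0, m1 - 2)
        return i0, j0, fx - j0, fy - i0

    def interpolate(self, points) -> np.ndarray:
        """Displacement u at arbitrary points; exact at the nodes."""
        p = _as_points(points)
        i0, j0, wx, wy = self._cell_coords(p)
        u = self.node_displacements
        u00 = u[i0, j0]
        u01 = u[i0, j0 + 1]
        u10 = u[i0 + 1, j0]
        u11 = u[i0 + 1, j0 + 1]
        wx = wx[..., None]
        wy = wy[..., None]
        return (
            u00 * (1 - wx) * (1 - wy)
            + u01 * wx * (1 - wy)
            + u10 * (1 - wx) * wy
            + u11 * wx * wy
        )

    def node_weights(self, points):
        """Bilinear weights of the four surrounding nodes for each point.

        Returns ``(i0, j0, w00, w01, w10, w11)``; used to scatter
        objective gradients from pixels back to grid nodes.
        """
        p = _as_points(points)
        i0, j0, wx, wy = self._cell_coords(p)
        return i0, j0, (1 - wx) * (1 - wy), wx * (1 - wy), (1 - wx) * wy, wx * wy

    def map_points(self, points) -> np.ndarray:
        p = _as_points(points)
        return p + self.interpolate(p)

    def node_positions(self) -> np.ndarray:
        """Physical coordinates of the grid nodes, shape (m1, m2, 2)."""
        m1, m2 = self.grid_shape
        x = self.origin[0] + np.linspace(0.0, self.domain_extent[0], m2)
        y = self.origin[1] + np.linspace(0.0, self.domain_extent[1], m1)
        xx, yy = np.meshgrid(x, y)
        return np.stack([xx, yy], axis=-1)


Transform = RigidTransform | AffineTransform | DeformationGrid


def map_points(transform: Transform, points) -> np.ndarray:
    """Apply a transform to an array of physical points."""
    return transform.map_points(points)


def interpolate_displacement(grid: DeformationGrid, query_point) -> np.ndarray:
    """Bilinearly interpolated displacement of a deformation grid."""
    return grid.interpolate(query_point)


def sample_bilinear(image: Image, points, with_gradient: bool = False):
    """Sample an image at physical points with bilinear interpolation.

    Points outside the pixel-center hull take the fill value 0 (the
    inverted background).  With ``with_gradient=True`` also returns the
    spatial derivative of the interpolant, (d/dx, d/dy) per point, which
    is zero outside the domain.
    """
    p = _as_points(points)
    h = image.spacing_um
    nr, nc = image.shape
    fx = (p[..., 0] - image.origin[0]) / h
    fy = (p[..., 1] - image.origin[1]) / h
    inside = (fx >= 0) & (fx <= nc - 1) & (fy >= 0) & (fy <= nr - 1)
    j0 = np.clip(np.floor(fx).astype(np.int64), 0, nc - 2)
    i0 = np.clip(np.floor(fy).astype(np.int64), 0, nr - 2)
    wx = np.clip(fx - j0, 0.0, 1.0)
    wy = np.clip(fy - i0, 0.0, 1.0)
    d = image.data
    v00 = d[i0, j0]
    v01 = d[i0, j0 + 1]
    v10 = d[i0 + 1, j0]
    v11 = d[i0 + 1, j0 + 1]
    top = v00 * (1 - wx) + v01 * wx
    bot = v10 * (1 - wx) + v11 * wx
    values = np.where(inside, top * (1 - wy) + bot * wy, 0.0)
    if not with_gradient:
        return values
    gx = np.where(inside, ((v01 - v00) * (1 - wy) + (v11 - v10) * wy) / h, 0.0)
    gy = np.where(inside, (bot - top) / h, 0.0)
    return values, np.stack([gx, gy], axis=-1)


def warp_image(template: Image, transform: Transform, output_grid: Image) -> Image:
    """Backward-warp the template onto the output grid: out(x) = T(y(x))."""
    x = output_grid.pixel_centers()
    y = transform.map_points(x)
    values = sample_bilinear(template, y)
    return Image(values, output_grid.spacing_um, output_grid.origin)


def promote(transform: Transform, grid_shape: tuple[int, int] | None = None,
            domain_extent: tuple[float, float] | None = None,
            origin: tuple[float, float] = (0.0, 0.0)) -> Transform:
    """Re-express a transform in the next, more general class.

    Rigid -> exactly equivalent affine.  Affine -> deformation grid whose
    node displacements are ``u(x) = (A x + b) - x`` (exact: affine maps
    lie in the bilinear span of any grid); requires ``grid_shape`` and
    ``domain_extent``.
    """
    if isinstance(transform, RigidTransform):
        rot = transform.rotation_matrix()
        c = np.asarray(transform.center)
        offset = c - rot @ c + np.array([transform.t1, transform.t2])
        return AffineTransform(rot, offset)
    if isinstance(transform, AffineTransform):
        if grid_shape is None or domain_extent is None:
            raise ValueError(
                "promoting an affine to a deformation grid requires "
                "grid_shape and domain_extent"
            )
        grid = DeformationGrid(
            np.zeros((*grid_shape, 2)), domain_extent, origin
        )
        nodes = grid.node_positions()
        grid.node_displacements = transform.map_points(nodes) - nodes
        return grid
    raise TypeError(f"cannot promote a {type(transform).__name__}")


def count_folds(grid: DeformationGrid, sampling_step: float | None = None) -> int:
    """Count orientation-reversing locations of ``y(x) = x + u(x)``.

    The domain is rastered into sampling cells of size ``sampling_step``
    (default half the node spacing) and the Jacobian of the interpolated
    map is approximated by central differences at each sampling-cell
    center; returns the number of strictly negative determinants.  The
    raster is finer than the node cells because the bilinear map's
    orientation can reverse in a narrow band along the node lines that
    the node-cell centers themselves never see.
    """
    dx, dy = grid.node_spacing
    if sampling_step is None:
        sampling_step = 0.5 * min(dx, dy)
    s = float(sampling_step)
    w, h = grid.domain_extent
    nx = max(1, int(round(w / s)))
    ny = max(1, int(round(h / s)))
    cx = grid.origin[0] + (np.arange(nx) + 0.5) * (w / nx)
    cy = grid.origin[1] + (np.arange(ny) + 0.5) * (h / ny)
    xx, yy = np.meshgrid(cx, cy)
    centers = np.stack([xx, yy], axis=-1)
    step = 0.5 * s
    ex = np.array([step, 0.0])
    ey = np.array([0.0, step])
    dydx = (grid.map_points(centers + ex) - grid.map_points(centers - ex)) / (2 * step)
    dydy = (grid.map_points(centers + ey) - grid.map_points(centers - ey)) / (2 * step)
    det = dydx[..., 0] * dydy[..., 1] - dydx[..., 1] * dydy[..., 0]
    return int(np.sum(det < 0))


def transform_to_json(transform: Transform) -> str:
    """Serialize a transform to a JSON document with a ``type`` tag."""
    if isinstance(transform, RigidTransform):
        doc = {
            "type": "rigid",
            "phi": transform.phi,
            "t1": transform.t1,
            "t2": transform.t2,
            "center": list(transform.center),
        }
    elif isinstance(transform, AffineTransform):
        doc = {
            "type": "affine",
            "matrix": transform.matrix.tolist(),
            "offset": transform.offset.tolist(),
        }
    elif isinstance(transform, DeformationGrid):
        doc = {
            "type": "deformable",
            "grid_shape": list(transform.grid_shape),
            "domain_extent": list(transform.domain_extent),
            "origin": list(transform.origin),
            "node_displacements": transform.node_displacements.ravel().tolist(),
        }
    else:
        raise TypeError(f"cannot serialize a {type(transform).__name__}")
    return json.dumps(doc)


def transform_from_json(doc: str | dict) -> Transform:
    """Inverse of :func:`transform_to_json`; accepts a JSON string or dict."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    kind = doc["type"]
    if kind == "rigid":
        return RigidTransform(doc["phi"], doc["t1"], doc["t2"], tuple(doc["center"]))
    if kind == "affine":
        return AffineTransform(np.array(doc["matrix"]), np.array(doc["offset"]))
    if kind == "deformable":
        m1, m2 = doc["grid_shape"]
        u = np.array(doc["node_displacements"]).reshape(m1, m2, 2)
        return DeformationGrid(u, tuple(doc["domain_extent"]), tuple(doc["origin"]))
    raise ValueError(f"unknown transform type {kind!r}")
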