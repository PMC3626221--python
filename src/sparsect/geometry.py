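"""Parallel-beam acquisition geometry and the sparse X-ray system matrix.

Coordinate conventions (used consistently across the package):

* The image is an ``side_px x side_px`` square of pixels centered at the
  origin of the (x, y) plane.  Array row 0 is the *top* of the image, so
  pixel ``(r, c)`` has center ``x = (c - (side_px - 1) / 2) * pixel_size``,
  ``y = ((side_px - 1) / 2 - r) * pixel_size``.
* A view at angle ``theta`` measures line integrals along rays
  ``{(x, y) : x cos(theta) + y sin(theta) = t}``; ``t`` is the signed
  perpendicular distance of the ray from the origin.
* Detector bin ``k`` is centered at
  ``t = (k - (n_detectors - 1) / 2) * detector_spacing``.
* Images are flattened row-major (C order) when multiplied by the system
  matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ImageGrid",
    "ProjectionGeometry",
    "SystemMatrix",
    "Sinogram",
    "build_system_matrix",
    "forward_project",
    "back_project",
]


@dataclass
class ImageGrid:
    """Square pixel lattice of attenuation coefficients."""

    values: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"image must be square 2D, got shape {self.values.shape}")
        if self.values.shape[0] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    @property
    def side_px(self) -> int:
        return self.values.shape[0]

    @classmethod
    def zeros(cls, side_px: int, pixel_size: float = 1.0) -> "ImageGrid":
        return cls(np.zeros((side_px, side_px)), pixel_size)


@dataclass
class ProjectionGeometry:
    """Parallel-beam view angles and detector layout."""

    angles_deg: np.ndarray
    n_detectors: int
    detector_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_1d(np.asarray(self.angles_deg, dtype=float))
        if self.angles_deg.size == 0:
            raise ValueError("at least one view angle is required")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.angles_deg < 0) or np.any(self.angles_deg >= 180):
            raise ValueError("angles must lie in [0, 180)")
        if self.n_detectors < 1:
            raise ValueError("n_detectors must be positive")
        if self.detector_spacing <= 0:
            raise ValueError("detector_spacing must be positive")

    @property
    def n_views(self) -> int:
        return int(self.angles_deg.size)

    @property
    def detector_offsets(self) -> np.ndarray:
        """Signed perpendicular offsets ``t`` of the detector bin centers."""
        k = np.arange(self.n_detectors, dtype=float)
        return (k - (self.n_detectors - 1) / 2.0) * self.detector_spacing

    @classmethod
    def uniform(
        cls, n_views: int, n_detectors: int, detector_spacing: float = 1.0
    ) -> "ProjectionGeometry":
        """``n_views`` angles uniformly spaced over [0, 180)."""
        angles = np.arange(n_views) * (180.0 / n_views)
        return cls(angles, n_detectors, detector_spacing)


@dataclass
class Sinogram:
    """Projection data: one row of line integrals per view angle."""

    values: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_views, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    def ravel(self) -> np.ndarray:
        return self.values.ravel()


@dataclass
class SystemMatrix:
    """Sparse ray/pixel chord-length matrix with cached row and column sums.

    Shape is ``(n_views * n_detectors, side_px ** 2)``; entry ``(j, i)`` is
    the length of the intersection of ray ``j`` with pixel ``i``.
    """

    matrix: sp.csr_matrix
    grid_side: int
    pixel_size: float
    geometry: ProjectionGeometry
    row_sums: np.ndarray = field(init=False)
    col_sums: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.row_sums = np.asarray(self.matrix.sum(axis=1)).ravel()
        self.col_sums = np.asarray(self.matrix.sum(axis=0)).ravel()

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dot(self, flat_image: np.ndarray) -> np.ndarray:
        return self.matrix.dot(flat_image)

    def rmatvec(self, flat_sino: np.ndarray) -> np.ndarray:
        return self.matrix.T.dot(flat_sino)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


def _ray_grid_intersections(
    p0x: float, p0y: float, dx: float, dy: float, half: float, n: int, px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Siddon-style traversal of one ray through the pixel lattice.

    The ray is ``p(s) = (p0x + s*dx, p0y + s*dy)`` with unit direction
    ``(dx, dy)``.  Returns flat row-major pixel indices and intersection
    lengths; empty arrays if the ray misses the image square ``[-half, half]^2``.
    """
    # Parametric entry/exit through the bounding square (slab clipping).
    s_min, s_max = -np.inf, np.inf
    for p0, d in ((p0x, dx), (p0y, dy)):
        if abs(d) < 1e-14:
            if abs(p0) >= half:
                return np.empty(0, dtype=np.intp), np.empty(0)
        else:
            s1 = (-half - p0) / d
            s2 = (half - p0) / d
            if s1 > s2:
                s1, s2 = s2, s1
            s_min = max(s_min, s1)
            s_max = min(s_max, s2)
    if not (s_max - s_min > 1e-12):
        return np.empty(0, dtype=np.intp), np.empty(0)

    # Grid-line crossing parameters within (s_min, s_max).
    lines = (np.arange(1, n) * px) - half  # interior grid lines
    crossings = [np.array([s_min, s_max])]
    if abs(dx) >= 1e-14:
        sx = (lines - p0x) / dx
        crossings.append(sx[(sx > s_min + 1e-12) & (sx < s_max - 1e-12)])
    if abs(dy) >= 1e-14:
        sy = (lines - p0y) / dy
        crossings.append(sy[(sy > s_min + 1e-12) & (sy < s_max - 1e-12)])
    s = np.unique(np.concatenate(crossings))
    lengths = np.diff(s)
    mids = 0.5 * (s[:-1] + s[1:])

    # Midpoint of each segment identifies the pixel it lies in.
    mx = p0x + mids * dx
    my = p0y + mids * dy
    cols = np.clip(np.floor((mx + half) / px).astype(np.intp), 0, n - 1)
    rows = np.clip(np.floor((half - my) / px).astype(np.intp), 0, n - 1)
    keep = lengths > 1e-12
    return rows[keep] * n + cols[keep], lengths[keep]


def build_system_matrix(grid: ImageGrid, geom: ProjectionGeometry) -> SystemMatrix:
    """Build the sparse system matrix of exact ray-pixel chord lengths.

    Ray ``j = view * n_detectors + k`` is the line
    ``x cos(theta) + y sin(theta) = t_k`` for view angle ``theta`` and
    detector offset ``t_k``.  Entries are exact intersection lengths under
    the indicator-function pixel basis, computed by Siddon-style traversal.
    """
    n = grid.side_px
    px = grid.pixel_size
    half = n * px / 2.0
    offsets = geom.detector_offsets

    rows_idx: list[np.ndarray] = []
    cols_idx: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for v, ang in enumerate(np.deg2rad(geom.angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        # Ray direction is perpendicular to the detector axis (c, s).
        dx, dy = -s, c
        for k, t in enumerate(offsets):
            j = v * geom.n_detectors + k
            cols, lengths = _ray_grid_intersections(t * c, t * s, dx, dy, half, n, px)
            if cols.size:
                rows_idx.append(np.full(cols.size, j, dtype=np.intp))
                cols_idx.append(cols)
                vals.append(lengths)

    m = geom.n_views * geom.n_detectors
    if rows_idx:
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
            shape=(m, n * n),
        ).tocsr()
    else:
        mat = sp.csr_matrix((m, n * n))
    return SystemMatrix(mat, n, px, geom)


def forward_project(A: SystemMatrix, grid: ImageGrid) -> Sinogram:
    """Apply the system matrix: ``y = A mu`` with row-major flattening."""
    if grid.side_px != A.grid_side:
        raise ValueError(
            f"grid side {grid.side_px} does not match system matrix side {A.grid_side}"
        )
    y = A.dot(grid.values.ravel())
    return Sinogram(y.reshape(A.geometry.n_views, A.geometry.n_detectors), A.geometry)


def back_project(A: SystemMatrix, sino: Sinogram) -> ImageGrid:
    """Apply the exact adjoint: ``A^T y`` reshaped onto the image grid."""
    if sino.values.shape != (A.geometry.n_views, A.geometry.n_detectors):
        raise ValueError("sinogram shape does not match system matrix geometry")
    img = A.rmatvec(sino.ravel()).reshape(A.grid_side, A.grid_side)
    return ImageGrid(img, A.pixel_size)
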