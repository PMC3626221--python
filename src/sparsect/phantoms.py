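"""Synthetic phantoms, sinogram simulation, Gaussian noise, view decimation.

Phantoms are built from additive geometric primitives (discs/ellipses and
rectangles) rasterized by center-point containment.  Coordinates of the
primitives are expressed in *fractional* units of the image side, with the
origin at the image center and y pointing up, so a spec is resolution
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageGrid, ProjectionGeometry, Sinogram, build_system_matrix, forward_project

__all__ = [
    "Primitive",
    "PhantomSpec",
    "NoiseSpec",
    "generate_phantom",
    "default_phantom_spec",
    "simulate_sinogram",
    "add_noise",
    "decimate_views",
]


@dataclass
class Primitive:
    """One additive shape.

    kind: "ellipse" (axes = semi-axes), "rect" (axes = half-widths), or
    "gaussian" (smooth blob, axes = sigmas) emulating the smooth attenuation
    gradients of real tissue; a disc is an ellipse with equal semi-axes.
    center/axes are fractions of the image side; rotation_deg rotates the
    shape counterclockwise.
    """

    kind: str
    center: tuple[float, float]
    axes: tuple[float, float]
    value: float
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "rect", "gaussian"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if min(self.axes) <= 0:
            raise ValueError("primitive axes must be positive")
        cx, cy = self.center
        # Ellipse reach is the major semi-axis; a rectangle reaches its
        # corner; a Gaussian is considered contained if its center is.
        if self.kind == "ellipse":
            reach = float(max(self.axes))
        elif self.kind == "rect":
            reach = float(np.hypot(*self.axes))
        else:
            reach = 0.0
        if max(abs(cx), abs(cy)) + reach > 0.5 + 1e-12:
            raise ValueError("primitive extends outside the image square")

    def render(self, xf: np.ndarray, yf: np.ndarray) -> np.ndarray:
        """Per-pixel contribution (without the value factor) on fractional
        pixel-center coordinates: a 0/1 containment mask for sharp shapes,
        a smooth profile for Gaussians."""
        th = np.deg2rad(self.rotation_deg)
        dx = xf - self.center[0]
        dy = yf - self.center[1]
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        a, b = self.axes
        if self.kind == "ellipse":
            return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
        if self.kind == "rect":
            return ((np.abs(u) <= a) & (np.abs(v) <= b)).astype(float)
        return np.exp(-0.5 * ((u / a) ** 2 + (v / b) ** 2))

    def mask(self, xf: np.ndarray, yf: np.ndarray) -> np.ndarray:
        """Boolean containment mask (sharp shapes only)."""
        if self.kind == "gaussian":
            raise ValueError("gaussian primitives have no sharp containment mask")
        return self.render(xf, yf) > 0


@dataclass
class PhantomSpec:
    side_px: int
    background: float = 0.0
    primitives: list[Primitive] = field(default_factory=list)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.side_px < 1:
            raise ValueError("side_px must be positive")
        if not np.isfinite(self.background):
            raise ValueError("background must be finite")


@dataclass
class NoiseSpec:
    """Target relative noise magnitude ||e||_2 / ||y||_2 and RNG seed."""

    relative_level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_level < 0:
            raise ValueError("relative_level must be nonnegative")


def generate_phantom(spec: PhantomSpec) -> ImageGrid:
    """Rasterize a phantom spec: background plus the sum of all primitives
    containing each pixel center.  Deterministic."""
    n = spec.side_px
    # Fractional pixel-center coordinates; row 0 is the top of the image.
    c = (np.arange(n) - (n - 1) / 2.0) / n
    xf = c[np.newaxis, :]
    yf = -c[:, np.newaxis]
    img = np.full((n, n), float(spec.background))
    for prim in spec.primitives:
        img += prim.value * prim.render(xf, yf)
    return ImageGrid(img, spec.pixel_size)


def default_phantom_spec(side_px: int = 128) -> PhantomSpec:
    """The package's standard test object: a body disc with low-contrast
    inserts (down to 2% of the peak) and a comb of thin bars emulating fine
    trabecular-like detail."""
    bar_w = 1.0 / side_px  # 2-pixel bars (half-width of one pixel)
    prims = [
        Primitive("ellipse", (0.0, 0.0), (0.45, 0.45), 0.2),
        # Smooth attenuation gradients, as in real tissue.
        Primitive("gaussian", (0.05, -0.02), (0.22, 0.28), 0.15),
        Primitive("gaussian", (-0.18, 0.05), (0.10, 0.12), -0.08),
        # Low-contrast inserts.
        Primitive("ellipse", (-0.20, 0.18), (0.09, 0.09), 0.5),
        Primitive("ellipse", (0.20, 0.18), (0.09, 0.09), 0.1),
        Primitive("ellipse", (-0.20, -0.10), (0.09, 0.09), 0.05),
        Primitive("ellipse", (0.20, -0.10), (0.09, 0.09), 0.02),
        # Comb of thin vertical bars.
        *[
            Primitive("rect", (-0.12 + 0.06 * i, -0.30), (bar_w, 0.06), 0.3)
            for i in range(5)
        ],
    ]
    return PhantomSpec(side_px=side_px, background=0.0, primitives=prims)


def simulate_sinogram(grid: ImageGrid, geom: ProjectionGeometry) -> Sinogram:
    """Exact line integrals of the pixelized image for every ray."""
    A = build_system_matrix(grid, geom)
    return forward_project(A, grid)


def add_noise(sino: Sinogram, noise: NoiseSpec) -> Sinogram:
    """Add white Gaussian noise rescaled so that the achieved ratio
    ``||e||_2 / ||y||_2`` equals ``relative_level`` exactly."""
    if noise.relative_level == 0:
        return sino
    y_norm = float(np.linalg.norm(sino.values))
    if y_norm == 0:
        raise ValueError("cannot add relative noise to an all-zero sinogram")
    rng = np.random.default_rng(noise.seed)
    e = rng.standard_normal(sino.values.shape)
    e *= noise.relative_level * y_norm / np.linalg.norm(e)
    return Sinogram(sino.values + e, sino.geometry)


def decimate_views(sino: Sinogram, n_keep: int) -> Sinogram:
    """Keep ``n_keep`` views at uniform index stride starting at index 0.

    The stride is ``n_views // n_keep`` (floor), mirroring uniform angular
    decimation when ``n_keep`` divides ``n_views``.
    """
    n_views = sino.geometry.n_views
    if n_keep < 1:
        raise ValueError("n_keep must be positive")
    if n_keep > n_views:
        raise ValueError(f"n_keep={n_keep} exceeds available views {n_views}")
    stride = n_views // n_keep
    idx = np.arange(n_keep) * stride
    geom = ProjectionGeometry(
        sino.geometry.angles_deg[idx],
        sino.geometry.n_detectors,
        sino.geometry.detector_spacing,
    )
    return Sinogram(sino.values[idx].copy(), geom)
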