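"""Independent reference implementations used only to check the package.

These deliberately use different machinery (shapely geometry, explicit
loops, dense linear algebra) than the code under test.
"""

import numpy as np
from shapely.geometry import LineString, box


def ray_segment(angle_deg: float, t: float, reach: float = 1e3):
    """A long segment along the ray x*cos + y*sin = t."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    px, py = t * c, t * s  # foot of the perpendicular from the origin
    dx, dy = -s, c
    return LineString(
        [(px - reach * dx, py - reach * dy), (px + reach * dx, py + reach * dy)]
    )


def chord_through_box(angle_deg: float, t: float, half: float) -> float:
    """Length of the ray's intersection with the square [-half, half]^2."""
    return ray_segment(angle_deg, t).intersection(box(-half, -half, half, half)).length


def chord_through_pixel(
    angle_deg: float, t: float, row: int, col: int, side: int, pixel_size: float = 1.0
) -> float:
    """Length of the ray's intersection with one pixel of a centered grid."""
    half = side * pixel_size / 2.0
    x0 = -half + col * pixel_size
    y1 = half - row * pixel_size
    pixel = box(x0, y1 - pixel_size, x0 + pixel_size, y1)
    return ray_segment(angle_deg, t).intersection(pixel).length


def dense_system_matrix(geom, side: int, pixel_size: float = 1.0) -> np.ndarray:
    """Dense chord-length matrix built pixel by pixel with shapely."""
    m = geom.n_views * geom.n_detectors
    out = np.zeros((m, side * side))
    for v, ang in enumerate(geom.angles_deg):
        for k, t in enumerate(geom.detector_offsets):
            j = v * geom.n_detectors + k
            for r in range(side):
                for c in range(side):
                    out[j, r * side + c] = chord_through_pixel(
                        ang, t, r, c, side, pixel_size
                    )
    return out


def ssim_brute_force(a, b, window_size=11, sigma=1.5, k1=0.01, k2=0.03, data_range=None):
    """Window-by-window SSIM with explicit loops and weighted statistics."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if data_range is None:
        data_range = b.max() - b.min()
    if data_range == 0:
        data_range = 1.0
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    half = window_size // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x**2) / (2 * sigma**2))
    w = np.outer(g, g)
    w /= w.sum()
    vals = []
    for i in range(half, a.shape[0] - half):
        for j in range(half, a.shape[1] - half):
            pa = a[i - half : i + half + 1, j - half : j + half + 1]
            pb = b[i - half : i + half + 1, j - half : j + half + 1]
            mu_a = (w * pa).sum()
            mu_b = (w * pb).sum()
            va = (w * pa * pa).sum() - mu_a**2
            vb = (w * pb * pb).sum() - mu_b**2
            cov = (w * pa * pb).sum() - mu_a * mu_b
            vals.append(
                ((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


def numerical_gradient(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g
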