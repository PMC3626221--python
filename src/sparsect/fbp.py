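"""Filtered backprojection with band-limited Ram-Lak / Shepp-Logan kernels.

Each view is convolved with the spatial-domain ramp kernel (zero-padded FFT
convolution), then smeared back over the image with linear interpolation in
the detector coordinate; the angular integral over [0, pi) is discretized as
``pi / n_views`` times the sum over views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .geometry import ImageGrid, Sinogram

__all__ = ["RampFilter", "build_ramp_filter", "fbp_reconstruct"]

_KINDS = ("ram-lak", "shepp-logan")


@dataclass
class RampFilter:
    kind: str
    n_taps: int
    detector_spacing: float
    kernel: np.ndarray


def build_ramp_filter(
    kind: str = "ram-lak", n_taps: int = 257, detector_spacing: float = 1.0
) -> RampFilter:
    """Band-limited ramp kernel in the spatial domain.

    Ram-Lak: ``h(0) = 1/(4 d^2)``, ``h(k) = -1/(pi k d)^2`` for odd ``k``,
    ``0`` for even nonzero ``k``.  Shepp-Logan is the Ram-Lak response
    apodized by a sinc window in frequency, with closed form
    ``h(k) = -2 / (pi^2 d^2 (4 k^2 - 1))``.
    """
    if kind not in _KINDS:
        raise ValueError(f"filter kind must be one of {_KINDS}, got {kind!r}")
    if n_taps < 1 or n_taps % 2 == 0:
        raise ValueError(f"n_taps must be odd and positive, got {n_taps}")
    if detector_spacing <= 0:
        raise ValueError("detector_spacing must be positive")
    d = detector_spacing
    k = np.arange(n_taps) - n_taps // 2
    if kind == "ram-lak":
        h = np.zeros(n_taps)
        h[k == 0] = 1.0 / (4.0 * d * d)
        odd = k % 2 != 0
        h[odd] = -1.0 / (np.pi * k[odd] * d) ** 2
    else:
        h = -2.0 / (np.pi**2 * d * d * (4.0 * k.astype(float) ** 2 - 1.0))
    return RampFilter(kind, n_taps, d, h)


def fbp_reconstruct(
    sino: Sinogram,
    side_px: int,
    filt: RampFilter | None = None,
    pixel_size: float = 1.0,
) -> ImageGrid:
    """Reconstruct an image from a parallel-beam sinogram by FBP."""
    if sino.geometry.n_views < 1:
        raise ValueError("sinogram must contain at least one view")
    geom = sino.geometry
    if filt is None:
        n_taps = 2 * geom.n_detectors + 1
        filt = build_ramp_filter("ram-lak", n_taps, geom.detector_spacing)
    if filt.detector_spacing != geom.detector_spacing:
        filt = build_ramp_filter(filt.kind, filt.n_taps, geom.detector_spacing)

    # Convolution approximates the filtering integral: multiply by spacing.
    filtered = (
        fftconvolve(sino.values, filt.kernel[np.newaxis, :], mode="same", axes=1)
        * geom.detector_spacing
    )

    n = side_px
    c = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    x = c[np.newaxis, :]
    y = -c[:, np.newaxis]
    offsets = geom.detector_offsets
    t0 = offsets[0]
    d = geom.detector_spacing

    img = np.zeros((n, n))
    for v, ang in enumerate(np.deg2rad(geom.angles_deg)):
        t = x * np.cos(ang) + y * np.sin(ang)
        # Linear interpolation in t; rays outside the detector contribute 0.
        pos = (t - t0) / d
        i0 = np.floor(pos).astype(np.intp)
        frac = pos - i0
        valid0 = (i0 >= 0) & (i0 < geom.n_detectors)
        valid1 = (i0 + 1 >= 0) & (i0 + 1 < geom.n_detectors)
        row = filtered[v]
        img += np.where(valid0, row[np.clip(i0, 0, geom.n_detectors - 1)] * (1 - frac), 0.0)
        img += np.where(valid1, row[np.clip(i0 + 1, 0, geom.n_detectors - 1)] * frac, 0.0)

    img *= np.pi / geom.n_views
    return ImageGrid(img, pixel_size)
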