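"""Reconstruction quality metrics: RRMSE, streak indicator, SSIM."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cs import tv_norm

__all__ = ["SsimConfig", "rrmse", "streak_indicator", "ssim"]


def _as_pair(y, y_ref) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(y, dtype=float)
    b = np.asarray(y_ref, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rrmse(y, y_ref) -> float:
    """Relative root mean square error ``||y - y_ref||_2 / ||y_ref||_2``."""
    a, b = _as_pair(y, y_ref)
    ref_norm = np.linalg.norm(b)
    if ref_norm == 0:
        raise ValueError("reference image has zero norm")
    return float(np.linalg.norm(a - b) / ref_norm)


def streak_indicator(y, y_ref) -> float:
    """Total variation of the difference image (exact, unsmoothed TV with
    the same forward-difference convention as the TV objective).  Lower
    values mean fewer streaking artifacts."""
    a, b = _as_pair(y, y_ref)
    return tv_norm(a - b, xi=0.0)


@dataclass
class SsimConfig:
    """Standard SSIM settings: 11x11 Gaussian window (sigma 1.5), stabilizers
    ``C1 = (K1*L)^2``, ``C2 = (K2*L)^2``, ``C3 = C2/2`` (which reduces the
    three-factor product to the usual two-term form), mean pooling."""

    window_size: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float | None = None  # default: observed range of the reference

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def kernel(self) -> np.ndarray:
        half = self.window_size // 2
        x = np.arange(-half, half + 1, dtype=float)
        g = np.exp(-(x**2) / (2.0 * self.sigma**2))
        k2d = np.outer(g, g)
        return k2d / k2d.sum()


def ssim(y, y_ref, cfg: SsimConfig | None = None) -> float:
    """Mean structural similarity over all fully interior sliding windows.

    Local luminance, contrast and structure similarities are computed from
    Gaussian-weighted window statistics; with ``C3 = C2/2`` their product
    collapses to the classical two-term SSIM formula.
    """
    cfg = cfg or SsimConfig()
    a, b = _as_pair(y, y_ref)
    if min(a.shape) < cfg.window_size:
        raise ValueError("images smaller than the SSIM window")
    L = cfg.data_range
    if L is None:
        L = float(b.max() - b.min())
    if L == 0:
        L = 1.0
    c1 = (cfg.k1 * L) ** 2
    c2 = (cfg.k2 * L) ** 2

    from scipy.signal import fftconvolve

    w = cfg.kernel()

    def filt(img: np.ndarray) -> np.ndarray:
        return fftconvolve(img, w, mode="valid")

    mu_a = filt(a)
    mu_b = filt(b)
    var_a = filt(a * a) - mu_a**2
    var_b = filt(b * b) - mu_b**2
    cov = filt(a * b) - mu_a * mu_b

    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))
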