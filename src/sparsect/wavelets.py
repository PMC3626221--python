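"""Orthonormal 2D discrete wavelet transform with periodic boundaries.

A periodized orthogonal filter bank is an orthogonal matrix, so the 2D
separable transform ``W X W^T`` preserves the l2 norm exactly and its
inverse is its transpose.  Images whose side is not a power of two are
symmetrically zero-padded (for the transform only), which keeps both the
norm-preservation and perfect-reconstruction contracts intact.

Supported families: ``haar``, ``db2``, ``db4`` (orthonormal Daubechies
scaling filters with 2, 4 and 8 taps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["WaveletOperator", "FAMILIES"]

_SQRT2 = np.sqrt(2.0)

# Orthonormal scaling (lowpass) filters; sum = sqrt(2), unit l2 norm.
FAMILIES: dict[str, np.ndarray] = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "db2": np.array(
        [
            0.48296291314469025,
            0.836516303737469,
            0.22414386804185735,
            -0.12940952255092145,
        ]
    ),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


@lru_cache(maxsize=32)
def _analysis_matrix(family: str, n: int) -> np.ndarray:
    """Orthogonal n x n one-level analysis matrix (lowpass rows stacked on
    highpass rows), filters placed periodically at even shifts."""
    h = FAMILIES[family]
    L = h.size
    g = ((-1) ** np.arange(L)) * h[::-1]  # quadrature mirror highpass
    W = np.zeros((n, n))
    half = n // 2
    for k in range(half):
        for m in range(L):
            j = (2 * k + m) % n
            W[k, j] += h[m]
            W[half + k, j] += g[m]
    return W


@dataclass
class WaveletOperator:
    """Multilevel orthonormal 2D DWT acting on ``side x side`` images.

    ``forward`` maps an image to an ``padded_side x padded_side`` coefficient
    array (approximation in the top-left corner, standard in-place layout);
    ``inverse`` maps coefficients back and crops to the original side.
    Because the transform is orthonormal and the padding is zero insertion,
    ``inverse`` is also the exact adjoint of ``forward``.
    """

    side: int
    family: str = "db4"
    levels: int = 4
    padded_side: int = field(init=False)

    def __post_init__(self) -> None:
        if self.side < 1:
            raise ValueError("side must be positive")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown wavelet family {self.family!r}; choose from {sorted(FAMILIES)}")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        self.padded_side = 1 << max(int(np.ceil(np.log2(self.side))), 0)
        if self.padded_side % (1 << self.levels) != 0:
            raise ValueError(
                f"padded side {self.padded_side} does not support {self.levels} levels"
            )
        pad = self.padded_side - self.side
        self._lo = pad // 2
        self._hi = self._lo + self.side

    @property
    def n_coeffs(self) -> int:
        return self.padded_side**2

    def _pad(self, img: np.ndarray) -> np.ndarray:
        if self.padded_side == self.side:
            return np.array(img, dtype=float)
        out = np.zeros((self.padded_side, self.padded_side))
        out[self._lo : self._hi, self._lo : self._hi] = img
        return out

    def forward(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        if img.shape != (self.side, self.side):
            raise ValueError(f"expected {(self.side, self.side)} image, got {img.shape}")
        x = self._pad(img)
        n = self.padded_side
        for _ in range(self.levels):
            W = _analysis_matrix(self.family, n)
            x[:n, :n] = W @ x[:n, :n] @ W.T
            n //= 2
        return x

    def inverse(self, coeffs: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (self.padded_side, self.padded_side):
            raise ValueError(
                f"expected {(self.padded_side, self.padded_side)} coefficients, got {coeffs.shape}"
            )
        x = coeffs.copy()
        sizes = [self.padded_side // (1 << lv) for lv in range(self.levels, 0, -1)]
        for n in sizes:
            W = _analysis_matrix(self.family, 2 * n)
            x[: 2 * n, : 2 * n] = W.T @ x[: 2 * n, : 2 * n] @ W
        return x[self._lo : self._hi, self._lo : self._hi].copy()
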