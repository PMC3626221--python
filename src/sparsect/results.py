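"""Reconstruction result container shared by the iterative solvers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageGrid

__all__ = ["ReconResult"]


@dataclass
class ReconResult:
    image: ImageGrid
    cost_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    iterations_run: int = 0
    converged: bool = False
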