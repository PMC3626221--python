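# sparsect

Sparse-view parallel-beam CT reconstruction toolkit. It implements a
compressed-sensing reconstruction that jointly minimizes total variation,
wavelet-domain l1, and a least-squares data term via smoothed nonlinear
conjugate gradient, alongside the classical baselines it is compared
against (filtered backprojection, ART/Kaczmarz, SART, TV-only), together
with a synthetic phantom simulator, a sinogram noise model, uniform view
decimation, and quantitative metrics (RRMSE, streak indicator, SSIM).

## Components

| Module | What it does |
| --- | --- |
| `sparsect.geometry` | Parallel-beam geometry; sparse system matrix of exact ray-pixel chord lengths (Siddon-style traversal); forward/backprojection |
| `sparsect.phantoms` | Primitive-based phantom generator (ellipses, rectangles, smooth Gaussian blobs), sinogram simulation, exact-ratio Gaussian noise, view decimation |
| `sparsect.fbp` | Filtered backprojection with band-limited Ram-Lak and Shepp-Logan kernels |
| `sparsect.algebraic` | Kaczmarz (ART) and SART iterative solvers |
| `sparsect.wavelets` | Periodized orthonormal 2D DWT (haar, db2, db4) |
| `sparsect.cs` | The joint TV + wavelet-l1 + least-squares objective, its gradient, the NLCG solver with backtracking line search, and regularization-weight search |
| `sparsect.metrics` | RRMSE, streak indicator (TV of the difference image), SSIM |
| `sparsect.io` / `sparsect.cli` | Image/sinogram I/O (TIFF/PNG/CSV/HDF5), experiment driver, CLI |

## CLI

```bash
# simulate a 50-view sinogram of the default 128x128 phantom
sparsect simulate --side 128 --views 50 --out sino.csv --phantom-out truth.tif

# reconstruct with each method
sparsect reconstruct --sinogram sino.csv --method fbp      --side 128 --out fbp.tif
sparsect reconstruct --sinogram sino.csv --method art      --side 128 --iters 30 --out art.tif
sparsect reconstruct --sinogram sino.csv --method tv       --side 128 --lambda1 0.8 --out tv.tif
sparsect reconstruct --sinogram sino.csv --method proposed --side 128 \
    --lambda1 0.5 --lambda2 0.08 --wavelet db4 --levels 4 --out cs.tif

# evaluate against the ground truth
sparsect evaluate --ref truth.tif --test cs.tif --metrics rrmse,si,ssim

# full multi-method, multi-view-count sweep from a JSON config
sparsect sweep --config experiment.json

# regularization-weight search against a reference image
sparsect param-search --sinogram sino.csv --reference truth.tif --side 128 --mode proposed
```

An experiment config is JSON with a phantom spec (or input image path),
geometry, view counts, noise level, and per-method settings; see
`sparsect.io.ExperimentConfig.from_json`.

## Library example

```python
import numpy as np
from sparsect import (
    CsConfig, ProjectionGeometry, build_system_matrix, default_phantom_spec,
    forward_project, generate_phantom, nlcg_reconstruct, rrmse, ImageGrid,
)

truth = generate_phantom(default_phantom_spec(128))
geom = ProjectionGeometry.uniform(50, 128)            # 50 views over 180 deg
A = build_system_matrix(ImageGrid(np.zeros((128, 128))), geom)
sino = forward_project(A, truth)
res = nlcg_reconstruct(A, sino, CsConfig(lambda1=0.5, lambda2=0.08))
print(rrmse(res.image.values, truth.values))
```

## Conventions

- Images are square, centered at the origin; array row 0 is the top;
  pixels are flattened row-major.
- A view at angle theta measures line integrals along rays
  `x cos(theta) + y sin(theta) = t`; detector bins are centered on
  `t = (k - (n_detectors - 1)/2) * detector_spacing`.
- Angles are degrees in [0, 180), strictly increasing.
- Noise is white Gaussian on the sinogram, rescaled so the achieved
  relative magnitude `||e||_2 / ||y||_2` hits the requested level exactly.
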