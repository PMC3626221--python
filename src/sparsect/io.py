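"""Image and sinogram I/O plus the end-to-end experiment driver.

Float images round-trip losslessly through TIFF (32/64-bit float) and
through the CSV array container.  PNG export is 16-bit, min-max scaled for
visualization, with the scaling recorded in a JSON sidecar.  Sinograms are
stored as CSV or HDF5 with their geometry (angles, detector spacing)
alongside.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .algebraic import AlgebraicConfig, art_reconstruct, sart_reconstruct
from .cs import CsConfig, nlcg_reconstruct
from .fbp import build_ramp_filter, fbp_reconstruct
from .geometry import (
    ImageGrid,
    ProjectionGeometry,
    Sinogram,
    build_system_matrix,
)
from .metrics import rrmse, ssim, streak_indicator
from .phantoms import (
    NoiseSpec,
    PhantomSpec,
    Primitive,
    add_noise,
    decimate_views,
    default_phantom_spec,
    generate_phantom,
    simulate_sinogram,
)
from .results import ReconResult

__all__ = [
    "read_image",
    "write_image",
    "save_sinogram",
    "load_sinogram",
    "ExperimentConfig",
    "run_experiment",
    "phantom_spec_from_dict",
]

log = logging.getLogger("sparsect")

METHODS = ("fbp", "art", "sart", "tv", "proposed")


# ---------------------------------------------------------------------------
# Images


def read_image(path: str | Path, pixel_size: float = 1.0) -> ImageGrid:
    """Read a grayscale image (TIFF/PNG/CSV) as an ImageGrid.

    Integer PNG/TIFF data are returned as raw float values (no rescaling);
    float TIFF and CSV round-trip bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    suffix = path.suffix.lower()
    if suffix == ".csv":
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"expected a grayscale image, got shape {arr.shape}")
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {arr.shape}")
    return ImageGrid(arr.astype(float), pixel_size)


def write_image(grid: ImageGrid, path: str | Path) -> None:
    """Write an image: float TIFF or CSV (lossless) or 16-bit PNG (min-max
    scaled; the scale/offset is stored in ``<path>.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        np.savetxt(path, grid.values, delimiter=",", fmt="%.17g")
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, grid.values.astype(np.float64))
    elif suffix == ".png":
        import imageio.v3 as iio

        lo, hi = float(grid.values.min()), float(grid.values.max())
        scale = hi - lo if hi > lo else 1.0
        scaled = np.round((grid.values - lo) / scale * 65535).astype(np.uint16)
        iio.imwrite(path, scaled)
        sidecar = {"min": lo, "max": hi, "dtype": "uint16"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unsupported image format: {suffix}")


# ---------------------------------------------------------------------------
# Sinograms


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    """Save a sinogram with its geometry, as CSV + JSON sidecar or HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    geom = sino.geometry
    if path.suffix.lower() == ".csv":
        np.savetxt(path, sino.values, delimiter=",", fmt="%.17g")
        meta = {
            "angles_deg": geom.angles_deg.tolist(),
            "n_detectors": geom.n_detectors,
            "detector_spacing": geom.detector_spacing,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=sino.values)
            f.create_dataset("angles_deg", data=geom.angles_deg)
            f.attrs["n_detectors"] = geom.n_detectors
            f.attrs["detector_spacing"] = geom.detector_spacing
    else:
        raise ValueError(f"unsupported sinogram format: {path.suffix}")


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such sinogram: {path}")
    if path.suffix.lower() == ".csv":
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        meta = json.loads(Path(str(path) + ".json").read_text())
        geom = ProjectionGeometry(
            np.asarray(meta["angles_deg"]),
            int(meta["n_detectors"]),
            float(meta["detector_spacing"]),
        )
    else:
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][()]
            geom = ProjectionGeometry(
                f["angles_deg"][()],
                int(f.attrs["n_detectors"]),
                float(f.attrs["detector_spacing"]),
            )
    return Sinogram(values, geom)


# ---------------------------------------------------------------------------
# Experiment configuration and driver


def phantom_spec_from_dict(d: dict) -> PhantomSpec:
    prims = [
        Primitive(
            kind=p.get("kind", "ellipse"),
            center=tuple(p["center"]),
            axes=tuple(p["axes"]),
            value=float(p["value"]),
            rotation_deg=float(p.get("rotation_deg", 0.0)),
        )
        for p in d.get("primitives", [])
    ]
    return PhantomSpec(
        side_px=int(d["side_px"]),
        background=float(d.get("background", 0.0)),
        primitives=prims,
        pixel_size=float(d.get("pixel_size", 1.0)),
    )


@dataclass
class ExperimentConfig:
    """Full sweep configuration: simulate -> decimate -> noise ->
    reconstruct -> evaluate for each method and view count."""

    phantom: PhantomSpec | None = None
    image_path: str | None = None
    full_views: int = 360
    n_detectors: int | None = None
    detector_spacing: float = 1.0
    view_counts: list[int] = field(default_factory=lambda: list(range(20, 130, 10)))
    noise_level: float = 0.0
    methods: list[str] = field(default_factory=lambda: ["fbp"])
    method_settings: dict = field(default_factory=dict)
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
        if max(self.view_counts, default=1) > self.full_views:
            raise ValueError("view_counts exceed the number of simulated views")
        if self.phantom is None and self.image_path is None:
            raise ValueError("either a phantom spec or an input image is required")

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        d = json.loads(Path(path).read_text())
        phantom = phantom_spec_from_dict(d["phantom"]) if "phantom" in d else None
        return cls(
            phantom=phantom,
            image_path=d.get("image_path"),
            full_views=int(d.get("full_views", 360)),
            n_detectors=d.get("n_detectors"),
            detector_spacing=float(d.get("detector_spacing", 1.0)),
            view_counts=list(d.get("view_counts", list(range(20, 130, 10)))),
            noise_level=float(d.get("noise_level", 0.0)),
            methods=list(d.get("methods", ["fbp"])),
            method_settings=dict(d.get("method_settings", {})),
            output_dir=str(d.get("output_dir", "results")),
            seed=int(d.get("seed", 0)),
        )


def _reconstruct_one(
    method: str,
    sino: Sinogram,
    side: int,
    pixel_size: float,
    settings: dict,
) -> ReconResult:
    if method == "fbp":
        filt = build_ramp_filter(
            settings.get("filter", "ram-lak"),
            settings.get("n_taps", 2 * sino.geometry.n_detectors + 1),
            sino.geometry.detector_spacing,
        )
        img = fbp_reconstruct(sino, side, filt, pixel_size)
        return ReconResult(img)

    grid = ImageGrid(np.zeros((side, side)), pixel_size)
    A = build_system_matrix(grid, sino.geometry)
    if method in ("art", "sart"):
        cfg = AlgebraicConfig(
            relaxation=settings.get("relaxation", 1.0),
            n_iterations=settings.get("iterations", 30 if method == "art" else 150),
            nonnegative=settings.get("nonnegative", False),
        )
        return (art_reconstruct if method == "art" else sart_reconstruct)(A, sino, cfg)
    cfg = CsConfig(
        lambda1=settings.get("lambda1", 0.001),
        lambda2=0.0 if method == "tv" else settings.get("lambda2", 0.0005),
        max_iterations=settings.get("iterations", 150),
        wavelet_family=settings.get("wavelet", "db4"),
        wavelet_levels=settings.get("levels", 4),
    )
    return nlcg_reconstruct(A, sino, cfg)


def run_experiment(cfg: ExperimentConfig) -> list[dict]:
    """Execute the sweep and write reconstructions, metrics.csv, and cost
    traces under ``cfg.output_dir``.  Deterministic for a fixed seed."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.phantom is not None:
        truth = generate_phantom(cfg.phantom)
    else:
        truth = read_image(cfg.image_path)
    side = truth.side_px
    n_det = cfg.n_detectors or side
    log.info("simulating %d-view sinogram for a %dx%d image", cfg.full_views, side, side)

    geom = ProjectionGeometry.uniform(cfg.full_views, n_det, cfg.detector_spacing)
    full_sino = simulate_sinogram(truth, geom)

    rows: list[dict] = []
    for views in cfg.view_counts:
        sino = decimate_views(full_sino, views)
        if cfg.noise_level > 0:
            # Per-stage seed derived from the experiment seed and view count.
            stage_seed = int(np.random.SeedSequence([cfg.seed, views]).generate_state(1)[0])
            sino = add_noise(sino, NoiseSpec(cfg.noise_level, stage_seed))
        for method in cfg.methods:
            log.info("reconstructing: method=%s views=%d", method, views)
            try:
                res = _reconstruct_one(
                    method, sino, side, truth.pixel_size, cfg.method_settings.get(method, {})
                )
            except Exception as exc:  # noqa: BLE001 - name the failing stage
                raise RuntimeError(f"stage reconstruct[{method}, {views} views] failed") from exc
            row = {
                "method": method,
                "views": views,
                "rrmse": rrmse(res.image.values, truth.values),
                "si": streak_indicator(res.image.values, truth.values),
                "ssim": ssim(res.image.values, truth.values),
            }
            rows.append(row)
            write_image(res.image, out / f"recon_{method}_{views:04d}.tif")
            if res.cost_trace.size:
                np.savetxt(
                    out / f"trace_{method}_{views:04d}.csv",
                    res.cost_trace,
                    delimiter=",",
                    fmt="%.17g",
                )

    with open(out / "metrics.csv", "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=["method", "views", "rrmse", "si", "ssim"])
        writer.writeheader()
        for row in rows:
            writer.writerow({**row, "rrmse": f"{row['rrmse']:.12g}",
                             "si": f"{row['si']:.12g}", "ssim": f"{row['ssim']:.12g}"})
    return rows
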