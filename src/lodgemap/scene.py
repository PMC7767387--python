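"""Synthetic paired pre/post-event scene generator.

Emulates the data situation of a typhoon lodging study: a dual-pol SAR
covariance grid and a 10-band optical reflectance stack acquired before and
after the event, over a patchy agricultural landscape of lodged rice, healthy
rice, water, buildings, wood and bare soil; ten lodged (L1–L10) and ten
healthy (H1–H10) circular sample plots; and labelled train/validation pixel
sets that exclude the plots.

Noise model
-----------
SAR intensities are class-mean linear power multiplied by Gamma(ENL, 1/ENL)
speckle (unit mean, CV = 1/sqrt(ENL)); the off-diagonal C12 has configurable
coherence magnitude and uniform random phase.  Optical reflectance is class
mean plus Gaussian noise.  Lodged plots change their class mean between the
epochs; healthy rice changes only by the configured illumination drift.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, mapping, shape

from . import reference as ref
from .geo import GridTransform, RasterStack
from .sar import C2Raster


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    grid_height: int = 256
    grid_width: int = 256
    pixel_size: float = 10.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(ref.DEFAULT_CLASS_FRACTIONS)
    )
    n_lodged_plots: int = 10
    n_healthy_plots: int = 10
    plot_radius: float = 4.0  # pixels
    sar_means: dict = field(default_factory=lambda: _deep_copy(ref.DEFAULT_SAR_MEANS_DB))
    enl: float = 4.0
    c12_correlation: float = 0.3
    speckle: bool = True
    optical_means: dict = field(default_factory=lambda: _deep_copy(ref.DEFAULT_OPTICAL_MEANS))
    optical_sd: float = 0.08
    n_train_pixels: int = 2876
    n_validation_pixels: int = 1427
    n_mask_train_pixels: int = 900
    patch_size: int = 16  # landscape granularity in pixels
    seed: int = 0

    def validate(self) -> None:
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class_fractions sum to {total}, not 1")
        if set(self.class_fractions) != set(ref.LEGEND.values()):
            raise ConfigurationError("class_fractions must cover exactly the legend classes")
        if self.enl < 1:
            raise ConfigurationError("enl must be >= 1")
        if self.optical_sd < 0 or not (0 <= self.c12_correlation <= 1):
            raise ConfigurationError("noise parameters out of range")
        margin = self.plot_radius + 1
        if 2 * margin >= min(self.grid_height, self.grid_width):
            raise ConfigurationError("plots do not fit inside the grid")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


def _deep_copy(d):
    return json.loads(json.dumps(d))


@dataclass
class Plot:
    label: str  # L1..L10 / H1..H10
    class_code: int
    polygon: object  # shapely polygon


@dataclass
class SceneBundle:
    sar_before: C2Raster
    sar_after: C2Raster
    optical_before: RasterStack
    optical_after: RasterStack
    truth: np.ndarray
    plots: list[Plot]
    train_pixels: pd.DataFrame  # crop-only RF training pixels (row, col, class_code)
    validation_pixels: pd.DataFrame  # crop-only validation pixels
    mask_train_pixels: pd.DataFrame  # all-class pixels for fitting the crop mask
    legend: dict[int, str]
    transform: GridTransform
    config: SimulationConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth.shape


def _patchy_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Blocky land-cover map: a coarse grid of patches upsampled to the scene."""
    codes = np.array(sorted(ref.LEGEND))
    probs = np.array([cfg.class_fractions[ref.LEGEND[c]] for c in codes])
    ph = -(-cfg.grid_height // cfg.patch_size)
    pw = -(-cfg.grid_width // cfg.patch_size)
    coarse = rng.choice(codes, size=(ph, pw), p=probs)
    full = np.repeat(np.repeat(coarse, cfg.patch_size, axis=0), cfg.patch_size, axis=1)
    return full[: cfg.grid_height, : cfg.grid_width].astype(np.uint8)


def _place_plots(cfg: SimulationConfig, transform: GridTransform, rng: np.random.Generator) -> list[Plot]:
    margin = cfg.plot_radius + 1.0
    centers: list[tuple[float, float]] = []
    plots: list[Plot] = []
    specs = [("L", ref.LODGED_RICE, cfg.n_lodged_plots), ("H", ref.HEALTHY_RICE, cfg.n_healthy_plots)]
    min_sep = 2.0 * cfg.plot_radius + 2.0
    for prefix, code, n in specs:
        for i in range(1, n + 1):
            for _ in range(10_000):
                r = rng.uniform(margin, cfg.grid_height - margin)
                c = rng.uniform(margin, cfg.grid_width - margin)
                if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
                    centers.append((r, c))
                    break
            else:
                raise ConfigurationError("could not place non-overlapping plots; grid too small")
            x, y = transform.pixel_center(r - 0.5, c - 0.5)
            poly = Point(x, y).buffer(cfg.plot_radius * cfg.pixel_size, quad_segs=32)
            plots.append(Plot(label=f"{prefix}{i}", class_code=code, polygon=poly))
    return plots


def _stamp_plots(truth: np.ndarray, plots: list[Plot], cfg: SimulationConfig) -> None:
    rows, cols = np.mgrid[0 : truth.shape[0], 0 : truth.shape[1]]
    t = GridTransform(pixel_size=cfg.pixel_size)
    for p in plots:
        cx, cy = p.polygon.centroid.x, p.polygon.centroid.y
        prow, pcol = t.world_to_pixel(cx, cy)
        mask = (rows - prow) ** 2 + (cols - pcol) ** 2 <= cfg.plot_radius**2
        truth[mask] = p.class_code


def _class_grid(truth: np.ndarray, values_by_code: dict[int, float]) -> np.ndarray:
    out = np.empty(truth.shape, dtype=float)
    for code, v in values_by_code.items():
        out[truth == code] = v
    return out


def _simulate_sar(
    cfg: SimulationConfig, truth: np.ndarray, epoch: str, transform: GridTransform, rng: np.random.Generator
) -> C2Raster:
    name_by_code = ref.LEGEND
    vv_db = _class_grid(truth, {c: cfg.sar_means[name_by_code[c]][epoch]["vv"] for c in name_by_code})
    vh_db = _class_grid(truth, {c: cfg.sar_means[name_by_code[c]][epoch]["vh"] for c in name_by_code})
    p_vv = 10.0 ** (vv_db / 10.0)
    p_vh = 10.0 ** (vh_db / 10.0)
    if cfg.speckle:
        shape_ = truth.shape
        p_vv = p_vv * rng.gamma(cfg.enl, 1.0 / cfg.enl, size=shape_)
        p_vh = p_vh * rng.gamma(cfg.enl, 1.0 / cfg.enl, size=shape_)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=truth.shape)
    c12 = cfg.c12_correlation * np.sqrt(p_vv * p_vh) * np.exp(1j * phase)
    return C2Raster(c11=p_vv, c22=p_vh, c12=c12, transform=transform)


def _simulate_optical(
    cfg: SimulationConfig, truth: np.ndarray, epoch: str, transform: GridTransform, rng: np.random.Generator
) -> RasterStack:
    bands = {}
    for bi, bname in enumerate(ref.OPTICAL_BANDS):
        mean = _class_grid(
            truth, {c: cfg.optical_means[ref.LEGEND[c]][epoch][bi] for c in ref.LEGEND}
        )
        if cfg.optical_sd > 0:
            mean = mean + rng.normal(0.0, cfg.optical_sd, size=truth.shape)
        bands[bname] = np.maximum(mean, 0.0)
    return RasterStack(bands, transform, {"epoch": epoch})


def _sample_pixel_sets(
    cfg: SimulationConfig, truth: np.ndarray, plots: list[Plot], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint labelled pixel sets excluding all sample plots.

    The lodged/healthy train and validation sets are crop-only (the
    classification and accuracy assessment concern rice pixels); a separate
    all-class set, stratified over every land-cover class present, serves to
    fit the crop-masking classifier.
    """
    h, w = truth.shape
    rows, cols = np.mgrid[0:h, 0:w]
    plot_mask = np.zeros(truth.shape, dtype=bool)
    t = GridTransform(pixel_size=cfg.pixel_size)
    for p in plots:
        prow, pcol = t.world_to_pixel(p.polygon.centroid.x, p.polygon.centroid.y)
        plot_mask |= (rows - prow) ** 2 + (cols - pcol) ** 2 <= cfg.plot_radius**2

    flat_ok = ~plot_mask.ravel()
    flat_truth = truth.ravel()
    crop = np.isin(flat_truth, ref.CROP_CODES)

    crop_pool = np.flatnonzero(flat_ok & crop)
    n_crop = cfg.n_validation_pixels + cfg.n_train_pixels
    if len(crop_pool) < n_crop:
        raise ConfigurationError(
            f"not enough crop pixels ({len(crop_pool)}) for train+validation ({n_crop})"
        )
    picked = rng.choice(crop_pool, size=n_crop, replace=False)
    val_idx = picked[: cfg.n_validation_pixels]
    train_idx = picked[cfg.n_validation_pixels :]

    taken = np.zeros(flat_truth.shape, dtype=bool)
    taken[picked] = True
    mask_parts = []
    pool_all = flat_ok & ~taken
    codes = np.array(sorted(ref.LEGEND))
    counts = np.array([np.count_nonzero(pool_all & (flat_truth == c)) for c in codes])
    want = np.maximum((cfg.n_mask_train_pixels * counts / max(counts.sum(), 1)).astype(int), 15)
    want = np.minimum(want, counts)
    for c, n in zip(codes, want):
        pool_c = np.flatnonzero(pool_all & (flat_truth == c))
        if n > 0:
            mask_parts.append(rng.choice(pool_c, size=int(n), replace=False))
    mask_idx = np.concatenate(mask_parts) if mask_parts else np.array([], dtype=int)

    def frame(idx):
        return pd.DataFrame(
            {"row": idx // w, "col": idx % w, "class_code": flat_truth[idx].astype(int)}
        ).sort_values(["row", "col"], ignore_index=True)

    return frame(train_idx), frame(val_idx), frame(mask_idx)


def generate_scene(config: SimulationConfig) -> SceneBundle:
    """Generate a fully labelled synthetic pre/post-event scene bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    transform = GridTransform(pixel_size=config.pixel_size)

    truth = _patchy_classes(config, rng)
    plots = _place_plots(config, transform, rng)
    _stamp_plots(truth, plots, config)

    sar_before = _simulate_sar(config, truth, "before", transform, rng)
    sar_after = _simulate_sar(config, truth, "after", transform, rng)
    optical_before = _simulate_optical(config, truth, "before", transform, rng)
    optical_after = _simulate_optical(config, truth, "after", transform, rng)
    train_px, val_px, mask_px = _sample_pixel_sets(config, truth, plots, rng)

    return SceneBundle(
        sar_before=sar_before,
        sar_after=sar_after,
        optical_before=optical_before,
        optical_after=optical_after,
        truth=truth,
        plots=plots,
        train_pixels=train_px,
        validation_pixels=val_px,
        mask_train_pixels=mask_px,
        legend=dict(ref.LEGEND),
        transform=transform,
        config=config,
    )


# ---------------------------------------------------------------------------
# File I/O: TIFF rasters + GeoJSON plots + CSV pixel sets, with a manifest
# ---------------------------------------------------------------------------


def _write_tiff(path: Path, array3d: np.ndarray, band_names: list[str], transform: GridTransform) -> None:
    desc = json.dumps({"bands": band_names, "transform": transform.to_dict()})
    tifffile.imwrite(path, array3d.astype(np.float32), description=desc, photometric="minisblack")


def _read_tiff(path: Path) -> tuple[np.ndarray, list[str], GridTransform]:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].tags["ImageDescription"].value
    meta = json.loads(desc)
    if arr.ndim == 2:
        arr = arr[None]
    return arr, meta["bands"], GridTransform.from_dict(meta["transform"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_scene(bundle: SceneBundle, directory: str | Path) -> dict:
    """Write a scene bundle to ``directory``; returns the manifest dict.

    Layout: multiband TIFF rasters (band names + geotransform in the image
    description), GeoJSON plot polygons, CSV pixel sets and legend, JSON
    config, and ``manifest.json`` listing each file with its SHA-256.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    for name, c2 in (("sar_before", bundle.sar_before), ("sar_after", bundle.sar_after)):
        arr = np.stack([c2.c11, c2.c22, c2.c12.real, c2.c12.imag])
        _write_tiff(d / f"{name}.tif", arr, ["C11", "C22", "C12_re", "C12_im"], c2.transform)
        files[f"{name}.tif"] = "sar_c2"
    for name, stack in (("optical_before", bundle.optical_before), ("optical_after", bundle.optical_after)):
        _write_tiff(d / f"{name}.tif", stack.to_array(np.float32), stack.names, stack.transform)
        files[f"{name}.tif"] = "optical"
    _write_tiff(d / "truth.tif", bundle.truth[None].astype(np.float32), ["class_code"], bundle.transform)
    files["truth.tif"] = "truth"

    geojson = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {"label": p.label, "class_code": p.class_code},
            }
            for p in bundle.plots
        ],
    }
    (d / "plots.geojson").write_text(json.dumps(geojson))
    files["plots.geojson"] = "plots"

    bundle.train_pixels.to_csv(d / "train_pixels.csv", index=False)
    bundle.validation_pixels.to_csv(d / "validation_pixels.csv", index=False)
    bundle.mask_train_pixels.to_csv(d / "mask_train_pixels.csv", index=False)
    files["train_pixels.csv"] = files["validation_pixels.csv"] = "pixel_set"
    files["mask_train_pixels.csv"] = "pixel_set"
    pd.DataFrame(
        {"class_code": list(bundle.legend), "class_name": list(bundle.legend.values())}
    ).to_csv(d / "legend.csv", index=False)
    files["legend.csv"] = "legend"
    (d / "config.json").write_text(json.dumps(bundle.config.to_dict(), indent=1))
    files["config.json"] = "config"

    manifest = {
        "coordinate_convention": "row-major grid, north-up affine transform, pixel-centre coordinates, local metric CRS",
        "files": {name: {"role": role, "sha256": _sha256(d / name)} for name, role in files.items()},
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_scene(directory: str | Path) -> SceneBundle:
    """Read a bundle previously written by :func:`write_scene`."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    for name in manifest["files"]:
        if not (d / name).exists():
            raise FileNotFoundError(f"scene file listed in manifest is missing: {name}")

    def c2_of(name):
        arr, _, t = _read_tiff(d / f"{name}.tif")
        return C2Raster(
            c11=arr[0].astype(float),
            c22=arr[1].astype(float),
            c12=arr[2].astype(float) + 1j * arr[3].astype(float),
            transform=t,
        )

    def stack_of(name):
        arr, bands, t = _read_tiff(d / f"{name}.tif")
        return RasterStack({b: arr[i].astype(float) for i, b in enumerate(bands)}, t)

    truth_arr, _, transform = _read_tiff(d / "truth.tif")
    plots = []
    for f in json.loads((d / "plots.geojson").read_text())["features"]:
        plots.append(
            Plot(label=f["properties"]["label"], class_code=f["properties"]["class_code"], polygon=shape(f["geometry"]))
        )
    config = SimulationConfig.from_dict(json.loads((d / "config.json").read_text()))
    legend_df = pd.read_csv(d / "legend.csv")
    return SceneBundle(
        sar_before=c2_of("sar_before"),
        sar_after=c2_of("sar_after"),
        optical_before=stack_of("optical_before"),
        optical_after=stack_of("optical_after"),
        truth=truth_arr[0].astype(np.uint8),
        plots=plots,
        train_pixels=pd.read_csv(d / "train_pixels.csv"),
        validation_pixels=pd.read_csv(d / "validation_pixels.csv"),
        mask_train_pixels=pd.read_csv(d / "mask_train_pixels.csv"),
        legend=dict(zip(legend_df.class_code, legend_df.class_name)),
        transform=transform,
        config=config,
    )
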