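"""End-to-end orchestration: simulate → features → plot stats → screening →
crop mask → Random-Forest classification (three cases) → accuracy report.

Two execution paths share the same stage computations:

* :func:`run_all` — in-memory fast path used by the library and tests;
* file-based stage functions (``stage_*``) used by the CLI, which communicate
  exclusively through documented file formats (TIFF/GeoJSON/CSV/JSON) so any
  stage can be inspected or replaced.  ``run_all_files`` chains them.

The accuracy assessment is always computed on the validation pixel set,
which is crop-only by construction; the MLC-derived rice mask shapes the map
product but does not enter the lodged/healthy contingency table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import reference as ref
from .classify import (
    CASES,
    ClassifierSpec,
    LabelRaster,
    crop_mask,
    fit_rf,
    rf_predict_pixels,
    case_features,
)
from .evaluation import AccuracyReport, evaluate_labels
from .geo import GridTransform, RasterStack
from .plotstats import BeforeAfterPlotTable, build_table
from .sar import feature_stack
from .scene import SceneBundle, SimulationConfig, generate_scene, read_scene, write_scene
from .screening import ScreeningReport, screen

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    scene: SimulationConfig = field(default_factory=SimulationConfig)
    cases: tuple[str, ...] = CASES
    n_trees: int = 100
    max_features_per_split: int = 2
    min_impurity: float = 0.2
    impurity_mode: str = "node_threshold"
    beta_threshold: int = 9
    speckle_filter: bool = True
    filter_window: int = 3
    compute_maps: bool = True
    seed: int = 0

    def classifier_spec(self, case: str) -> ClassifierSpec:
        return ClassifierSpec(
            case=case,
            n_trees=self.n_trees,
            max_features_per_split=self.max_features_per_split,
            min_impurity=self.min_impurity,
            impurity_mode=self.impurity_mode,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scene = SimulationConfig(**raw.pop("scene", {}))
        cfg = cls(scene=scene, **raw)
        if any(c not in CASES for c in cfg.cases):
            raise ValueError(f"cases must be among {CASES}")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cases"] = list(self.cases)
        return d


def sar_optical_stacks(bundle: SceneBundle, cfg: RunConfig) -> tuple[RasterStack, RasterStack]:
    """Combined 20-parameter (SAR features + optical bands) stacks per epoch."""
    kw = dict(
        enl=bundle.config.enl,
        window=cfg.filter_window,
        speckle_filter=cfg.speckle_filter and bundle.config.speckle,
    )
    before = feature_stack(bundle.sar_before, **kw).merge(bundle.optical_before)
    after = feature_stack(bundle.sar_after, **kw).merge(bundle.optical_after)
    return before, after


def parameter_domains() -> dict[str, str]:
    d = {p: "sar" for p in ref.SAR_PARAMS}
    d.update({b: "optical" for b in ref.OPTICAL_BANDS})
    return d


def resolve_case_features(report: ScreeningReport, case: str) -> list[str]:
    """Feature list per case with a graded fallback when selection is empty.

    If no parameter of a domain survives all three steps, fall back to the
    step-1 pass set of that domain, then to every parameter of the domain
    (logged); classification always has a non-empty feature set.
    """

    def domain_set(domain: str) -> list[str]:
        sel = report.selected_set(domain)
        if sel:
            return sel
        s1 = report.step1_set(domain)
        if s1:
            log.warning("%s: no parameter passed all steps; falling back to step-1 set %s", domain, s1)
            return s1
        allp = [r.parameter for r in report.results if r.domain == domain]
        log.warning("%s: no parameter passed step 1; falling back to all %s", domain, allp)
        return allp

    return case_features(case, domain_set("sar"), domain_set("optical"))


@dataclass
class CaseResult:
    case: str
    features: list[str]
    report: AccuracyReport
    label_map: LabelRaster | None


@dataclass
class PipelineResult:
    bundle: SceneBundle
    table: BeforeAfterPlotTable
    screening: ScreeningReport
    mask: np.ndarray
    cases: dict[str, CaseResult]
    config: RunConfig

    def summary(self) -> dict:
        return {
            "seed": self.config.seed,
            "osf": self.screening.osf,
            "osi": self.screening.osi,
            "cases": {
                c: {
                    "features": r.features,
                    "OA": r.report.oa,
                    "Kappa": r.report.kappa,
                    "rounded": r.report.rounded(),
                }
                for c, r in self.cases.items()
            },
        }


def run_all(config: RunConfig) -> PipelineResult:
    """Execute the full analysis in memory and return all stage outputs."""
    config.scene.seed = config.seed
    bundle = generate_scene(config.scene)
    before, after = sar_optical_stacks(bundle, config)
    table = build_table(before, after, bundle.plots, parameter_domains())
    report = screen(table, beta_threshold=config.beta_threshold)
    mask = crop_mask(bundle.optical_after, bundle.mask_train_pixels)

    val = bundle.validation_pixels
    cases: dict[str, CaseResult] = {}
    for case in config.cases:
        feats = resolve_case_features(report, case)
        spec = config.classifier_spec(case)
        model = fit_rf(spec, bundle.train_pixels, after, feats)
        pred = rf_predict_pixels(model, after, feats, val["row"], val["col"])
        acc = evaluate_labels(pred, val["class_code"].to_numpy(), labels=list(ref.CROP_CODES))
        label_map = None
        if config.compute_maps:
            h, w = after.shape
            grid = np.full((h, w), ref.NONCROP_LABEL, dtype=np.uint8)
            rows, cols = np.nonzero(mask)
            if rows.size:
                grid[rows, cols] = rf_predict_pixels(model, after, feats, rows, cols)
            legend = {c: ref.LEGEND[c] for c in ref.CROP_CODES}
            legend[ref.NONCROP_LABEL] = "non_crop"
            label_map = LabelRaster(grid, legend, after.transform, {"case": case, "features": feats, "seed": spec.seed})
        cases[case] = CaseResult(case=case, features=feats, report=acc, label_map=label_map)
    return PipelineResult(bundle=bundle, table=table, screening=report, mask=mask, cases=cases, config=config)


# ---------------------------------------------------------------------------
# File-based stages (CLI path)
# ---------------------------------------------------------------------------


def _write_stack(stack: RasterStack, path: Path) -> None:
    desc = json.dumps({"bands": stack.names, "transform": stack.transform.to_dict(), "meta": stack.meta})
    tifffile.imwrite(path, stack.to_array(np.float32), description=desc, photometric="minisblack")


def _read_stack(path: Path) -> RasterStack:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = json.loads(tf.pages[0].tags["ImageDescription"].value)
    if arr.ndim == 2:
        arr = arr[None]
    return RasterStack(
        {b: arr[i].astype(float) for i, b in enumerate(meta["bands"])},
        GridTransform.from_dict(meta["transform"]),
        meta.get("meta", {}),
    )


def stage_simulate(config: RunConfig, out: Path) -> Path:
    config.scene.seed = config.seed
    bundle = generate_scene(config.scene)
    write_scene(bundle, out)
    return out


def stage_features(scene_dir: Path, out: Path, config: RunConfig) -> Path:
    bundle = read_scene(scene_dir)
    before, after = sar_optical_stacks(bundle, config)
    out.mkdir(parents=True, exist_ok=True)
    _write_stack(before, out / "features_before.tif")
    _write_stack(after, out / "features_after.tif")
    return out


def stage_screen(scene_dir: Path, features_dir: Path, out: Path, config: RunConfig) -> Path:
    bundle = read_scene(scene_dir)
    before = _read_stack(features_dir / "features_before.tif")
    after = _read_stack(features_dir / "features_after.tif")
    table = build_table(before, after, bundle.plots, parameter_domains())
    report = screen(table, beta_threshold=config.beta_threshold)
    out.mkdir(parents=True, exist_ok=True)
    table.per_plot.to_csv(out / "plot_table.csv", index=False)
    table.aggregates().to_csv(out / "plot_aggregates.csv")
    report.frame.to_csv(out / "screening.csv")
    (out / "screening.json").write_text(json.dumps(report.to_dict(), indent=1))
    return out


def stage_classify(
    scene_dir: Path, features_dir: Path, screening_json: Path, case: str, out: Path, config: RunConfig
) -> Path:
    bundle = read_scene(scene_dir)
    after = _read_stack(features_dir / "features_after.tif")
    rep = json.loads(screening_json.read_text())
    osf, osi = rep["osf"], rep["osi"]
    feats = case_features(case, osf or rep["step1_sar"] or list(ref.SAR_PARAMS), osi or rep["step1_optical"] or list(ref.OPTICAL_BANDS))
    spec = config.classifier_spec(case)
    mask = crop_mask(bundle.optical_after, bundle.mask_train_pixels)
    model = fit_rf(spec, bundle.train_pixels, after, feats)

    out.mkdir(parents=True, exist_ok=True)
    h, w = after.shape
    grid = np.full((h, w), ref.NONCROP_LABEL, dtype=np.uint8)
    rows, cols = np.nonzero(mask)
    if rows.size:
        grid[rows, cols] = rf_predict_pixels(model, after, feats, rows, cols)
    desc = json.dumps(
        {
            "bands": ["label"],
            "transform": after.transform.to_dict(),
            "meta": {"case": case, "features": feats, "seed": spec.seed,
                     "legend": {str(c): ref.LEGEND[c] for c in ref.CROP_CODES} | {str(ref.NONCROP_LABEL): "non_crop"}},
        }
    )
    tifffile.imwrite(out / f"labels_{case}.tif", grid[None], description=desc, photometric="minisblack")

    val = bundle.validation_pixels
    pred = rf_predict_pixels(model, after, feats, val["row"], val["col"])
    pd.DataFrame(
        {"row": val["row"], "col": val["col"], "pred": pred, "truth": val["class_code"]}
    ).to_csv(out / f"val_predictions_{case}.csv", index=False)
    return out


def stage_evaluate(pred_csv: Path, out_file: Path) -> AccuracyReport:
    df = pd.read_csv(pred_csv)
    acc = evaluate_labels(df["pred"], df["truth"], labels=list(ref.CROP_CODES))
    payload = {
        "contingency_cc_by_gt": acc.contingency.to_numpy().tolist(),
        "labels": [ref.LEGEND[c] for c in ref.CROP_CODES],
        "PA": {ref.LEGEND[k]: v for k, v in acc.pa.items()},
        "UA": {ref.LEGEND[k]: v for k, v in acc.ua.items()},
        "OA": acc.oa,
        "Kappa": acc.kappa,
        "rounded": {
            "PA": {ref.LEGEND[k]: v for k, v in acc.rounded()["PA"].items()},
            "UA": {ref.LEGEND[k]: v for k, v in acc.rounded()["UA"].items()},
            "OA": acc.rounded()["OA"],
            "Kappa": acc.rounded()["Kappa"],
        },
    }
    out_file.parent.mkdir(parents=True, exist_ok=True)
    out_file.write_text(json.dumps(payload, indent=1))
    return acc


def run_all_files(config: RunConfig, out: Path) -> dict:
    """File-chained pipeline: identical to invoking the five stages in order."""
    out = Path(out)
    scene_dir = out / "scene"
    feat_dir = out / "features"
    screen_dir = out / "screening"
    cls_dir = out / "classification"
    stage_simulate(config, scene_dir)
    stage_features(scene_dir, feat_dir, config)
    stage_screen(scene_dir, feat_dir, screen_dir, config)
    summary = {"seed": config.seed, "cases": {}}
    rep = json.loads((screen_dir / "screening.json").read_text())
    summary["osf"], summary["osi"] = rep["osf"], rep["osi"]
    for case in config.cases:
        stage_classify(scene_dir, feat_dir, screen_dir / "screening.json", case, cls_dir, config)
        acc = stage_evaluate(cls_dir / f"val_predictions_{case}.csv", out / f"report_{case}.json")
        summary["cases"][case] = {"OA": acc.oa, "Kappa": acc.kappa, "rounded": acc.rounded()}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
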