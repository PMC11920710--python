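"""End-to-end orchestration: generate -> split -> train -> evaluate -> ablate.

A run lives in one output directory:

    out_dir/
      manifest.json        split assignment, morphologies, global TAWSS extremes
      models/<id>.ply      labeled point clouds
      checkpoints/         trained network archives (.npz)
      reports/             metric reports (JSON + CSV)
      run_log.jsonl        structured stage log

All stages are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryConfig
from .metrics import MetricReport, evaluate_split
from .morphology import (
    ParamRanges,
    SplitManifest,
    make_splits,
    sample_morphologies,
)
from .network import (
    TrainedModel,
    TrainingData,
    UNetConfig,
    build_unet,
    load_model,
    save_model,
    train,
)
from .ordering import Ordering, axis_order, pca_order
from .ply import read_cloud_ply
from .surrogate import SurrogateConfig, generate_dataset

__all__ = [
    "RunConfig",
    "run_generate",
    "load_split_arrays",
    "run_train",
    "run_evaluate",
    "run_ablate_ordering",
]

ORDERING_METHODS = ("pca", "x", "y", "z")


@dataclass
class RunConfig:
    """Single configuration object for a full experiment."""

    n_models: int = 1800
    split_batch_size: int = 300
    test_per_batch: int = 60
    val_frac: float = 0.10
    seed: int = 0
    sampling: str = "uniform"
    grid_rows: int = 64
    grid_cols: int = 64
    ordering: str = "pca"
    out_dir: str = "runs/default"
    ranges: ParamRanges = field(default_factory=ParamRanges)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    epochs: int = 200
    train_batch_size: int = 16

    def unet_config(self) -> UNetConfig:
        # pooling depth scales with the grid so the bottleneck stays at 4x4
        levels = max(1, int(np.log2(min(self.grid_rows, self.grid_cols) // 4)))
        return UNetConfig(
            points=self.grid_rows * self.grid_cols,
            grid_rows=self.grid_rows,
            grid_cols=self.grid_cols,
            levels=min(levels, 4),
            epochs=self.epochs,
            batch_size=self.train_batch_size,
            seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["surrogate"].pop("waveform", None)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        from .surrogate import ModulatorConfig, ViscosityParams

        if "ranges" in d:
            d["ranges"] = ParamRanges(**d["ranges"])
        if "geometry" in d:
            g = d["geometry"]
            if "row_quota" in g:
                g["row_quota"] = tuple(g["row_quota"])
            d["geometry"] = GeometryConfig(**g)
        if "surrogate" in d:
            s = d["surrogate"]
            if "viscosity" in s:
                s["viscosity"] = ViscosityParams(**s["viscosity"])
            if "modulators" in s:
                s["modulators"] = ModulatorConfig(**s["modulators"])
            d["surrogate"] = SurrogateConfig(**s)
        return cls(**d)


def _log(out_dir: str | Path, stage: str, t0: float, **fields) -> None:
    rec = {"stage": stage, "wall_time_s": round(time.time() - t0, 3), **fields}
    path = Path(out_dir) / "run_log.jsonl"
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "a") as fh:
        fh.write(json.dumps(rec) + "\n")


def run_generate(cfg: RunConfig, overwrite: bool = False) -> SplitManifest:
    """Sample morphologies, build splits, and label the whole dataset."""
    t0 = time.time()
    morphs = sample_morphologies(cfg.ranges, cfg.n_models, cfg.seed, method=cfg.sampling)
    manifest = make_splits(
        [m.model_id for m in morphs],
        batch_size=cfg.split_batch_size,
        test_per_batch=cfg.test_per_batch,
        val_frac=cfg.val_frac,
        seed=cfg.seed,
        morphologies=morphs,
    )
    manifest = generate_dataset(
        manifest,
        geometry_cfg=cfg.geometry,
        surrogate_cfg=cfg.surrogate,
        out_dir=cfg.out_dir,
        grid_rows=cfg.grid_rows,
        grid_cols=cfg.grid_cols,
        overwrite=overwrite,
    )
    _log(
        cfg.out_dir,
        "generate",
        t0,
        seed=cfg.seed,
        n_models=cfg.n_models,
        tawss_global_max=manifest.tawss_global_max,
        tawss_global_min=manifest.tawss_global_min,
    )
    return manifest


def frame_references(cloud) -> tuple[np.ndarray, np.ndarray]:
    """Inflow direction and front-face normal recovered from cloud structure.

    The inflow direction is the displacement between the centroids of the
    first two axial stations (both on the LM); the front normal is the
    cosine-weighted mean radial offset over each station ring, which for the
    structured sampling points along the bifurcation-plane normal used to
    define the circumferential angle.  Both rotate with the cloud, so the
    PCA frame they orient is pose-independent.
    """
    c0 = cloud.coords[cloud.station_index == 0].mean(axis=0)
    c1 = cloud.coords[cloud.station_index == 1].mean(axis=0)
    inflow = c1 - c0
    normal = np.zeros(3)
    for row in np.unique(cloud.station_index):
        m = cloud.station_index == row
        offsets = cloud.coords[m] - cloud.coords[m].mean(axis=0)
        normal += np.cos(cloud.circ_angle[m]) @ offsets
    return inflow / np.linalg.norm(inflow), normal / np.linalg.norm(normal)


def make_ordering(cloud, method: str) -> Ordering:
    """Canonical ordering of one surface cloud by the configured method."""
    method = method.lower()
    if method == "pca":
        axis, normal = frame_references(cloud)
        return pca_order(cloud.coords, reference_axis=axis, reference_normal=normal)
    if method in ("x", "y", "z"):
        return axis_order(cloud.coords, method)
    raise ValueError(f"unknown ordering method {method!r}; use one of {ORDERING_METHODS}")


def load_split_arrays(
    out_dir: str | Path, manifest: SplitManifest, split: str, ordering: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load one split as ordered network arrays (X: aligned coords, Y: TAWSS)."""
    ids = {"train": manifest.train_ids, "val": manifest.val_ids, "test": manifest.test_ids}[split]
    xs, ys = [], []
    for model_id in ids:
        cloud, tw = read_cloud_ply(Path(out_dir) / "models" / f"{model_id}.ply")
        if tw is None:
            raise ValueError(f"{model_id}: cloud has no TAWSS labels")
        o = make_ordering(cloud, ordering)
        xs.append(o.aligned(cloud.coords)[o.permutation])
        ys.append(tw[o.permutation])
    return np.asarray(xs), np.asarray(ys), list(ids)


def run_train(
    cfg: RunConfig,
    manifest: SplitManifest | None = None,
    unet_cfg: UNetConfig | None = None,
    checkpoint_name: str = "model.npz",
) -> TrainedModel:
    """Train the U-Net on the generated dataset with the configured ordering."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    if manifest is None:
        manifest = SplitManifest.load(out / "manifest.json")
    if manifest.tawss_global_max is None:
        raise ValueError("manifest lacks global TAWSS extremes; run generation first")
    train_x, train_y, _ = load_split_arrays(out, manifest, "train", cfg.ordering)
    val_x, val_y, _ = load_split_arrays(out, manifest, "val", cfg.ordering)
    data = TrainingData(
        train_x=train_x,
        train_y=train_y,
        val_x=val_x,
        val_y=val_y,
        tawss_global_max=manifest.tawss_global_max,
        tawss_global_min=manifest.tawss_global_min,
    )
    model = build_unet(unet_cfg if unet_cfg is not None else cfg.unet_config())
    train(model, data)
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    save_model(model, ckpt_dir / checkpoint_name)
    pd.DataFrame(
        {k: pd.Series(v) for k, v in model.history.items()}
    ).to_csv(ckpt_dir / (Path(checkpoint_name).stem + "_history.csv"), index=False)
    final_val = model.history["val_name"][-1] if model.history["val_name"] else None
    _log(
        cfg.out_dir,
        "train",
        t0,
        seed=cfg.seed,
        ordering=cfg.ordering,
        parameter_count=model.parameter_count,
        epochs_run=len(model.history["train_mse"]),
        final_val_name=final_val,
    )
    return model


def run_evaluate(
    cfg: RunConfig,
    model: TrainedModel | str | Path,
    split: str = "test",
    manifest: SplitManifest | None = None,
    report_name: str | None = None,
) -> MetricReport:
    """Compute per-model MRE/NAME over one split with a trained model."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    if manifest is None:
        manifest = SplitManifest.load(out / "manifest.json")
    if isinstance(model, (str, Path)):
        model = load_model(model)
    if model.tawss_global_max is None or not np.isclose(
        model.tawss_global_max, manifest.tawss_global_max
    ) or not np.isclose(model.tawss_global_min, manifest.tawss_global_min):
        raise ValueError(
            "checkpoint normalization constants do not match the dataset manifest"
        )
    x, y, ids = load_split_arrays(out, manifest, split, cfg.ordering)
    preds, truths = {}, {}
    bs = cfg.train_batch_size
    for s in range(0, len(x), bs):
        p = model.net.forward(x[s : s + bs], train=False)[..., 0]
        p = np.clip(model.denormalize(p), model.tawss_global_min, model.tawss_global_max)
        for j, model_id in enumerate(ids[s : s + bs]):
            preds[model_id] = p[j]
            truths[model_id] = y[s + j]
    report = evaluate_split(truths, preds, manifest.tawss_global_max, manifest.tawss_global_min)
    rep_dir = out / "reports"
    rep_dir.mkdir(parents=True, exist_ok=True)
    stem = report_name or f"metrics_{split}_{cfg.ordering}"
    report.save(rep_dir / f"{stem}.json", rep_dir / f"{stem}.csv")
    _log(
        cfg.out_dir,
        "evaluate",
        t0,
        split=split,
        ordering=cfg.ordering,
        n_models=len(ids),
        mre_mean=report.mre_mean,
        name_mean=report.name_mean,
    )
    return report


def run_ablate_ordering(
    cfg: RunConfig, manifest: SplitManifest | None = None
) -> pd.DataFrame:
    """Train one model per ordering (x, y, z, pca) under identical budgets.

    Returns a four-row table (ordering, MRE mean/std, NAME mean/std) over the
    test split; the dataset and all seeds are shared across arms.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    if manifest is None:
        manifest = SplitManifest.load(out / "manifest.json")
    rows = []
    failures = []
    for method in ORDERING_METHODS:
        arm = replace(cfg, ordering=method)
        try:
            model = run_train(arm, manifest=manifest, checkpoint_name=f"model_{method}.npz")
            report = run_evaluate(
                arm, model, split="test", manifest=manifest, report_name=f"ablate_{method}"
            )
            rows.append(
                {
                    "ordering": method,
                    "mre_mean": report.mre_mean,
                    "mre_std": report.mre_std,
                    "name_mean": report.name_mean,
                    "name_std": report.name_std,
                }
            )
        except Exception as exc:  # partial results are still reported
            failures.append((method, repr(exc)))
    table = pd.DataFrame(rows)
    rep_dir = out / "reports"
    rep_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(rep_dir / "ablation_ordering.csv", index=False)
    _log(cfg.out_dir, "ablate_ordering", t0, n_arms=len(rows), failures=failures)
    if failures:
        raise RuntimeError(f"ablation arms failed: {failures}; partial table saved")
    return table
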