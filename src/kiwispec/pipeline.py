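"""End-to-end workflow: simulate -> calibrate -> segment -> extract -> split
-> select -> train -> evaluate -> map.

Every stage is a pure function of its inputs and the run seed; a run writes
its artifacts (selection, model, evaluation report, map) plus a manifest with
the configuration hash, seed, package/library versions and artifact digests,
so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import SpectralDataset, fit_lssvm, fit_mlr, fit_plsr
from .envi import Hypercube, calibrate_reflectance, trim_range
from .evaluation import evaluate, split_dataset
from .mapping import pixelwise_predict, render_map
from .segmentation import build_mask, label_fruits, roi_mean_spectrum
from .selection import bw_select, gapls_select, spa_select
from .synthetic import SceneConfig, generate_attributes, generate_scene

__all__ = ["PipelineConfig", "run_pipeline", "assemble_dataset"]

TRIM_RANGES = {"visnir": (450.0, 1000.0), "nir": (951.0, 1670.0)}


@dataclass
class PipelineConfig:
    """One run of the full workflow on synthetic scenes."""

    out_dir: str = "kiwispec_run"
    attribute: str = "firmness"
    spectral_mode: str = "visnir"
    n_fruits: int = 133
    fruits_per_scene: int = 4
    trim: tuple[float, float] | None = None  # None -> standard range for the mode
    mask_band: float = 700.0
    mask_threshold: float | None = None
    min_area: int = 50
    selector: str = "spa"  # bw | spa | gapls | none
    n_ews: int = 7
    selector_params: dict = field(default_factory=dict)
    model: str = "mlr"  # mlr | plsr | lssvm
    model_params: dict = field(default_factory=dict)
    split_ratio: tuple[int, int] = (2, 1)
    stratify_by_variety: bool = False
    noise_sd: float = 0.001
    gradient: float = 0.0
    seed: int = 20170810
    render: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if d.get("trim") is not None:
            d["trim"] = tuple(d["trim"])
        d["split_ratio"] = tuple(d.get("split_ratio", (2, 1)))
        return cls(**d)


def assemble_dataset(cfg: PipelineConfig):
    """Simulate scenes until ``n_fruits`` fruits are imaged, calibrate and
    trim each cube, segment, and extract one whole-fruit mean spectrum per
    fruit aligned with the reference table.

    Returns ``(dataset, table, first_scene)`` where ``first_scene`` keeps the
    first trimmed reflectance cube, its mask and truth for mapping.
    """
    table = generate_attributes(cfg.n_fruits, seed=cfg.seed)
    trim = cfg.trim or TRIM_RANGES[cfg.spectral_mode]
    n_scenes = int(np.ceil(cfg.n_fruits / cfg.fruits_per_scene))
    rows: list[np.ndarray] = [None] * cfg.n_fruits  # type: ignore[list-item]
    first_scene = None
    wavelengths = None
    for s in range(n_scenes):
        lo = s * cfg.fruits_per_scene
        sub = table.iloc[lo : lo + cfg.fruits_per_scene]
        scene_cfg = SceneConfig(
            spectral_mode=cfg.spectral_mode,
            n_fruits=len(sub),
            noise_sd=cfg.noise_sd,
            gradient=cfg.gradient,
            gradient_attribute=cfg.attribute if cfg.attribute != "ph" else "firmness",
            seed=cfg.seed + 1000 + s,
        )
        raw, dark, white, truth = generate_scene(scene_cfg, sub.reset_index(drop=True))
        cube = trim_range(calibrate_reflectance(raw, dark, white), *trim)
        mask = build_mask(cube, band=cfg.mask_band, threshold=cfg.mask_threshold)
        regions = label_fruits(mask, min_area=cfg.min_area)
        wavelengths = cube.wavelengths
        # match each segmented region to the generator's fruit id by majority
        # overlap with the ground-truth labels
        for reg in regions:
            labs, counts = np.unique(truth.labels[reg.mask], return_counts=True)
            keep = labs > 0
            if not keep.any():
                continue
            fruit_k = int(labs[keep][np.argmax(counts[keep])])  # 1-based in scene
            rows[lo + fruit_k - 1] = roi_mean_spectrum(cube, reg)
        if first_scene is None:
            first_scene = {"cube": cube, "mask": mask, "truth": truth, "regions": regions}
    missing = [i for i, r in enumerate(rows) if r is None]
    if missing:
        raise RuntimeError(f"segmentation lost fruits at table rows {missing}")
    X = np.stack(rows)
    ds = SpectralDataset(X, table[cfg.attribute].to_numpy(), wavelengths, cfg.attribute)
    return ds, table, first_scene


_FITTERS = {"mlr": fit_mlr, "plsr": fit_plsr, "lssvm": fit_lssvm}


def _select(cfg: PipelineConfig, cal: SpectralDataset):
    params = dict(cfg.selector_params)
    if cfg.selector == "none":
        return None
    if cfg.selector == "bw":
        full_plsr = fit_plsr(cal, max_lvs=params.pop("max_lvs", 20))
        return bw_select(full_plsr, k=cfg.n_ews, **params)
    if cfg.selector == "spa":
        return spa_select(
            cal.X, cal.y, cal.wavelengths,
            max_vars=params.pop("max_vars", cfg.n_ews),
            seed=params.pop("seed", cfg.seed + 7),
            **params,
        )
    if cfg.selector == "gapls":
        params.setdefault("top_k", cfg.n_ews)
        return gapls_select(
            cal.X, cal.y, cal.wavelengths,
            seed=params.pop("seed", cfg.seed + 11),
            **params,
        )
    raise ValueError(f"unknown selector {cfg.selector!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow; returns a manifest dict (also written to
    ``out_dir/manifest.json``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/extract"
    try:
        ds, table, first_scene = assemble_dataset(cfg)

        stage = "split"
        strata = table["variety"].to_numpy() if cfg.stratify_by_variety else None
        split = split_dataset(ds.n_samples, ratio=cfg.split_ratio, seed=cfg.seed + 3, strata=strata)
        cal = ds.subset(rows=split.calibration)

        stage = "select"
        selection = _select(cfg, cal)
        if selection is not None:
            ds_sel = ds.subset(bands=selection.indices)
            selection.to_json(out / "selection.json")
            selection.to_csv(out / "selection.csv")
        else:
            ds_sel = ds

        stage = "train"
        fitter = _FITTERS[cfg.model]
        model = fitter(ds_sel.subset(rows=split.calibration), **cfg.model_params)
        model.to_json(out / "model.json")

        stage = "evaluate"
        report = evaluate(model, ds_sel, split, model_id=f"{cfg.selector}-{cfg.model}")
        report.to_json(out / "report.json")
        pd.DataFrame([report.to_dict()]).to_csv(out / "report.csv", index=False)

        stage = "map"
        map_meta = None
        if cfg.attribute != "ph" and first_scene is not None:
            y_cal = ds.y[split.calibration]
            pmap = pixelwise_predict(
                first_scene["cube"], first_scene["mask"], model,
                display_range=(float(y_cal.min()), float(y_cal.max())),
            )
            pmap.to_json(out / "map.json")
            if cfg.render:
                render_map(pmap, out / "map.png")
            map_meta = {
                "out_of_range_fraction": pmap.out_of_range_fraction,
                "display_range": list(pmap.display_range),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    cfg_dict = asdict(cfg)
    cfg_dict.pop("out_dir")  # hash identifies the analysis, not the destination
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=list)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {"kiwispec": __version__, "numpy": np.__version__},
        "n_samples": ds.n_samples,
        "n_bands_full": ds.n_bands,
        "n_bands_selected": (selection.n_selected if selection is not None else ds.n_bands),
        "selected_wavelengths_nm": (
            selection.wavelengths.tolist() if selection is not None else None
        ),
        "report": report.to_dict(),
        "map": map_meta,
        "artifacts": {},
    }
    for f in sorted(out.glob("*")):
        if f.name not in ("manifest.json", "map.png") and f.is_file():
            manifest["artifacts"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
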