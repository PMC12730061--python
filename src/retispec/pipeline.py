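"""End-to-end run orchestration: simulate -> calibrate -> reconstruct ->
extract-roi -> analyze -> train -> compare.

A :class:`RunConfig` fully determines a run; every artifact lands in the run
directory and is listed, with its SHA-256 hash, in ``manifest.json``, so any
output is traceable to config + seed.  Stage failures abort with the stage
name in the exception.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .analysis import per_band_test, plot_group_curves, summarize_groups
from .calibration import GammaDecode, PolynomialExpansion, evaluate, fit_calibration
from .classify import (TrainConfig, build_modality_arrays, compare_modalities,
                       make_splits, train_eval)
from .core import default_grid
from .reconstruction import band_montage, reconstruct_cube, select_range
from .roi import ROI_NAMES, RoiConfig, RoiSpectrumTable, locate_rois
from .synthetic import (CameraModel, cohort_phantoms, default_camera, default_effect,
                        make_cohort, make_colorchecker, photograph_patches)

logger = logging.getLogger("retispec")

__all__ = ["RunConfig", "StageError", "run_pipeline", "reconstructed_roi_spectra"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    # cohort: group -> (n_subjects, n_images); None = published composition
    groups: dict | None = None
    image_size: int = 64
    max_images_per_subject: int | None = 2
    # calibration
    k: int = 12
    expansion_order: int = 3
    gamma: float = 2.2
    noise_sd: float = 0.01
    patches_csv: str | None = None  # external target; default: simulate one
    # effect / analysis
    effect_amplitude: float = 0.10
    compare: tuple[str, str] = ("Dementia", "Normal")
    stratify: str | None = None
    # classifier
    n_folds: int = 2
    classifier: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["compare"] = list(self.compare)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "compare" in d:
            d["compare"] = tuple(d["compare"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def reconstructed_roi_spectra(cohort, cam: CameraModel, model, effect=None,
                              seed: int = 0, size: int = 512,
                              roi_config: RoiConfig | None = None,
                              max_images_per_subject: int | None = None,
                              ) -> RoiSpectrumTable:
    """ROI mean spectra of every cohort image, via spectral reconstruction.

    Each phantom is rendered, the five ROI windows of its RGB image are
    reconstructed with the calibration model, and the per-window mean
    spectrum is recorded with the image's metadata.  Only the ROI windows are
    reconstructed, never the full cube.
    """
    roi_config = roi_config or RoiConfig().scaled(size)
    rows, spectra = [], []
    for row, phantom in cohort_phantoms(cohort, cam=cam, effect=effect, seed=seed,
                                        size=size,
                                        max_images_per_subject=max_images_per_subject):
        layout = locate_rois((size, size), phantom.fovea_center, roi_config)
        for name in ROI_NAMES:
            ys, xs = layout.slices(name)
            window = phantom.rgb_image[ys, xs]
            cube = reconstruct_cube(window, model)
            rows.append(dict(subject_id=row["subject_id"], eye=row["eye"],
                             group=row["group"], sex=row["sex"], age=row["age"],
                             image_id=row["image_id"], roi=name))
            spectra.append(cube.data.mean(axis=(0, 1)))
    return RoiSpectrumTable(pd.DataFrame(rows), np.vstack(spectra), model.grid)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all seven stages; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = default_grid()
    cam = default_camera(grid, noise_sd=config.noise_sd, seed=config.seed)
    effect = default_effect(grid, amplitude=config.effect_amplitude)
    manifest: dict = {"config": config.to_dict(), "stages": [], "seed": config.seed}
    artifacts: list[Path] = []

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                manifest["stages"].append(
                    {"name": name, "seconds": round(time.time() - self_inner.t0, 3)})
                return False
        return _Ctx()

    with stage("simulate"):
        cohort = make_cohort(config.groups, seed=config.seed)
        rio.cohort_to_csv(cohort, outdir / "subjects.csv", outdir / "images.csv")
        if config.patches_csv is None:
            patches = photograph_patches(make_colorchecker(grid, seed=config.seed), cam)
            rio.patches_to_csv(patches, outdir / "patches.csv")
            patches_path = outdir / "patches.csv"
        else:
            patches_path = Path(config.patches_csv)
        artifacts += [outdir / "subjects.csv", outdir / "images.csv"]

    with stage("calibrate"):
        if not patches_path.exists():
            raise FileNotFoundError(f"calibration patch file not found: {patches_path}")
        patches = rio.patches_from_csv(patches_path)
        model = fit_calibration(patches, k=config.k,
                                expansion=PolynomialExpansion(order=config.expansion_order),
                                decode=GammaDecode(gamma=config.gamma))
        rio.model_to_json(model, outdir / "model.json")
        report = evaluate(model, patches)
        pd.DataFrame({"patch_id": patches.patch_ids,
                      "delta_e00": report.per_patch_de,
                      "spectral_rmse": report.per_patch_rmse}).to_csv(
            outdir / "calibration_report.csv", index=False)
        artifacts += [outdir / "model.json", outdir / "calibration_report.csv"]

    with stage("reconstruct"):
        row, phantom = next(cohort_phantoms(cohort, cam=cam, effect=effect,
                                            seed=config.seed, size=config.image_size))
        cube = reconstruct_cube(phantom.rgb_image, model,
                                provenance={"image_id": row["image_id"]})
        rio.write_envi(cube, outdir / "example_cube")
        rio.write_png(phantom.rgb_image, outdir / "example_rgb.png")
        sub = select_range(cube, 550.0, 780.0)
        for view in band_montage(cube):
            denom = max(view.vmax - view.vmin, 1e-9)
            rio.write_png((view.image - view.vmin) / denom,
                          outdir / f"band_{view.wavelength:.0f}nm.png")
        artifacts += [outdir / "example_cube.hdr", outdir / "example_rgb.png"]

    with stage("extract-roi"):
        roi_config = RoiConfig().scaled(config.image_size)
        table = reconstructed_roi_spectra(
            cohort, cam, model, effect=effect, seed=config.seed,
            size=config.image_size, roi_config=roi_config,
            max_images_per_subject=config.max_images_per_subject)
        rio.spectra_to_csv(table, outdir / "roi_spectra.csv")
        layout = locate_rois((config.image_size,) * 2,
                             (config.image_size // 2,) * 2, roi_config)
        rio.layout_to_json(layout, outdir / "roi_layout.json")
        artifacts += [outdir / "roi_spectra.csv", outdir / "roi_layout.json"]

    with stage("analyze"):
        summaries = summarize_groups(table, stratifier=config.stratify)
        rows = []
        for s in summaries:
            rows.append({"roi": s.roi, "group": s.group, "stratum": s.stratum,
                         "n_subjects": s.n_subjects,
                         **{f"mean_{w:.0f}": m for w, m in
                            zip(table.grid.wavelengths[::50], s.mean[::50])}})
        pd.DataFrame(rows).to_csv(outdir / "group_summaries.csv", index=False)
        tests = {}
        ga, gb = config.compare
        present = set(table.meta["group"])
        if {ga, gb} <= present:
            for name in ROI_NAMES:
                tests[name] = per_band_test(table, ga, gb, name)
            pd.concat([
                pd.DataFrame({"roi": name, "wavelength_nm": table.grid.wavelengths,
                              "t": r.t, "p": r.p, "q": r.q,
                              "significant": r.significant})
                for name, r in tests.items()
            ]).to_csv(outdir / "band_tests.csv", index=False)
        plot_group_curves(summaries, outdir / "group_curves.png", tests=tests or None,
                          wavelengths=table.grid.wavelengths)
        artifacts += [outdir / "group_summaries.csv", outdir / "group_curves.png"]

    with stage("train"):
        data = build_modality_arrays(
            cohort, cam=cam, model=model, effect=effect, seed=config.seed,
            size=config.image_size,
            max_images_per_subject=config.max_images_per_subject)
        plans = make_splits(cohort, n_folds=config.n_folds, seed=config.seed)
        rio.splits_to_json(plans, outdir / "splits.json")
        tcfg = TrainConfig(seed=config.seed, **config.classifier)
        fold_metrics = {"HSI": [], "ORI": []}
        rows = []
        for modality in ("HSI", "ORI"):
            for plan in plans:
                res = train_eval(data[modality], data["labels"], data["subject_ids"],
                                 plan, tcfg)
                fold_metrics[modality].append(res.metrics)
                rows.append({"modality": modality, "fold": plan.fold,
                             "accuracy": res.metrics.accuracy,
                             **{f"macro_{k}": v for k, v in res.metrics.macro.items()}})
        pd.DataFrame(rows).to_csv(outdir / "fold_metrics.csv", index=False)
        artifacts += [outdir / "splits.json", outdir / "fold_metrics.csv"]

    with stage("compare"):
        if config.n_folds >= 2:
            report = compare_modalities(fold_metrics["HSI"], fold_metrics["ORI"])
            report.to_csv(outdir / "modality_comparison.csv", index=False)
            artifacts.append(outdir / "modality_comparison.csv")

    manifest["artifacts"] = {str(p.relative_to(outdir)): _sha256(p)
                             for p in artifacts if p.exists()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
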