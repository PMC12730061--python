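"""File formats: ENVI cubes, PNG images, CSV tables, JSON models/plans.

Cubes are stored as ENVI band-sequential float32 with the wavelength list in
the text header, so they open in standard hyperspectral tooling.  Calibration
models serialize to a single JSON file carrying the grid, the documented
polynomial term order, both fitted matrices (row-major) and the
illuminant/observer identifiers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .calibration import (CalibrationModel, CorrectionMatrix, GammaDecode,
                          PolynomialExpansion, SpectralBasis)
from .classify import SplitPlan
from .core import Colorimetry, WavelengthGrid
from .reconstruction import HyperspectralCube
from .roi import RoiLayout, RoiSpectrumTable
from .synthetic import ColorPatchSet

logger = logging.getLogger("retispec")

__all__ = [
    "write_envi", "read_envi", "write_png", "read_png",
    "patches_to_csv", "patches_from_csv", "cohort_to_csv",
    "spectra_to_csv", "spectra_from_csv",
    "model_to_json", "model_from_json",
    "layout_to_json", "splits_to_json", "splits_from_json",
    "load_yaml", "dump_yaml",
]


# --- ENVI cubes -------------------------------------------------------------

def write_envi(cube: HyperspectralCube, path_base: str | Path) -> Path:
    """Write ``<base>.hdr`` + ``<base>.img`` (BSQ float32, little-endian)."""
    base = Path(path_base)
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.1f}" for x in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        "description = {reconstructed reflectance cube}\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    base.with_suffix(".hdr").write_text(header)
    bsq = np.ascontiguousarray(np.moveaxis(cube.data.astype("<f4"), 2, 0))
    bsq.tofile(base.with_suffix(".img"))
    return base.with_suffix(".hdr")


def read_envi(hdr_path: str | Path) -> HyperspectralCube:
    hdr_path = Path(hdr_path)
    text = hdr_path.read_text()
    fields = {}
    buf = text.replace("\n", " ")
    for key in ("samples", "lines", "bands", "data type", "interleave", "byte order"):
        for line in text.splitlines():
            if line.lower().startswith(key):
                fields[key] = line.split("=", 1)[1].strip()
    if fields.get("interleave", "bsq").lower() != "bsq" or fields.get("data type") != "4":
        raise ValueError("only BSQ float32 ENVI files are supported")
    w, h, b = int(fields["samples"]), int(fields["lines"]), int(fields["bands"])
    i0 = buf.index("wavelength =")
    wl_str = buf[i0:].split("{", 1)[1].split("}", 1)[0]
    wl = np.array([float(x) for x in wl_str.split(",")])
    step = wl[1] - wl[0] if len(wl) > 1 else 1.0
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
    data = np.fromfile(hdr_path.with_suffix(".img"), dtype="<f4").reshape(b, h, w)
    return HyperspectralCube(data=np.moveaxis(data, 0, 2), grid=grid,
                             provenance={"source": str(hdr_path)})


# --- images -----------------------------------------------------------------

def write_png(image: np.ndarray, path: str | Path) -> None:
    """Write a float [0,1] image (grayscale or RGB) as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255).round().astype(np.uint8))


def read_png(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(float) / 255.0


# --- CSV tables -------------------------------------------------------------

def patches_to_csv(patches: ColorPatchSet, path: str | Path) -> None:
    """One row per patch: id, camera rgb, reference XYZ, reflectance bands."""
    cols = {"patch_id": patches.patch_ids}
    rgb = patches.rgb if patches.rgb is not None else np.full((patches.n_patches, 3), np.nan)
    for i, c in enumerate("rgb"):
        cols[c] = rgb[:, i]
    for i, c in enumerate(("X", "Y", "Z")):
        cols[c] = patches.reference_xyz[:, i]
    frame = pd.DataFrame(cols)
    wl = patches.grid.wavelengths
    refl = pd.DataFrame(patches.reflectance,
                        columns=[f"refl_{w:.0f}" for w in wl])
    pd.concat([frame, refl], axis=1).to_csv(path, index=False)


def patches_from_csv(path: str | Path, colorimetry: Colorimetry | None = None) -> ColorPatchSet:
    frame = pd.read_csv(path)
    refl_cols = [c for c in frame.columns if c.startswith("refl_")]
    wl = np.array([float(c.split("_")[1]) for c in refl_cols])
    grid = WavelengthGrid(wl[0], wl[-1], wl[1] - wl[0] if len(wl) > 1 else 1.0)
    rgb = frame[["r", "g", "b"]].to_numpy()
    if np.isnan(rgb).all():
        rgb = None
    return ColorPatchSet(reflectance=frame[refl_cols].to_numpy(),
                         reference_xyz=frame[["X", "Y", "Z"]].to_numpy(),
                         grid=grid, colorimetry=colorimetry or Colorimetry(grid=grid),
                         rgb=rgb, patch_ids=frame["patch_id"].to_numpy())


def cohort_to_csv(cohort, subjects_path: str | Path, images_path: str | Path) -> None:
    cohort.subjects.to_csv(subjects_path, index=False)
    cohort.images.to_csv(images_path, index=False)


def spectra_to_csv(table: RoiSpectrumTable, path: str | Path) -> None:
    """Long format: subject_id, eye, group, roi, wavelength_nm, reflectance."""
    table.to_long().to_csv(path, index=False)


def spectra_from_csv(path: str | Path) -> RoiSpectrumTable:
    return RoiSpectrumTable.from_long(pd.read_csv(path))


# --- JSON models ------------------------------------------------------------

def model_to_json(model: CalibrationModel, path: str | Path) -> None:
    doc = {
        "grid": model.grid.to_dict(),
        "expansion": {"order": model.expansion.order,
                      "include_constant": model.expansion.include_constant,
                      "terms": [list(t) for t in model.expansion.term_list]},
        "decode": {"kind": model.decode.kind, "gamma": model.decode.gamma},
        "correction": {"M": model.correction.M.tolist(),
                       "max_residual": model.correction.max_residual,
                       "rank": model.correction.rank},
        "basis": {"mean_spectrum": model.basis.mean_spectrum.tolist(),
                  "eigenvectors": model.basis.eigenvectors.tolist(),
                  "explained_variance_ratio": model.basis.explained_variance_ratio.tolist(),
                  "score_map": model.basis.score_map.tolist()},
        "illuminant": model.colorimetry.illuminant,
        "observer": model.colorimetry.observer,
    }
    Path(path).write_text(json.dumps(doc))


def model_from_json(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    grid = WavelengthGrid.from_dict(doc["grid"])
    expansion = PolynomialExpansion(order=doc["expansion"]["order"],
                                    include_constant=doc["expansion"]["include_constant"])
    stored = [tuple(t) for t in doc["expansion"]["terms"]]
    if list(expansion.term_list) != stored:
        raise ValueError("model file term order does not match this version")
    return CalibrationModel(
        expansion=expansion,
        decode=GammaDecode(kind=doc["decode"]["kind"], gamma=doc["decode"]["gamma"]),
        correction=CorrectionMatrix(M=np.array(doc["correction"]["M"]),
                                    max_residual=doc["correction"]["max_residual"],
                                    rank=doc["correction"]["rank"]),
        basis=SpectralBasis(
            mean_spectrum=np.array(doc["basis"]["mean_spectrum"]),
            eigenvectors=np.array(doc["basis"]["eigenvectors"]),
            explained_variance_ratio=np.array(doc["basis"]["explained_variance_ratio"]),
            score_map=np.array(doc["basis"]["score_map"])),
        grid=grid,
        colorimetry=Colorimetry(illuminant=doc["illuminant"], grid=grid),
    )


def layout_to_json(layout: RoiLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "side": layout.side, "fovea_center": list(layout.fovea_center),
        "windows": {k: list(v) for k, v in layout.windows.items()},
    }))


def splits_to_json(plans: list[SplitPlan], path: str | Path) -> None:
    Path(path).write_text(json.dumps([
        {"fold": p.fold, "train": list(p.train), "val": list(p.val),
         "test": list(p.test), "fractions": list(p.fractions), "seed": p.seed}
        for p in plans
    ]))


def splits_from_json(path: str | Path) -> list[SplitPlan]:
    docs = json.loads(Path(path).read_text())
    return [SplitPlan(fold=d["fold"], train=tuple(d["train"]), val=tuple(d["val"]),
                      test=tuple(d["test"]), fractions=tuple(d["fractions"]),
                      seed=d["seed"]) for d in docs]


# --- YAML config ------------------------------------------------------------

def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(doc: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
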