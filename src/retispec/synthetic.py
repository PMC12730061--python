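"""Synthetic calibration target, camera, fundus phantoms, and cohort.

This module defines the study conditions the rest of the package is tested
under:

- a seeded 24-patch reflectance target ("color checker") with smooth spectra
  and reference XYZ computed under the configured illuminant/observer;
- a generic RGB camera model (three Gaussian sensitivity bands near
  460/540/610 nm, gamma 2.2 encoding, additive linear noise);
- fundus phantoms: 512 x 512 ground-truth reflectance fields composed of
  three tissue classes (background fundus, vessel arcades, fovea) built from
  smooth hemoglobin-like curves, plus a cognitive-group effect that elevates
  reflectance only above 550 nm with scales Normal:MCI:Dementia = 0:0.5:1;
- a cohort table reproducing the demographic composition of the study
  population (137 subjects, 3256 images split 1254/1320/682 across
  Normal/MCI/Dementia by default).

Every generator is seeded and bit-reproducible, and every phantom exposes its
ground-truth spectra so reconstruction error is computable pixel-wise.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import GammaDecode
from .core import Colorimetry, GridMismatchError, WavelengthGrid, default_grid
from .reconstruction import HyperspectralCube
from .roi import ROI_NAMES, RoiConfig, RoiSpectrumTable, locate_rois

logger = logging.getLogger("retispec")

GROUPS = ("Normal", "MCI", "Dementia")

__all__ = [
    "GROUPS",
    "CameraModel",
    "ColorPatchSet",
    "SpectralEffect",
    "FundusPhantom",
    "GroupSpec",
    "CohortTable",
    "TABLE1_COMPOSITION",
    "default_camera",
    "render_rgb",
    "make_colorchecker",
    "photograph_patches",
    "default_effect",
    "make_phantom",
    "make_cohort",
    "cohort_phantoms",
    "truth_roi_spectra",
]


def _seed_seq(base_seed: int, *parts) -> np.random.SeedSequence:
    """Deterministic child seed from a base seed and string/int parts."""
    ints = [int(base_seed) & 0x7FFFFFFF]
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode()))
        else:
            ints.append(int(p) & 0xFFFFFFFF)
    return np.random.SeedSequence(ints)


def _gauss(w: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((w - mu) / sd) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# camera


@dataclass
class CameraModel:
    """Generic RGB camera: spectral sensitivities + gamma encoding + noise.

    Channel responses are normalized so a unit-reflectance scene renders as
    (1, 1, 1); ``noise_sd`` is the SD of additive Gaussian noise on the
    linear signal before encoding.
    """

    sensitivities: np.ndarray  # (3, B), nonnegative
    gamma: float = 2.2
    noise_sd: float = 0.01
    grid: WavelengthGrid = field(default_factory=default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, dtype=float)
        if s.shape != (3, self.grid.n_bands):
            raise GridMismatchError("sensitivities must be (3, n_bands) on the grid")
        if (s < 0).any() or (s.sum(axis=1) <= 0).any():
            raise ValueError("sensitivities must be nonnegative with positive integral")
        self.sensitivities = s

    @property
    def decode(self) -> GammaDecode:
        return GammaDecode(kind="power", gamma=self.gamma)


def default_camera(grid: WavelengthGrid | None = None, noise_sd: float = 0.01,
                   seed: int = 0) -> CameraModel:
    """Three Gaussian sensitivity bands near 460/540/610 nm, gamma 2.2."""
    grid = grid or default_grid()
    w = grid.wavelengths
    sens = np.stack([
        _gauss(w, 610.0, 38.0),  # R
        _gauss(w, 545.0, 33.0),  # G
        _gauss(w, 460.0, 28.0),  # B
    ])
    return CameraModel(sensitivities=sens, gamma=2.2, noise_sd=noise_sd,
                       grid=grid, seed=seed)


def render_rgb(spectra: np.ndarray, cam: CameraModel,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Render reflectance spectra (..., B) to camera RGB (..., 3) in [0, 1].

    Linear channel = sum_lambda reflectance * sensitivity * dlambda,
    normalized so unit reflectance maps to (1,1,1); then noise is added on
    the linear signal, the gamma encoding applied, and the result clipped.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != cam.grid.n_bands:
        raise GridMismatchError("spectra are not on the camera's grid")
    weights = cam.sensitivities.sum(axis=1)  # per-channel normalizer
    linear = spectra @ (cam.sensitivities / weights[:, None]).T
    if cam.noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng(cam.seed)
        linear = linear + rng.normal(0.0, cam.noise_sd, size=linear.shape)
    return np.clip(cam.decode.encode(np.clip(linear, 0.0, None)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# calibration target


@dataclass
class ColorPatchSet:
    """24 reflectance patches with reference XYZ and (optionally) camera RGB."""

    reflectance: np.ndarray  # (N, B)
    reference_xyz: np.ndarray  # (N, 3)
    grid: WavelengthGrid
    colorimetry: Colorimetry
    rgb: np.ndarray | None = None  # (N, 3), filled by photograph_patches
    patch_ids: np.ndarray = None

    def __post_init__(self) -> None:
        if self.patch_ids is None:
            self.patch_ids = np.arange(1, self.reflectance.shape[0] + 1)

    @property
    def n_patches(self) -> int:
        return self.reflectance.shape[0]


def make_colorchecker(grid: WavelengthGrid | None = None, seed: int = 1,
                      colorimetry: Colorimetry | None = None) -> ColorPatchSet:
    """Seeded 24-patch target: 6 achromatic + 18 smooth chromatic spectra.

    Chromatic patches are logistic functions of sums of smooth Gaussian bumps
    and spectral edges (widths >= 20 nm), which keeps every spectrum in (0, 1)
    with bounded band-to-band change, mimicking the variety of a standard
    reflective color target (dark/light skin tones through saturated
    primaries and a neutral gray ramp).
    """
    grid = grid or default_grid()
    colorimetry = colorimetry or Colorimetry(grid=grid)
    w = grid.wavelengths
    rng = np.random.default_rng(_seed_seq(seed, "colorchecker"))
    spectra = []
    # neutral ramp: six gray levels with a slight seeded tilt
    for level in np.linspace(0.04, 0.92, 6):
        tilt = rng.uniform(-0.02, 0.02) * (w - 580.0) / 200.0
        spectra.append(np.clip(level + tilt, 0.01, 0.99))
    # chromatic patches
    for _ in range(18):
        base = rng.uniform(-1.6, 0.4)
        f = np.full_like(w, base)
        for _ in range(rng.integers(1, 4)):
            mu = rng.uniform(400.0, 760.0)
            sd = rng.uniform(25.0, 90.0)
            amp = rng.uniform(-2.2, 2.2)
            f = f + amp * _gauss(w, mu, sd)
        if rng.random() < 0.6:  # red/orange-style reflectance edge
            mu = rng.uniform(480.0, 660.0)
            width = rng.uniform(20.0, 60.0)
            f = f + rng.uniform(-2.0, 2.5) * _sigmoid((w - mu) / width)
        spectra.append(_sigmoid(f))
    refl = np.vstack(spectra)
    xyz = colorimetry.spectrum_to_xyz(refl)
    return ColorPatchSet(reflectance=refl, reference_xyz=xyz, grid=grid,
                         colorimetry=colorimetry)


def photograph_patches(patches: ColorPatchSet, cam: CameraModel,
                       seed: int | None = None) -> ColorPatchSet:
    """Render each patch spectrum through the camera, filling ``rgb``."""
    rng = np.random.default_rng(_seed_seq(cam.seed if seed is None else seed, "photo"))
    rgb = render_rgb(patches.reflectance, cam, rng=rng)
    return replace(patches, rgb=rgb)


# ---------------------------------------------------------------------------
# group effect and subject variability


@dataclass
class SpectralEffect:
    """Wavelength-localized group effect added to the ground-truth spectra.

    ``profile`` is zero below ``start_nm`` and rises to 1 at the plateau;
    a phantom of group g receives ``group_scales[g] * amplitude * profile``.
    """

    profile: np.ndarray  # (B,), in [0, 1]
    amplitude: float = 0.10
    group_scales: dict = field(default_factory=lambda: {"Normal": 0.0, "MCI": 0.5, "Dementia": 1.0})
    start_nm: float = 550.0

    def for_group(self, group: str) -> np.ndarray:
        if group not in self.group_scales:
            raise ValueError(f"unknown group {group!r}")
        return self.group_scales[group] * self.amplitude * self.profile


def default_effect(grid: WavelengthGrid | None = None, amplitude: float = 0.10,
                   start_nm: float = 550.0, center_nm: float = 620.0,
                   width_nm: float = 30.0, top_nm: float = 760.0) -> SpectralEffect:
    """Clamped logistic ramp: 0 at/below 550 nm, plateau by ~700-780 nm."""
    grid = grid or default_grid()
    w = grid.wavelengths
    L = _sigmoid((w - center_nm) / width_nm)
    L0 = _sigmoid((start_nm - center_nm) / width_nm)
    L1 = _sigmoid((top_nm - center_nm) / width_nm)
    prof = np.clip((L - L0) / (L1 - L0), 0.0, 1.0)
    prof[w <= start_nm] = 0.0
    return SpectralEffect(profile=prof, amplitude=amplitude, start_nm=start_nm)


_DEV_SDS = np.array([0.020, 0.050, 0.020, 0.020, 0.015])


def _deviation_bases(grid: WavelengthGrid) -> np.ndarray:
    """Smooth spectral modes of between-subject variability.

    Overall brightness, short-wavelength (pigmentation-like), mid- and
    long-wavelength bumps, and a tilt.  The pigmentation mode dominates
    (fundus color varies far more at short wavelengths between subjects than
    at long ones), so nuisance variability is strongest outside the
    disease-effect band.
    """
    w = grid.wavelengths
    return np.vstack([
        np.ones_like(w),
        _gauss(w, 450.0, 55.0),
        _gauss(w, 550.0, 45.0),
        _gauss(w, 660.0, 55.0),
        (w - 580.0) / 200.0,
    ])


def sample_deviation(rng: np.random.Generator, grid: WavelengthGrid,
                     scale: float = 1.0) -> np.ndarray:
    z = rng.standard_normal(len(_DEV_SDS)) * _DEV_SDS * scale
    return z @ _deviation_bases(grid)


def deviation_band_sd(grid: WavelengthGrid, scale: float = 1.0) -> np.ndarray:
    """Per-band SD of the subject-deviation model (closed form)."""
    phi = _deviation_bases(grid)
    return scale * np.sqrt(((_DEV_SDS[:, None] * phi) ** 2).sum(axis=0))


# ---------------------------------------------------------------------------
# tissue model and phantom geometry


def tissue_spectra(grid: WavelengthGrid) -> np.ndarray:
    """Baseline reflectance of (background, vessel, fovea), shape (3, B).

    Smooth sigmoid-plus-Gaussian curves with hemoglobin-like absorption dips
    near 542/577 nm and the steep red rise typical of fundus reflectance.
    """
    w = grid.wavelengths
    bg = (0.18 + 0.42 * _sigmoid((w - 585.0) / 25.0)
          - 0.05 * _gauss(w, 542.0, 12.0) - 0.05 * _gauss(w, 577.0, 10.0))
    vessel = (0.10 + 0.33 * _sigmoid((w - 600.0) / 20.0)
              - 0.06 * _gauss(w, 542.0, 14.0) - 0.06 * _gauss(w, 577.0, 12.0))
    fovea = 0.75 * bg - 0.05 * _gauss(w, 460.0, 40.0)
    return np.clip(np.vstack([bg, vessel, fovea]), 0.02, 0.95)


def _paint_curve(buf: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> None:
    h, w = buf.shape
    ri = np.clip(np.round(rows).astype(int), 0, h - 1)
    ci = np.clip(np.round(cols).astype(int), 0, w - 1)
    np.add.at(buf, (ri, ci), 1.0)


def _phantom_geometry(size: int, eye: str, rng: np.random.Generator):
    """Soft tissue-class weight maps and a smooth multiplicative texture.

    Returns (weights (3, H, W) float32 summing to 1 per pixel, fovea_center,
    texture (H, W)).  Vessels are superior/inferior arcade arcs (plus fainter
    secondary arcs) around the fovea; the fovea is a soft Gaussian disc.
    """
    f = size / 512.0
    cy = cx = size // 2
    yy, xx = np.mgrid[0:size, 0:size]
    fovea_w = np.exp(-0.5 * (((yy - cy) ** 2 + (xx - cx) ** 2) / (45.0 * f) ** 2))

    buf = np.zeros((size, size), dtype=float)
    t = np.linspace(0.10 * np.pi, 0.90 * np.pi, 4000)
    a_r = 150.0 * f * rng.uniform(0.92, 1.08)
    a_c = 210.0 * f * rng.uniform(0.92, 1.08)
    for sign, amp in ((-1, 1.0), (+1, 1.0), (-1, 0.55), (+1, 0.55)):
        rows = cy + sign * (a_r * amp) * np.sin(t)
        cols = cx + (a_c * amp) * np.cos(t)
        _paint_curve(buf, rows, cols)
    buf = ndimage.gaussian_filter(buf, 2.5 * max(f, 0.25))
    pos = buf[buf > 0]
    scale = np.percentile(pos, 99.0) if pos.size else 1.0
    vessel_w = np.clip(buf / max(scale, 1e-9), 0.0, 1.0) * 0.85
    if eye.upper() in ("OS", "L", "LEFT"):
        vessel_w = vessel_w[:, ::-1]

    noise = rng.standard_normal((size, size))
    sm = ndimage.gaussian_filter(noise, 25.0 * max(f, 0.2))
    sd = sm.std()
    texture = 1.0 + 0.02 * (sm / sd if sd > 0 else sm)

    bg_w = np.clip(1.0 - vessel_w - fovea_w, 0.0, None)
    weights = np.stack([bg_w, vessel_w, fovea_w]).astype(np.float32)
    weights /= weights.sum(axis=0, keepdims=True)
    return weights, (cy, cx), texture.astype(np.float32)


@dataclass
class FundusPhantom:
    """Synthetic fundus image with exact per-pixel ground-truth spectra.

    The truth field is low-rank: ``truth(x, l) = clip(texture(x) *
    sum_c weights_c(x) spectra_c(l) + additive(l), 0, 1)``, where
    ``additive`` bundles the group effect and subject/eye/image deviations.
    Windows or the full cube are materialized on demand.
    """

    group: str
    subject_id: str
    eye: str
    grid: WavelengthGrid
    fovea_center: tuple[int, int]
    weights: np.ndarray  # (3, H, W)
    class_spectra: np.ndarray  # (3, B)
    texture: np.ndarray  # (H, W)
    additive: np.ndarray  # (B,)
    rgb_image: np.ndarray | None = None  # (H, W, 3)

    @property
    def size(self) -> int:
        return self.weights.shape[1]

    def truth_window(self, top: int, left: int, side_y: int, side_x: int | None = None) -> np.ndarray:
        side_x = side_y if side_x is None else side_x
        w = self.weights[:, top:top + side_y, left:left + side_x]
        tex = self.texture[top:top + side_y, left:left + side_x]
        spectra32 = self.class_spectra.astype(np.float32, copy=False)
        field_ = np.tensordot(w, spectra32, axes=(0, 0))  # (sy, sx, B) float32
        field_ *= tex[:, :, None]
        field_ += self.additive.astype(np.float32, copy=False)
        np.clip(field_, 0.0, 1.0, out=field_)
        return field_

    def truth_cube(self) -> HyperspectralCube:
        h = self.size
        out = np.empty((h, h, self.grid.n_bands), dtype=np.float32)
        for r0 in range(0, h, 64):
            r1 = min(r0 + 64, h)
            out[r0:r1] = self.truth_window(r0, 0, r1 - r0, h).astype(np.float32)
        return HyperspectralCube(data=out, grid=self.grid,
                                 provenance={"source": f"{self.subject_id}/{self.eye}",
                                             "kind": "truth"})

    def truth_roi_means(self, config: RoiConfig | None = None) -> dict[str, np.ndarray]:
        config = (config or RoiConfig()).scaled(self.size) if config is None else config
        layout = locate_rois((self.size, self.size), self.fovea_center, config)
        out = {}
        for name in ROI_NAMES:
            ys, xs = layout.slices(name)
            out[name] = self.truth_window(ys.start, xs.start,
                                          ys.stop - ys.start, xs.stop - xs.start
                                          ).mean(axis=(0, 1))
        return out


def make_phantom(group: str, subject_id: str = "S000", eye: str = "OD",
                 cam: CameraModel | None = None, effect: SpectralEffect | None = None,
                 seed: int = 0, size: int = 512,
                 subject_dev: np.ndarray | None = None,
                 eye_dev: np.ndarray | None = None,
                 image_dev: np.ndarray | None = None,
                 eye_dev_scale: float = 0.3, image_dev_scale: float = 0.15) -> FundusPhantom:
    """Generate one seeded fundus phantom of the requested group.

    Deviations not supplied are drawn from the phantom's own seeded stream;
    cohort-level generation passes ``subject_dev``/``eye_dev`` explicitly so
    a subject's images share their subject-level spectrum shift.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    grid = cam.grid if cam is not None else default_grid()
    cam = cam or default_camera(grid)
    effect = effect or default_effect(grid)
    rng = np.random.default_rng(_seed_seq(seed, "phantom", subject_id, eye))
    weights, fovea_center, texture = _phantom_geometry(size, eye, rng)
    if subject_dev is None:
        subject_dev = sample_deviation(rng, grid)
    if eye_dev is None:
        eye_dev = sample_deviation(rng, grid, scale=eye_dev_scale)
    if image_dev is None:
        image_dev = sample_deviation(rng, grid, scale=image_dev_scale)
    additive = effect.for_group(group) + subject_dev + eye_dev + image_dev
    phantom = FundusPhantom(group=group, subject_id=subject_id, eye=eye, grid=grid,
                            fovea_center=fovea_center, weights=weights,
                            class_spectra=tissue_spectra(grid), texture=texture,
                            additive=additive)
    phantom.rgb_image = _render_phantom(phantom, cam, rng)
    return phantom


def _render_phantom(phantom: FundusPhantom, cam: CameraModel,
                    rng: np.random.Generator, chunk_rows: int = 64) -> np.ndarray:
    h = phantom.size
    out = np.empty((h, h, 3), dtype=float)
    for r0 in range(0, h, chunk_rows):
        r1 = min(r0 + chunk_rows, h)
        truth = phantom.truth_window(r0, 0, r1 - r0, h)
        out[r0:r1] = render_rgb(truth, cam, rng=rng)
    return out


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class GroupSpec:
    """Requested composition of one diagnostic group."""

    n_subjects: int
    n_images: int
    n_male: int | None = None
    age_range_male: tuple[int, int] = (60, 85)
    age_range_female: tuple[int, int] = (60, 85)
    mmse_range_male: tuple[int, int] = (20, 30)
    mmse_range_female: tuple[int, int] = (20, 30)


#: Published demographic composition: subjects, images, sex counts, and the
#: printed age / MMSE ranges per group.
TABLE1_COMPOSITION: dict[str, GroupSpec] = {
    "Normal": GroupSpec(49, 1254, n_male=21, age_range_male=(68, 85),
                        age_range_female=(60, 82), mmse_range_male=(28, 30),
                        mmse_range_female=(27, 30)),
    "MCI": GroupSpec(54, 1320, n_male=19, age_range_male=(61, 82),
                     age_range_female=(60, 85), mmse_range_male=(23, 27),
                     mmse_range_female=(23, 27)),
    "Dementia": GroupSpec(34, 682, n_male=12, age_range_male=(68, 87),
                          age_range_female=(60, 80), mmse_range_male=(12, 23),
                          mmse_range_female=(13, 22)),
}


@dataclass
class CohortTable:
    """Subject- and image-level cohort records.

    ``subjects``: subject_id, group, sex, age, mmse, n_images.
    ``images``: image_id, subject_id, group, sex, age, eye, image_index.
    Every subject belongs to exactly one group and has two eyes; images are
    spread as evenly as possible across subjects and eyes.
    """

    subjects: pd.DataFrame
    images: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_eyes(self) -> int:
        return 2 * len(self.subjects)

    @property
    def n_images(self) -> int:
        return len(self.images)

    def group_image_counts(self) -> dict[str, int]:
        return self.images.groupby("group").size().to_dict()

    def group_subject_counts(self) -> dict[str, int]:
        return self.subjects.groupby("group").size().to_dict()


def _coerce_spec(group: str, spec) -> GroupSpec:
    if isinstance(spec, GroupSpec):
        return spec
    n_subj, n_img = spec
    if group in TABLE1_COMPOSITION:
        ref = TABLE1_COMPOSITION[group]
        return replace(ref, n_subjects=n_subj, n_images=n_img,
                       n_male=min(ref.n_male, n_subj))
    return GroupSpec(n_subjects=n_subj, n_images=n_img)


def make_cohort(composition: dict | None = None, seed: int = 0) -> CohortTable:
    """Build a cohort with exact per-group subject and image counts.

    ``composition`` maps group name to a :class:`GroupSpec` or a
    ``(n_subjects, n_images)`` tuple; the default is the published Table-1
    composition (137 subjects, 3256 images).  Ages, sexes and MMSE scores are
    sampled uniformly within each group's printed ranges.
    """
    composition = composition or TABLE1_COMPOSITION
    rng = np.random.default_rng(_seed_seq(seed, "cohort"))
    subj_rows, img_rows = [], []
    prefix = {"Normal": "N", "MCI": "M", "Dementia": "D"}
    for group, raw_spec in composition.items():
        spec = _coerce_spec(group, raw_spec)
        if spec.n_subjects <= 0 or spec.n_images <= 0:
            raise ValueError(f"{group}: subject and image counts must be positive")
        if spec.n_images < spec.n_subjects:
            raise ValueError(
                f"{group}: {spec.n_images} images cannot cover {spec.n_subjects} subjects"
            )
        n_male = spec.n_male if spec.n_male is not None else round(0.4 * spec.n_subjects)
        sexes = ["M"] * n_male + ["F"] * (spec.n_subjects - n_male)
        base, extra = divmod(spec.n_images, spec.n_subjects)
        order = rng.permutation(spec.n_subjects)
        quotas = np.full(spec.n_subjects, base)
        quotas[order[:extra]] += 1
        for i in range(spec.n_subjects):
            sex = sexes[i]
            age_lo, age_hi = spec.age_range_male if sex == "M" else spec.age_range_female
            mmse_lo, mmse_hi = (spec.mmse_range_male if sex == "M"
                                else spec.mmse_range_female)
            sid = f"{prefix.get(group, group[:1].upper())}{i + 1:03d}"
            age = int(rng.integers(age_lo, age_hi + 1))
            mmse = int(rng.integers(mmse_lo, mmse_hi + 1))
            n_img = int(quotas[i])
            subj_rows.append(dict(subject_id=sid, group=group, sex=sex, age=age,
                                  mmse=mmse, n_images=n_img))
            per_eye = [n_img - n_img // 2, n_img // 2]  # OD gets the odd image
            idx = 0
            for eye, n_eye in zip(("OD", "OS"), per_eye):
                for j in range(n_eye):
                    img_rows.append(dict(image_id=f"{sid}-{eye}-{j:03d}",
                                         subject_id=sid, group=group, sex=sex,
                                         age=age, eye=eye, image_index=idx))
                    idx += 1
    cohort = CohortTable(subjects=pd.DataFrame(subj_rows), images=pd.DataFrame(img_rows))
    for group, raw_spec in composition.items():
        spec = _coerce_spec(group, raw_spec)
        assert cohort.group_image_counts()[group] == spec.n_images
    return cohort


def cohort_phantoms(cohort: CohortTable, cam: CameraModel | None = None,
                    effect: SpectralEffect | None = None, seed: int = 0,
                    size: int = 512, max_images_per_subject: int | None = None):
    """Yield ``(image_row, FundusPhantom)`` for every image of the cohort.

    Subject- and eye-level spectral deviations are drawn once per subject
    resp. eye (seeded by id), so repeat images of the same eye share them.
    """
    grid = cam.grid if cam is not None else default_grid()
    cam = cam or default_camera(grid)
    effect = effect or default_effect(grid)
    for sid, sub_imgs in cohort.images.groupby("subject_id", sort=True):
        subj_rng = np.random.default_rng(_seed_seq(seed, "subject", sid))
        subject_dev = sample_deviation(subj_rng, grid)
        eye_devs = {eye: sample_deviation(
            np.random.default_rng(_seed_seq(seed, "eye", sid, eye)), grid, scale=0.3)
            for eye in ("OD", "OS")}
        for _, row in sub_imgs.iterrows():
            if (max_images_per_subject is not None
                    and row["image_index"] >= max_images_per_subject):
                continue
            img_rng = np.random.default_rng(
                _seed_seq(seed, "image", str(row["image_id"])))
            image_dev = sample_deviation(img_rng, grid, scale=0.15)
            phantom = make_phantom(row["group"], subject_id=sid, eye=row["eye"],
                                   cam=cam, effect=effect,
                                   seed=int(img_rng.integers(2**31)), size=size,
                                   subject_dev=subject_dev,
                                   eye_dev=eye_devs[row["eye"]],
                                   image_dev=image_dev)
            yield row, phantom


def truth_roi_spectra(cohort: CohortTable, effect: SpectralEffect | None = None,
                      seed: int = 0, size: int = 512,
                      config: RoiConfig | None = None) -> RoiSpectrumTable:
    """Ground-truth subject-level ROI mean spectra, without image rendering.

    Uses one shared phantom geometry (no per-subject anatomy jitter) and the
    per-subject/eye/image deviation model for a single image per subject, so
    the result is the analytic ROI mean the full image pipeline would
    converge to.  Intended for large statistical simulations (e.g. null
    replicates) where rendering every image would be wasteful.
    """
    grid = default_grid()
    effect = effect or default_effect(grid)
    config = config or RoiConfig().scaled(size)
    geo_rng = np.random.default_rng(_seed_seq(0, "fastpath-geometry"))
    weights, fovea_center, texture = _phantom_geometry(size, "OD", geo_rng)
    layout = locate_rois((size, size), fovea_center, config)
    spectra_c = tissue_spectra(grid)  # (3, B)
    base_roi = {}
    for name in ROI_NAMES:
        ys, xs = layout.slices(name)
        wmean = (weights[:, ys, xs] * texture[None, ys, xs]).mean(axis=(1, 2))
        base_roi[name] = wmean @ spectra_c  # (B,)

    rows, spectra = [], []
    for _, subj in cohort.subjects.iterrows():
        sid = subj["subject_id"]
        subj_rng = np.random.default_rng(_seed_seq(seed, "subject", sid))
        dev = (sample_deviation(subj_rng, grid)
               + sample_deviation(subj_rng, grid, scale=0.3)
               + sample_deviation(subj_rng, grid, scale=0.15))
        add = effect.for_group(subj["group"]) + dev
        for name in ROI_NAMES:
            rows.append(dict(subject_id=sid, eye="OD", group=subj["group"],
                             sex=subj["sex"], age=subj["age"], roi=name))
            spectra.append(np.clip(base_roi[name] + add, 0.0, 1.0))
    return RoiSpectrumTable(pd.DataFrame(rows), np.vstack(spectra), grid)
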