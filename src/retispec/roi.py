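"""Standardized five-window ROI sampling of fundus images.

The five regions — S1 and S2 above the temporal vascular arcade, F on the
fovea, I1 and I2 below the arcade — are square windows (240 x 240 px on a
512 x 512 image) placed relative to the fovea center.  Window geometry is
configuration, not anatomy: the displacement vectors default to values that
put S/I windows over the arcades of the synthetic phantoms and are scaled
proportionally for other image sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import WavelengthGrid
from .reconstruction import HyperspectralCube

logger = logging.getLogger("retispec")

ROI_NAMES = ("S1", "S2", "F", "I1", "I2")

__all__ = [
    "ROI_NAMES",
    "RoiConfig",
    "RoiLayout",
    "RoiSpectrumTable",
    "locate_rois",
    "roi_mean_spectrum",
    "roi_spectra_from_cube",
    "detect_fovea",
]


@dataclass(frozen=True)
class RoiConfig:
    """Window side length and fovea-relative displacements (pixels).

    Defaults target a 512 x 512 image: side 240, S/I rows displaced by
    -/+136 and columns by -/+136 (S1/I1 temporal-left, S2/I2 temporal-right).
    """

    side: int = 240
    dy: int = 136
    dx: int = 136

    def scaled(self, height: int, reference: int = 512) -> "RoiConfig":
        """Proportionally rescaled config for a different image size."""
        f = height / reference
        return RoiConfig(side=max(2, int(round(self.side * f))),
                         dy=int(round(self.dy * f)), dx=int(round(self.dx * f)))


@dataclass(frozen=True)
class RoiLayout:
    """Top-left corners of the five named windows, one shared side length."""

    windows: dict  # name -> (top, left)
    side: int
    fovea_center: tuple[int, int]

    def pixel_count(self) -> int:
        return self.side * self.side

    def slices(self, name: str) -> tuple[slice, slice]:
        if name not in self.windows:
            raise KeyError(f"unknown ROI {name!r}")
        top, left = self.windows[name]
        return slice(top, top + self.side), slice(left, left + self.side)


def locate_rois(shape_hw: tuple[int, int], fovea_center: tuple[int, int],
                config: RoiConfig | None = None) -> RoiLayout:
    """Place the five windows relative to the fovea; never clamp.

    A window that would extend outside the image is an error naming the
    offending ROI.  Overlap between windows is permitted (240 px windows on a
    512 px image necessarily overlap); the overlap fraction is logged.
    """
    config = config or RoiConfig()
    h, w = shape_hw
    fy, fx = fovea_center
    half = config.side // 2
    centers = {
        "F": (fy, fx),
        "S1": (fy - config.dy, fx - config.dx),
        "S2": (fy - config.dy, fx + config.dx),
        "I1": (fy + config.dy, fx - config.dx),
        "I2": (fy + config.dy, fx + config.dx),
    }
    windows = {}
    for name, (cy, cx) in centers.items():
        top, left = cy - half, cx - half
        if top < 0 or left < 0 or top + config.side > h or left + config.side > w:
            raise ValueError(
                f"ROI {name} (top-left {top},{left}, side {config.side}) "
                f"does not fit a {h}x{w} image"
            )
        windows[name] = (top, left)
    layout = RoiLayout(windows=windows, side=config.side,
                       fovea_center=(int(fy), int(fx)))
    _log_overlap(layout, (h, w))
    return layout


def _log_overlap(layout: RoiLayout, shape_hw: tuple[int, int]) -> None:
    cover = np.zeros(shape_hw, dtype=np.int16)
    for name in layout.windows:
        ys, xs = layout.slices(name)
        cover[ys, xs] += 1
    overlapped = float((cover > 1).sum()) / max(1, (cover > 0).sum())
    logger.debug("ROI windows overlap on %.1f%% of covered pixels", 100 * overlapped)


def roi_mean_spectrum(cube: HyperspectralCube, layout: RoiLayout, roi_name: str) -> np.ndarray:
    """Unweighted per-band mean over one window's pixels."""
    ys, xs = layout.slices(roi_name)
    h, w, _ = cube.shape
    if ys.stop > h or xs.stop > w:
        raise ValueError(f"layout does not fit cube of shape {cube.shape}")
    return np.asarray(cube.data[ys, xs].mean(axis=(0, 1), dtype=np.float64))


def detect_fovea(rgb_image: np.ndarray, smooth_sigma: float = 12.0,
                 margin_frac: float = 0.25) -> tuple[int, int]:
    """Fallback fovea localization: darkest smoothed region near the center.

    The search is restricted to the central (1 - 2*margin_frac) portion of
    the image so vignetting at the rim cannot win.
    """
    inten = np.asarray(rgb_image, dtype=float)
    if inten.ndim == 3:
        inten = inten.mean(axis=2)
    sm = ndimage.gaussian_filter(inten, smooth_sigma)
    h, w = sm.shape
    my, mx = int(h * margin_frac), int(w * margin_frac)
    inner = sm[my:h - my, mx:w - mx]
    iy, ix = np.unravel_index(np.argmin(inner), inner.shape)
    return (iy + my, ix + mx)


@dataclass
class RoiSpectrumTable:
    """ROI mean spectra with per-row subject metadata.

    ``meta`` rows align with ``spectra`` rows; columns: subject_id, eye,
    group, roi (plus any of age, sex, image_id).
    """

    meta: pd.DataFrame
    spectra: np.ndarray  # (N, B)
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        if len(self.meta) != self.spectra.shape[0]:
            raise ValueError("meta and spectra row counts differ")
        if self.spectra.shape[1] != self.grid.n_bands:
            raise ValueError("spectra length does not match grid")
        self.meta = self.meta.reset_index(drop=True)

    def subset(self, mask) -> "RoiSpectrumTable":
        mask = np.asarray(mask)
        return RoiSpectrumTable(self.meta.loc[mask].reset_index(drop=True),
                                self.spectra[mask], self.grid)

    def concat(self, other: "RoiSpectrumTable") -> "RoiSpectrumTable":
        return RoiSpectrumTable(pd.concat([self.meta, other.meta], ignore_index=True),
                                np.vstack([self.spectra, other.spectra]), self.grid)

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: one row per (record, wavelength)."""
        wl = self.grid.wavelengths
        n, b = self.spectra.shape
        rep = self.meta.loc[self.meta.index.repeat(b)].reset_index(drop=True)
        rep["wavelength_nm"] = np.tile(wl, n)
        rep["reflectance"] = self.spectra.ravel()
        return rep

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "RoiSpectrumTable":
        wl = np.sort(frame["wavelength_nm"].unique())
        step = wl[1] - wl[0] if len(wl) > 1 else 1.0
        grid = WavelengthGrid(float(wl[0]), float(wl[-1]), float(step))
        id_cols = [c for c in frame.columns if c not in ("wavelength_nm", "reflectance")]
        meta_rows, spectra = [], []
        for keys, g in frame.groupby(id_cols, sort=False, dropna=False):
            g = g.sort_values("wavelength_nm")
            meta_rows.append(dict(zip(id_cols, keys if isinstance(keys, tuple) else (keys,))))
            spectra.append(g["reflectance"].to_numpy())
        return cls(pd.DataFrame(meta_rows), np.vstack(spectra), grid)


def roi_spectra_from_cube(cube: HyperspectralCube, layout: RoiLayout,
                          meta: dict) -> RoiSpectrumTable:
    """Mean spectra of all five windows of one cube, tagged with metadata."""
    rows, spectra = [], []
    for name in ROI_NAMES:
        rows.append({**meta, "roi": name})
        spectra.append(roi_mean_spectrum(cube, layout, name))
    return RoiSpectrumTable(pd.DataFrame(rows), np.vstack(spectra), cube.grid)
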