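"""Per-pixel spectral reconstruction and cube manipulation.

A calibrated model is applied pixel-wise to an RGB fundus image to obtain a
hyperspectral reflectance cube (H x W x 401 on the default grid).  Downstream
views: a wavelength sub-range (550-780 nm by default, 231 bands), grayscale
band montages, and the 3-channel reduction used as classifier input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationModel, reconstruct_spectrum
from .core import WavelengthGrid

logger = logging.getLogger("retispec")

__all__ = [
    "HyperspectralCube",
    "BandView",
    "reconstruct_cube",
    "select_range",
    "band_montage",
    "cube_to_three_channel",
]


@dataclass
class HyperspectralCube:
    """H x W x B reflectance array tied to its wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but grid has {self.grid.n_bands}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, wavelength_nm: float) -> np.ndarray:
        return self.data[:, :, self.grid.index_of(wavelength_nm)]


@dataclass
class BandView:
    wavelength: float
    image: np.ndarray
    vmin: float = 0.0
    vmax: float = 1.0


def reconstruct_cube(rgb_image: np.ndarray, model: CalibrationModel,
                     chunk_rows: int = 32, provenance: dict | None = None) -> HyperspectralCube:
    """Reconstruct a full reflectance cube from an H x W x 3 image in [0, 1].

    Processes the image in row chunks to bound peak memory; output is float32.
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    h, w, _ = img.shape
    out = np.empty((h, w, model.grid.n_bands), dtype=np.float32)
    for r0 in range(0, h, chunk_rows):
        r1 = min(r0 + chunk_rows, h)
        out[r0:r1] = reconstruct_spectrum(img[r0:r1], model).astype(np.float32)
    return HyperspectralCube(data=out, grid=model.grid, provenance=provenance or {})


def select_range(cube: HyperspectralCube, lo: float = 550.0, hi: float = 780.0) -> HyperspectralCube:
    """Sub-cube restricted to wavelengths in [lo, hi] inclusive."""
    if lo > hi:
        raise ValueError("need lo <= hi")
    i0 = cube.grid.index_of(lo)
    i1 = cube.grid.index_of(hi)
    grid = WavelengthGrid(lo, hi, cube.grid.step_nm)
    return HyperspectralCube(data=cube.data[:, :, i0:i1 + 1], grid=grid,
                             provenance={**cube.provenance, "range_nm": (lo, hi)})


def band_montage(cube: HyperspectralCube,
                 wavelengths: tuple[float, ...] = (550.0, 600.0, 650.0, 700.0, 780.0),
                 ) -> list[BandView]:
    """Grayscale views of the requested bands under a shared intensity scale.

    Off-grid wavelengths fall back to the nearest band with a warning.
    """
    views: list[BandView] = []
    idxs = []
    for wl in wavelengths:
        try:
            idx = cube.grid.index_of(wl)
        except ValueError:
            idx = cube.grid.nearest_index(wl)
            logger.warning("wavelength %.1f nm off grid; using nearest band %.1f nm",
                           wl, cube.grid.wavelengths[idx])
        idxs.append(idx)
    stack = cube.data[:, :, idxs]
    vmin, vmax = float(stack.min()), float(stack.max())
    for wl_idx, idx in enumerate(idxs):
        views.append(BandView(wavelength=float(cube.grid.wavelengths[idx]),
                              image=cube.data[:, :, idx], vmin=vmin, vmax=vmax))
    return views


def _rescale01(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros_like(img, dtype=float)
    return (img - lo) / (hi - lo)


def cube_to_three_channel(cube: HyperspectralCube, strategy: str = "thirds",
                          bands: tuple[float, float, float] | None = None) -> np.ndarray:
    """Reduce a cube to the H x W x 3 classifier input.

    Strategies:

    - ``"thirds"`` (default): average the bands in three equal wavelength
      thirds of the cube's range — parameter-free and preserves the
      long-wavelength signal when applied after :func:`select_range`.
    - ``"bands"``: three named wavelengths (``bands`` argument).
    - ``"pca"``: first three principal components over the spectral axis.

    Output normalization to [0, 1] is linear and *fixed* for the reflectance
    strategies (a clip of physical reflectance, so the absolute spectral
    level — the quantity that differs between groups — survives); only the
    PCA strategy, whose components have no physical scale, is min-max
    rescaled per cube.  The strategy id should be recorded by callers in run
    metadata.
    """
    data = np.asarray(cube.data, dtype=float)
    if data.shape[2] < 3:
        raise ValueError("cube needs at least 3 bands")
    if strategy == "thirds":
        edges = np.linspace(0, data.shape[2], 4).round().astype(int)
        chans = [data[:, :, edges[i]:edges[i + 1]].mean(axis=2) for i in range(3)]
        out = np.stack(chans, axis=-1)
    elif strategy == "bands":
        if bands is None or len(bands) != 3:
            raise ValueError("'bands' strategy needs three wavelengths")
        out = np.stack([cube.band(wl) for wl in bands], axis=-1)
    elif strategy == "pca":
        from sklearn.decomposition import PCA

        h, w, b = data.shape
        flat = data.reshape(-1, b)
        comps = PCA(n_components=3, random_state=0).fit_transform(flat)
        out = comps.reshape(h, w, 3)
        lo, hi = float(out.min()), float(out.max())
        if hi - lo < 1e-12:
            return np.zeros_like(out)
        return (out - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown 3-channel strategy {strategy!r}")
    return np.clip(out, 0.0, 1.0)
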