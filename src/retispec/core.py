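"""Shared spectral axis and colorimetry primitives.

Every spectrum in the package lives on a :class:`WavelengthGrid`, by default
the 380-780 nm visible range sampled at 1 nm (401 bands).  Colorimetry
(spectrum -> XYZ -> CIELAB -> CIEDE2000) uses an analytic multi-lobe Gaussian
fit of the CIE 1931 2-degree standard observer and either the equal-energy
illuminant E or a smooth Planckian (6504 K) stand-in for daylight D65; the
white point is always computed self-consistently from the same observer and
illuminant, so round trips inside the package are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("retispec")

DEFAULT_START_NM = 380.0
DEFAULT_END_NM = 780.0
DEFAULT_STEP_NM = 1.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis shared by all spectra.

    The default grid covers the visible band 380-780 nm at 1 nm steps,
    giving 401 bands.
    """

    start_nm: float = DEFAULT_START_NM
    end_nm: float = DEFAULT_END_NM
    step_nm: float = DEFAULT_STEP_NM

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.end_nm < self.start_nm:
            raise ValueError("wavelength grid must be strictly increasing")
        span = (self.end_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    @property
    def n_bands(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an on-grid wavelength; raises if off grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        idx = int(round(pos))
        if abs(pos - idx) > 1e-6 or not (0 <= idx < self.n_bands):
            raise ValueError(f"{wavelength_nm} nm is not on the grid")
        return idx

    def nearest_index(self, wavelength_nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))

    def to_dict(self) -> dict:
        return {"start_nm": self.start_nm, "end_nm": self.end_nm, "step_nm": self.step_nm}

    @classmethod
    def from_dict(cls, d: dict) -> "WavelengthGrid":
        return cls(d["start_nm"], d["end_nm"], d["step_nm"])


def default_grid() -> WavelengthGrid:
    return WavelengthGrid()


class GridMismatchError(ValueError):
    """Raised when spectra and a model/camera disagree on the wavelength axis."""


def _asym_gauss(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    # piecewise-sigma Gaussian lobe used by the analytic 1931-observer fit
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie1931_cmfs(grid: WavelengthGrid) -> np.ndarray:
    """Analytic fit of the CIE 1931 2-deg color matching functions.

    Returns an (n_bands, 3) array [x̄, ȳ, z̄] (Wyman-Sloan multi-lobe
    Gaussian approximation, accurate to ~1% of peak).
    """
    w = grid.wavelengths
    xbar = (
        1.056 * _asym_gauss(w, 599.8, 37.9, 31.0)
        + 0.362 * _asym_gauss(w, 442.0, 16.0, 26.7)
        - 0.065 * _asym_gauss(w, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * _asym_gauss(w, 568.8, 46.9, 40.5) + 0.286 * _asym_gauss(w, 530.9, 16.3, 31.1)
    zbar = 1.217 * _asym_gauss(w, 437.0, 11.8, 36.0) + 0.681 * _asym_gauss(w, 459.0, 26.0, 13.8)
    return np.stack([xbar, ybar, zbar], axis=1)


def illuminant_spd(name: str, grid: WavelengthGrid) -> np.ndarray:
    """Relative spectral power distribution of a supported illuminant.

    ``"E"`` is the equal-energy illuminant; ``"D65"`` is a smooth Planckian
    radiator at 6504 K normalized to unit mean, standing in for CIE daylight.
    """
    w = grid.wavelengths
    if name.upper() == "E":
        return np.ones_like(w)
    if name.upper() == "D65":
        lam = w * 1e-9
        c2 = 1.4388e-2  # m·K
        spd = lam**-5 / np.expm1(c2 / (lam * 6504.0))
        return spd / spd.mean()
    raise ValueError(f"unknown illuminant {name!r}")


@dataclass(frozen=True)
class Colorimetry:
    """Bundle of observer + illuminant used consistently through a model."""

    illuminant: str = "D65"
    observer: str = "CIE1931-2deg-analytic"
    grid: WavelengthGrid = field(default_factory=default_grid)

    def _tables(self) -> tuple[np.ndarray, np.ndarray]:
        return cie1931_cmfs(self.grid), illuminant_spd(self.illuminant, self.grid)

    def spectrum_to_xyz(self, reflectance: np.ndarray) -> np.ndarray:
        """Tristimulus values of reflectance spectra, Y(white)=1.

        Accepts (..., n_bands); returns (..., 3).
        """
        reflectance = np.asarray(reflectance, dtype=float)
        if reflectance.shape[-1] != self.grid.n_bands:
            raise GridMismatchError("spectrum length does not match grid")
        cmfs, spd = self._tables()
        weights = cmfs * spd[:, None]  # (B, 3)
        k = 1.0 / weights[:, 1].sum()
        return k * (reflectance @ weights)

    @property
    def white_point(self) -> np.ndarray:
        cmfs, spd = self._tables()
        weights = cmfs * spd[:, None]
        return weights.sum(axis=0) / weights[:, 1].sum()

    def xyz_to_lab(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        t = xyz / self.white_point
        delta = 6.0 / 29.0
        f = np.where(t > delta**3, np.cbrt(np.maximum(t, 0)), t / (3 * delta**2) + 4.0 / 29.0)
        L = 116.0 * f[..., 1] - 16.0
        a = 500.0 * (f[..., 0] - f[..., 1])
        b = 200.0 * (f[..., 1] - f[..., 2])
        return np.stack([L, a, b], axis=-1)

    def spectrum_to_lab(self, reflectance: np.ndarray) -> np.ndarray:
        return self.xyz_to_lab(self.spectrum_to_xyz(reflectance))


def ciede2000(lab_a: np.ndarray, lab_b: np.ndarray) -> np.ndarray:
    """CIEDE2000 color difference (kL = kC = kH = 1).

    Vectorized over leading dimensions; inputs are CIELAB triplets.
    """
    lab_a = np.asarray(lab_a, dtype=float)
    lab_b = np.asarray(lab_b, dtype=float)
    L1, a1, b1 = lab_a[..., 0], lab_a[..., 1], lab_a[..., 2]
    L2, a2, b2 = lab_b[..., 0], lab_b[..., 1], lab_b[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((C1p == 0), 0.0, h1p)
    h2p = np.where((C2p == 0), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    return np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
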