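"""Camera-to-spectrum calibration from a 24-patch color target.

The calibration chain has two fitted stages, both solved with the
Moore-Penrose pseudo-inverse (minimum-norm least squares):

1. *Color correction*: the (linearized) camera RGB triplet is expanded into
   third-order polynomial terms and mapped to reference tristimulus XYZ by a
   3 x T matrix, ``M = A pinv(V)``.
2. *Spectral estimation*: the 24 target reflectance spectra are decomposed by
   PCA into a mean spectrum plus k orthonormal basis functions; a k x T
   regression maps the polynomial expansion of the corrected XYZ to the k
   basis scores.  A reconstructed spectrum is ``mean + scores @ eigenvectors``.

Quality is reported as per-patch CIEDE2000 against the reference colors and
per-patch spectral RMSE.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Colorimetry, WavelengthGrid, ciede2000

logger = logging.getLogger("retispec")

__all__ = [
    "PolynomialExpansion",
    "GammaDecode",
    "CorrectionMatrix",
    "SpectralBasis",
    "CalibrationModel",
    "DeltaEReport",
    "expand",
    "fit_correction",
    "fit_basis",
    "fit_calibration",
    "reconstruct_spectrum",
    "evaluate",
    "ciede2000",
]


@dataclass(frozen=True)
class PolynomialExpansion:
    """Full polynomial expansion of a 3-vector up to ``order``.

    Terms are all monomials ``x^a y^b z^c`` with ``a+b+c <= order``
    (``a+b+c >= 1`` when the constant is excluded), ordered by ascending total
    degree and, within a degree, by descending ``(a, b, c)``.  For order 3
    with constant the expansion has 20 terms.
    """

    order: int = 3
    include_constant: bool = True

    @property
    def term_list(self) -> tuple[tuple[int, int, int], ...]:
        lo = 0 if self.include_constant else 1
        terms = []
        for d in range(lo, self.order + 1):
            degree_terms = [
                (a, b, d - a - b)
                for a, b in itertools.product(range(d, -1, -1), range(d, -1, -1))
                if a + b <= d
            ]
            degree_terms.sort(key=lambda t: (-t[0], -t[1]))
            terms.extend(degree_terms)
        return tuple(terms)

    @property
    def n_terms(self) -> int:
        return len(self.term_list)


def expand(triplets: np.ndarray, expansion: PolynomialExpansion) -> np.ndarray:
    """Evaluate the monomial terms for triplets of shape (..., 3)."""
    t = np.asarray(triplets, dtype=float)
    if t.shape[-1] != 3:
        raise ValueError("expected (..., 3) triplets")
    x, y, z = t[..., 0], t[..., 1], t[..., 2]
    cols = [x**a * y**b * z**c for a, b, c in expansion.term_list]
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class GammaDecode:
    """Inverse of the camera's encoding nonlinearity, applied before expansion."""

    kind: str = "power"  # "power" | "none" | "srgb"
    gamma: float = 2.2

    def decode(self, rgb: np.ndarray) -> np.ndarray:
        rgb = np.asarray(rgb, dtype=float)
        if self.kind == "none":
            return rgb
        if self.kind == "power":
            return np.clip(rgb, 0.0, None) ** self.gamma
        if self.kind == "srgb":
            rgb = np.clip(rgb, 0.0, None)
            return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
        raise ValueError(f"unknown decode kind {self.kind!r}")

    def encode(self, linear: np.ndarray) -> np.ndarray:
        linear = np.asarray(linear, dtype=float)
        if self.kind == "none":
            return linear
        if self.kind == "power":
            return np.clip(linear, 0.0, None) ** (1.0 / self.gamma)
        if self.kind == "srgb":
            linear = np.clip(linear, 0.0, None)
            return np.where(
                linear <= 0.0031308, 12.92 * linear, 1.055 * linear ** (1 / 2.4) - 0.055
            )
        raise ValueError(f"unknown decode kind {self.kind!r}")


@dataclass
class CorrectionMatrix:
    """3 x T map from expanded linear RGB to XYZ, with its training residual."""

    M: np.ndarray
    max_residual: float
    rank: int


@dataclass
class SpectralBasis:
    """PCA decomposition of the target spectra plus the score regression."""

    mean_spectrum: np.ndarray  # (B,)
    eigenvectors: np.ndarray  # (k, B), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,)
    score_map: np.ndarray  # (k, T)

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class CalibrationModel:
    """Everything needed to turn a camera RGB triplet into a spectrum."""

    expansion: PolynomialExpansion
    decode: GammaDecode
    correction: CorrectionMatrix
    basis: SpectralBasis
    grid: WavelengthGrid
    colorimetry: Colorimetry = field(default_factory=Colorimetry)

    def correct_rgb(self, rgb: np.ndarray) -> np.ndarray:
        """Corrected XYZ for RGB triplets of shape (..., 3)."""
        v = expand(self.decode.decode(rgb), self.expansion)
        return v @ self.correction.M.T


@dataclass
class DeltaEReport:
    per_patch_de: np.ndarray
    per_patch_rmse: np.ndarray

    @property
    def mean_de(self) -> float:
        return float(self.per_patch_de.mean())

    @property
    def max_de(self) -> float:
        return float(self.per_patch_de.max())

    @property
    def mean_rmse(self) -> float:
        return float(self.per_patch_rmse.mean())


def fit_correction(patches, expansion: PolynomialExpansion | None = None,
                   decode: GammaDecode | None = None,
                   pinv_rcond: float | None = None) -> CorrectionMatrix:
    """Fit the polynomial color-correction matrix by pseudo-inverse.

    ``patches`` must carry camera ``rgb`` and ``reference_xyz``.  With V the
    T x N matrix of expanded (linearized) RGB columns and A the 3 x N matrix
    of reference XYZ columns, the minimum-norm least-squares solution is
    ``M = A pinv(V)``.

    ``pinv_rcond`` truncates singular values below that fraction of the
    largest one.  The default (None) keeps machine precision, which
    reproduces exactly representable systems to numerical accuracy; see
    :func:`fit_calibration` for the practical truncated default.
    """
    expansion = expansion or PolynomialExpansion()
    decode = decode or GammaDecode()
    if patches.rgb is None:
        raise ValueError("patch set has no camera RGB; photograph it first")
    V = expand(decode.decode(patches.rgb), expansion).T  # (T, N)
    A = np.asarray(patches.reference_xyz, dtype=float).T  # (3, N)
    rank = int(np.linalg.matrix_rank(V))
    if rank < min(V.shape):
        logger.warning(
            "rank-deficient expansion matrix (rank %d < %d); "
            "returning minimum-norm solution", rank, min(V.shape),
        )
    M = A @ np.linalg.pinv(V, rcond=pinv_rcond if pinv_rcond is not None else 1e-15)
    resid = np.linalg.norm(M @ V - A, axis=0)
    return CorrectionMatrix(M=M, max_residual=float(resid.max()), rank=rank)


def fit_basis(patches, correction: CorrectionMatrix,
              expansion: PolynomialExpansion | None = None,
              decode: GammaDecode | None = None, k: int = 12,
              pinv_rcond: float | None = None) -> SpectralBasis:
    """PCA basis of the target spectra and the XYZ-to-score regression.

    The same polynomial expansion used for color correction is applied to the
    corrected XYZ before regressing onto the first k principal-component
    scores (again by pseudo-inverse).
    """
    expansion = expansion or PolynomialExpansion()
    decode = decode or GammaDecode()
    R = np.asarray(patches.reflectance, dtype=float)  # (N, B)
    n = R.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    mean = R.mean(axis=0)
    Rc = R - mean
    # PCA via SVD of the centered spectra
    _, s, Vt = np.linalg.svd(Rc, full_matrices=False)
    eig = Vt[:k]  # (k, B)
    var = s**2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    scores = Rc @ eig.T  # (N, k)

    xyz = expand(decode.decode(patches.rgb), expansion) @ correction.M.T  # (N, 3)
    Vx = expand(xyz, expansion).T  # (T, N)
    score_map = scores.T @ np.linalg.pinv(
        Vx, rcond=pinv_rcond if pinv_rcond is not None else 1e-15)  # (k, T)
    return SpectralBasis(mean_spectrum=mean, eigenvectors=eig,
                         explained_variance_ratio=evr, score_map=score_map)


def fit_calibration(patches, k: int = 12,
                    expansion: PolynomialExpansion | None = None,
                    decode: GammaDecode | None = None,
                    colorimetry: Colorimetry | None = None,
                    pinv_rcond: float | None = 3e-2) -> CalibrationModel:
    """Fit the full RGB-to-spectrum calibration from a photographed target.

    Unlike the low-level fitters, this end-to-end entry point truncates the
    pseudo-inverses at ``pinv_rcond = 3e-2`` by default: third-order
    expansions fitted on 24 patches are severely ill-conditioned, and the
    small singular directions encode wiggles that explode on colors outside
    the target's gamut (fundus tissue is far outside it).  At this
    truncation the reconstruction Jacobian recovers the physically expected
    structure (long-wavelength bands respond to the red channel, short to
    blue).  Pass ``None`` for the machine-precision solution.
    """
    expansion = expansion or PolynomialExpansion()
    decode = decode or GammaDecode()
    colorimetry = colorimetry or Colorimetry(grid=patches.grid)
    correction = fit_correction(patches, expansion, decode, pinv_rcond=pinv_rcond)
    basis = fit_basis(patches, correction, expansion, decode, k=k,
                      pinv_rcond=pinv_rcond)
    return CalibrationModel(expansion=expansion, decode=decode, correction=correction,
                            basis=basis, grid=patches.grid, colorimetry=colorimetry)


def reconstruct_spectrum(rgb: np.ndarray, model: CalibrationModel,
                         clip: tuple[float, float] = (0.0, 1.5)) -> np.ndarray:
    """Reflectance spectra for RGB triplets of shape (..., 3).

    Affine in the basis scores: zero scores give the mean target spectrum.
    Out-of-range values are clipped to ``clip`` (physical reflectance cannot
    be negative; a 1.5 ceiling tolerates mild pseudo-inverse overshoot) and
    the clipped fraction is logged when non-negligible.
    """
    xyz = model.correct_rgb(rgb)
    scores = expand(xyz, model.expansion) @ model.basis.score_map.T
    spectra = model.basis.mean_spectrum + scores @ model.basis.eigenvectors
    n_clipped = int(np.count_nonzero((spectra < clip[0]) | (spectra > clip[1])))
    if n_clipped:
        frac = n_clipped / spectra.size
        level = logging.WARNING if frac > 0.01 else logging.DEBUG
        logger.log(level, "clipped %.3f%% of reconstructed reflectance values",
                   100.0 * frac)
    return np.clip(spectra, clip[0], clip[1])


def evaluate(model: CalibrationModel, patches) -> DeltaEReport:
    """Calibration quality on a photographed patch set.

    Reconstructs every patch spectrum from its camera RGB, converts both the
    reconstruction and the reference spectrum to CIELAB under the model's
    illuminant/observer, and reports per-patch CIEDE2000 and spectral RMSE.
    """
    recon = reconstruct_spectrum(patches.rgb, model)
    ref = np.asarray(patches.reflectance, dtype=float)
    cm = model.colorimetry
    lab_recon = cm.spectrum_to_lab(recon)
    lab_ref = cm.spectrum_to_lab(ref)
    de = ciede2000(lab_recon, lab_ref)
    rmse = np.sqrt(((recon - ref) ** 2).mean(axis=1))
    return DeltaEReport(per_patch_de=de, per_patch_rmse=rmse)
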