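"""Group-level spectral-curve statistics.

Computes mean +/- SD reflectance envelopes per (ROI, group), optionally
stratified by sex or age decade, and per-wavelength two-sample tests between
groups.  All statistics operate on *subject-level* spectra: repeat images and
both eyes of a subject are averaged first, so subjects — not images — are the
units of inference.  Per-band tests are Welch's two-tailed t-test by default
(pooled-variance optionally), with raw p < 0.05 flags mirrored by
Benjamini-Hochberg FDR q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import WavelengthGrid
from .roi import RoiSpectrumTable

logger = logging.getLogger("retispec")

__all__ = [
    "GroupCurveSummary",
    "BandTestResult",
    "subject_level",
    "summarize_groups",
    "per_band_test",
    "flagged_fraction",
    "plot_group_curves",
]


@dataclass
class GroupCurveSummary:
    roi: str
    group: str
    stratum: str | None
    mean: np.ndarray
    spread: np.ndarray  # SD by default; half-range when spread_kind="range"
    n_subjects: int
    spread_kind: str = "sd"


@dataclass
class BandTestResult:
    roi: str
    group_a: str
    group_b: str
    grid: WavelengthGrid
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_a: int
    n_b: int
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        """Raw per-band significance flags (p < alpha, uncorrected)."""
        return self.p < self.alpha

    @property
    def significant_fdr(self) -> np.ndarray:
        return self.q < self.alpha


def subject_level(table: RoiSpectrumTable) -> RoiSpectrumTable:
    """Average all spectra sharing (subject_id, roi) into one record."""
    keep = [c for c in ("group", "sex", "age") if c in table.meta.columns]
    meta_rows, spectra = [], []
    key = table.meta[["subject_id", "roi"]].apply(tuple, axis=1)
    for (sid, roi), idx in table.meta.groupby(key, sort=True).groups.items():
        idx = np.asarray(idx)
        row = {"subject_id": sid, "roi": roi}
        row.update(table.meta.loc[idx[0], keep].to_dict())
        meta_rows.append(row)
        spectra.append(table.spectra[idx].mean(axis=0))
    return RoiSpectrumTable(pd.DataFrame(meta_rows), np.vstack(spectra), table.grid)


def _strata(meta: pd.DataFrame, stratifier: str | None) -> pd.Series:
    if stratifier is None or stratifier == "none":
        return pd.Series(["all"] * len(meta), index=meta.index)
    if stratifier == "sex":
        return meta["sex"].astype(str)
    if stratifier == "age-decade":
        return (meta["age"] // 10 * 10).astype(int).astype(str) + "s"
    raise ValueError(f"unknown stratifier {stratifier!r}")


def summarize_groups(table: RoiSpectrumTable, stratifier: str | None = None,
                     spread_kind: str = "sd") -> list[GroupCurveSummary]:
    """Mean and spread curves per (roi, group[, stratum]).

    ``spread_kind`` is ``"sd"`` (the default envelope) or ``"range"``
    (half the max-min range).  Empty (roi, group) cells are omitted with a
    warning rather than raising.
    """
    subj = subject_level(table)
    strata = _strata(subj.meta, stratifier)
    out: list[GroupCurveSummary] = []
    for (roi, group, stratum), idx in subj.meta.groupby(
            [subj.meta["roi"], subj.meta["group"], strata], sort=True).groups.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            logger.warning("empty cell (%s, %s, %s) omitted", roi, group, stratum)
            continue
        block = subj.spectra[idx]
        if spread_kind == "sd":
            spread = block.std(axis=0, ddof=1) if len(idx) > 1 else np.zeros(block.shape[1])
        elif spread_kind == "range":
            spread = 0.5 * (block.max(axis=0) - block.min(axis=0))
        else:
            raise ValueError(f"unknown spread kind {spread_kind!r}")
        out.append(GroupCurveSummary(roi=roi, group=group,
                                     stratum=None if stratum == "all" else stratum,
                                     mean=block.mean(axis=0), spread=spread,
                                     n_subjects=len(idx), spread_kind=spread_kind))
    return out


def per_band_test(table: RoiSpectrumTable, group_a: str, group_b: str, roi: str,
                  equal_var: bool = False, alpha: float = 0.05) -> BandTestResult:
    """Per-wavelength two-tailed t-test between two groups in one ROI.

    Welch's unequal-variance test by default; operates on subject-level
    spectra.  Benjamini-Hochberg q-values accompany the raw p-values.
    """
    subj = subject_level(table)
    sel = subj.meta["roi"] == roi
    a = subj.spectra[(sel & (subj.meta["group"] == group_a)).to_numpy()]
    b = subj.spectra[(sel & (subj.meta["group"] == group_b)).to_numpy()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 subjects per group in {roi}; got {len(a)} vs {len(b)}"
        )
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    p = np.where(np.isnan(p), 1.0, np.asarray(p))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return BandTestResult(roi=roi, group_a=group_a, group_b=group_b, grid=table.grid,
                          t=t, p=p, q=q, n_a=len(a), n_b=len(b), alpha=alpha)


def flagged_fraction(result: BandTestResult, lo_nm: float | None = None,
                     hi_nm: float | None = None, corrected: bool = False) -> float:
    """Fraction of bands in [lo, hi] flagged significant."""
    w = result.grid.wavelengths
    mask = np.ones_like(w, dtype=bool)
    if lo_nm is not None:
        mask &= w >= lo_nm
    if hi_nm is not None:
        mask &= w <= hi_nm
    flags = result.significant_fdr if corrected else result.significant
    return float(flags[mask].mean())


_PANEL_ORDER = ("F", "I1", "I2", "S1", "S2")


def plot_group_curves(summaries: list[GroupCurveSummary], path: str,
                      tests: dict[str, BandTestResult] | None = None,
                      title: str | None = None,
                      wavelengths: np.ndarray | None = None) -> None:
    """Five-panel (a-e: F, I1, I2, S1, S2) mean +/- spread envelope figure.

    ``tests`` optionally maps ROI name to a band test whose significant bands
    are shaded.  Written to ``path`` (PNG/SVG by extension).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True, sharey=True)
    axes = axes.ravel()
    colors = {"Normal": "tab:green", "MCI": "tab:orange", "Dementia": "tab:red"}
    for i, roi in enumerate(_PANEL_ORDER):
        ax = axes[i]
        for s in summaries:
            if s.roi != roi:
                continue
            wl = (wavelengths if wavelengths is not None
                  else np.linspace(380, 780, len(s.mean)))
            label = s.group if s.stratum is None else f"{s.group}/{s.stratum}"
            c = colors.get(s.group)
            ax.plot(wl, s.mean, label=f"{label} (n={s.n_subjects})", color=c)
            ax.fill_between(wl, s.mean - s.spread, s.mean + s.spread, alpha=0.2, color=c)
        if tests and roi in tests:
            res = tests[roi]
            sig = res.significant
            ax.fill_between(res.grid.wavelengths, 0, 1, where=sig,
                            transform=ax.get_xaxis_transform(),
                            color="gray", alpha=0.12, linewidth=0)
        ax.set_title(f"({chr(ord('a') + i)}) {roi}")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("reflectance")
    axes[0].legend(fontsize=8)
    axes[-1].axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
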