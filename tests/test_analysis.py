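"""Group spectral summaries and per-band hypothesis tests."""

import numpy as np
import pandas as pd
import pytest

import retispec as r
from retispec.analysis import (flagged_fraction, per_band_test, subject_level,
                               summarize_groups)
from retispec.roi import RoiSpectrumTable


def _table(grid, rows, spectra):
    return RoiSpectrumTable(pd.DataFrame(rows), np.asarray(spectra, float), grid)


@pytest.fixture(scope="module")
def cohort_table(grid):
    """Ground-truth ROI spectra for a 20/group synthetic cohort."""
    cohort = r.make_cohort({g: (20, 20) for g in r.GROUPS}, seed=11)
    return r.truth_roi_spectra(cohort, seed=11)


class TestSummaries:
    def test_single_subject_group_has_zero_spread(self, grid):
        rows = [dict(subject_id="a", eye="OD", group="Normal", roi="F"),
                dict(subject_id="b", eye="OD", group="MCI", roi="F")]
        spectra = np.random.default_rng(0).uniform(0, 1, (2, grid.n_bands))
        out = summarize_groups(_table(grid, rows, spectra))
        assert all(np.allclose(s.spread, 0) for s in out)

    def test_identical_subjects_mean_equals_either(self, grid):
        spec = np.random.default_rng(1).uniform(0, 1, grid.n_bands)
        rows = [dict(subject_id=s, eye="OD", group="Normal", roi="F") for s in "ab"]
        out = summarize_groups(_table(grid, rows, [spec, spec]))
        assert np.allclose(out[0].mean, spec)
        assert np.allclose(out[0].spread, 0)

    def test_eyes_averaged_before_group_statistics(self, grid):
        rows = [dict(subject_id="a", eye="OD", group="Normal", roi="F"),
                dict(subject_id="a", eye="OS", group="Normal", roi="F")]
        spectra = np.stack([np.full(grid.n_bands, 0.2), np.full(grid.n_bands, 0.6)])
        out = summarize_groups(_table(grid, rows, spectra))
        assert out[0].n_subjects == 1
        assert np.allclose(out[0].mean, 0.4)

    def test_group_means_at_700nm_ordered_by_severity(self, cohort_table, grid):
        i700 = grid.index_of(700)
        out = summarize_groups(cohort_table)
        for roi in r.ROI_NAMES:
            by_group = {s.group: s.mean[i700] for s in out if s.roi == roi}
            assert by_group["Dementia"] > by_group["MCI"] > by_group["Normal"]

    def test_stratified_counts_partition_total(self, cohort_table):
        plain = summarize_groups(cohort_table)
        by_sex = summarize_groups(cohort_table, stratifier="sex")
        for roi in r.ROI_NAMES:
            for group in r.GROUPS:
                total = next(s.n_subjects for s in plain
                             if s.roi == roi and s.group == group)
                parts = sum(s.n_subjects for s in by_sex
                            if s.roi == roi and s.group == group)
                assert parts == total

    def test_age_decade_strata_labels(self, cohort_table):
        out = summarize_groups(cohort_table, stratifier="age-decade")
        assert {s.stratum for s in out} <= {"60s", "70s", "80s"}

    def test_range_spread_option(self, cohort_table):
        sd = summarize_groups(cohort_table)[0]
        rg = summarize_groups(cohort_table, spread_kind="range")[0]
        assert rg.spread_kind == "range"
        assert rg.spread.max() >= sd.spread.max()


class TestPerBandTest:
    def test_same_sample_gives_t_zero_p_one(self, grid):
        rows, spectra = [], []
        for grp in ("A", "B"):
            for s in range(4):
                rows.append(dict(subject_id=f"{grp}{s}", eye="OD", group=grp, roi="F"))
                spectra.append(np.linspace(0, 1, grid.n_bands) + s)
        res = per_band_test(_table(grid, rows, spectra), "A", "B", "F")
        assert np.allclose(res.t, 0) and np.allclose(res.p, 1)

    def test_insufficient_subjects_rejected(self, grid):
        rows = [dict(subject_id="a", eye="OD", group="A", roi="F"),
                dict(subject_id="b", eye="OD", group="B", roi="F"),
                dict(subject_id="c", eye="OD", group="B", roi="F")]
        spectra = np.random.default_rng(0).uniform(0, 1, (3, grid.n_bands))
        with pytest.raises(ValueError):
            per_band_test(_table(grid, rows, spectra), "A", "B", "F")

    def test_scale_equivariance(self, cohort_table):
        res = per_band_test(cohort_table, "Dementia", "Normal", "F")
        scaled = RoiSpectrumTable(cohort_table.meta, 7.3 * cohort_table.spectra,
                                  cohort_table.grid)
        res2 = per_band_test(scaled, "Dementia", "Normal", "F")
        assert np.allclose(res.t, res2.t) and np.allclose(res.p, res2.p)

    def test_power_localized_to_long_wavelengths(self, cohort_table):
        """Dementia vs Normal at n=20/group: >=80% of 650-780 nm bands flagged,
        <10% of sub-500 nm bands."""
        for roi in r.ROI_NAMES:
            res = per_band_test(cohort_table, "Dementia", "Normal", roi)
            assert flagged_fraction(res, 650, 780) >= 0.8
            assert flagged_fraction(res, None, 500) < 0.1

    def test_fdr_q_values_never_below_p(self, cohort_table):
        res = per_band_test(cohort_table, "MCI", "Normal", "S1")
        assert np.all(res.q >= res.p - 1e-12)

    def test_null_type_one_error_near_nominal(self):
        """Normal-vs-Normal truth spectra: raw per-band flag rate ~5%."""
        rates = []
        for rep in range(40):
            c = r.make_cohort({"Normal": (24, 24)}, seed=5000 + rep)
            tab = r.truth_roi_spectra(c, seed=6000 + rep)
            meta = tab.meta.copy()
            subs = sorted(meta.subject_id.unique())
            meta["group"] = np.where(meta.subject_id.isin(subs[:12]), "A", "B")
            res = per_band_test(RoiSpectrumTable(meta, tab.spectra, tab.grid),
                                "A", "B", "F")
            rates.append(res.significant.mean())
        assert abs(np.mean(rates) - 0.05) < 0.04

    def test_monotone_power_in_effect_amplitude(self):
        """Flagged 650-780 nm fraction grows with the injected amplitude."""
        fracs = []
        for amp in (0.0, 0.04, 0.10):
            vals = []
            for s in range(3):
                c = r.make_cohort({"Normal": (12, 12), "Dementia": (12, 12)},
                                  seed=300 + s)
                eff = r.default_effect(amplitude=amp)
                tab = r.truth_roi_spectra(c, effect=eff, seed=400 + s)
                res = per_band_test(tab, "Dementia", "Normal", "F")
                vals.append(flagged_fraction(res, 650, 780))
            fracs.append(np.mean(vals))
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[2] > fracs[0]


def test_subject_level_collapses_repeat_images(grid):
    rows = [dict(subject_id="a", eye="OD", group="Normal", roi="F"),
            dict(subject_id="a", eye="OD", group="Normal", roi="F"),
            dict(subject_id="a", eye="OS", group="Normal", roi="S1")]
    spectra = np.random.default_rng(0).uniform(0, 1, (3, grid.n_bands))
    out = subject_level(_table(grid, rows, spectra))
    assert len(out.meta) == 2  # (a, F) and (a, S1)


def test_plot_writes_figure(tmp_path, cohort_table):
    from retispec.analysis import plot_group_curves

    summaries = summarize_groups(cohort_table)
    tests = {roi: per_band_test(cohort_table, "Dementia", "Normal", roi)
             for roi in r.ROI_NAMES}
    out = tmp_path / "curves.png"
    plot_group_curves(summaries, out, tests=tests,
                      wavelengths=cohort_table.grid.wavelengths)
    assert out.stat().st_size > 0
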