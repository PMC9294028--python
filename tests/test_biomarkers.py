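"""Endpoint arithmetic, the mono-exponential T2 fit (vs a grid-search oracle),
threshold semantics, Dixon maps, ROI means and belt-phantom QC."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muscleqmri import (
    ConfigurationError,
    ImageVolume,
    MultiEchoSeries,
    PhantomSpec,
    T2Map,
    Tissue,
    TissueLabelMap,
    compute_mvi,
    compute_volumes,
    extract_visit_biomarkers,
    fat_fraction_map,
    fit_t2_map,
    percent_non_elevated,
    qc_phantom_t2,
    render_visit,
    roi_mean,
)

TE = (20.0, 40.0, 60.0, 80.0, 100.0)


def make_series(t2_values, s0=1000.0, sigma=0.0, te=TE, seed=0, first_echo_factor=1.0):
    """Pack per-voxel T2 values into a 1 x n x 1 multi-echo series."""
    t2 = np.atleast_1d(np.asarray(t2_values, dtype=float))
    te_arr = np.asarray(te)
    sig = s0 * np.exp(-te_arr[None, :] / t2[:, None])
    sig[:, 0] *= first_echo_factor
    if sigma > 0:
        rng = np.random.default_rng(seed)
        sig = np.hypot(sig + rng.normal(0, sigma, sig.shape), rng.normal(0, sigma, sig.shape))
    return MultiEchoSeries(tuple(te), sig[None, :, None, :], (1.0, 1.0, 5.0))


def t2_grid_oracle(y, te, grid=None):
    """Brute-force 1-D grid search with closed-form S0 per candidate T2."""
    if grid is None:
        grid = np.arange(1.0, 300.0001, 0.25)
    te = np.asarray(te, dtype=float)
    best_t2, best_cost = np.nan, np.inf
    for t2 in grid:
        g = np.exp(-te / t2)
        s0 = float(y @ g / (g @ g))
        cost = float(np.sum((s0 * g - y) ** 2))
        if cost < best_cost:
            best_t2, best_cost = t2, cost
    return best_t2


class TestVolumesAndMVI:
    def test_volume_arithmetic(self):
        lab = np.zeros((20, 20, 4), dtype=np.int16)
        lab.ravel()[:1000] = Tissue.LEAN_MUSCLE
        mv, imf, _ = compute_volumes(TissueLabelMap(lab, (1, 1, 5)))
        assert mv == 1000 * 5.0
        assert imf == 0.0

    @pytest.mark.parametrize(
        "mv,imf,expected",
        [(750000, 250000, 75.0), (123.0, 0.0, 100.0), (0.0, 55.0, 0.0), (500, 500, 50.0)],
    )
    def test_mvi_formula(self, mv, imf, expected):
        assert compute_mvi(mv, imf) == pytest.approx(expected, abs=1e-12)

    def test_mvi_undefined_for_empty_thigh(self):
        with pytest.raises(ZeroDivisionError):
            compute_mvi(0.0, 0.0)

    @given(st.floats(0.1, 1e7), st.floats(0.0, 1e7))
    @settings(max_examples=50, deadline=None)
    def test_mvi_identity(self, mv, imf):
        assert compute_mvi(mv, imf) == pytest.approx(100.0 * (1.0 - imf / (mv + imf)), rel=1e-12)

    def test_generator_infiltration_recovered_from_truth_volumes(self, subject_with_infiltration, small_spec):
        vi = render_visit(subject_with_infiltration([0.3]), 0, small_spec, seed=1)
        mv, imf, _ = compute_volumes(vi.truth_labels)
        assert imf / (mv + imf) == pytest.approx(0.30, abs=0.01)


class TestT2Fit:
    def test_noiseless_exact_recovery(self):
        series = make_series([50.0])
        t2map = fit_t2_map(series)
        assert t2map.t2_ms[0, 0, 0] == pytest.approx(50.0, abs=0.01)
        assert t2map.fit_ok[0, 0, 0]

    def test_first_echo_excluded_from_fit(self):
        clean = make_series([40.0])
        corrupted = make_series([40.0], first_echo_factor=7.3)
        a = fit_t2_map(clean)
        b = fit_t2_map(corrupted)
        assert a.t2_ms[0, 0, 0] == b.t2_ms[0, 0, 0]  # exact: echo 1 never enters

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        t2s = rng.uniform(20, 200, 50)
        base = fit_t2_map(make_series(t2s))
        scaled_sig = fit_t2_map(
            MultiEchoSeries(TE, 3.5 * make_series(t2s).data, (1, 1, 5))
        )
        np.testing.assert_allclose(scaled_sig.t2_ms, base.t2_ms, rtol=1e-6)
        te2 = tuple(2.0 * t for t in TE)
        scaled_te = fit_t2_map(make_series(2.0 * t2s, te=te2))
        np.testing.assert_allclose(scaled_te.t2_ms, 2.0 * base.t2_ms, rtol=1e-6)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        sigma = 1000.0 / 50.0  # SNR 50
        series = make_series(np.full(n, 60.0), sigma=sigma, seed=3)
        t2map = fit_t2_map(series)
        te_kept = np.asarray(TE[1:])
        for j in range(n):
            y = series.data[0, j, 0, 1:]
            oracle = t2_grid_oracle(y, te_kept)
            assert abs(t2map.t2_ms[0, j, 0] - oracle) <= 0.25  # one grid step

    def test_too_few_echoes_rejected(self):
        sig = np.ones((2, 2, 1, 3))
        with pytest.raises(ConfigurationError):
            fit_t2_map(MultiEchoSeries((20.0, 40.0, 60.0), sig, (1, 1, 5)))

    def test_nonpositive_signal_flagged_invalid(self):
        sig = np.zeros((1, 1, 1, 5))
        t2map = fit_t2_map(MultiEchoSeries(TE, sig, (1, 1, 5)))
        assert not t2map.fit_ok[0, 0, 0]


class TestPercentNonElevated:
    def _t2map(self, values):
        v = np.asarray(values, dtype=float)[None, :, None]
        return T2Map(v, np.ones_like(v), np.ones_like(v, dtype=bool))

    def test_strict_threshold_counting(self):
        assert percent_non_elevated(self._t2map([40, 50, 54, 60])) == 75.0

    def test_values_at_threshold_count_as_elevated(self):
        assert percent_non_elevated(self._t2map([55.0, 55.0, 55.0])) == 0.0

    def test_all_below(self):
        assert percent_non_elevated(self._t2map([40, 40])) == 100.0

    def test_invalid_fits_excluded_from_both_sides(self):
        t2map = self._t2map([40, 40, 900, 900])
        t2map.fit_ok[0, 2:, 0] = False
        assert percent_non_elevated(t2map) == 100.0

    def test_empty_mask_warns_nan(self):
        with pytest.warns(UserWarning):
            out = percent_non_elevated(self._t2map([40.0]), np.zeros((1, 1, 1), bool))
        assert np.isnan(out)


class TestFatFraction:
    @pytest.mark.parametrize("w,f,expected", [(100, 0, 0.0), (50, 50, 0.5), (0, 100, 1.0)])
    def test_boundary_cases(self, w, f, expected):
        wv = ImageVolume(np.full((1, 1, 1), float(w)), (1, 1, 5))
        fv = ImageVolume(np.full((1, 1, 1), float(f)), (1, 1, 5))
        out = fat_fraction_map(wv, fv)
        assert out.ff[0, 0, 0] == expected and out.valid[0, 0, 0]

    def test_zero_denominator_invalid(self):
        z = ImageVolume(np.zeros((1, 1, 1)), (1, 1, 5))
        out = fat_fraction_map(z, z)
        assert not out.valid[0, 0, 0]

    @given(st.floats(0.0, 1e5), st.floats(0.0, 1e5))
    @settings(max_examples=50, deadline=None)
    def test_complement_identity(self, w, f):
        wv = ImageVolume(np.full((1, 1, 1), w), (1, 1, 5))
        fv = ImageVolume(np.full((1, 1, 1), f), (1, 1, 5))
        a = fat_fraction_map(wv, fv)
        b = fat_fraction_map(fv, wv)
        if a.valid[0, 0, 0]:
            assert a.ff[0, 0, 0] + b.ff[0, 0, 0] == pytest.approx(1.0, abs=1e-12)


class TestRoiMean:
    def _labels(self):
        lab = np.zeros((4, 4, 1), dtype=np.int16)
        lab[:2, :, 0] = Tissue.LEAN_MUSCLE
        lab[2:, :, 0] = Tissue.INTERMUSCULAR_FAT
        return TissueLabelMap(lab, (1, 1, 5))

    def test_constant_map(self):
        lab = self._labels()
        vals = np.full((4, 4, 1), 7.5)
        assert roi_mean(vals, lab, "muscle_bundle") == 7.5
        assert roi_mean(vals, lab, "lean_muscle") == 7.5

    def test_weighted_bundle_mean(self):
        lab = self._labels()
        vals = np.zeros((4, 4, 1))
        vals[:2] = 40.0
        vals[2:] = 150.0
        assert roi_mean(vals, lab, "lean_muscle") == 40.0
        assert roi_mean(vals, lab, "muscle_bundle") == 95.0

    def test_empty_roi_warns_nan(self):
        lab = TissueLabelMap(np.zeros((2, 2, 1), dtype=np.int16), (1, 1, 5))
        with pytest.warns(UserWarning):
            assert np.isnan(roi_mean(np.ones((2, 2, 1)), lab, "lean_muscle"))

    def test_noiseless_bundle_t2_mean_matches_mixture(self, subject_with_infiltration):
        f = 0.3
        spec = PhantomSpec(slice_count=3, in_plane_shape=(64, 64), noise_sigma=0.0, lean_t2_slope=0.0)
        vi = render_visit(subject_with_infiltration([f]), 0, spec, seed=4)
        t2map = fit_t2_map(vi.multi_echo, vi.truth_labels.bundle_mask)
        got = roi_mean(t2map.t2_ms, vi.truth_labels, "muscle_bundle", valid=t2map.fit_ok)
        lab = vi.truth_labels
        f_vox = lab.count(Tissue.INTERMUSCULAR_FAT) / lab.bundle_mask.sum()
        assert got == pytest.approx((1 - f_vox) * 40.0 + f_vox * 150.0, rel=1e-3)


class TestPhantomQC:
    def test_in_range_passes(self, cohort10, small_spec):
        vi = render_visit(cohort10[0], 0, small_spec, seed=1)
        region = vi.truth_labels.data == Tissue.PHANTOM
        t2map = fit_t2_map(vi.multi_echo, region)
        rep = qc_phantom_t2(t2map, region, (80.0, 100.0))
        assert rep.passed and 80 <= rep.median_t2_ms <= 100

    def test_miscalibrated_echo_timing_fails(self, cohort10, small_spec):
        vi = render_visit(cohort10[0], 0, small_spec, seed=1, t2_scale=1.3)
        region = vi.truth_labels.data == Tissue.PHANTOM
        t2map = fit_t2_map(vi.multi_echo, region)
        rep = qc_phantom_t2(t2map, region, (80.0, 100.0))
        assert rep.status == "fail"
        assert rep.median_t2_ms == pytest.approx(117.0, rel=0.05)

    def test_empty_region_is_error(self):
        v = np.full((1, 1, 1), 90.0)
        t2map = T2Map(v, v, np.ones_like(v, dtype=bool))
        rep = qc_phantom_t2(t2map, np.zeros((1, 1, 1), bool), (80, 100))
        assert rep.status == "error"


class TestExtractVisitBiomarkers:
    def test_noiseless_end_to_end_truth_recovery(self, subject_with_infiltration):
        f = 0.25
        spec = PhantomSpec(
            slice_count=4, in_plane_shape=(64, 64), noise_sigma=0.0, lean_t2_slope=0.0,
            ff_lean_slope=0.0,
        )
        vi = render_visit(subject_with_infiltration([f]), 0, spec, seed=7)
        lab = vi.truth_labels
        t2map = fit_t2_map(vi.multi_echo, lab.data != Tissue.BACKGROUND)
        ffmap = fat_fraction_map(vi.dixon_water, vi.dixon_fat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bm = extract_visit_biomarkers(lab, t2map, ffmap)
        f_vox = lab.count(Tissue.INTERMUSCULAR_FAT) / lab.bundle_mask.sum()
        assert bm.mvi_percent == pytest.approx(100 * (1 - f_vox), abs=1e-9)
        assert bm.t2_lean_ms == pytest.approx(40.0, rel=1e-3)
        assert bm.ff_lean_percent == pytest.approx(10.0, rel=1e-6)
        assert bm.pct_non_elevated == pytest.approx(100 * (1 - f_vox), abs=0.5)
        assert bm.ff_bundle_percent == pytest.approx(100 * ((1 - f_vox) * 0.10 + f_vox * 0.90), rel=1e-6)
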