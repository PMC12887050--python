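"""Tests for ROI statistics, Cohen's d, FLIRR and granule counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomics.flim_fit import FitConfig, ParamMaps
from cardiomics.flim_metrics import (
    GroupStats,
    cohens_d,
    compute_flirr,
    detect_granules,
    roi_stats,
)
from cardiomics.flim_synth import (
    AcquisitionSpec,
    SceneLayout,
    ValidationError,
    make_scene,
)


def _uniform_maps(shape, a1=np.nan, a2=np.nan, channel="x"):
    full = lambda v: np.full(shape, float(v))
    nanmap = np.full(shape, np.nan)
    valid = np.ones(shape, dtype=bool)
    return ParamMaps(full(a1), full(a2), nanmap, nanmap, nanmap, nanmap, valid,
                     channel, FitConfig())


class TestRoiStats:
    def test_constant_field(self):
        stats = roi_stats(np.full((5, 5), 3.7), np.ones((5, 5)))
        assert stats.mean == pytest.approx(3.7)
        assert stats.sd == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_case(self):
        values = np.array([[1.0, 3.0]])
        stats = roi_stats(values, np.ones((1, 2)))
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(1.0)  # population formula, /N

    def test_histogram_counts_sum_to_pixel_count(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 10))
        stats = roi_stats(vals, np.ones((10, 10)))
        assert stats.hist_counts.sum() == 100

    def test_matches_two_pass_computation(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(2.0, 0.5, size=(20, 20))
        mask = rng.random((20, 20)) > 0.4
        stats = roi_stats(vals, mask)
        sel = vals[mask]
        assert stats.mean == pytest.approx(sel.mean(), rel=1e-12)
        assert stats.sd == pytest.approx(np.sqrt(((sel - sel.mean()) ** 2).mean()), rel=1e-12)

    def test_no_valid_pixels_is_error(self):
        with pytest.raises(ValidationError, match="valid pixels"):
            roi_stats(np.full((4, 4), np.nan), np.ones((4, 4)))


class TestCohensD:
    def test_fad_a1_printed_summary(self):
        g_cm = GroupStats.from_summary("CM", 76.4, 6.0, 23)
        g_cmb = GroupStats.from_summary("CMB", 68.2, 6.0, 27)
        assert cohens_d(g_cm, g_cmb) == pytest.approx(1.37, abs=0.005)

    def test_nadh_a2_printed_summary(self):
        g1 = GroupStats.from_summary("CM", 28.4, 5.8, 23)
        g2 = GroupStats.from_summary("CMB", 26.4, 5.8, 27)
        assert cohens_d(g1, g2) == pytest.approx(0.34, abs=0.005)

    def test_identical_groups_give_zero(self):
        g = GroupStats.from_values("g", [1.0, 2.0, 3.0])
        assert cohens_d(g, g) == 0.0

    def test_zero_pooled_sd_is_nan(self):
        g1 = GroupStats.from_summary("a", 1.0, 0.0, 5)
        g2 = GroupStats.from_summary("b", 2.0, 0.0, 5)
        assert np.isnan(cohens_d(g1, g2))

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance_and_antisymmetry(self, shift, scale):
        rng = np.random.default_rng(7)
        v1 = rng.normal(1.0, 1.0, 8)
        v2 = rng.normal(2.0, 1.5, 6)
        g1, g2 = GroupStats.from_values("a", v1), GroupStats.from_values("b", v2)
        d = cohens_d(g1, g2)
        g1s = GroupStats.from_values("a", scale * v1 + shift)
        g2s = GroupStats.from_values("b", scale * v2 + shift)
        assert cohens_d(g1s, g2s) == pytest.approx(d, rel=1e-9)
        assert cohens_d(g2, g1) == pytest.approx(-d, rel=1e-9)


class TestFlirr:
    def test_printed_group_means_reproduce_cm_flirr(self):
        maps_n = _uniform_maps((6, 6), a2=28.4, channel="NADH")
        maps_f = _uniform_maps((6, 6), a1=68.2, channel="FAD")
        res = compute_flirr(maps_n, maps_f, np.ones((6, 6), dtype=int))
        assert round(res.per_cell[1], 2) == 0.42

    def test_equal_fractions_give_unity(self):
        maps_n = _uniform_maps((4, 4), a2=33.0)
        maps_f = _uniform_maps((4, 4), a1=33.0)
        res = compute_flirr(maps_n, maps_f, np.ones((4, 4), dtype=int))
        assert res.per_cell[1] == 1.0

    def test_cmb_fractions_give_printed_ratio(self):
        maps_n = _uniform_maps((4, 4), a2=26.4)
        maps_f = _uniform_maps((4, 4), a1=76.4)
        res = compute_flirr(maps_n, maps_f, np.ones((4, 4), dtype=int))
        assert res.per_cell[1] == pytest.approx(26.4 / 76.4, rel=1e-9)  # 0.3455

    def test_swapped_channels_reciprocal_on_uniform_maps(self):
        maps_n = _uniform_maps((4, 4), a2=28.4, a1=28.4)
        maps_f = _uniform_maps((4, 4), a1=68.2, a2=68.2)
        masks = np.ones((4, 4), dtype=int)
        fwd = compute_flirr(maps_n, maps_f, masks).per_cell[1]
        rev = compute_flirr(maps_f, maps_n, masks).per_cell[1]
        assert fwd * rev == pytest.approx(1.0, rel=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValidationError, match="co-registered"):
            compute_flirr(
                _uniform_maps((4, 4), a2=1), _uniform_maps((5, 5), a1=1), np.ones((4, 4))
            )

    def test_invalid_pixels_excluded_from_cell_mean(self):
        maps_n = _uniform_maps((4, 4), a2=30.0)
        maps_f = _uniform_maps((4, 4), a1=60.0)
        maps_f.a1[0, 0] = np.nan
        res = compute_flirr(maps_n, maps_f, np.ones((4, 4), dtype=int))
        assert np.isnan(res.flirr_map[0, 0])
        assert res.per_cell[1] == pytest.approx(0.5)


def _tau_map_with_granules(centers, cell_value=1.0, granule_value=0.5, radius=2):
    tau = np.full((40, 40), cell_value)
    cells = np.ones((40, 40), dtype=int)
    rr, cc = np.mgrid[0:40, 0:40]
    for r, c in centers:
        tau[(rr - r) ** 2 + (cc - c) ** 2 <= radius**2] = granule_value
    return tau, cells


class TestDetectGranules:
    def test_no_granules_all_counts_zero(self):
        tau, cells = _tau_map_with_granules([])
        out = detect_granules(tau, cells, threshold=0.75)
        assert out.per_cell_counts == {1: 0}

    def test_three_planted_granules_counted(self):
        tau, cells = _tau_map_with_granules([(8, 8), (20, 30), (32, 12)])
        out = detect_granules(tau, cells, threshold=0.75)
        assert out.per_cell_counts[1] == 3
        assert all(g.mean_tau_m < 0.75 for g in out.granules)

    def test_min_area_excludes_small_components(self):
        tau, cells = _tau_map_with_granules([(10, 10)], radius=1)  # ~4 px
        assert detect_granules(tau, cells, threshold=0.75, min_area=10).per_cell_counts[1] == 0
        assert detect_granules(tau, cells, threshold=0.75, min_area=1).per_cell_counts[1] == 1

    def test_total_granule_pixels_monotone_in_threshold(self):
        import warnings

        rng = np.random.default_rng(5)
        tau = rng.uniform(0.3, 1.5, size=(40, 40))
        cells = np.ones((40, 40), dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            areas = [
                sum(g.area for g in
                    detect_granules(tau, cells, threshold=t, min_area=1).granules)
                for t in (0.4, 0.6, 0.8)
            ]
        assert areas == sorted(areas)

    def test_counts_non_increasing_in_min_area(self):
        rng = np.random.default_rng(5)
        tau = rng.uniform(0.3, 1.5, size=(40, 40))
        cells = np.ones((40, 40), dtype=int)
        counts = [
            sum(detect_granules(tau, cells, threshold=0.6, min_area=ma)
                .per_cell_counts.values())
            for ma in (1, 3, 6)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_high_threshold_warns(self):
        tau, cells = _tau_map_with_granules([(10, 10)])
        with pytest.warns(UserWarning, match="median"):
            detect_granules(tau, cells, threshold=1.4)

    def test_generator_integration_recovers_planted_count(self):
        spec = AcquisitionSpec(frame_shape=(48, 48))
        layout = SceneLayout(n_cells=2, granule_rate=2.0, cell_radius=10)
        truth = make_scene(layout, spec, 21)
        planted = {lbl: 0 for lbl in truth.cell_groups}
        for g in truth.granules:
            planted[g.cell_label] += 1
        cyto_tau = layout.group_params["cells"].tau_m
        out = detect_granules(truth.tau_m, truth.cell_masks,
                              threshold=0.75 * cyto_tau, min_area=3)
        assert out.per_cell_counts == planted
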