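import numpy as np
import pandas as pd
import pytest

from aeoscan.landcover import PurePixelSet
from aeoscan.nddi_mad import (
    COMPOSITES_PER_YEAR,
    DesertificationMapper,
    MADMap,
    NDDICube,
    ReferenceCurve,
    area_estimate,
    build_nddi_cube,
    build_reference_curve,
    classify_desertified,
    compute_mad,
    compute_nddi,
    ptile_threshold,
    relative_error,
    savitzky_golay,
)
from aeoscan.raster_core import ClassMap, GridGeometry, Legend


def _geom(rows, cols, cell=1000.0, crs="metre:local"):
    return GridGeometry(0, rows * cell, cell, cell, rows, cols, crs_tag=crs)


def _cube(values):
    values = np.asarray(values, dtype=float)
    return NDDICube(geometry=_geom(values.shape[1], values.shape[2]), values=values)


def _pure(rowcols, cls=Legend.DESERTIFIED):
    table = pd.DataFrame(
        [
            {"cell_id": i + 1, "row": r, "col": c, "class": cls, "proportion": 1.0}
            for i, (r, c) in enumerate(rowcols)
        ]
    )
    return PurePixelSet(table=table, t_desert=0.7, t_other=0.9)


class TestNDDI:
    def test_equal_bands_give_zero(self):
        assert compute_nddi(np.array([0.2]), np.array([0.2]))[0] == 0.0

    def test_hand_arithmetic(self):
        assert compute_nddi(np.array([0.30]), np.array([0.10]))[0] == pytest.approx(0.5)

    def test_zero_second_band_boundary(self):
        assert compute_nddi(np.array([0.4]), np.array([0.0]))[0] == pytest.approx(1.0)

    def test_nonpositive_sum_masked(self):
        out = compute_nddi(np.array([0.0, -0.1]), np.array([0.0, 0.05]))
        assert np.isnan(out).all()

    def test_antisymmetric_under_band_swap_and_bounded(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.01, 1, 100), rng.uniform(0.01, 1, 100)
        fwd, rev = compute_nddi(a, b), compute_nddi(b, a)
        np.testing.assert_allclose(fwd, -rev, atol=1e-15)
        assert (np.abs(fwd) <= 1).all()

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_nddi(np.ones(3), np.ones(4))


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.3)
        np.testing.assert_allclose(savitzky_golay(x, 5, 2), x)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_polynomials_up_to_order_reproduced(self, order):
        t = np.linspace(0, 1, 30)
        coeffs = [0.7, -1.2, 2.0, 0.5][: order + 1]
        x = sum(c * t**k for k, c in enumerate(coeffs))
        out = savitzky_golay(x, 7, order)
        np.testing.assert_allclose(out[3:-3], x[3:-3], atol=1e-9)

    def test_interior_weights_match_least_squares_oracle(self):
        # solve the window-5/order-2 local least-squares system directly
        A = np.vander(np.arange(-2, 3), 3, increasing=True)
        weights = np.linalg.lstsq(A, np.eye(5), rcond=None)[0][0]
        np.testing.assert_allclose(weights, np.array([-3, 12, 17, 12, -3]) / 35, atol=1e-12)
        # an impulse through the filter reads out the central weights
        x = np.zeros(11)
        x[5] = 1.0
        out = savitzky_golay(x, 5, 2)
        np.testing.assert_allclose(out[3:8], weights[::-1], atol=1e-12)

    def test_invalid_window_or_order_rejected(self):
        x = np.zeros(10)
        for window, order in [(4, 2), (1, 0), (11, 2), (5, 5)]:
            with pytest.raises(ValueError):
                savitzky_golay(x, window, order)


class TestReferenceCurve:
    def test_single_pure_cell_equals_its_series(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(-0.5, 0.5, (46, 3, 3))
        curve = build_reference_curve(_cube(values), _pure([(1, 2)]))
        np.testing.assert_allclose(curve.raw, values[:, 1, 2])

    def test_opposite_series_cancel(self):
        s = np.sin(np.linspace(0, 3, 46))
        values = np.zeros((46, 1, 2))
        values[:, 0, 0], values[:, 0, 1] = s, -s
        curve = build_reference_curve(_cube(values), _pure([(0, 0), (0, 1)]))
        np.testing.assert_allclose(curve.raw, 0.0, atol=1e-15)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError, match="no pure cells"):
            build_reference_curve(_cube(np.zeros((46, 2, 2))), _pure([(0, 0)]),
                                  class_label=Legend.VEGETATION)

    def test_desertified_curve_flatter_than_vegetation(self):
        from aeoscan.synthetic import SceneSpec, generate_scene

        scene = generate_scene(SceneSpec(n_rows=20, n_cols=20, noise_sd=0.0,
                                         fine_mixing=0.0, seed=2))
        cube = build_nddi_cube(scene.coarse_series, scene.coarse_geometry)
        rows, cols = np.nonzero(scene.truth_coarse.labels == Legend.DESERTIFIED)
        d_pure = _pure(list(zip(rows, cols)))
        rows, cols = np.nonzero(scene.truth_coarse.labels == Legend.VEGETATION)
        v_pure = _pure(list(zip(rows, cols)), cls=Legend.VEGETATION)
        d_curve = build_reference_curve(cube, d_pure)
        v_curve = build_reference_curve(cube, v_pure, class_label=Legend.VEGETATION)
        assert np.ptp(d_curve.raw) < np.ptp(v_curve.raw)
        assert d_curve.raw.mean() > v_curve.raw.mean()


class TestMAD:
    def test_self_distance_zero(self):
        s = np.sin(np.linspace(0, 3, 46))
        values = np.tile(s[:, None, None], (1, 1, 1))
        ref = ReferenceCurve(raw=s, filtered=s, class_label=1, window=5, order=2)
        mad = compute_mad(_cube(values), ref)
        assert mad.values[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_hand_arithmetic_oracle(self):
        values = np.array([0.3, 0.1]).reshape(2, 1, 1)
        ref = ReferenceCurve(raw=np.array([0.2, 0.4]), filtered=np.array([0.2, 0.4]),
                             class_label=1, window=3, order=1)
        mad = compute_mad(_cube(values), ref)
        assert mad.values[0, 0] == pytest.approx(0.2)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(-1, 1, (46, 2, 2))
        r = rng.uniform(-1, 1, 46)
        ref = ReferenceCurve(raw=r, filtered=r, class_label=1, window=5, order=2)
        ref_neg = ReferenceCurve(raw=-r, filtered=-r, class_label=1, window=5, order=2)
        np.testing.assert_allclose(
            compute_mad(_cube(values), ref).values,
            compute_mad(_cube(-values), ref_neg).values,
            atol=1e-15,
        )

    def test_matches_direct_loop_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(-1, 1, (46, 10, 10))
        r = rng.uniform(-1, 1, 46)
        ref = ReferenceCurve(raw=r, filtered=r, class_label=1, window=5, order=2)
        mad = compute_mad(_cube(values), ref)
        for i in range(10):
            for j in range(10):
                expected = sum(abs(values[k, i, j] - r[k]) for k in range(46)) / 46
                assert abs(mad.values[i, j] - expected) < 1e-12

    def test_masked_composites_average_over_available(self):
        values = np.array([0.3, np.nan, 0.1, 0.5]).reshape(4, 1, 1)
        r = np.array([0.2, 0.2, 0.2, 0.2])
        ref = ReferenceCurve(raw=r, filtered=r, class_label=1, window=3, order=1)
        mad = compute_mad(_cube(values), ref, min_coverage=0.5)
        assert mad.values[0, 0] == pytest.approx((0.1 + 0.1 + 0.3) / 3)

    def test_low_coverage_pixel_flagged_and_masked(self):
        values = np.full((4, 1, 1), np.nan)
        values[0, 0, 0] = 0.3
        r = np.zeros(4)
        ref = ReferenceCurve(raw=r, filtered=r, class_label=1, window=3, order=1)
        mad = compute_mad(_cube(values), ref, min_coverage=0.8)
        assert np.isnan(mad.values[0, 0])
        assert mad.low_coverage[0, 0]

    def test_length_mismatch_rejected(self):
        r = np.zeros(10)
        ref = ReferenceCurve(raw=r, filtered=r, class_label=1, window=3, order=1)
        with pytest.raises(ValueError, match="composites"):
            compute_mad(_cube(np.zeros((46, 1, 1))), ref)


class TestPtileThreshold:
    def test_uniform_sort_and_count_oracle(self):
        mad = MADMap(geometry=_geom(10, 10), values=np.arange(1.0, 101.0).reshape(10, 10))
        thr = ptile_threshold(mad, 0.25)
        assert thr == pytest.approx(25.75)
        assert (mad.values <= np.floor(thr)).sum() == 25

    def test_full_inclusion_limit_is_max(self):
        mad = MADMap(geometry=_geom(2, 2), values=np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert ptile_threshold(mad, 1 - 1e-12) == pytest.approx(4.0)

    def test_two_population_map_separated(self):
        values = np.concatenate([np.full(90, 0.01), np.full(10, 0.99)]).reshape(10, 10)
        mad = MADMap(geometry=_geom(10, 10), values=values)
        thr = ptile_threshold(mad, 0.9)
        assert 0.01 <= thr < 0.99
        assert ((values <= thr).sum()) == 90

    def test_monotone_in_prior_fraction(self):
        rng = np.random.default_rng(4)
        mad = MADMap(geometry=_geom(10, 10), values=rng.random((10, 10)))
        priors = np.linspace(0.05, 0.95, 10)
        thrs = [ptile_threshold(mad, p) for p in priors]
        assert all(a <= b for a, b in zip(thrs, thrs[1:]))

    def test_degenerate_map_warns_and_returns_value(self):
        mad = MADMap(geometry=_geom(2, 2), values=np.full((2, 2), 0.3))
        with pytest.warns(UserWarning, match="degenerate"):
            assert ptile_threshold(mad, 0.5) == 0.3

    def test_invalid_prior_rejected(self):
        mad = MADMap(geometry=_geom(1, 1), values=np.ones((1, 1)))
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                ptile_threshold(mad, p)


class TestClassifyAndArea:
    def test_threshold_extremes(self):
        mad = MADMap(geometry=_geom(2, 2), values=np.array([[0.1, 0.2], [0.3, 0.4]]))
        assert classify_desertified(mad, 0.05).class_count(Legend.DESERTIFIED) == 0
        assert classify_desertified(mad, 0.4).class_count(Legend.DESERTIFIED) == 4

    def test_boundary_inclusive_and_mask_preserved(self):
        values = np.array([[0.1, np.nan], [0.2, 0.3]])
        mad = MADMap(geometry=_geom(2, 2), values=values)
        out = classify_desertified(mad, 0.2)
        assert out.labels[0, 0] == Legend.DESERTIFIED
        assert out.labels[1, 0] == Legend.DESERTIFIED  # == threshold counts
        assert out.labels[0, 1] == Legend.NODATA
        assert out.labels[1, 1] == Legend.OTHERS

    def test_area_counting(self):
        labels = np.full((10, 1), Legend.DESERTIFIED)
        assert area_estimate(ClassMap(geometry=_geom(10, 1), labels=labels)) == pytest.approx(10.0)
        empty = ClassMap(geometry=_geom(2, 2), labels=np.full((2, 2), Legend.OTHERS))
        assert area_estimate(empty) == 0.0

    def test_half_km_cells(self):
        labels = np.full((3, 3), Legend.DESERTIFIED)
        cmap = ClassMap(geometry=_geom(3, 3, cell=500.0), labels=labels)
        assert area_estimate(cmap) == pytest.approx(2.25)

    def test_non_metric_crs_rejected(self):
        cmap = ClassMap(geometry=_geom(2, 2, crs="degrees"), labels=np.ones((2, 2), int))
        with pytest.raises(ValueError, match="metric"):
            area_estimate(cmap)


class TestRelativeError:
    @pytest.mark.parametrize(
        "estimated,investigated,expected",
        [
            (1714806, 1726700, 0.69),
            (1758942, 1706700, 3.06),
            (1724094, 1701600, 1.32),
            (5000, 5000, 0.0),
        ],
    )
    def test_survey_comparison_values(self, estimated, investigated, expected):
        assert relative_error(estimated, investigated) == expected

    def test_nonpositive_investigated_rejected(self):
        with pytest.raises(ValueError):
            relative_error(10.0, 0.0)


class TestDesertificationMapper:
    def test_fit_predict_recovers_truth_fraction(self, small_scene):
        cube = build_nddi_cube(small_scene.coarse_series, small_scene.coarse_geometry)
        labels = small_scene.truth_coarse.labels
        rows, cols = np.nonzero(labels == Legend.DESERTIFIED)
        pure = _pure(list(zip(rows, cols)))
        frac = (labels == Legend.DESERTIFIED).mean()
        mapper = DesertificationMapper(prior_fraction=frac)
        out = mapper.fit_predict(cube, pure)
        agree = np.mean((out.labels == Legend.DESERTIFIED) == (labels == Legend.DESERTIFIED))
        assert agree >= 0.9
        assert mapper.threshold_ > 0
        assert mapper.mad_map_.values.shape == labels.shape

    def test_cube_carries_46_composites(self, small_scene):
        cube = build_nddi_cube(small_scene.coarse_series, small_scene.coarse_geometry)
        assert cube.n_composites == COMPOSITES_PER_YEAR == 46

    def test_predict_before_fit_and_missing_rule(self, small_scene):
        cube = build_nddi_cube(small_scene.coarse_series, small_scene.coarse_geometry)
        with pytest.raises(RuntimeError):
            DesertificationMapper(prior_fraction=0.3).predict(cube)
        rows, cols = np.nonzero(small_scene.truth_coarse.labels == Legend.DESERTIFIED)
        mapper = DesertificationMapper().fit(cube, _pure(list(zip(rows, cols))))
        with pytest.raises(ValueError, match="threshold or prior"):
            mapper.predict(cube)

    def test_sklearn_params(self):
        mapper = DesertificationMapper(prior_fraction=0.25, sg_window=7)
        params = mapper.get_params()
        assert params["prior_fraction"] == 0.25 and params["sg_window"] == 7
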