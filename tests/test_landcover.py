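import numpy as np
import pandas as pd
import pytest

from aeoscan.landcover import (
    LandCoverClassifier,
    PurePixelSet,
    TrainingSet,
    band_pair_separability,
    class_proportions,
    select_pure_pixels,
    train_classifier,
)
from aeoscan.raster_core import BandStack, ClassMap, Legend, build_grid_frame
from aeoscan.synthetic import generate_training_points


class TestClassifier:
    def test_linearly_separable_toy_is_memorised(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])
        y = np.array([1, 1, 2, 2])
        model = LandCoverClassifier().fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            LandCoverClassifier().fit(np.zeros((3, 2)), np.ones(3))

    def test_degree_two_kernel_separates_xor(self):
        X = np.array([[-1.0, -1.0], [1.0, 1.0], [-1.0, 1.0], [1.0, -1.0]])
        y = np.array([1, 1, 2, 2])
        model = LandCoverClassifier(kernel_degree=2).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_sklearn_param_interface(self):
        model = LandCoverClassifier(kernel_degree=3, C=1.0)
        assert model.get_params()["kernel_degree"] == 3
        model.set_params(kernel_degree=2)
        assert model.kernel_degree == 2

    def test_classify_map_masks_and_band_count(self, make_stack):
        X = np.array([[0.0, 0.0], [10.0, 10.0]])
        model = LandCoverClassifier().fit(X, np.array([1, 2]))
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        stack = make_stack(np.stack([np.full((2, 2), 10.0)] * 2), mask=mask)
        cmap = model.classify_map(stack)
        assert cmap.labels[0, 0] == Legend.NODATA
        assert (cmap.labels[~mask] == 2).all()
        with pytest.raises(ValueError, match="bands"):
            model.classify_map(make_stack(np.ones((3, 2, 2))))

    def test_fully_masked_stack_yields_all_nodata(self, make_stack):
        model = LandCoverClassifier().fit(np.array([[0.0], [1.0]]), np.array([1, 2]))
        stack = make_stack(np.ones((1, 3, 3)), mask=np.ones((3, 3), bool))
        assert (model.classify_map(stack).labels == Legend.NODATA).all()

    def test_synthetic_scene_recovered_above_95_percent(self, small_scene):
        train = generate_training_points(small_scene, 33, seed=11)
        model = train_classifier(train, kernel_degree=2)
        cmap = model.classify_map(small_scene.fine_ms)
        agree = np.mean(cmap.labels == small_scene.truth_fine.labels)
        assert agree >= 0.95
        # training samples themselves are reproduced on separable classes
        np.testing.assert_array_equal(model.predict(train.samples), train.labels)


def _frame_with(proportions, valid=None):
    n = next(iter(proportions.values())).shape
    from aeoscan.raster_core import GridFrame, GridGeometry

    geom = GridGeometry(0, n[0] * 100.0, 100.0, 100.0, n[0], n[1])
    ids = np.arange(1, n[0] * n[1] + 1).reshape(n)
    return GridFrame(geometry=geom, cell_ids=ids, proportions=proportions,
                     valid=valid if valid is not None else np.ones(n, bool))


class TestProportionsAndPurePixels:
    def test_counting_oracle(self, square_geometry):
        labels = np.array(
            [[Legend.DESERTIFIED, Legend.DESERTIFIED], [Legend.DESERTIFIED, Legend.VEGETATION]]
        )
        cmap = ClassMap(geometry=square_geometry(2, 2), labels=labels)
        frame = build_grid_frame(square_geometry(2, 2), 200.0)
        out = class_proportions(cmap, frame)
        assert out.proportions[Legend.DESERTIFIED][0, 0] == pytest.approx(0.75)
        assert out.proportions[Legend.VEGETATION][0, 0] == pytest.approx(0.25)

    def test_homogeneous_cell_is_one(self, square_geometry):
        cmap = ClassMap(geometry=square_geometry(2, 2),
                        labels=np.full((2, 2), Legend.DESERTIFIED))
        out = class_proportions(cmap, build_grid_frame(square_geometry(2, 2), 200.0))
        assert out.proportions[Legend.DESERTIFIED][0, 0] == 1.0

    def test_all_masked_cell_flagged_invalid(self, square_geometry):
        cmap = ClassMap(geometry=square_geometry(2, 2), labels=np.full((2, 2), Legend.NODATA))
        out = class_proportions(cmap, build_grid_frame(square_geometry(2, 2), 200.0))
        assert not out.valid[0, 0]
        assert np.isnan(out.proportions[Legend.DESERTIFIED][0, 0])

    def test_fractions_partition_to_one(self, small_scene):
        frame = build_grid_frame(small_scene.truth_fine.geometry, 1000.0)
        out = class_proportions(small_scene.truth_fine, frame)
        total = sum(out.proportions[c] for c in Legend.VALID)
        np.testing.assert_allclose(total[out.valid], 1.0, atol=1e-9)

    def test_misaligned_frame_rejected(self, square_geometry):
        cmap = ClassMap(geometry=square_geometry(4, 4), labels=np.ones((4, 4), int))
        bad = build_grid_frame(square_geometry(6, 6), 200.0)
        with pytest.raises(ValueError):
            class_proportions(cmap, bad)

    def test_pure_selection_rules(self):
        frame = _frame_with(
            {
                Legend.DESERTIFIED: np.array([[0.75, 0.70, 0.5]]),
                Legend.VEGETATION: np.array([[0.1, 0.0, 0.3]]),
                Legend.OTHERS: np.array([[0.15, 0.30, 0.2]]),
            }
        )
        pure = select_pure_pixels(frame)
        assert pure.table["class"].tolist() == [Legend.DESERTIFIED]
        assert pure.table["cell_id"].tolist() == [1]  # 0.75 > 0.70; 0.70 exactly is not pure

    def test_boundary_exact_threshold_is_not_pure(self):
        frame = _frame_with(
            {
                Legend.DESERTIFIED: np.array([[0.0]]),
                Legend.VEGETATION: np.array([[0.90]]),
                Legend.OTHERS: np.array([[0.10]]),
            }
        )
        assert select_pure_pixels(frame).table.empty

    def test_raising_threshold_never_adds_cells(self, small_scene):
        frame = build_grid_frame(small_scene.truth_fine.geometry, 1000.0)
        frame = class_proportions(small_scene.truth_fine, frame)
        loose = select_pure_pixels(frame, t_desert=0.6, t_other=0.8)
        tight = select_pure_pixels(frame, t_desert=0.8, t_other=0.95)
        loose_ids = set(zip(loose.table.cell_id, loose.table["class"]))
        tight_ids = set(zip(tight.table.cell_id, tight.table["class"]))
        assert tight_ids <= loose_ids

    def test_unpopulated_frame_rejected(self, square_geometry):
        frame = build_grid_frame(square_geometry(2, 2), 200.0)
        with pytest.raises(ValueError, match="not populated"):
            select_pure_pixels(frame)


def _pure_set(cells_by_class):
    records = [
        {"cell_id": i + 1, "row": r, "col": c, "class": cls, "proportion": 1.0}
        for i, (cls, (r, c)) in enumerate(
            (cls, rc) for cls, rcs in cells_by_class.items() for rc in rcs
        )
    ]
    return PurePixelSet(table=pd.DataFrame(records), t_desert=0.7, t_other=0.9)


class TestBandPairSeparability:
    def test_identical_bands_rank_last(self):
        rng = np.random.default_rng(0)
        base = rng.random((10, 1, 2, 2))
        series = np.concatenate([base, base, -base], axis=1)  # band2 == band1, band3 = -band1
        pure = _pure_set({Legend.DESERTIFIED: [(0, 0)], Legend.VEGETATION: [(1, 1)]})
        df = band_pair_separability(series, pure)
        first = df.iloc[0]
        assert {first.band_a, first.band_b} == {"band1", "band3"}
        assert first.total_r == pytest.approx(-2.0)  # anti-correlated in both classes
        last = df[~df.degenerate].iloc[-1]
        assert {last.band_a, last.band_b} == {"band1", "band2"}
        assert last.total_r == pytest.approx(2.0)

    def test_phenology_decorrelates_red_nir_pair(self):
        """Red flat for desert but dipping for vegetation while NIR pulses:
        the red/NIR pair separates classes better than red with a red-like twin."""
        t = np.arange(46)
        pulse = np.exp(-0.5 * ((t - 23) / 6) ** 2)
        red_desert, nir_desert = np.full(46, 0.4) + 0.001 * t, np.full(46, 0.3) + 0.001 * t
        red_veg = 0.1 - 0.05 * pulse
        nir_veg = 0.25 + 0.25 * pulse
        series = np.zeros((46, 3, 1, 2))
        series[:, 0, 0, 0], series[:, 1, 0, 0] = red_desert, nir_desert
        series[:, 2, 0, 0] = red_desert * 1.1
        series[:, 0, 0, 1], series[:, 1, 0, 1] = red_veg, nir_veg
        series[:, 2, 0, 1] = red_veg * 1.1 + 0.01
        pure = _pure_set({Legend.DESERTIFIED: [(0, 0)], Legend.VEGETATION: [(0, 1)]})
        df = band_pair_separability(series, pure, band_labels=["red", "nir", "red_twin"])
        top = df.iloc[0]
        assert {top.band_a, top.band_b} == {"red", "nir"}

    def test_constant_series_pair_flagged(self):
        series = np.zeros((10, 2, 1, 1))
        series[:, 0, 0, 0] = np.arange(10.0)
        series[:, 1, 0, 0] = 5.0  # constant
        pure = _pure_set({Legend.DESERTIFIED: [(0, 0)]})
        df = band_pair_separability(series, pure)
        assert bool(df.iloc[0].degenerate)
        assert np.isnan(df.iloc[0].total_r)


class TestTrainingSet:
    def test_masked_samples_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            TrainingSet(samples=np.array([[1.0, np.nan]]), labels=np.array([1]))

    def test_dataframe_roundtrip(self):
        ts = TrainingSet(samples=np.array([[1.0, 2.0]]), labels=np.array([1]),
                         provenance=["p0"])
        df = ts.to_dataframe()
        assert list(df.columns) == ["band1", "band2", "label", "provenance"]
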