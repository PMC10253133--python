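"""Smoothed neighbourhood features and the random-forest tissue classifier."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import box

from tmascreen.tissue_classifier import (
    FWHM_TO_SIGMA,
    RAW_FEATURES,
    ClassifierModel,
    TrainingRegion,
    add_smoothed_features,
    classify,
    compose_training_image,
    label_cells_by_annotations,
    train_classifier,
)


def cell_table(xy, feature, base=None):
    df = pd.DataFrame(
        {
            "x_um": [p[0] for p in xy],
            "y_um": [p[1] for p in xy],
            "nucleus_area_um2": feature,
        }
    )
    df["base_class"] = base if base is not None else "Negative"
    return df


class TestSmoothedFeatures:
    def test_isolated_cell_keeps_raw_value(self):
        df = add_smoothed_features(cell_table([(0, 0)], [5.0]), fwhm=25.0)
        assert df.loc[0, "smoothed_nucleus_area_um2"] == 5.0

    def test_coincident_identical_cells_unchanged(self):
        df = add_smoothed_features(cell_table([(1, 1), (1, 1)], [3.0, 3.0]))
        assert (df["smoothed_nucleus_area_um2"] == 3.0).all()

    def test_two_cell_closed_form_at_sigma(self):
        sigma = 25.0 / FWHM_TO_SIGMA
        df = add_smoothed_features(
            cell_table([(0.0, 0.0), (sigma, 0.0)], [0.0, 1.0]), fwhm=25.0
        )
        w = math.exp(-0.5)
        assert df.loc[0, "smoothed_nucleus_area_um2"] == pytest.approx(
            w / (1 + w), abs=1e-9
        )
        assert df.loc[1, "smoothed_nucleus_area_um2"] == pytest.approx(
            1 / (1 + w), abs=1e-9
        )

    def test_same_base_class_restriction(self):
        sigma = 25.0 / FWHM_TO_SIGMA
        df = add_smoothed_features(
            cell_table([(0.0, 0.0), (sigma, 0.0)], [0.0, 1.0],
                       base=["Negative", "Positive"]),
            fwhm=25.0, same_base_class=True,
        )
        # neighbours of the other base class are ignored entirely
        assert df.loc[0, "smoothed_nucleus_area_um2"] == 0.0
        assert df.loc[1, "smoothed_nucleus_area_um2"] == 1.0
        pooled = add_smoothed_features(
            cell_table([(0.0, 0.0), (sigma, 0.0)], [0.0, 1.0],
                       base=["Negative", "Positive"]),
            fwhm=25.0, same_base_class=False,
        )
        assert pooled.loc[0, "smoothed_nucleus_area_um2"] > 0.0

    def test_beyond_cutoff_not_pooled(self):
        sigma = 25.0 / FWHM_TO_SIGMA
        df = add_smoothed_features(
            cell_table([(0.0, 0.0), (3.5 * sigma, 0.0)], [0.0, 1.0])
        )
        assert df.loc[0, "smoothed_nucleus_area_um2"] == 0.0

    @given(st.integers(2, 12), st.integers(0, 1000))
    @settings(deadline=None, max_examples=30)
    def test_smoothing_is_convex_combination(self, n, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 40, (n, 2))
        vals = rng.uniform(-5, 5, n)
        df = add_smoothed_features(cell_table(list(map(tuple, xy)), vals))
        sm = df["smoothed_nucleus_area_um2"]
        assert (sm >= vals.min() - 1e-9).all()
        assert (sm <= vals.max() + 1e-9).all()

    def test_nan_feature_falls_back_to_raw(self):
        df = add_smoothed_features(
            cell_table([(0, 0), (1, 0)], [np.nan, 2.0])
        )
        # NaN neighbour ignored; the NaN cell averages over its finite
        # neighbour
        assert df.loc[1, "smoothed_nucleus_area_um2"] == 2.0
        assert df.loc[0, "smoothed_nucleus_area_um2"] == pytest.approx(2.0)


class TestComposeTrainingImage:
    def tile(self, value, size=100):
        img = np.full((size, size, 3), value, dtype=np.uint8)
        ann = [(box(10.0, 10.0, 40.0, 40.0), "Tumour")]
        return TrainingRegion(image=img, annotations=ann, pixel_size=2.0)

    def test_single_tile_passthrough(self):
        reg = self.tile(100)
        out = compose_training_image([reg])
        assert out is reg

    def test_fourteen_tile_montage_layout(self):
        regions = [self.tile(50 + i) for i in range(14)]
        out = compose_training_image(regions, gutter_um=50.0)
        ncols, nrows, gut = 4, 4, 25  # ceil(sqrt(14)), px gutter at 2 um/px
        assert out.image.shape == (
            nrows * 100 + (nrows - 1) * gut,
            ncols * 100 + (ncols - 1) * gut,
            3,
        )
        assert len(out.annotations) == 14

    def test_annotation_offsets_follow_placement(self):
        regions = [self.tile(60), self.tile(70)]
        out = compose_training_image(regions, gutter_um=50.0)
        (p0, _), (p1, _) = out.annotations
        # second tile sits one tile + gutter to the right (row-major)
        dx = p1.bounds[0] - p0.bounds[0]
        assert dx == pytest.approx(100 * 2.0 + 50.0)

    def test_mixed_pixel_sizes_rejected(self):
        a = self.tile(10)
        b = self.tile(10)
        b.pixel_size = 1.0
        with pytest.raises(ValueError, match="pixel size"):
            compose_training_image([a, b])


class TestLabelByAnnotations:
    def test_cells_inside_polygon_labelled(self):
        cells = cell_table([(20.0, 20.0), (80.0, 80.0)], [1.0, 1.0])
        labels = label_cells_by_annotations(
            cells, [(box(0, 0, 50, 50), "Stroma")]
        )
        assert labels.iloc[0] == "Stroma"
        assert pd.isna(labels.iloc[1])


def separable_training_frame(n_per_class=60, sd=1.0, gap=3.0, seed=0):
    """Feature table with two classes separated by ``gap`` SDs."""
    rng = np.random.default_rng(seed)
    rows = []
    for k, cls in enumerate(["NormalEpithelium", "Tumour"]):
        for _ in range(n_per_class):
            rows.append(
                {
                    "x_um": rng.uniform(0, 100),
                    "y_um": rng.uniform(0, 100),
                    "nucleus_area_um2": rng.normal(30 + gap * sd * 10 * k, sd * 10),
                    "nucleus_circularity": rng.normal(0.9 - 0.2 * k, 0.02),
                    "nucleus_h_od_mean": rng.normal(0.5 + 0.2 * k, 0.05),
                    "nucleus_dab_od_mean": rng.normal(0.3, 0.05),
                    "cell_dab_od_mean": rng.normal(0.2, 0.05),
                    "cytoplasm_dab_od_mean": rng.normal(0.1, 0.05),
                    "base_class": "Positive",
                }
            )
    df = pd.DataFrame(rows)
    labels = pd.Series(
        ["NormalEpithelium"] * n_per_class + ["Tumour"] * n_per_class
    )
    return add_smoothed_features(df), labels


class TestTrainClassifier:
    def test_separable_classes_learned(self):
        cells, labels = separable_training_frame()
        model = train_classifier(cells, labels, seed=0)
        pred = classify(model, cells)["tissue_class"]
        assert (pred.to_numpy() == labels.to_numpy()).mean() == 1.0
        assert model.oob_accuracy >= 0.95

    def test_permuted_labels_score_at_chance(self):
        cells, labels = separable_training_frame(n_per_class=100)
        rng = np.random.default_rng(1)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()))
        model = train_classifier(cells, shuffled, seed=0)
        p0 = 0.5
        se = math.sqrt(p0 * (1 - p0) / len(labels))
        assert abs(model.oob_accuracy - p0) < 3 * se + 0.05

    def test_same_seed_reproduces_predictions(self):
        cells, labels = separable_training_frame()
        a = train_classifier(cells, labels, seed=3)
        b = train_classifier(cells, labels, seed=3)
        pd.testing.assert_series_equal(
            classify(a, cells)["tissue_class"], classify(b, cells)["tissue_class"]
        )

    def test_single_class_rejected(self):
        cells, labels = separable_training_frame()
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(cells, pd.Series(["Tumour"] * len(cells)), seed=0)

    def test_small_class_warns(self):
        cells, labels = separable_training_frame(n_per_class=60)
        labels = labels.copy()
        labels.iloc[:55] = "Tumour"  # leaves 5 NormalEpithelium
        with pytest.warns(UserWarning, match="training cells"):
            train_classifier(cells, labels, seed=0)


class TestClassify:
    def test_marker_status_never_altered(self):
        cells, labels = separable_training_frame()
        model = train_classifier(cells, labels, seed=0)
        cells = cells.copy()
        cells["base_class"] = ["Positive", "Negative"] * (len(cells) // 2)
        out = classify(model, cells)
        assert (out["base_class"] == cells["base_class"]).all()

    def test_empty_table_gives_empty_result(self):
        cells, labels = separable_training_frame()
        model = train_classifier(cells, labels, seed=0)
        out = classify(model, cells.iloc[0:0])
        assert out.empty and "tissue_class" in out.columns

    def test_missing_feature_named_in_error(self):
        cells, labels = separable_training_frame()
        model = train_classifier(cells, labels, seed=0)
        broken = cells.drop(columns=["nucleus_circularity"])
        with pytest.raises(ValueError, match="nucleus_circularity"):
            classify(model, broken)


class TestSerialisation:
    def test_save_load_predicts_identically(self, tmp_path):
        cells, labels = separable_training_frame()
        model = train_classifier(cells, labels, seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = ClassifierModel.load(path)
        assert loaded.feature_names == model.feature_names
        assert loaded.seed == model.seed
        pd.testing.assert_series_equal(
            classify(loaded, cells)["tissue_class"],
            classify(model, cells)["tissue_class"],
        )
        assert path.with_suffix(".joblib.json").exists()
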