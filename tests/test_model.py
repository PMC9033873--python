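"""Feature extraction, series-aware splitting, and head training."""

import numpy as np
import pytest

from brightwell.augment import AugmentationPolicy, identity_policy
from brightwell.model import (
    DatasetSplit,
    TrainConfig,
    builtin_extract,
    builtin_extractor,
    fit_head_on_features,
    kfold_series_split,
    load_model,
    predict_viability,
    pretrained_extract,
    save_model,
    series_key,
    split_dataset,
    train_head,
)
from brightwell.simulate import PlateImage, simulate_plate, BUILTIN_PROFILES, PlateDesign


class TestBuiltinExtract:
    def test_constant_image_statistics(self):
        img = PlateImage(np.full((32, 32, 3), 0.5))
        vec = builtin_extract(img, tiles_per_side=2)
        # 4 tile means, 4 tile SDs, 4 tile gradients, 32-bin histogram
        assert len(vec) == 3 * 4 + 32
        assert np.allclose(vec[:4], 0.5)
        assert np.allclose(vec[4:12], 0.0)
        hist = vec[12:]
        assert hist.sum() == pytest.approx(1.0)
        # all mass in the single bin containing the 0.5 luminance
        assert hist.max() == 1.0
        assert np.argmax(hist) in (15, 16)

    def test_default_dimension_800(self):
        img = PlateImage(np.random.default_rng(0).random((64, 64, 3)))
        assert len(builtin_extract(img)) == 3 * 16**2 + 32

    def test_image_smaller_than_grid_rejected(self):
        img = PlateImage(np.zeros((8, 8, 3)))
        with pytest.raises(ValueError):
            builtin_extract(img, tiles_per_side=16)

    def test_deterministic(self, rng):
        img = PlateImage(rng.random((48, 48, 3)))
        assert np.array_equal(builtin_extract(img), builtin_extract(img))

    def test_density_signal_dominates_render_noise(self, small_design):
        """Feature distance between sparse and dense wells exceeds distance
        between independent renders at equal density (10 seeded renders)."""
        from brightwell.simulate import render_well, NoiseSpec

        prof = BUILTIN_PROFILES["lineA"]
        ext = builtin_extractor()
        noise = NoiseSpec()

        def feats(n_cells, seed):
            rng = np.random.Generator(np.random.PCG64(seed))
            return ext(render_well(prof, n_cells, 96, 112, noise, rng))

        cross, within = [], []
        for s in range(10):
            f20, f200 = feats(20, s), feats(200, s + 100)
            g20 = feats(20, s + 200)
            cross.append(np.linalg.norm(f20 - f200))
            within.append(np.linalg.norm(f20 - g20))
        assert np.mean(cross) > np.mean(within)
        assert min(cross) > 0


class TestPretrainedPlugin:
    def test_unavailable_backbone_raises_not_silently_falls_back(self):
        img = PlateImage(np.zeros((32, 32, 3)))
        with pytest.raises(RuntimeError, match="not installed|no pretrained"):
            pretrained_extract(img, "mobilenet_v2")


class TestSplits:
    def test_standard_split_counts_198_66(self, labels_only_plate):
        split = split_dataset(labels_only_plate, test_series=6, seed=0)
        assert len(split.test_ids) == 66
        assert len(split.train_ids) + len(split.validation_ids) == 198

    def test_no_series_straddles_split(self, labels_only_plate):
        split = split_dataset(labels_only_plate, test_series=6, seed=1)
        by_id = {r.well_id: r for r in labels_only_plate}
        groups = {
            "train": {series_key(by_id[i]) for i in split.train_ids},
            "val": {series_key(by_id[i]) for i in split.validation_ids},
            "test": {series_key(by_id[i]) for i in split.test_ids},
        }
        assert not groups["train"] & groups["test"]
        assert not groups["val"] & groups["test"]
        assert not groups["train"] & groups["val"]

    def test_every_test_series_is_complete_ladder(self, labels_only_plate):
        split = split_dataset(labels_only_plate, test_series=6, seed=2)
        by_id = {r.well_id: r for r in labels_only_plate}
        series = {}
        for i in split.test_ids:
            series.setdefault(series_key(by_id[i]), set()).add(
                by_id[i].concentration_um
            )
        for concs in series.values():
            assert len(concs) == 11

    def test_zero_test_series(self, labels_only_plate):
        split = split_dataset(labels_only_plate, test_series=0, seed=0)
        assert split.test_ids == ()
        assert len(split.train_ids) + len(split.validation_ids) == 264

    def test_too_many_test_series_rejected(self, labels_only_plate):
        with pytest.raises(ValueError):
            split_dataset(labels_only_plate, test_series=25)

    def test_same_seed_same_split(self, labels_only_plate):
        a = split_dataset(labels_only_plate, test_series=6, seed=9)
        b = split_dataset(labels_only_plate, test_series=6, seed=9)
        assert a == b

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(("a", "b"), ("b",), ())


class TestKfold:
    def test_fourfold_partitions_all_wells(self, labels_only_plate):
        folds = kfold_series_split(labels_only_plate, k=4, seed=0)
        all_ids = {r.well_id for r in labels_only_plate}
        test_union = set()
        for f in folds:
            assert len(f.test_ids) == 66  # 6 series of 11
            assert not test_union & set(f.test_ids)
            test_union |= set(f.test_ids)
        assert test_union == all_ids

    def test_k_below_two_rejected(self, labels_only_plate):
        with pytest.raises(ValueError):
            kfold_series_split(labels_only_plate, k=1)

    def test_same_seed_same_folds(self, labels_only_plate):
        a = kfold_series_split(labels_only_plate, k=4, seed=3)
        b = kfold_series_split(labels_only_plate, k=4, seed=3)
        assert a == b


def affine_feature_problem(n=120, d=12, seed=0):
    """Identifiable sanity fixture: features are exact affine functions of
    the label, so a tiny head must drive validation MSE to ~0."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 2, n)
    A = rng.normal(size=d)
    b = rng.normal(size=d)
    x = y[:, None] * A[None, :] + b[None, :]
    return x[: n // 2], y[: n // 2], x[n // 2:], y[n // 2:]


class TestHeadTraining:
    def test_affine_fixture_reaches_tiny_validation_mse(self):
        xt, yt, xv, yv = affine_feature_problem()
        head, hist = fit_head_on_features(
            xt, yt, xv, yv, TrainConfig(max_epochs=200, patience=200), seed=0
        )
        assert min(v for _, v in hist) < 1e-3

    def test_training_r2_above_099_on_fixture(self):
        from brightwell.evaluate import linear_agreement

        xt, yt, xv, yv = affine_feature_problem()
        head, _ = fit_head_on_features(xt, yt, xv, yv, seed=0)
        pred = head.forward(xt)
        assert linear_agreement(yt, pred).r_squared > 0.99

    def test_identical_seeds_identical_weights(self):
        xt, yt, xv, yv = affine_feature_problem()
        cfg = TrainConfig(max_epochs=50, patience=50)
        h1, _ = fit_head_on_features(xt, yt, xv, yv, cfg, seed=4)
        h2, _ = fit_head_on_features(xt, yt, xv, yv, cfg, seed=4)
        assert np.array_equal(h1.w1, h2.w1)
        assert np.array_equal(h1.w2, h2.w2)
        assert h1.b2 == h2.b2

    def test_non_finite_loss_aborts_with_diagnostics(self):
        xt, yt, xv, yv = affine_feature_problem()
        # absurd learning rate forces divergence to overflow
        cfg = TrainConfig(max_epochs=50, learning_rate=1e120)
        with pytest.raises(RuntimeError, match="non-finite"):
            fit_head_on_features(xt, yt, xv, yv, cfg, seed=0)

    def test_empty_training_set_rejected(self, small_plate):
        records, _ = small_plate
        split = DatasetSplit((), (records[0].well_id,), ())
        with pytest.raises(ValueError, match="training"):
            train_head(records, split, builtin_extractor(), AugmentationPolicy())


class TestEndToEndSmall:
    @pytest.fixture(scope="class")
    def trained(self, small_plate):
        records, _ = small_plate
        split = split_dataset(records, test_series=0, validation_fraction=0.5, seed=0)
        ext = builtin_extractor(tiles_per_side=4)
        cfg = TrainConfig(max_epochs=60, patience=60, views_per_image=4)
        model = train_head(records, split, ext, AugmentationPolicy(),
                           config=cfg, seed=0)
        return records, ext, model

    def test_training_is_seed_reproducible(self, small_plate, trained):
        records, ext, model = trained
        split = split_dataset(records, test_series=0, validation_fraction=0.5, seed=0)
        cfg = TrainConfig(max_epochs=60, patience=60, views_per_image=4)
        again = train_head(records, split, ext, AugmentationPolicy(),
                           config=cfg, seed=0)
        assert np.array_equal(model.head.w1, again.head.w1)
        assert model.head.b2 == again.head.b2

    def test_predictions_clipped_and_duplicates_identical(self, trained):
        records, ext, model = trained
        preds = predict_viability(model, [records[0], records[0]], ext)
        assert len(preds) == 2
        assert preds["predicted_viability"].iloc[0] == preds["predicted_viability"].iloc[1]
        assert (preds["predicted_viability"].between(0, 2)).all()

    def test_raw_prediction_retained(self, trained):
        records, ext, model = trained
        preds = predict_viability(model, records[:5], ext)
        clipped = np.clip(preds["predicted_raw"], 0, 2)
        assert np.allclose(clipped, preds["predicted_viability"])

    def test_dimension_mismatch_rejected(self, trained):
        records, _, model = trained
        wrong = builtin_extractor(tiles_per_side=8)
        with pytest.raises(ValueError, match="dimension"):
            predict_viability(model, records[:2], wrong)

    def test_missing_image_yields_error_entry_not_crash(self, trained):
        import dataclasses

        records, ext, model = trained
        bad = dataclasses.replace(records[0], image_path="does/not/exist.png")
        preds = predict_viability(model, [bad, records[1]], ext)
        assert preds["error"].iloc[0] != ""
        assert preds["error"].iloc[1] == ""
        assert np.isnan(preds["predicted_viability"].iloc[0])

    def test_model_round_trip_via_npz(self, trained, tmp_path):
        records, ext, model = trained
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.extractor_name == model.extractor_name
        assert np.array_equal(back.head.w1, model.head.w1)
        p1 = predict_viability(model, records[:3], ext)
        p2 = predict_viability(back, records[:3], ext)
        assert np.allclose(p1["predicted_raw"], p2["predicted_raw"])
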