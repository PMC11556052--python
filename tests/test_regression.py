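import numpy as np
import pytest

from craniage.phantom import GeometryError, Volume3D
from craniage.regression import (
    RegressorConfig,
    TrainedRegressor,
    augment,
    evaluate,
    split_dataset,
    standardize_roi,
    train_regressor,
)
from craniage.roi import ROIBox


def toy_cohort(n, rng, edge=12):
    """Cubes whose mean intensity encodes age exactly (noiseless affine)."""
    items = []
    for i in range(n):
        v = rng.uniform(0.1, 0.9)
        cube = np.full((edge, edge, edge), v)
        age = 17 + 62 * (v - 0.1) / 0.8
        items.append((f"T{i:03d}", cube, age))
    return items


TOY_CFG = RegressorConfig(epochs=40, input_edge=12, channels=(4, 8),
                          learning_rate=0.02, batch_size=16,
                          augment_rotation=False, augment_inversion=False,
                          augment_mirroring=False, seed=2)


class TestStandardize:
    @pytest.fixture(scope="class")
    def volume(self):
        rng = np.random.default_rng(0)
        return Volume3D(rng.uniform(0, 255, size=(40, 40, 40)).astype(np.float32),
                        spacing=1.0)

    def test_matching_edge_is_identity(self, volume):
        box = ROIBox(4, 20, 4, 20, 4, 20)
        cube = standardize_roi(volume, box, edge=16)
        crop = volume.intensities[4:20, 4:20, 4:20] / 255.0
        assert np.allclose(cube, crop, atol=1e-12)

    def test_constant_crop_stays_constant(self):
        vol = Volume3D(np.full((40, 40, 40), 80.0, dtype=np.float32), spacing=1.0)
        cube = standardize_roi(vol, ROIBox(0, 30, 0, 30, 0, 30), edge=16)
        assert np.allclose(cube, 80.0 / 255.0)

    def test_default_edge_is_64(self):
        assert RegressorConfig().input_edge == 64

    def test_output_in_unit_range(self, volume):
        cube = standardize_roi(volume, ROIBox(0, 33, 0, 40, 0, 21), edge=16)
        assert cube.min() >= 0.0 and cube.max() <= 1.0


class TestAugment:
    def test_all_toggles_off_is_identity(self, rng):
        cube = rng.uniform(size=(8, 8, 8))
        cfg = RegressorConfig(augment_rotation=False, augment_inversion=False,
                              augment_mirroring=False)
        assert np.array_equal(augment(cube, cfg, rng), cube)

    def test_mirror_twice_is_identity(self, rng):
        cube = rng.uniform(size=(8, 8, 8))
        flipped = np.flip(cube, axis=1)
        assert np.array_equal(np.flip(flipped, axis=1), cube)

    def test_inversion_of_constant_cube(self):
        cfg = RegressorConfig(augment_rotation=False, augment_mirroring=False,
                              augment_inversion=True)
        cube = np.full((6, 6, 6), 0.3)
        rng = np.random.default_rng(1)
        outs = {round(float(augment(cube, cfg, rng).mean()), 6) for _ in range(20)}
        assert outs <= {0.3, 0.7} and 0.7 in outs

    def test_augmentation_preserves_shape_and_range(self, rng):
        cube = rng.uniform(size=(8, 8, 8))
        out = augment(cube, RegressorConfig(), rng)
        assert out.shape == cube.shape
        assert out.min() >= 0 and out.max() <= 1


class TestSplit:
    def test_study_split_223_into_178_45(self):
        train, test = split_dataset(list(range(223)), (4, 1), seed=0)
        assert (len(train), len(test)) == (178, 45)
        assert set(train).isdisjoint(test)

    def test_same_seed_same_split(self):
        a = split_dataset(list(range(50)), (4, 1), seed=9)
        b = split_dataset(list(range(50)), (4, 1), seed=9)
        assert a == b

    def test_even_split(self):
        train, test = split_dataset(list(range(10)), (1, 1), seed=0)
        assert (len(train), len(test)) == (5, 5)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1], (4, 1), seed=0)


class TestRegressor:
    @pytest.fixture(scope="class")
    def toy_model(self):
        rng = np.random.default_rng(4)
        items = toy_cohort(80, rng)
        train, test = split_dataset(items, (4, 1), seed=1)
        model = train_regressor([c for _, c, _ in train], [a for _, _, a in train],
                                TOY_CFG)
        return model, train, test

    def test_learns_noiseless_affine_signal(self, toy_model):
        model, train, test = toy_model
        report = evaluate(model, train, test)
        assert report.rmse_test <= 2.0

    def test_persistence_round_trip(self, toy_model, tmp_path):
        model, _, test = toy_model
        p = tmp_path / "reg.npz"
        model.save(p)
        back = TrainedRegressor.load(p)
        cubes = [c for _, c, _ in test]
        assert np.allclose(back.predict(cubes), model.predict(cubes))
        assert back.config == model.config

    def test_target_normalization_changes_little_on_toy_signal(self):
        rng = np.random.default_rng(5)
        items = toy_cohort(80, rng)
        train, test = split_dataset(items, (4, 1), seed=1)
        import dataclasses
        errs = {}
        for norm in (False, True):
            cfg = dataclasses.replace(TOY_CFG, normalize_target=norm)
            m = train_regressor([c for _, c, _ in train], [a for _, _, a in train],
                                cfg)
            errs[norm] = evaluate(m, train, test).rmse_test
        assert errs[True] <= 2.0 and errs[False] <= 2.0

    def test_mirrored_input_prediction_stays_within_jitter(self):
        """With mirroring in the training augmentations, a mirrored cube
        predicts within the model's own residual error bound."""
        rng = np.random.default_rng(6)
        items = []
        for i in range(60):
            v = rng.uniform(0.1, 0.9)
            cube = np.full((12, 12, 12), v)
            cube += rng.uniform(0, 0.05, size=cube.shape)
            items.append((f"M{i}", np.clip(cube, 0, 1), 17 + 62 * (v - 0.1) / 0.8))
        import dataclasses
        cfg = dataclasses.replace(TOY_CFG, augment_mirroring=True, epochs=40)
        model = train_regressor([c for _, c, _ in items], [a for _, _, a in items],
                                cfg)
        report = evaluate(model, items[:50], items[50:])
        jitter = max(report.rmse_train, 1.0)
        for _, cube, _ in items[:10]:
            d = abs(model.predict([cube])[0]
                    - model.predict([np.flip(cube, axis=0)])[0])
            assert d <= 2 * jitter

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            train_regressor([np.zeros((12, 12, 12))], [30.0], TOY_CFG)


class TestEvaluate:
    class _Stub:
        def __init__(self, fn):
            self.fn = fn

        def predict(self, cubes):
            return np.array([self.fn(c) for c in cubes])

    @staticmethod
    def items(ages):
        return [(f"S{i}", np.full((4, 4, 4), a / 100), float(a))
                for i, a in enumerate(ages)]

    def test_perfect_predictions_zero_error(self):
        items = self.items([20, 30, 40, 50])
        model = self._Stub(lambda c: float(c[0, 0, 0] * 100))
        rep = evaluate(model, items[:2], items[2:])
        assert rep.rmse_train == 0.0 and rep.rmse_test == 0.0

    def test_constant_mean_predictor_error_equals_population_sd(self):
        ages = [20.0, 30.0, 40.0, 50.0]
        items = self.items(ages)
        mean = float(np.mean(ages))
        model = self._Stub(lambda c: mean)
        rep = evaluate(model, items, items)
        assert rep.rmse_train == pytest.approx(np.std(ages))

    def test_report_row_bookkeeping(self):
        items = self.items([20, 30, 40, 50, 60])
        model = self._Stub(lambda c: 35.0)
        rep = evaluate(model, items[:3], items[3:])
        assert len(rep.records) == 5
        assert rep.records["split"].value_counts().to_dict() == {"train": 3, "test": 2}
        assert rep.summary()["n_test"] == 2
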