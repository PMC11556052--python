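import numpy as np
import pytest

from craniage.phantom import GeometryError, LandmarkAnnotation, Volume3D
from craniage.roi import (
    AggregationError,
    ConfusionMatrix,
    SliceClassifierConfig,
    aggregate_roi,
    confusion,
    landmark_roi,
    make_slice_dataset,
    precision_recall,
    train_slice_classifier,
)


class TestLandmarkROI:
    def test_printed_formula_substitution(self):
        ann = LandmarkAnnotation(atlas_z_min=40, atlas_z_max=80,
                                 dens_apex=(256, 300, 75))
        box = landmark_roi(ann, (512, 512, 200), half_width=64)
        assert (box.x0, box.x1) == (192, 320)
        assert (box.y0, box.y1) == (236, 364)
        assert (box.z0, box.z1) == (40, 80)

    def test_near_border_clipping(self, caplog):
        ann = LandmarkAnnotation(atlas_z_min=5, atlas_z_max=20,
                                 dens_apex=(10, 60, 18))
        with caplog.at_level("WARNING", logger="craniage.roi"):
            box = landmark_roi(ann, (128, 128, 64), half_width=64)
        assert box.x0 == 0 and box.x1 == 74
        assert "clipped" in caplog.text

    def test_degenerate_half_width_rejected(self):
        ann = LandmarkAnnotation(atlas_z_min=5, atlas_z_max=20,
                                 dens_apex=(10, 60, 18))
        with pytest.raises(GeometryError):
            landmark_roi(ann, (128, 128, 64), half_width=0)


class TestSliceDataset:
    @pytest.fixture(scope="class")
    def volume(self):
        return Volume3D(np.zeros((40, 48, 56), dtype=np.float32) + 5.0, spacing=1.0)

    def test_one_sample_per_slice_per_projection(self, volume, mini_fixture):
        from craniage.roi import ROIBox
        box = ROIBox(4, 10, 6, 12, 8, 16)
        samples = make_slice_dataset(volume, box)
        assert len(samples) == 40 + 48 + 56
        v = mini_fixture.volumes[0]
        assert len(make_slice_dataset(v, mini_fixture.boxes[0])) == 3 * 48

    def test_axial_positive_count_matches_z_extent(self, volume):
        from craniage.roi import ROIBox
        box = ROIBox(0, 40, 0, 48, 10, 30)
        samples = make_slice_dataset(volume, box)
        axial_pos = [s for s in samples if s.projection == "axial" and s.label == 1]
        assert len(axial_pos) == 20
        assert {s.index for s in axial_pos} == set(range(10, 30))

    def test_full_volume_box_saturates_labels(self, volume):
        from craniage.roi import ROIBox
        box = ROIBox(0, 40, 0, 48, 0, 56)
        assert all(s.label == 1 for s in make_slice_dataset(volume, box))


class TestAggregateROI:
    def test_hand_computed_example(self):
        triples = ([("axial", i, 1) for i in (10, 12, 14)]
                   + [("sagittal", 100, 1), ("coronal", 200, 1)]
                   + [("axial", 3, 0), ("sagittal", 5, 0)])
        summary, box = aggregate_roi(triples, (512, 512, 300), half_width=64)
        assert summary.Zm == pytest.approx(12.0)
        assert summary.z_std == pytest.approx(1.632993, abs=1e-5)
        assert summary.Xm == 100 and summary.Ym == 200
        assert (box.z0, box.z1) == (10, 14)  # round(12 +/- 1.633)
        assert (box.x0, box.x1) == (36, 164)

    def test_symmetric_run_centres_on_midpoint(self):
        triples = ([("axial", i, 1) for i in range(20, 31)]
                   + [("sagittal", 50, 1), ("coronal", 50, 1)])
        summary, _ = aggregate_roi(triples, (128, 128, 64))
        assert summary.Zm == pytest.approx(25.0)

    def test_insufficient_positives_names_projection(self):
        with pytest.raises(AggregationError, match="axial"):
            aggregate_roi([("axial", 5, 1), ("sagittal", 1, 1), ("coronal", 1, 1)],
                          (64, 64, 64))
        with pytest.raises(AggregationError, match="coronal"):
            aggregate_roi([("axial", 5, 1), ("axial", 7, 1), ("sagittal", 1, 1)],
                          (64, 64, 64))

    def test_truth_labels_recover_z_midpoint_and_overlap(self, mini_fixture):
        """With perfect labels, Zm sits within one voxel of the true box's Z
        midpoint and the aggregated Z band overlaps the truth (Dice >= 0.5)."""
        for v, box in zip(mini_fixture.volumes, mini_fixture.boxes):
            samples = make_slice_dataset(v, box)
            summary, agg = aggregate_roi(samples, v.shape, half_width=13)
            mid = (box.z0 + box.z1 - 1) / 2
            assert abs(summary.Zm - mid) <= 1.0
            inter = max(0, min(agg.z1, box.z1) - max(agg.z0, box.z0))
            dice = 2 * inter / ((agg.z1 - agg.z0) + (box.z1 - box.z0))
            assert dice >= 0.5


class TestConfusion:
    def test_perfect_predictions(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert precision_recall(cm) == (1.0, 1.0)

    def test_direct_ratio_example(self):
        cm = ConfusionMatrix(tp=38, fp=62, tn=0, fn=1)
        p, r = precision_recall(cm)
        assert p == pytest.approx(0.38)
        assert r == pytest.approx(38 / 39)

    def test_no_positive_predictions_sentinel(self):
        cm = confusion([0, 0, 0], [0, 1, 1])
        p, r = precision_recall(cm)
        assert np.isnan(p) and r == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])

    def test_counts_match_brute_force_recount(self, rng):
        pred = rng.integers(0, 2, size=500)
        true = rng.integers(0, 2, size=500)
        cm = confusion(pred, true)
        assert cm.total == 500
        tp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 1)
        fp = sum(1 for p, t in zip(pred, true) if p == 1 and t == 0)
        fn = sum(1 for p, t in zip(pred, true) if p == 0 and t == 1)
        assert (cm.tp, cm.fp, cm.fn) == (tp, fp, fn)
        p, r = precision_recall(cm)
        assert p == pytest.approx(tp / (tp + fp))
        assert r == pytest.approx(tp / (tp + fn))


class TestClassifierTraining:
    @staticmethod
    def blob_samples(n, rng, size=24):
        from craniage.roi import SliceSample
        samples = []
        for i in range(n):
            img = rng.normal(20, 5, size=(size, size))
            label = int(i % 2 == 0)
            if label:
                x0, y0 = rng.integers(6, size - 6, size=2)
                img[x0 - 3 : x0 + 3, y0 - 3 : y0 + 3] += 120
            samples.append(SliceSample(np.clip(img, 0, 255), "axial", i, label))
        return samples

    def test_separable_blobs_reach_high_training_accuracy(self, rng):
        samples = self.blob_samples(240, rng)
        cfg = SliceClassifierConfig(input_resize=24, learning_rate=0.01,
                                    epochs=10, batch_size=32, seed=1)
        clf = train_slice_classifier(samples, cfg)
        pred = clf.predict([s.image for s in samples])
        acc = np.mean(pred == [s.label for s in samples])
        assert acc >= 0.99

    def test_training_is_deterministic(self, rng):
        samples = self.blob_samples(64, rng)
        cfg = SliceClassifierConfig(input_resize=24, learning_rate=0.01,
                                    epochs=2, batch_size=32, seed=3)
        l1 = train_slice_classifier(samples, cfg).log.final_loss
        l2 = train_slice_classifier(samples, cfg).log.final_loss
        assert l1 == l2

    def test_single_class_input_rejected(self, rng):
        from craniage.roi import SliceSample
        samples = [SliceSample(np.zeros((8, 8)), "axial", i, 0) for i in range(10)]
        with pytest.raises(ValueError):
            train_slice_classifier(samples, SliceClassifierConfig(input_resize=8))
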