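"""Synthetic generators and trainer doubles."""

import numpy as np
import pytest

from afcs.preprocess import MaskRange, color_range_mask
from afcs.synthetic import (
    ScenarioCoverageError,
    ScriptedLossTable,
    SyntheticDatasetSpec,
    make_blob_dataset,
    make_green_plant_image,
    make_tiny_cnn,
    nearest_prototype_accuracy,
    scripted_trainer,
)


class TestBlobDataset:
    def test_seed_reproducibility_is_byte_exact(self):
        spec = SyntheticDatasetSpec(
            n_classes=4, n_per_class=50, image_size=32,
            signal_strength=140.0, noise_sd=25.0, seed=7,
        )
        a, b = make_blob_dataset(spec), make_blob_dataset(spec)
        np.testing.assert_array_equal(a.images, b.images)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.images.tobytes() == b.images.tobytes()

    def test_noiseless_prototypes_classify_perfectly(self):
        spec = SyntheticDatasetSpec(
            n_classes=3, n_per_class=10, image_size=16,
            signal_strength=120.0, noise_sd=0.0, seed=1,
        )
        assert nearest_prototype_accuracy(make_blob_dataset(spec)) == 1.0

    def test_zero_signal_is_chance_level(self):
        spec = SyntheticDatasetSpec(
            n_classes=4, n_per_class=100, image_size=16,
            signal_strength=0.0, noise_sd=30.0, seed=2,
        )
        acc = nearest_prototype_accuracy(make_blob_dataset(spec))
        # 400 draws at p=0.25: allow ~4 binomial standard errors
        assert abs(acc - 0.25) < 4 * np.sqrt(0.25 * 0.75 / 400)

    def test_stratified_splits_partition_the_set(self):
        dataset = make_blob_dataset(SyntheticDatasetSpec(seed=3))
        splits = dataset.splits((0.7, 0.15, 0.15))
        total = sum(len(y) for _, y in splits.values())
        assert total == len(dataset.labels)
        for _, y in splits.values():
            assert len(np.unique(y)) == dataset.spec.n_classes

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(n_classes=1)
        with pytest.raises(ValueError):
            SyntheticDatasetSpec(image_size=4)


class TestGreenPlantImage:
    @pytest.mark.parametrize("colorspace", ["rgb", "hsv"])
    @pytest.mark.parametrize("fraction", [0.0, 0.3, 1.0])
    def test_mask_recovers_ground_truth_exactly(self, colorspace, fraction):
        mask_range = MaskRange(colorspace=colorspace)
        img, truth = make_green_plant_image(
            seed=13, green_fraction=fraction, size=24, mask_range=mask_range
        )
        masked, kept = color_range_mask(img, mask_range, return_mask=True)
        np.testing.assert_array_equal(kept, truth)
        assert kept.sum() == int(round(fraction * 24 * 24))
        if fraction == 1.0:
            np.testing.assert_array_equal(masked, img)
        if fraction == 0.0:
            assert masked.sum() == 0

    def test_generator_is_pure_function_of_seed(self):
        a = make_green_plant_image(5, 0.4, size=16)
        b = make_green_plant_image(5, 0.4, size=16)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_green_plant_image(0, 1.5)


class TestScriptedTrainer:
    def test_replays_columns_and_positions(self):
        trainer = scripted_trainer({"A": [0.5, 0.4, 0.3], "B": [0.9, 0.8]})
        assert trainer.train_one_epoch() == 0.5
        token = trainer.snapshot()
        assert trainer.train_one_epoch() == 0.4
        trainer.set_activation("B")
        assert trainer.train_one_epoch() == 0.9
        trainer.restore(token)
        assert trainer.current_epoch == 1
        assert trainer.active_activation == "A"
        assert trainer.train_one_epoch() == 0.4  # exact replay

    def test_missing_cell_is_a_coverage_error(self):
        trainer = scripted_trainer({"A": [0.5]})
        trainer.train_one_epoch()
        with pytest.raises(ScenarioCoverageError):
            trainer.train_one_epoch()
        with pytest.raises(ScenarioCoverageError):
            trainer.set_activation("Z")

    def test_hold_last_plateaus_instead_of_failing(self):
        trainer = scripted_trainer({"A": [0.5, 0.4]}, hold_last=True)
        losses = [trainer.train_one_epoch() for _ in range(4)]
        assert losses == [0.5, 0.4, 0.4, 0.4]

    def test_probe_losses_prepend_to_columns(self):
        table = ScriptedLossTable(
            columns={"A": [0.4]}, probe_losses={"A": 0.9}
        )
        assert table.columns["A"] == (0.9, 0.4)

    def test_csv_round_trip(self, tmp_path):
        table = ScriptedLossTable(columns={"A": [0.5, 0.4], "B": [0.7]})
        path = tmp_path / "table.csv"
        table.to_csv(path)
        again = ScriptedLossTable.from_csv(path)
        assert again.columns == table.columns


class TestTinyCNNContract:
    def test_snapshot_restore_is_bit_exact(self, small_cnn, probe_batch):
        before = small_cnn.evaluate("val")
        token = small_cnn.snapshot()
        for _ in range(3):
            small_cnn.train_one_epoch()
        assert small_cnn.evaluate("val") != before
        small_cnn.restore(token)
        after = small_cnn.evaluate("val")
        assert after == before
        np.testing.assert_array_equal(
            small_cnn.predict_proba(probe_batch), small_cnn.predict_proba(probe_batch)
        )

    def test_restore_also_rewinds_data_order(self, small_cnn):
        token = small_cnn.snapshot()
        first = [small_cnn.train_one_epoch() for _ in range(2)]
        small_cnn.restore(token)
        again = [small_cnn.train_one_epoch() for _ in range(2)]
        assert first == again

    def test_parameter_budget_and_site_registry(self, small_cnn):
        assert small_cnn.n_parameters() <= 50_000
        assert [site.label for site in small_cnn.activation_sites] == [
            "block1", "block2",
        ]

    def test_learns_above_chance_within_five_epochs(self, small_blob_dataset):
        trainer = make_tiny_cnn(n_classes=3, seed=11, dataset=small_blob_dataset)
        for _ in range(5):
            trainer.train_one_epoch()
        # chance is 1/3 on this 3-class set
        assert trainer.last_epoch_metrics["val_accuracy"] > 1.0 / 3.0

    def test_default_dataset_is_reproducible(self):
        a = make_tiny_cnn(n_classes=4, seed=9)
        b = make_tiny_cnn(n_classes=4, seed=9)
        la = a.train_one_epoch()
        lb = b.train_one_epoch()
        assert la == lb
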