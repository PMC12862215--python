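"""Loss masking, batch stratification, schedule mechanics, learnability."""

import numpy as np
import pytest

from orfcall import io as tio
from orfcall.model import ModelConfig, build_model
from orfcall.records import EncodedSample, NONE
from orfcall.simulate import SynthConfig, generate_transcriptome
from orfcall.train import (PlateauController, TrainConfig, masked_cross_entropy,
                           stratified_batches, train)


def _samples(n_coding, n_noncoding, length=10):
    out = []
    for i in range(n_coding + n_noncoding):
        biotype = "coding" if i < n_coding else "noncoding"
        out.append(
            EncodedSample(
                transcript_id=f"t{i}",
                tokens=np.ones(length, dtype=np.int8),
                labels=np.full(length, NONE, dtype=np.int8),
                valid_length=length,
                biotype=biotype,
            )
        )
    return out


class TestStratifiedBatches:
    def test_every_sample_once(self):
        samples = _samples(13, 7)
        batches = stratified_batches(samples, 4, seed=0)
        flat = sorted(i for b in batches for i in b)
        assert flat == list(range(20))

    def test_proportionality_bound(self):
        samples = _samples(80, 20)
        batches = stratified_batches(samples, 4, seed=1)
        global_frac = 0.8
        for batch in batches:
            frac = sum(samples[i].biotype == "coding" for i in batch) / len(batch)
            assert abs(frac - global_frac) <= 1 / 4 + 1e-12

    def test_all_coding_plain_shuffle(self):
        samples = _samples(12, 0)
        batches = stratified_batches(samples, 4, seed=0)
        assert sorted(i for b in batches for i in b) == list(range(12))

    def test_deterministic_given_seed(self):
        samples = _samples(10, 10)
        assert stratified_batches(samples, 4, seed=5) == stratified_batches(
            samples, 4, seed=5
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            stratified_batches([], 4, seed=0)


class TestMaskedCrossEntropy:
    def test_confident_correct_logits_near_zero_loss(self):
        labels = np.array([[0, 1, 2]])
        logits = np.full((1, 3, 3), -50.0)
        for j, lab in enumerate(labels[0]):
            logits[0, j, lab] = 50.0
        assert masked_cross_entropy(logits, labels, [3]) < 1e-6

    def test_uniform_logits_give_ln3(self):
        logits = np.zeros((2, 5, 3))
        labels = np.random.default_rng(0).integers(0, 3, size=(2, 5))
        assert masked_cross_entropy(logits, labels, [5, 5]) == pytest.approx(
            np.log(3.0), abs=1e-12
        )

    def test_padded_positions_do_not_contribute(self, rng):
        logits = rng.normal(size=(1, 6, 3))
        labels = rng.integers(0, 3, size=(1, 6))
        base = masked_cross_entropy(logits, labels, [4])
        tampered = logits.copy()
        tampered[0, 4:] = rng.normal(size=(2, 3)) * 100
        assert masked_cross_entropy(tampered, labels, [4]) == pytest.approx(base)


class TestPlateauController:
    def test_lr_halved_after_three_flat_epochs(self):
        """Losses [1.0, 0.9, 0.9, 0.9, 0.9] with patience 3: the reduction
        fires at the third consecutive non-improving epoch (epoch 5)."""
        ctrl = PlateauController(plateau_patience=3, early_stop_patience=5)
        reductions = []
        for epoch, loss in enumerate([1.0, 0.9, 0.9, 0.9, 0.9], start=1):
            signal = ctrl.update(loss, epoch)
            if signal["reduce_lr"]:
                reductions.append(epoch)
        assert reductions == [5]

    def test_early_stop_after_five_flat_epochs_best_is_pre_streak(self):
        ctrl = PlateauController(plateau_patience=3, early_stop_patience=5)
        stopped_at = None
        for epoch, loss in enumerate([1.0, 0.8, 0.9, 0.9, 0.9, 0.9, 0.9], start=1):
            if ctrl.update(loss, epoch)["stop"]:
                stopped_at = epoch
                break
        assert stopped_at == 7
        assert ctrl.best_epoch == 2

    def test_counter_resets_on_lr_reduction(self):
        ctrl = PlateauController(plateau_patience=2, early_stop_patience=6)
        fired = [ctrl.update(1.0 + 0.0, e)["reduce_lr"] for e in range(1, 6)]
        # epochs 1 improves (from inf); 2,3 flat -> fire; 4,5 flat -> fire
        assert fired == [False, False, True, False, True]


class TestTrainLoop:
    def _tiny_setup(self, seed=0, n=24):
        config = SynthConfig(
            n_coding=n // 2, n_noncoding=n // 2,
            utr5_len=(5, 10), cds_codons=(8, 15), utr3_len=(5, 10),
            min_spurious_orf=7, seed=seed,
        )
        records = generate_transcriptome(config)
        l_max = max(r.length for r in records)
        samples = tio.build_dataset(records, l_max)
        cfg = ModelConfig(
            embedding_dim=8, local_channels=4, stage_channels=(4, 6, 8),
            blocks_per_stage=(1, 1, 1), stage_kernels=(3, 3, 5),
            stage_dilations=(1, 2, 2), head_channels=4,
        )
        return samples, build_model(cfg, seed=seed)

    def test_single_epoch_runs_and_reports(self):
        samples, model = self._tiny_setup()
        result = train(model, samples, samples,
                       TrainConfig(max_epochs=1, batch_size=8, seed=0))
        assert len(result.history) == 1
        assert result.best_epoch == 1

    def test_best_val_loss_is_history_minimum(self):
        samples, model = self._tiny_setup()
        result = train(model, samples, samples,
                       TrainConfig(max_epochs=3, batch_size=8, seed=0))
        assert result.best_val_loss == pytest.approx(
            min(h["val_loss"] for h in result.history)
        )

    def test_reproducible_given_seed(self):
        samples, model_a = self._tiny_setup(seed=3)
        _, model_b = self._tiny_setup(seed=3)
        res_a = train(model_a, samples, samples,
                      TrainConfig(max_epochs=2, batch_size=8, seed=3))
        res_b = train(model_b, samples, samples,
                      TrainConfig(max_epochs=2, batch_size=8, seed=3))
        assert res_a.history == res_b.history

    def test_loss_decreases_across_seeds(self):
        """Five epochs on a 200-sample synthetic set strictly decrease
        the training loss in at least 4 of 5 seeds."""
        wins = 0
        for seed in range(5):
            config = SynthConfig(
                n_coding=100, n_noncoding=100,
                utr5_len=(5, 10), cds_codons=(8, 15), utr3_len=(5, 10),
                min_spurious_orf=7, seed=seed,
            )
            records = generate_transcriptome(config)
            l_max = max(r.length for r in records)
            samples = tio.build_dataset(records, l_max)
            cfg = ModelConfig(
                embedding_dim=8, local_channels=4, stage_channels=(4, 6, 8),
                blocks_per_stage=(1, 1, 1), stage_kernels=(3, 3, 5),
                stage_dilations=(1, 2, 2), head_channels=4,
            )
            model = build_model(cfg, seed=seed)
            result = train(model, samples, samples,
                           TrainConfig(max_epochs=5, batch_size=16, seed=seed))
            losses = [h["train_loss"] for h in result.history]
            if all(b < a for a, b in zip(losses, losses[1:])):
                wins += 1
        assert wins >= 4

    def test_empty_split_rejected(self):
        samples, model = self._tiny_setup()
        with pytest.raises(ValueError):
            train(model, [], samples, TrainConfig(max_epochs=1))

    def test_invalid_patience_config(self):
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=0)
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=4, early_stop_patience=3)
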