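"""Architecture mechanics: shapes, determinism, padding behaviour,
probability decoding, and the receptive-field arithmetic."""

import numpy as np
import pytest

from orfcall.model import (ModelConfig, RawDecoding, build_model,
                           load_checkpoint, raw_argmax_decode,
                           receptive_field_span, save_checkpoint,
                           to_probabilities)
from orfcall.records import NONE, TIS, TTS
from orfcall.train import masked_cross_entropy_grad


class TestBuildAndForward:
    def test_logit_shape(self, tiny_model_config, rng):
        model = build_model(tiny_model_config, seed=0)
        tokens = rng.integers(0, 5, size=(2, 100))
        assert model.forward(tokens).shape == (2, 100, 3)

    def test_default_config_shape_small_batch(self):
        # full-width architecture, short input: shape contract only
        model = build_model(ModelConfig(), seed=0)
        tokens = np.ones((1, 40), dtype=np.int64)
        assert model.forward(tokens).shape == (1, 40, 3)

    def test_all_padding_input_finite(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=0)
        logits = model.forward(np.zeros((1, 30), dtype=np.int64), lengths=[0])
        assert np.isfinite(logits).all()

    def test_padding_embedding_row_is_zero(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=0)
        assert (model.embed.W.value[0] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(stage_channels=(32, 64))
        with pytest.raises(ValueError):
            ModelConfig(embedding_dim=0)

    def test_token_out_of_range_rejected(self, tiny_model_config):
        model = build_model(tiny_model_config, seed=0)
        with pytest.raises(ValueError):
            model.forward(np.full((1, 10), 5))

    def test_length_preservation(self, tiny_model_config, rng):
        model = build_model(tiny_model_config, seed=0)
        for length in (1, 50, 500):
            tokens = rng.integers(0, 5, size=(1, length))
            assert model.forward(tokens).shape[1] == length

    def test_eval_mode_deterministic(self, tiny_model_config, rng):
        model = build_model(tiny_model_config, seed=0)
        tokens = rng.integers(0, 5, size=(2, 60))
        a = model.forward(tokens, train=False)
        b = model.forward(tokens, train=False)
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_padding_insensitive_in_eval_mode(self, tiny_model_config, rng):
        """A transcript's logits over its valid positions are the same
        whether it runs alone or inside a zero-padded batch."""
        model = build_model(tiny_model_config, seed=0)
        tokens = rng.integers(1, 5, size=40)
        alone = model.forward(tokens[None, :], lengths=[40], train=False)
        padded = np.zeros((2, 64), dtype=np.int64)
        padded[0, :40] = tokens
        padded[1, :25] = rng.integers(1, 5, size=25)
        batch = model.forward(padded, lengths=[40, 25], train=False)
        np.testing.assert_allclose(alone[0], batch[0, :40], atol=1e-5)


class TestGradients:
    def test_padding_embedding_receives_no_gradient(self, tiny_model_config, rng):
        model = build_model(tiny_model_config, seed=0)
        tokens = rng.integers(0, 5, size=(2, 30))
        labels = rng.integers(0, 3, size=(2, 30))
        logits = model.forward(tokens, lengths=[30, 20], train=True)
        _, grad = masked_cross_entropy_grad(logits, labels, [30, 20])
        for p in model.params():
            p.zero_grad()
        model.backward(grad)
        assert (model.embed.W.grad[0] == 0).all()
        assert np.abs(model.embed.W.grad[1:]).sum() > 0

    def test_directional_derivative_matches_finite_difference(
        self, tiny_model_config, rng
    ):
        """Backprop through the full stack agrees with a central finite
        difference along a random parameter direction (linear readout
        loss keeps the check well-conditioned in float32)."""
        model = build_model(tiny_model_config, seed=0)
        # nudge parameters off the identity-start initialisation: the
        # zero-initialised residual branches sit on ReLU/BatchNorm kinks
        # where finite differences are ill-conditioned
        nudge = np.random.default_rng(99)
        for p in model.params():
            p.value += nudge.normal(0, 0.05, size=p.value.shape).astype(np.float32)
        model.embed.W.value[0] = 0.0
        tokens = rng.integers(0, 5, size=(2, 20))
        w = rng.normal(size=(2, 20, 3))

        def loss():
            return float(
                (model.forward(tokens, train=True).astype(np.float64) * w).sum()
            )

        model.forward(tokens, train=True)
        for p in model.params():
            p.zero_grad()
        model.backward(w.astype(np.float32))
        params = model.params()
        dirs = [
            np.random.default_rng(5 + i).normal(size=p.value.shape).astype(np.float32)
            for i, p in enumerate(params)
        ]
        dirs[0][0] = 0.0  # the frozen padding embedding row
        analytic = sum(float((p.grad * d).sum()) for p, d in zip(params, dirs))
        eps = 3e-4
        for p, d in zip(params, dirs):
            p.value += eps * d
        l1 = loss()
        for p, d in zip(params, dirs):
            p.value -= 2 * eps * d
        l2 = loss()
        fd = (l1 - l2) / (2 * eps)
        # float32 forward + ReLU kinks limit the attainable agreement
        assert fd == pytest.approx(analytic, rel=0.1)


class TestProbabilities:
    def test_uniform_logits(self):
        probs = to_probabilities(np.zeros((1, 1, 3)))
        np.testing.assert_allclose(probs, 1 / 3)

    def test_closed_form_softmax(self):
        probs = to_probabilities(np.array([np.log(2.0), 0.0, 0.0]))
        np.testing.assert_allclose(probs, [0.5, 0.25, 0.25], atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        logits = rng.normal(size=(3, 50, 3)) * 10
        probs = to_probabilities(logits)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-6)


class TestArgmaxDecode:
    def test_published_probability_row_decodes_to_none(self):
        # a weak TIS signal (p_TIS ~0.03) loses to the non-site class
        probs = np.array([[3.314e-02, 1.099e-04, 9.667e-01]])
        assert raw_argmax_decode(probs).classes[0] == NONE

    def test_clear_tis_wins(self):
        assert raw_argmax_decode(np.array([[0.6, 0.1, 0.3]])).classes[0] == TIS

    def test_exact_tie_goes_to_none(self):
        probs = np.array([[1 / 3, 1 / 3, 1 / 3]])
        assert raw_argmax_decode(probs).classes[0] == NONE

    def test_tis_tts_tie_goes_to_tis(self):
        probs = np.array([[0.45, 0.45, 0.10]])
        assert raw_argmax_decode(probs).classes[0] == TIS

    def test_runs_extracted(self):
        probs = np.full((10, 3), [0.0, 0.0, 1.0])
        probs[2:5] = [1.0, 0.0, 0.0]
        probs[7:9] = [0.0, 1.0, 0.0]
        decoding = raw_argmax_decode(probs)
        assert decoding.tis_runs == [(2, 3)]
        assert decoding.tts_runs == [(7, 2)]


class TestReceptiveField:
    def test_default_architecture_span(self):
        assert receptive_field_span(ModelConfig()) == 2003

    def test_single_small_stage(self):
        cfg = ModelConfig(
            local_channels=4,
            stage_channels=(4,),
            blocks_per_stage=(1,),
            stage_kernels=(3,),
            stage_dilations=(1,),
            embedding_dim=8,
            head_channels=4,
        )
        assert receptive_field_span(cfg) == 7

    def test_monotone_in_dilation(self):
        base = receptive_field_span(ModelConfig())
        wider = receptive_field_span(ModelConfig(stage_dilations=(1, 2, 6)))
        assert wider > base


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tiny_model_config, rng, tmp_path):
        model = build_model(tiny_model_config, seed=0)
        tokens = rng.integers(0, 5, size=(1, 30))
        before = model.forward(tokens, train=False)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, metadata={"l_max": 30})
        loaded, meta = load_checkpoint(path)
        after = loaded.forward(tokens, train=False)
        np.testing.assert_allclose(before, after, atol=1e-6)
        assert meta["l_max"] == 30
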