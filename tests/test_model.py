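import numpy as np
import pytest

import acpfuse as af
from acpfuse.model import prepare_inputs


class TestModelConfig:
    def test_defaults_mirror_published_architecture(self):
        cfg = af.ModelConfig()
        assert (cfg.max_len, cfg.vocab_size) == (210, 21)
        assert cfg.conv_filters == (32,) and cfg.conv_kernel == 16
        assert cfg.pool_size == 8 and cfg.hf_dense_units == (128, 64)
        assert cfg.hf_dropout == 0.2 and cfg.threshold == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conv_filters": ()},
            {"conv_filters": (32, 64, 128)},
            {"hf_dropout": 1.0},
            {"threshold": 0.0},
            {"channels": "both"},
            {"channels": "dual", "hf_scheme": "none"},
            {"channels": "hf_only", "hf_scheme": "none"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            af.ModelConfig(**kwargs)

    def test_round_trips_through_dict(self):
        cfg = af.ModelConfig(conv_filters=(32, 64), hf_scheme="AAC")
        assert af.ModelConfig.from_dict(cfg.to_dict()) == cfg


def fit_tiny(config, dataset):
    model = af.build_model(config)
    model.fit(*prepare_inputs(dataset, config))
    return model


class TestArchitectureContracts:
    def test_dual_model_accepts_both_inputs(self, separable_dataset, fast_config):
        model = fit_tiny(fast_config, separable_dataset)
        X_seq, X_hf, _ = prepare_inputs(separable_dataset, fast_config)
        proba = model.predict_proba(X_seq, X_hf)
        assert proba.shape == (len(separable_dataset),)
        assert np.all((proba > 0) & (proba < 1))

    def test_hf_width_mismatch_rejected(self):
        import dataclasses

        cfg = dataclasses.replace(af.ModelConfig(), channels="hf_only", hf_scheme="AAC")
        model = af.build_model(cfg)
        with pytest.raises(ValueError, match="width"):
            model.predict_proba(None, np.zeros((2, 21)))

    def test_cnn_only_rejects_missing_sequences(self):
        import dataclasses

        cfg = dataclasses.replace(af.ModelConfig(), channels="cnn_only", hf_scheme="none")
        model = af.build_model(cfg)
        with pytest.raises(ValueError, match="encoded sequences"):
            model.predict_proba(None, np.zeros((2, 20)))

    def test_cnn_only_ignores_handcrafted_vector(self, separable_dataset):
        cfg = af.ModelConfig(channels="cnn_only", hf_scheme="none", epochs=5, seed=1)
        model = fit_tiny(cfg, separable_dataset)
        X_seq, _, _ = prepare_inputs(separable_dataset, cfg)
        p1 = model.predict_proba(X_seq, None)
        p2 = model.predict_proba(X_seq, np.random.default_rng(0).random((len(X_seq), 150)))
        assert np.array_equal(p1, p2)

    def test_hf_only_ignores_encoded_sequence(self, separable_dataset):
        cfg = af.ModelConfig(channels="hf_only", hf_scheme="AAC", epochs=5, seed=1)
        model = fit_tiny(cfg, separable_dataset)
        _, X_hf, _ = prepare_inputs(separable_dataset, cfg)
        scrambled = np.random.default_rng(0).integers(0, 21, size=(len(X_hf), 210))
        assert np.array_equal(
            model.predict_proba(None, X_hf), model.predict_proba(scrambled, X_hf)
        )


class TestTraining:
    def test_loss_decreases_on_separable_data(self, separable_dataset, fast_config):
        model = fit_tiny(fast_config, separable_dataset)
        hist = model.training_history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_training_accuracy_on_strong_effect(self, separable_dataset, fast_config):
        model = fit_tiny(fast_config, separable_dataset)
        X_seq, X_hf, y = prepare_inputs(separable_dataset, fast_config)
        _, labels = model.predict(X_seq, X_hf)
        assert (labels == y).mean() > 0.95

    def test_seeded_training_is_reproducible(self, separable_dataset, fast_config):
        X_seq, X_hf, y = prepare_inputs(separable_dataset, fast_config)
        p = []
        for _ in range(2):
            model = af.build_model(fast_config)
            model.fit(X_seq, X_hf, y)
            p.append(model.predict_proba(X_seq, X_hf))
        assert np.allclose(p[0], p[1], atol=1e-10)

    def test_single_class_data_rejected(self, separable_dataset, fast_config):
        X_seq, X_hf, y = prepare_inputs(separable_dataset, fast_config)
        model = af.build_model(fast_config)
        with pytest.raises(ValueError, match="both classes"):
            model.fit(X_seq, X_hf, np.ones_like(y))


class TestPrediction:
    def test_hard_labels_use_strict_threshold(self, separable_dataset, fast_config):
        model = fit_tiny(fast_config, separable_dataset)
        X_seq, X_hf, _ = prepare_inputs(separable_dataset, fast_config)
        proba, labels = model.predict(X_seq, X_hf)
        assert np.array_equal(labels, (proba > 0.5).astype(int))

    def test_inference_is_deterministic_and_order_preserving(
        self, separable_dataset, fast_config
    ):
        model = fit_tiny(fast_config, separable_dataset)
        frame1 = af.predict_records(model, separable_dataset.records)
        frame2 = af.predict_records(model, separable_dataset.records)
        assert frame1.equals(frame2)
        assert list(frame1["id"]) == separable_dataset.ids

    def test_save_load_round_trip(self, tmp_path, separable_dataset, fast_config):
        model = fit_tiny(fast_config, separable_dataset)
        X_seq, X_hf, _ = prepare_inputs(separable_dataset, fast_config)
        model.save(tmp_path / "ckpt")
        restored = af.PeptideClassifier.load(tmp_path / "ckpt")
        assert restored.config == model.config
        assert np.allclose(
            restored.predict_proba(X_seq, X_hf), model.predict_proba(X_seq, X_hf)
        )

    def test_untrained_model_warns(self, separable_dataset, fast_config):
        model = af.build_model(fast_config)
        X_seq, X_hf, _ = prepare_inputs(separable_dataset, fast_config)
        with pytest.warns(UserWarning, match="untrained"):
            model.predict_proba(X_seq, X_hf)


def test_two_layer_convolution_variant_builds_and_learns(separable_dataset):
    cfg = af.ModelConfig(conv_filters=(32, 64), epochs=5, seed=2)
    model = af.build_model(cfg)
    model.fit(*prepare_inputs(separable_dataset, cfg))
    hist = model.training_history
    assert hist[-1]["train_loss"] < hist[0]["train_loss"]
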