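"""Decode rules, thresholds, and CTC training of the transcriber."""

import numpy as np
import pytest

import adspeech as ad
from adspeech.generator import (
    CTCTranscriber,
    FramePath,
    GeneratorConfig,
    TrainConfigCTC,
    collapse_to_feature_sequence,
    frame_argmax,
    silence_run_threshold,
)
from adspeech.synthetic import default_tone_mapping, generate_toy_audio

TINY_CONFIG = GeneratorConfig(
    conv_specs=((8, (3, 5), (1, 2)),),
    rnn_layers=1,
    rnn_cells_per_direction=12,
    n_bins=20,
)


def toy_dataset(inv, n_utts=10, seed=0, n_tokens=(2, 5)):
    """Sinusoid utterances with known token sequences (no silences)."""
    rng = np.random.default_rng(seed)
    mapping = default_tone_mapping(inv, range(inv.size - 1), f_min=500, f_step=900)
    X, y = [], []
    for _ in range(n_utts):
        k = int(rng.integers(*n_tokens))
        toks = [int(t) for t in rng.integers(0, inv.size - 1, size=k)]
        seq = ad.FeatureSequence(toks)
        wave, _ = generate_toy_audio(seq, mapping, inv, token_dur_s=0.2,
                                     sample_rate=8000, rng=rng)
        X.append(wave)
        y.append(toks)
    return X, y, mapping


@pytest.fixture(scope="module")
def trained_tiny(tiny_inv_module):
    inv = tiny_inv_module
    X, y, _ = toy_dataset(inv, n_utts=10, seed=1)
    cfg = GeneratorConfig(**{**TINY_CONFIG.__dict__, "sample_rate": 8000.0})
    tcfg = TrainConfigCTC(iterations=120, batch_size=6, seed=5)
    est = CTCTranscriber(inventory=inv, config=cfg, train_config=tcfg)
    est.fit(X, y)
    return est, X, y


@pytest.fixture(scope="module")
def tiny_inv_module():
    return ad.build_inventory(["a", "b", "c", "d"], "<sil>")


class TestSilenceRunThreshold:
    @pytest.mark.parametrize(
        "thr, frame, want",
        [(3.0, 0.01, 300), (1.0, 0.01, 100), (5.0, 0.01, 500), (0.015, 0.01, 2)],
    )
    def test_threshold_arithmetic(self, thr, frame, want):
        assert silence_run_threshold(thr, frame) == want

    @pytest.mark.parametrize("thr, frame", [(0, 0.01), (-1, 0.01), (1, 0)])
    def test_non_positive_rejected(self, thr, frame):
        with pytest.raises(ValueError):
            silence_run_threshold(thr, frame)


class TestFrameArgmax:
    def test_one_hot_rows_recovered(self):
        lp = np.log(np.eye(3)[[2, 0, 1]] + 1e-9)
        assert frame_argmax(lp).labels.tolist() == [2, 0, 1]

    def test_uniform_ties_break_to_lowest_id(self):
        lp = np.zeros((4, 3))
        assert frame_argmax(lp).labels.tolist() == [0, 0, 0, 0]

    def test_empty(self):
        assert frame_argmax(np.zeros((0, 3))).labels.size == 0


class TestCollapse:
    def path(self, labels):
        return FramePath(np.array(labels, dtype=np.int64))

    def test_long_blank_run_becomes_silence(self, tiny_inv):
        blank = tiny_inv.size
        labels = [0, 0] + [blank] * 300 + [1, 1]
        out = collapse_to_feature_sequence(self.path(labels), 300, tiny_inv)
        assert out.tokens == [0, tiny_inv.silence_id, 1]

    def test_short_blank_run_dropped_but_separates_repeat(self, tiny_inv):
        blank = tiny_inv.size
        labels = [0, 0] + [blank] * 299 + [0]
        out = collapse_to_feature_sequence(self.path(labels), 300, tiny_inv)
        assert out.tokens == [0, 0]

    def test_all_blank_below_threshold_is_empty(self, tiny_inv):
        out = collapse_to_feature_sequence(
            self.path([tiny_inv.size] * 10), 300, tiny_inv)
        assert out.tokens == []

    def test_repeat_merge_within_run(self, tiny_inv):
        out = collapse_to_feature_sequence(self.path([2, 2, 2, 3]), 5, tiny_inv)
        assert out.tokens == [2, 3]

    def test_random_paths_properties(self, tiny_inv):
        # paths hold non-silence token classes and blank, as CTC training
        # (silence-free targets) makes the model emit
        rng = np.random.default_rng(8)
        blank = tiny_inv.size
        for _ in range(50):
            labels = rng.choice(
                [0, 1, 2, 3, blank], size=rng.integers(0, 40))
            N = int(rng.integers(1, 6))
            out = collapse_to_feature_sequence(self.path(labels), N, tiny_inv)
            assert len(out) <= len(labels)
            assert blank not in out.tokens
            # silence tokens == maximal blank runs of length ≥ N
            runs, i = 0, 0
            while i < len(labels):
                j = i
                while j < len(labels) and labels[j] == labels[i]:
                    j += 1
                if labels[i] == blank and j - i >= N:
                    runs += 1
                i = j
            assert sum(t == tiny_inv.silence_id for t in out.tokens) == runs


class TestGeneratorConfig:
    def test_full_scale_defaults(self, tiny_inv):
        cfg = GeneratorConfig()
        assert [c[0] for c in cfg.conv_specs] == [32, 32, 96]
        assert cfg.rnn_layers == 5 and cfg.rnn_cells_per_direction == 512
        assert cfg.effective_frame_s == pytest.approx(0.010)
        assert cfg.output_classes(tiny_inv) == tiny_inv.size + 1

    def test_time_stride_changes_frame_rate(self):
        cfg = GeneratorConfig(conv_specs=((8, (3, 3), (2, 1)),))
        assert cfg.effective_frame_s == pytest.approx(0.020)
        # decode threshold follows the coarser frame rate
        assert silence_run_threshold(3.0, cfg.effective_frame_s) == 150


class TestTraining:
    def test_loss_decreases_and_is_deterministic(self, trained_tiny, tiny_inv_module):
        est, X, y = trained_tiny
        hist = est.loss_history_
        assert len(hist) == 120
        assert hist[-1] < hist[0]

        cfg = GeneratorConfig(**{**TINY_CONFIG.__dict__, "sample_rate": 8000.0})
        tcfg = TrainConfigCTC(iterations=10, batch_size=6, seed=5)
        h1 = CTCTranscriber(tiny_inv_module, cfg, tcfg).fit(X, y).loss_history_
        h2 = CTCTranscriber(tiny_inv_module, cfg, tcfg).fit(X, y).loss_history_
        assert h1 == h2
        assert h1 == hist[:10]

    def test_over_length_filter_and_empty_dataset_error(self, tiny_inv):
        cfg = GeneratorConfig(**{**TINY_CONFIG.__dict__, "sample_rate": 8000.0})
        tcfg = TrainConfigCTC(iterations=2, max_utterance_s=1.0, seed=0)
        long_wave = np.zeros(16001)  # > 1 s at 8 kHz
        with pytest.raises(ValueError, match="exceed"):
            CTCTranscriber(tiny_inv, cfg, tcfg).fit([long_wave], [[0]])

    def test_silence_in_target_rejected(self, tiny_inv):
        cfg = GeneratorConfig(**{**TINY_CONFIG.__dict__, "sample_rate": 8000.0})
        with pytest.raises(ValueError, match="silence"):
            CTCTranscriber(tiny_inv, cfg, TrainConfigCTC(iterations=1)).fit(
                [np.zeros(4000)], [[tiny_inv.silence_id]])

    def test_checkpoint_roundtrip(self, trained_tiny, tiny_inv_module, tmp_path):
        est, X, _ = trained_tiny
        p = tmp_path / "gen.npz"
        est.save(p)
        back = CTCTranscriber.load(p, tiny_inv_module)
        a = est.predict_log_posteriors(X[0])
        b = back.predict_log_posteriors(X[0])
        assert np.allclose(a, b)

    def test_checkpoint_inventory_hash_guard(self, trained_tiny, tmp_path):
        est, _, _ = trained_tiny
        p = tmp_path / "gen.npz"
        est.save(p)
        other = ad.build_inventory(["x", "y", "z", "w"], "<sil>")
        with pytest.raises(ValueError, match="inventory"):
            CTCTranscriber.load(p, other)


class TestEndToEndRecovery:
    def test_toy_audio_transcription_reaches_low_ter(self, tiny_inv_module):
        """Well-separated tones must be recoverable: pooled TER < 0.3."""
        inv = tiny_inv_module
        X, y, _ = toy_dataset(inv, n_utts=12, seed=2, n_tokens=(2, 5))
        cfg = GeneratorConfig(**{**TINY_CONFIG.__dict__, "sample_rate": 8000.0})
        # toy-scale recipe: the tiny network tolerates a larger step size,
        # which gets it past the early all-blank phase within the budget
        tcfg = TrainConfigCTC(iterations=500, batch_size=6, seed=3,
                              learning_rate=0.003)
        est = CTCTranscriber(inventory=inv, config=cfg, train_config=tcfg,
                             silence_threshold_s=3.0)
        est.fit(X, y)
        total_ed = sum(ad.edit_distance(ref, hyp.tokens)
                       for ref, hyp in zip(y, est.transform(X)))
        ter = total_ed / sum(len(r) for r in y)
        assert ter < 0.3
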