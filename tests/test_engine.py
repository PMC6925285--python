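"""Assessment engine: scoring semantics, masking, training contract."""

import numpy as np
import pytest

import adspeech as ad
from adspeech.engine import AssessmentClassifier, pad_and_mask, score_sequence


def quick_engine(**kw):
    defaults = dict(cells_per_direction=8, max_epochs=12, patience=5,
                    seed=0, vocab_size=318)
    defaults.update(kw)
    return AssessmentClassifier(**defaults)


@pytest.fixture(scope="module")
def fitted(small_cohort_module):
    est = quick_engine(max_epochs=120, patience=20)
    est.fit(small_cohort_module)
    return est


@pytest.fixture(scope="module")
def small_cohort_module(inv318_module):
    spec = ad.CohortSpec(n_subjects_per_class=5, tests_per_subject=2, seed=11)
    spec.ch.mean_length = 60
    spec.ad.mean_length = 30
    seqs, _ = ad.generate_cohort(spec, inv318_module)
    return seqs


@pytest.fixture(scope="module")
def inv318_module():
    return ad.default_inventory()


class TestPadAndMask:
    def test_equal_lengths_mask_all_true(self):
        ids, lengths, mask = pad_and_mask([[1, 2], [3, 4]])
        assert mask.all() and ids.shape == (2, 2) and lengths.tolist() == [2, 2]

    def test_right_padding_and_lengths(self):
        ids, lengths, mask = pad_and_mask([[5, 6, 7], [1, 2, 3, 4, 5]])
        assert ids.shape == (2, 5)
        assert lengths.tolist() == [3, 5]
        assert mask[0].tolist() == [True, True, True, False, False]
        assert ids[0, 3:].tolist() == [0, 0]

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            pad_and_mask([])


class TestScoreSemantics:
    def test_zeroed_head_gives_exactly_half(self, fitted):
        est = quick_engine()
        est._build(np.random.default_rng(0), 318)
        est.layers_["head"].params["W"][...] = 0.0
        est.layers_["head"].params["b"][...] = 0.0
        p = est.score_samples([[1, 2, 3], [7] * 40])
        assert np.allclose(p, 0.5)

    def test_scores_in_open_unit_interval(self, fitted, small_cohort_module):
        p = fitted.score_samples(small_cohort_module)
        assert np.all((p > 0) & (p < 1))

    def test_inference_deterministic(self, fitted, small_cohort_module):
        a = fitted.score_samples(small_cohort_module[:4])
        b = fitted.score_samples(small_cohort_module[:4])
        assert np.array_equal(a, b)

    def test_empty_sequence_rejected(self, fitted):
        with pytest.raises(ValueError, match="empty"):
            fitted.score_samples([[]])

    def test_out_of_vocabulary_rejected(self, fitted):
        with pytest.raises(ValueError, match="vocabulary"):
            fitted.score_samples([[999]])

    def test_batching_invariance(self, fitted, small_cohort_module):
        """score(x) must match score of x inside any padded batch."""
        batch = small_cohort_module[:6]  # mixed lengths
        pooled = fitted.score_samples(batch)
        solo = np.array([score_sequence(s, fitted) for s in batch])
        assert np.allclose(pooled, solo, atol=1e-5)


class TestTraining:
    def test_converges_on_separable_cohort(self, fitted, small_cohort_module):
        hist = fitted.history_["val_loss"]
        assert hist[fitted.best_epoch_] <= hist[0]
        y = np.array([s.label for s in small_cohort_module])
        p = fitted.score_samples(small_cohort_module)
        assert ad.auroc(p, y) > 0.8  # trained on these; loose sanity bar

    def test_single_class_training_rejected(self, small_cohort_module):
        ch_only = [s for s in small_cohort_module if s.label == 0]
        with pytest.raises(ValueError, match="both classes"):
            quick_engine().fit(ch_only)

    def test_same_seed_reproduces_history(self, small_cohort_module):
        h1 = quick_engine(max_epochs=5).fit(small_cohort_module).history_
        h2 = quick_engine(max_epochs=5).fit(small_cohort_module).history_
        assert h1 == h2

    def test_early_stop_bounds_epochs(self, small_cohort_module):
        est = quick_engine(max_epochs=60, patience=3)
        est.fit(small_cohort_module)
        n_epochs = len(est.history_["val_loss"])
        assert n_epochs <= est.best_epoch_ + est.patience + 1

    def test_explicit_validation_set_used(self, small_cohort_module):
        tr = small_cohort_module[:6] + small_cohort_module[-6:]
        va = small_cohort_module[6:8] + small_cohort_module[-8:-6]
        est = quick_engine(max_epochs=4)
        est.fit(tr, X_val=va)
        assert len(est.history_["val_loss"]) >= 1

    def test_checkpoint_roundtrip(self, fitted, small_cohort_module, tmp_path):
        p = tmp_path / "engine.npz"
        fitted.save(p)
        back = AssessmentClassifier.load(p)
        a = fitted.score_samples(small_cohort_module[:3])
        b = back.score_samples(small_cohort_module[:3])
        assert np.allclose(a, b)


class TestArchitectureComparisons:
    def test_gru_has_fewer_parameters_than_lstm(self):
        ns = {}
        for cell in ("gru", "lstm", "simple"):
            est = quick_engine(cell_type=cell)
            est._build(np.random.default_rng(0), 318)
            ns[cell] = est.n_params_
        assert ns["simple"] < ns["gru"] < ns["lstm"]

    def test_cell_budget_matched_across_directionality(self):
        bi = AssessmentClassifier(bidirectional=True)
        uni = AssessmentClassifier(bidirectional=False)
        assert bi._cells() == 128 and uni._cells() == 256

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            quick_engine(cell_type="magic").fit(
                [ad.FeatureSequence([1, 2], label=0),
                 ad.FeatureSequence([3], label=1),
                 ad.FeatureSequence([1], label=0),
                 ad.FeatureSequence([2, 2], label=1)])
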