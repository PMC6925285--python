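"""Synthetic cohorts, corruption model, and toy audio alignment."""

import numpy as np
import pytest

import adspeech as ad
from adspeech.frontend import frame_count, log_filterbank
from adspeech.synthetic import (
    ClassParams,
    CohortSpec,
    CorruptionSpec,
    corrupt,
    default_tone_mapping,
    generate_cohort,
    generate_sequence,
    generate_toy_audio,
)
from adspeech.tokens import summarize


class TestCohort:
    def test_default_cohort_has_120_sequences(self, inv318):
        seqs, manifest = generate_cohort(CohortSpec(seed=0), inv318)
        assert len(seqs) == 120 == len(manifest)
        assert sum(s.label == 0 for s in seqs) == 60
        assert sum(s.label == 1 for s in seqs) == 60
        assert len({s.sample_id for s in seqs}) == 120

    def test_bit_exact_reproducibility(self, inv318):
        a, _ = generate_cohort(CohortSpec(seed=42), inv318)
        b, _ = generate_cohort(CohortSpec(seed=42), inv318)
        assert all(x.tokens == y.tokens for x, y in zip(a, b))

    def test_degenerate_parameters_give_constant_sequence(self, inv318):
        params = ClassParams(mean_length=20, silence_rate=0.0,
                             immediate_repeat_prob=1.0, vocabulary_size=1)
        seq = generate_sequence(params, inv318, np.random.default_rng(0))
        assert len(set(seq.tokens)) == 1

    def test_silence_fraction_recovers_parameter(self, inv318):
        params = ClassParams(mean_length=400, silence_rate=0.30,
                             immediate_repeat_prob=0.0, vocabulary_size=30)
        rng = np.random.default_rng(5)
        toks = []
        for _ in range(10):  # ≥ 1000 tokens pooled
            toks += generate_sequence(params, inv318, rng).tokens
        frac = sum(t == inv318.silence_id for t in toks) / len(toks)
        assert frac == pytest.approx(0.30, abs=0.05)

    def test_class_statistics_differ_in_specified_directions(self, inv318):
        seqs, _ = generate_cohort(CohortSpec(seed=7), inv318)

        def pooled(label):
            ss = [summarize(s, inv318) for s in seqs if s.label == label]
            tot = sum(x.length for x in ss)
            return (np.mean([x.length for x in ss]),
                    sum(x.silence_count for x in ss) / tot,
                    sum(x.immediate_repeat_count for x in ss) / tot,
                    np.mean([x.unique_token_count for x in ss]))

        ch, adr = pooled(0), pooled(1)
        assert adr[0] < ch[0]       # shorter
        assert adr[1] > ch[1]       # more silence
        assert adr[2] > ch[2]       # more repeats
        assert adr[3] < ch[3]       # poorer vocabulary

    def test_invalid_probability_rejected(self, inv318):
        spec = CohortSpec()
        spec.ad.silence_rate = 1.5
        with pytest.raises(ValueError):
            generate_cohort(spec, inv318)


class TestCorruption:
    def seq(self, inv, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return ad.FeatureSequence([int(t) for t in rng.integers(0, inv.size, n)])

    def test_zero_probabilities_identity(self, inv318):
        s = self.seq(inv318)
        out = corrupt(s, CorruptionSpec(0, 0, 0), inv318)
        assert out.tokens == s.tokens

    def test_full_deletion_empties(self, inv318):
        s = self.seq(inv318)
        out = corrupt(s, CorruptionSpec(0, 0, 1.0), inv318)
        assert out.tokens == []

    def test_substitution_rate_matches_expected_ter(self, inv318):
        cspec = CorruptionSpec(substitution_prob=0.1, insertion_prob=0.0,
                               deletion_prob=0.0, seed=13)
        rng = np.random.default_rng(13)
        total_ed, total_len = 0, 0
        for k in range(10):
            s = self.seq(inv318, n=100, seed=k)
            c = corrupt(s, cspec, inv318, rng=rng)
            total_ed += ad.edit_distance(s, c)
            total_len += len(s)
        assert total_ed / total_len == pytest.approx(0.1, abs=0.05)

    def test_deterministic_given_spec_seed(self, inv318):
        s = self.seq(inv318)
        cspec = CorruptionSpec(0.1, 0.1, 0.1, seed=3)
        assert corrupt(s, cspec, inv318).tokens == corrupt(s, cspec, inv318).tokens

    def test_overlapping_sub_del_rejected(self):
        with pytest.raises(ValueError):
            CorruptionSpec(0.7, 0.0, 0.7).validate()


class TestToyAudio:
    def test_empty_sequence_empty_waveform(self, tiny_inv):
        wave, labels = generate_toy_audio(
            ad.FeatureSequence([]), {}, tiny_inv)
        assert wave.size == 0 and labels.size == 0

    def test_duration_arithmetic(self, tiny_inv):
        wave, _ = generate_toy_audio(
            ad.FeatureSequence([0]), {0: 500.0}, tiny_inv,
            token_dur_s=0.5, sample_rate=16000)
        assert wave.size == 8000

    def test_unmapped_token_rejected(self, tiny_inv):
        with pytest.raises(ValueError, match="no mapped frequency"):
            generate_toy_audio(ad.FeatureSequence([0, 1]), {0: 500.0}, tiny_inv)

    def test_frame_labels_align_with_frontend(self, tiny_inv):
        seq = ad.FeatureSequence([0, tiny_inv.silence_id, 2])
        mapping = default_tone_mapping(tiny_inv, seq.tokens)
        wave, labels = generate_toy_audio(seq, mapping, tiny_inv,
                                          token_dur_s=0.2, sample_rate=16000)
        fm = log_filterbank(wave, 16000, n_bins=20)
        assert labels.size == fm.n_frames == frame_count(wave.size, 400, 160)
        # frame centered inside each 0.2 s segment carries that token
        for k, tok in enumerate(seq.tokens):
            mid_frame = int((k * 0.2 + 0.1) / 0.010)
            assert labels[mid_frame] == tok

    def test_distinct_frequencies_assigned(self, tiny_inv):
        mapping = default_tone_mapping(tiny_inv, [0, 1, 2, tiny_inv.silence_id])
        assert tiny_inv.silence_id not in mapping
        assert len(set(mapping.values())) == 3
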