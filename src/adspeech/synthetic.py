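"""Synthetic cohorts, transcription-error corruption, and toy audio.

Clinical speech corpora for this task are not redistributable, so the
package ships a generative stand-in exposing exactly the speech
characteristics the Feature Sequence is designed to carry:

* **pausing** — silence tokens inserted in runs (geometric run length),
  at a higher rate for AD-like sequences;
* **disfluent repetition** — immediate token repeats, more frequent in AD;
* **vocabulary richness** — each class samples from a limited active
  syllable subset, smaller for AD;
* **speech quantity** — sequence length, normally distributed around a
  class mean, shorter for AD.

The cohort shape mirrors a 10 + 10 subject design with six
neuropsychological-test responses per subject (120 one-minute samples).
A corruption model (independent per-token substitution/deletion plus
geometric insertions) emulates automatic-transcription errors, and a toy
audio synthesizer renders token sequences as distinct sinusoids with
known frame alignments so the CTC transcriber can be exercised end to
end without any real speech corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .frontend import frame_count
from .tokens import FeatureSequence, TokenInventory

__all__ = [
    "ClassParams",
    "CohortSpec",
    "CorruptionSpec",
    "generate_sequence",
    "generate_cohort",
    "corrupt",
    "generate_toy_audio",
    "default_tone_mapping",
]


@dataclass
class ClassParams:
    """Class-conditional generative parameters for one diagnosis group."""

    mean_length: float
    silence_rate: float            # stationary fraction of silence tokens
    immediate_repeat_prob: float
    vocabulary_size: int
    mean_silence_run: float = 1.5  # mean run length of consecutive silences
    length_sd_frac: float = 0.15   # sd of length as a fraction of the mean

    def validate(self) -> None:
        if not 0 <= self.silence_rate < 1:
            raise ValueError("silence_rate must be in [0, 1)")
        if not 0 <= self.immediate_repeat_prob <= 1:
            raise ValueError("immediate_repeat_prob must be in [0, 1]")
        if self.vocabulary_size < 1 or self.mean_length < 1:
            raise ValueError("vocabulary_size and mean_length must be ≥ 1")
        if self.mean_silence_run < 1:
            raise ValueError("mean_silence_run must be ≥ 1")


# Defaults encode the AD-like pattern: more and longer pauses, more
# repetition, poorer vocabulary, less speech per minute.  Effect sizes are
# deliberately large so desk-scale recovery experiments are stable; they
# make no claim to clinical calibration.
DEFAULT_CH = ClassParams(mean_length=150, silence_rate=0.05,
                         immediate_repeat_prob=0.05, vocabulary_size=40,
                         mean_silence_run=1.2)
DEFAULT_AD = ClassParams(mean_length=60, silence_rate=0.30,
                         immediate_repeat_prob=0.25, vocabulary_size=15,
                         mean_silence_run=2.0)


@dataclass
class CohortSpec:
    """Two-class cohort design: subjects × tests per class, with seeds."""

    n_subjects_per_class: int = 10
    tests_per_subject: int = 6
    ch: ClassParams = field(default_factory=lambda: ClassParams(**vars(DEFAULT_CH)))
    ad: ClassParams = field(default_factory=lambda: ClassParams(**vars(DEFAULT_AD)))
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_per_class < 1 or self.tests_per_subject < 1:
            raise ValueError("cohort dimensions must be ≥ 1")
        self.ch.validate()
        self.ad.validate()

    @property
    def n_sequences(self) -> int:
        return 2 * self.n_subjects_per_class * self.tests_per_subject


def generate_sequence(params: ClassParams, inv: TokenInventory,
                      rng: np.random.Generator, sample_id: str = "",
                      label: Optional[int] = None) -> FeatureSequence:
    """Draw one Feature Sequence from a class-conditional model.

    First-order draw per position: with ``immediate_repeat_prob`` copy
    the previous token; otherwise either start a silence run (geometric
    length, mean ``mean_silence_run``) or sample uniformly from the active
    vocabulary.  The silence trigger probability is solved so the
    stationary silence fraction equals ``silence_rate``; repeats copy the
    previous token (silence included) and leave that fraction invariant.
    """
    params.validate()
    if params.vocabulary_size > inv.size - 1:
        raise ValueError("vocabulary_size exceeds available syllables")
    length = max(2, int(round(rng.normal(
        params.mean_length, params.length_sd_frac * params.mean_length))))
    vocab = rng.choice(inv.size - 1, size=params.vocabulary_size, replace=False)
    s, m = params.silence_rate, params.mean_silence_run
    trigger = s / (m * (1 - s) + s) if s > 0 else 0.0
    toks: list[int] = []
    sil_remaining = 0
    while len(toks) < length:
        if toks and rng.random() < params.immediate_repeat_prob:
            toks.append(toks[-1])
            continue
        if sil_remaining > 0:
            toks.append(inv.silence_id)
            sil_remaining -= 1
            continue
        if rng.random() < trigger:
            sil_remaining = rng.geometric(1.0 / m)
            toks.append(inv.silence_id)
            sil_remaining -= 1
        else:
            toks.append(int(rng.choice(vocab)))
    return FeatureSequence(toks[:length], sample_id=sample_id, label=label)


def generate_cohort(spec: CohortSpec, inv: TokenInventory
                    ) -> tuple[list[FeatureSequence], list[dict]]:
    """Generate the full labeled cohort plus a manifest-style record list.

    Returns ``spec.n_sequences`` sequences (CH label 0 first, AD label 1),
    deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    test_names = ["fluency", "fluency", "picture", "picture", "memory", "memory"]
    seqs: list[FeatureSequence] = []
    manifest: list[dict] = []
    for label, cls_name, params in ((0, "CH", spec.ch), (1, "AD", spec.ad)):
        for subj in range(spec.n_subjects_per_class):
            for test in range(spec.tests_per_subject):
                sid = f"{cls_name}{subj:03d}_t{test}"
                seq = generate_sequence(params, inv, rng, sample_id=sid, label=label)
                seq.test_type = test_names[test % len(test_names)]
                seqs.append(seq)
                manifest.append({"id": sid, "label": label,
                                 "test_type": seq.test_type})
    return seqs, manifest


@dataclass
class CorruptionSpec:
    """Per-token error model emulating automatic transcription."""

    substitution_prob: float = 0.05
    insertion_prob: float = 0.05
    deletion_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for p in (self.substitution_prob, self.insertion_prob, self.deletion_prob):
            if not 0 <= p <= 1:
                raise ValueError("corruption probabilities must be in [0, 1]")
        if self.substitution_prob + self.deletion_prob > 1:
            raise ValueError("substitution + deletion probability exceeds 1")


def corrupt(seq: FeatureSequence, cspec: CorruptionSpec, inv: TokenInventory,
            rng: Optional[np.random.Generator] = None) -> FeatureSequence:
    """Apply substitution/deletion per token plus geometric insertions.

    Each reference token is deleted with ``deletion_prob``, else
    substituted by a uniformly random different token with
    ``substitution_prob``; after every position (and at the start) random
    tokens are inserted while a ``insertion_prob`` coin keeps coming up.
    Deterministic for a given spec seed when no generator is supplied.
    """
    cspec.validate()
    rng = np.random.default_rng(cspec.seed) if rng is None else rng

    def insertions() -> list[int]:
        out = []
        while rng.random() < cspec.insertion_prob:
            out.append(int(rng.integers(inv.size)))
        return out

    toks: list[int] = insertions()
    for t in seq.tokens:
        u = rng.random()
        if u < cspec.deletion_prob:
            pass
        elif u < cspec.deletion_prob + cspec.substitution_prob:
            sub = int(rng.integers(inv.size - 1))
            toks.append(sub + 1 if sub >= t else sub)  # uniform over ≠ t
        else:
            toks.append(t)
        toks.extend(insertions())
    return FeatureSequence(toks, sample_id=seq.sample_id,
                           label=seq.label, test_type=seq.test_type)


def default_tone_mapping(inv: TokenInventory, token_ids,
                         f_min: float = 400.0, f_step: float = 400.0
                         ) -> dict[int, float]:
    """Assign each non-silence token a distinct, well-separated frequency."""
    mapping = {}
    k = 0
    for t in sorted(set(int(t) for t in token_ids)):
        if t == inv.silence_id:
            continue
        mapping[t] = f_min + k * f_step
        k += 1
    return mapping


def generate_toy_audio(
    seq: FeatureSequence,
    mapping: dict[int, float],
    inv: TokenInventory,
    token_dur_s: float = 0.2,
    sample_rate: float = 16000.0,
    noise_sd: float = 0.01,
    hop_s: float = 0.010,
    win_s: float = 0.025,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a token sequence as concatenated sinusoid segments.

    Non-silence tokens become pure tones at their mapped frequency;
    silence tokens become near-silent noise.  Returns the waveform and
    ground-truth per-frame token ids (frame centers at the front-end's
    hop), for CTC training and alignment checks.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    seg = int(round(token_dur_s * sample_rate))
    pieces = []
    for t in seq.tokens:
        if t == inv.silence_id:
            pieces.append(np.zeros(seg))
        else:
            if t not in mapping:
                raise ValueError(f"token id {t} has no mapped frequency")
            tt = np.arange(seg) / sample_rate
            pieces.append(0.5 * np.sin(2 * np.pi * mapping[t] * tt))
    wave = np.concatenate(pieces) if pieces else np.zeros(0)
    wave = wave + rng.normal(0.0, noise_sd, size=wave.shape)

    win = int(round(win_s * sample_rate))
    hop = int(round(hop_s * sample_rate))
    n_frames = frame_count(wave.size, win, hop)
    centers = (np.arange(n_frames) * hop + win // 2) / sample_rate
    idx = np.minimum((centers / token_dur_s).astype(np.int64),
                     max(len(seq.tokens) - 1, 0))
    labels = np.array([seq.tokens[i] for i in idx], dtype=np.int64) \
        if seq.tokens else np.zeros(0, dtype=np.int64)
    return wave, labels
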