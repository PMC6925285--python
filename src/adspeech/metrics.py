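"""Sequence-quality metrics for generated Feature Sequences.

Three measures compare an automatic transcription against a reference:
edit distance (ED, unit-cost Levenshtein), token error rate
(TER = ED / reference length, which may exceed 1), and signed length
difference (LD = len(hyp) − len(ref); negative means the hypothesis is
shorter).  Silence tokens count as ordinary tokens in all three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tokens import FeatureSequence

__all__ = [
    "SequenceComparison",
    "edit_distance",
    "token_error_rate",
    "length_difference",
    "compare_sequences",
    "aggregate_comparisons",
]


def _ids(seq) -> list[int]:
    return seq.tokens if isinstance(seq, FeatureSequence) else list(seq)


@dataclass(frozen=True)
class SequenceComparison:
    edit_distance: int
    token_error_rate: float
    length_difference: int


def edit_distance(ref, hyp) -> int:
    """Minimal number of insertions, deletions and substitutions."""
    a, b = _ids(ref), _ids(hyp)
    if not a:
        return len(b)
    if not b:
        return len(a)
    b_arr = np.asarray(b)
    prev = np.arange(len(b) + 1)
    for i, ai in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (b_arr != ai)
        dele = prev[1:] + 1
        np.minimum(sub, dele, out=sub)
        # insertions need the running minimum along the row
        for j in range(1, len(b) + 1):
            cur[j] = min(sub[j - 1], cur[j - 1] + 1)
        prev = cur
    return int(prev[-1])


def token_error_rate(ref, hyp) -> float:
    """ED normalized by the reference length; undefined for empty refs."""
    a = _ids(ref)
    if len(a) == 0:
        raise ValueError("token error rate needs a non-empty reference")
    return edit_distance(a, _ids(hyp)) / len(a)


def length_difference(ref, hyp) -> int:
    """len(hyp) − len(ref): negative when the hypothesis under-transcribes."""
    return len(_ids(hyp)) - len(_ids(ref))


def compare_sequences(ref, hyp) -> SequenceComparison:
    ed = edit_distance(ref, hyp)
    a = _ids(ref)
    if len(a) == 0:
        raise ValueError("comparison needs a non-empty reference")
    return SequenceComparison(
        edit_distance=ed,
        token_error_rate=ed / len(a),
        length_difference=len(_ids(hyp)) - len(a),
    )


def aggregate_comparisons(comps: Sequence[SequenceComparison]) -> dict[str, float]:
    """mean ± sd summary of ED / TER / LD over a corpus."""
    if not comps:
        raise ValueError("no comparisons to aggregate")
    ed = np.array([c.edit_distance for c in comps], dtype=float)
    ter = np.array([c.token_error_rate for c in comps])
    ld = np.array([c.length_difference for c in comps], dtype=float)
    return {
        "ed_mean": float(ed.mean()), "ed_sd": float(ed.std(ddof=1)) if len(ed) > 1 else 0.0,
        "ter_mean": float(ter.mean()), "ter_sd": float(ter.std(ddof=1)) if len(ter) > 1 else 0.0,
        "ld_mean": float(ld.mean()), "ld_sd": float(ld.std(ddof=1)) if len(ld) > 1 else 0.0,
        "n": len(comps),
    }
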