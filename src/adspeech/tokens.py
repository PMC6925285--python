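"""Closed token vocabulary and the Feature Sequence data type.

A speech sample is represented as an ordered sequence of syllable tokens
drawn from a closed inventory of base syllables plus one reserved silence
token.  Pauses appear as silence tokens, disfluent repetition as immediate
token repeats, and vocabulary richness as the number of distinct tokens —
the three speech characteristics the representation is designed to carry.

The default packaged inventory holds 317 Mandarin base syllables
(romanized, tone markers stripped), giving a token space of 318 including
silence.  Any other unit list (another language, phonemes, words) can be
loaded from a plain-text file, one unit per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

__all__ = [
    "TokenInventory",
    "FeatureSequence",
    "SequenceSummary",
    "build_inventory",
    "default_inventory",
    "load_inventory",
    "encode",
    "decode",
    "summarize",
    "read_sequence_file",
    "write_sequence_file",
]

DEFAULT_SILENCE = "<sil>"


@dataclass(frozen=True)
class TokenInventory:
    """Closed token space: base syllables plus one silence token.

    Ids are assigned deterministically: syllables in list order get
    ``0 .. n-1`` and the silence token always gets the last id ``n``,
    so ``size == len(syllables) + 1``.  The CTC blank is *not* part of
    the inventory; acoustic models append it as an extra class.
    """

    syllables: tuple[str, ...]
    silence_token: str = DEFAULT_SILENCE

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dupes = sorted({s for s in self.syllables if s in seen or seen.add(s)})
        if dupes:
            raise ValueError(f"duplicate syllables in inventory: {dupes}")
        if not self.syllables:
            raise ValueError("inventory needs at least one syllable")
        if self.silence_token in seen:
            raise ValueError(
                f"silence marker {self.silence_token!r} collides with a syllable"
            )

    @property
    def size(self) -> int:
        """Number of token classes including silence."""
        return len(self.syllables) + 1

    @property
    def silence_id(self) -> int:
        return len(self.syllables)

    def id_of(self, token: str) -> int:
        try:
            return self._str_to_id[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in inventory") from None

    def token_of(self, token_id: int) -> str:
        if not 0 <= token_id < self.size:
            raise IndexError(f"token id {token_id} outside [0, {self.size})")
        if token_id == self.silence_id:
            return self.silence_token
        return self.syllables[token_id]

    def __contains__(self, token: str) -> bool:
        return token in self._str_to_id

    def __len__(self) -> int:
        return self.size

    @property
    def _str_to_id(self) -> dict[str, int]:
        # cached lazily on the instance; dataclass is frozen so use __dict__
        cached = self.__dict__.get("_map")
        if cached is None:
            cached = {s: i for i, s in enumerate(self.syllables)}
            cached[self.silence_token] = len(self.syllables)
            self.__dict__["_map"] = cached
        return cached

    def content_hash(self) -> str:
        """Stable hash identifying the inventory, stored in checkpoints."""
        import hashlib

        h = hashlib.sha256()
        for s in self.syllables:
            h.update(s.encode("utf-8") + b"\n")
        h.update(self.silence_token.encode("utf-8"))
        return h.hexdigest()[:16]


@dataclass
class FeatureSequence:
    """One sample's ordered token ids ``s_1 .. s_T`` with optional label.

    Labels follow the clinical convention 0 = cognitively healthy (CH),
    1 = Alzheimer's disease (AD).
    """

    tokens: list[int]
    sample_id: str = ""
    label: Optional[int] = None
    test_type: str = ""

    def __post_init__(self) -> None:
        self.tokens = [int(t) for t in self.tokens]
        if any(t < 0 for t in self.tokens):
            raise ValueError("token ids must be non-negative")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 (CH) or 1 (AD), got {self.label}")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def length(self) -> int:
        return len(self.tokens)

    def validate(self, inv: TokenInventory) -> "FeatureSequence":
        bad = [t for t in self.tokens if t >= inv.size]
        if bad:
            raise ValueError(
                f"sequence {self.sample_id!r} has token ids {bad[:5]} outside "
                f"inventory of size {inv.size}"
            )
        return self


@dataclass(frozen=True)
class SequenceSummary:
    """Interpretable per-sample counts derived from a Feature Sequence."""

    length: int
    silence_count: int
    non_silence_count: int
    unique_token_count: int
    immediate_repeat_count: int
    silence_run_count: int


def build_inventory(
    syllable_list: Sequence[str], silence_marker: str = DEFAULT_SILENCE
) -> TokenInventory:
    """Build a :class:`TokenInventory` from an ordered syllable list.

    Ids follow list order; silence gets the last id.  Duplicates and a
    silence marker occurring in the list are rejected.
    """
    return TokenInventory(tuple(syllable_list), silence_marker)


def load_inventory(path: str | Path, silence_marker: str = DEFAULT_SILENCE) -> TokenInventory:
    """Load an inventory from a UTF-8 text file, one syllable per line."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return build_inventory([ln.strip() for ln in lines if ln.strip()], silence_marker)


def default_inventory(silence_marker: str = DEFAULT_SILENCE) -> TokenInventory:
    """The packaged 317-syllable inventory (token space of 318)."""
    text = (
        resources.files("adspeech.data").joinpath("syllables_317.txt").read_text("utf-8")
    )
    return build_inventory([ln for ln in text.splitlines() if ln], silence_marker)


def encode(
    strings: Iterable[str],
    inv: TokenInventory,
    sample_id: str = "",
    label: Optional[int] = None,
) -> FeatureSequence:
    """Map token strings to ids, preserving order and length."""
    ids = []
    for pos, s in enumerate(strings):
        if s not in inv:
            raise ValueError(f"unknown token {s!r} at position {pos}")
        ids.append(inv.id_of(s))
    return FeatureSequence(ids, sample_id=sample_id, label=label)


def decode(seq: FeatureSequence, inv: TokenInventory) -> list[str]:
    """Map token ids back to strings (inverse of :func:`encode`)."""
    return [inv.token_of(t) for t in seq.tokens]


def summarize(seq: FeatureSequence, inv: TokenInventory) -> SequenceSummary:
    """Count the clinically meaningful surface features of a sequence.

    ``immediate_repeat_count`` counts positions whose token equals the
    previous one; ``silence_run_count`` counts maximal runs of silence
    tokens.  Silence tokens take part in repeat counting like any other
    token.
    """
    seq.validate(inv)
    sil = inv.silence_id
    toks = seq.tokens
    silence = sum(1 for t in toks if t == sil)
    repeats = sum(1 for a, b in zip(toks, toks[1:]) if a == b)
    runs = sum(
        1 for i, t in enumerate(toks) if t == sil and (i == 0 or toks[i - 1] != sil)
    )
    return SequenceSummary(
        length=len(toks),
        silence_count=silence,
        non_silence_count=len(toks) - silence,
        unique_token_count=len(set(toks)),
        immediate_repeat_count=repeats,
        silence_run_count=runs,
    )


def read_sequence_file(
    path: str | Path,
    inv: TokenInventory,
    sample_id: str = "",
    label: Optional[int] = None,
) -> FeatureSequence:
    """Read a plain-text sequence file: whitespace-separated token strings."""
    text = Path(path).read_text(encoding="utf-8")
    return encode(text.split(), inv, sample_id=sample_id or str(path), label=label)


def write_sequence_file(seq: FeatureSequence, inv: TokenInventory, path: str | Path) -> None:
    Path(path).write_text(" ".join(decode(seq, inv)) + "\n", encoding="utf-8")
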