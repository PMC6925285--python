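"""Feature Sequence Generator: CRNN acoustic model + silence-aware decode.

The transcriber maps normalized log-filterbank features to per-frame
posteriors over the token classes plus a CTC blank, through a stack of 2-D
convolutions (batch-normalized, clipped-ReLU) followed by bidirectional
recurrent layers (layer-normalized) and a per-frame affine map.  It is
trained with CTC loss, Adam, and global gradient-norm clipping.

Decoding is greedy: the argmax class per frame, then a collapse in which
(i) a maximal run of at least N consecutive blank frames becomes one
silence token, where N = ceil(silence_threshold_s / effective_frame_s)
(e.g. a 3 s threshold at a 10 ms frame rate gives N = 300); (ii) shorter
blank runs are dropped but still separate repeated tokens; (iii) each
maximal run of one non-blank label emits a single token.

The full-scale architecture (conv filters 32/32/96 with kernels (11,41),
(11,21), (11,21); five bidirectional layers of 512 GRU cells per
direction) is the default config; tests and desk-scale runs use reduced
configs.  Time strides default to 1 so one output frame spans one 10 ms
hop; frequency strides of 2 on the first two convolutions cut compute
without touching the frame rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _nn
from .ctc import ctc_forward_loss, ctc_loss_and_grad  # re-exported for API
from .frontend import FeatureMatrix, cmvn, log_filterbank
from .tokens import FeatureSequence, TokenInventory

__all__ = [
    "GeneratorConfig",
    "TrainConfigCTC",
    "FramePath",
    "CTCTranscriber",
    "train_generator",
    "frame_argmax",
    "silence_run_threshold",
    "collapse_to_feature_sequence",
]


@dataclass
class GeneratorConfig:
    """Architecture and front-end hyper-parameters of the transcriber."""

    conv_specs: tuple = (
        (32, (11, 41), (1, 2)),
        (32, (11, 21), (1, 2)),
        (96, (11, 21), (1, 1)),
    )
    rnn_layers: int = 5
    rnn_cells_per_direction: int = 512
    bidirectional: bool = True
    n_bins: int = 80
    sample_rate: float = 16000.0
    win_s: float = 0.025
    hop_s: float = 0.010
    relu_cap: float = 20.0

    @property
    def effective_frame_s(self) -> float:
        """Seconds of audio per output frame: hop × product of time strides."""
        prod = 1
        for _, _, (st, _) in self.conv_specs:
            prod *= st
        return self.hop_s * prod

    def output_classes(self, inv: TokenInventory) -> int:
        return inv.size + 1  # + blank

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_specs"] = [[f, list(k), list(s)] for f, k, s in self.conv_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["conv_specs"] = tuple(
            (f, tuple(k), tuple(s)) for f, k, s in d["conv_specs"]
        )
        return cls(**d)


@dataclass
class TrainConfigCTC:
    """CTC training recipe: Adam 5e-4, clip 400, batch 32, ≤10 s utterances."""

    learning_rate: float = 0.0005
    grad_clip: float = 400.0
    batch_size: int = 32
    iterations: int = 50000
    max_utterance_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.grad_clip, self.batch_size,
               self.iterations, self.max_utterance_s) <= 0:
            raise ValueError("all CTC training parameters must be positive")


@dataclass
class FramePath:
    """Per-output-frame class ids (blank included) from greedy decoding."""

    labels: np.ndarray
    effective_frame_s: float = 0.010


def frame_argmax(log_posteriors: np.ndarray, effective_frame_s: float = 0.010) -> FramePath:
    """Greedy per-frame decode; ties go to the lowest class id."""
    lp = np.asarray(log_posteriors)
    if lp.size == 0:
        return FramePath(np.zeros(0, dtype=np.int64), effective_frame_s)
    return FramePath(lp.argmax(axis=1).astype(np.int64), effective_frame_s)


def silence_run_threshold(threshold_s: float, effective_frame_s: float) -> int:
    """Minimum blank-run length N that transcribes to a silence token.

    N = ceil(threshold_s / effective_frame_s): a 3 s threshold at the
    default 10 ms frame rate requires at least 300 consecutive blanks.
    """
    if threshold_s <= 0 or effective_frame_s <= 0:
        raise ValueError("threshold and frame duration must be positive")
    ratio = threshold_s / effective_frame_s
    # exact-quotient guard: 3.0 / 0.01 must give 300, not ceil(300.0000…)
    if abs(ratio - round(ratio)) < 1e-9 * max(1.0, abs(ratio)):
        return int(round(ratio))
    return int(math.ceil(ratio))


def collapse_to_feature_sequence(
    path: FramePath, n_blank_threshold: int, inv: TokenInventory
) -> FeatureSequence:
    """Collapse a frame path into a Feature Sequence.

    Maximal blank runs of length ≥ N emit one silence token; shorter blank
    runs vanish but still separate repeated labels; each maximal non-blank
    run emits one token.  The output never contains the blank.
    """
    if n_blank_threshold < 1:
        raise ValueError("blank-run threshold must be ≥ 1")
    blank = inv.size
    labels = np.asarray(path.labels)
    if np.any((labels < 0) | (labels > blank)):
        raise ValueError("frame label outside [0, inventory.size]")
    out: list[int] = []
    i = 0
    n = labels.size
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] == blank:
            if j - i >= n_blank_threshold:
                out.append(inv.silence_id)
        else:
            out.append(int(labels[i]))
        i = j
    return FeatureSequence(out)


class CTCTranscriber(BaseEstimator):
    """CRNN speech-to-token-sequence model trained with CTC.

    Parameters
    ----------
    inventory : TokenInventory the output tokens live in.
    config : GeneratorConfig, architecture (full-scale by default).
    train_config : TrainConfigCTC, optimization recipe.
    silence_threshold_s : minimum pause duration (seconds) transcribed as
        a silence token; typical settings are 1, 3 or 5 s.

    Fitted attributes
    -----------------
    layers_ : ordered layer dict; loss_history_ : per-iteration CTC loss;
    n_excluded_ : utterances dropped by the max-duration filter.
    """

    def __init__(
        self,
        inventory: Optional[TokenInventory] = None,
        config: Optional[GeneratorConfig] = None,
        train_config: Optional[TrainConfigCTC] = None,
        silence_threshold_s: float = 3.0,
    ):
        self.inventory = inventory
        self.config = config
        self.train_config = train_config
        self.silence_threshold_s = silence_threshold_s

    # ------------------------------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        cfg = self.config_
        inv = self.inventory
        layers: dict[str, _nn.Layer] = {}
        c_in = 1
        f_dim = cfg.n_bins
        for k, (n_filt, kernel, stride) in enumerate(cfg.conv_specs):
            layers[f"conv{k}"] = _nn.Conv2D(rng, c_in, n_filt, kernel, stride)
            layers[f"bn{k}"] = _nn.BatchNorm2D(n_filt)
            layers[f"act{k}"] = _nn.ClippedReLU(cfg.relu_cap)
            c_in = n_filt
            f_dim = -(-f_dim // stride[1])
        d_in = c_in * f_dim
        H = cfg.rnn_cells_per_direction
        for k in range(cfg.rnn_layers):
            if cfg.bidirectional:
                layers[f"rnn{k}"] = _nn.BiRecurrentLayer(rng, "gru", d_in, H)
                d_in = 2 * H
            else:
                layers[f"rnn{k}"] = _nn.RecurrentLayer(rng, "gru", d_in, H)
                d_in = H
            layers[f"ln{k}"] = _nn.LayerNorm(d_in)
        layers["out"] = _nn.Dense(rng, d_in, cfg.output_classes(inv))
        self.layers_ = layers

    def _conv_out_len(self, lengths: np.ndarray) -> np.ndarray:
        for _, _, (st, _) in self.config_.conv_specs:
            lengths = -(-lengths // st)
        return lengths

    def _forward(self, feats: np.ndarray, lengths: np.ndarray, train: bool
                 ) -> tuple[np.ndarray, np.ndarray]:
        """feats (B, T, F) → logits (B, T', classes) and frame lengths."""
        cfg = self.config_
        x = feats[:, None, :, :]  # (B, 1, T, F)
        for k in range(len(cfg.conv_specs)):
            x = self.layers_[f"conv{k}"].forward(x)
            x = self.layers_[f"bn{k}"].forward(x, train=train)
            x = self.layers_[f"act{k}"].forward(x)
        B, C, Tp, Fp = x.shape
        self._conv_shape = (B, C, Tp, Fp)
        h = x.transpose(0, 2, 1, 3).reshape(B, Tp, C * Fp)
        out_lens = self._conv_out_len(lengths)
        for k in range(cfg.rnn_layers):
            rnn = self.layers_[f"rnn{k}"]
            if isinstance(rnn, _nn.BiRecurrentLayer):
                h = rnn.forward(h, out_lens)
            else:
                h = rnn.forward(h)
            h = self.layers_[f"ln{k}"].forward(h)
        logits = self.layers_["out"].forward(h)
        return logits, out_lens

    def _backward(self, dlogits: np.ndarray) -> None:
        cfg = self.config_
        dh = self.layers_["out"].backward(dlogits)
        for k in range(cfg.rnn_layers - 1, -1, -1):
            dh = self.layers_[f"ln{k}"].backward(dh)
            dh = self.layers_[f"rnn{k}"].backward(dh)
        B, C, Tp, Fp = self._conv_shape
        dx = dh.reshape(B, Tp, C, Fp).transpose(0, 2, 1, 3)
        for k in range(len(cfg.conv_specs) - 1, -1, -1):
            dx = self.layers_[f"act{k}"].backward(dx)
            dx = self.layers_[f"bn{k}"].backward(dx)
            dx = self.layers_[f"conv{k}"].backward(dx)

    def _features(self, waveform: np.ndarray) -> np.ndarray:
        cfg = self.config_
        fm = log_filterbank(waveform, cfg.sample_rate, cfg.n_bins, cfg.win_s, cfg.hop_s)
        return cmvn(fm).values

    # ------------------------------------------------------------------
    def fit(self, X: Sequence[np.ndarray], y: Sequence, verbose: bool = False
            ) -> "CTCTranscriber":
        """Train on waveforms ``X`` with token-id (or string) targets ``y``.

        Targets are the reference syllable tokens, silence excluded (CTC
        learns pause frames as blanks).  Utterances longer than the
        configured maximum are removed before batching.
        """
        if self.inventory is None:
            raise ValueError("an inventory is required to fit")
        self.config_ = self.config or GeneratorConfig()
        tc = self.train_config or TrainConfigCTC()
        inv = self.inventory
        blank = inv.size

        targets = []
        for tgt in y:
            ids = tgt.tokens if isinstance(tgt, FeatureSequence) else [
                inv.id_of(t) if isinstance(t, str) else int(t) for t in tgt]
            if any(t == inv.silence_id for t in ids):
                raise ValueError("CTC targets must not contain silence tokens")
            targets.append(ids)

        max_samples = tc.max_utterance_s * self.config_.sample_rate
        keep = [i for i, w in enumerate(X) if len(w) <= max_samples]
        self.n_excluded_ = len(X) - len(keep)
        if not keep:
            raise ValueError(
                f"all {len(X)} utterances exceed {tc.max_utterance_s} s; nothing to train on")

        rng = np.random.default_rng(tc.seed)
        self._build(rng)
        feats = [self._features(np.asarray(X[i], dtype=np.float64)) for i in keep]
        targets = [targets[i] for i in keep]

        params = _nn.collect_params(self.layers_)
        opt = _nn.Adam(params, tc.learning_rate)
        self.loss_history_ = []
        n = len(feats)
        for it in range(tc.iterations):
            idx = rng.choice(n, size=min(tc.batch_size, n), replace=n < tc.batch_size)
            loss = self._train_step(idx, feats, targets, opt, blank)
            self.loss_history_.append(loss)
            if verbose and (it % 50 == 0 or it == tc.iterations - 1):
                print(f"iter {it}: ctc loss {loss:.4f}")
        self.inventory_hash_ = inv.content_hash()
        return self

    def _train_step(self, idx, feats, targets, opt, blank) -> float:
        batch_f = [feats[i] for i in idx]
        batch_t = [targets[i] for i in idx]
        lengths = np.array([f.shape[0] for f in batch_f])
        T = lengths.max()
        B = len(batch_f)
        padded = np.zeros((B, T, batch_f[0].shape[1]))
        for b, f in enumerate(batch_f):
            padded[b, : f.shape[0]] = f
        for layer in self.layers_.values():
            layer.zero_grads()
        logits, out_lens = self._forward(padded, lengths, train=True)
        dlogits = np.zeros_like(logits)
        total, n_ok = 0.0, 0
        for b in range(B):
            L = int(out_lens[b])
            loss_b, grad_b = ctc_loss_and_grad(logits[b, :L], batch_t[b], blank)
            if np.isfinite(loss_b):
                total += loss_b
                dlogits[b, :L] = grad_b
                n_ok += 1
        if n_ok == 0:
            return float("inf")
        dlogits /= n_ok
        self._backward(dlogits)
        grads = _nn.collect_grads(self.layers_)
        tc = self.train_config or TrainConfigCTC()
        _nn.clip_global_norm(grads, tc.grad_clip)
        opt.step(grads)
        return total / n_ok

    # ------------------------------------------------------------------
    def predict_log_posteriors(self, waveform: np.ndarray) -> np.ndarray:
        """(frames, classes) log posteriors for one waveform."""
        feats = self._features(np.asarray(waveform, dtype=np.float64))
        logits, out_lens = self._forward(
            feats[None], np.array([feats.shape[0]]), train=False)
        return _nn.log_softmax(logits[0, : int(out_lens[0])])

    def predict_frame_path(self, waveform: np.ndarray) -> FramePath:
        return frame_argmax(
            self.predict_log_posteriors(waveform), self.config_.effective_frame_s)

    def transcribe(self, waveform: np.ndarray,
                   silence_threshold_s: Optional[float] = None) -> FeatureSequence:
        """Waveform → Feature Sequence with the silence-run decode rule."""
        thr = self.silence_threshold_s if silence_threshold_s is None else silence_threshold_s
        path = self.predict_frame_path(waveform)
        n = silence_run_threshold(thr, path.effective_frame_s)
        return collapse_to_feature_sequence(path, n, self.inventory)

    def transform(self, X: Sequence[np.ndarray]) -> list[FeatureSequence]:
        return [self.transcribe(w) for w in X]

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = dict(_nn.collect_params(self.layers_))
        for k in range(len(self.config_.conv_specs)):
            bn = self.layers_[f"bn{k}"]
            arrays[f"bn{k}.running_mean"] = bn.running_mean
            arrays[f"bn{k}.running_var"] = bn.running_var
        meta = {
            "config": self.config_.to_dict(),
            "inventory_hash": self.inventory_hash_,
            "silence_threshold_s": self.silence_threshold_s,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path, inventory: TokenInventory) -> "CTCTranscriber":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if inventory.content_hash() != meta["inventory_hash"]:
            raise ValueError("checkpoint was trained with a different inventory")
        est = cls(inventory=inventory,
                  config=GeneratorConfig.from_dict(meta["config"]),
                  silence_threshold_s=meta["silence_threshold_s"])
        est.config_ = est.config
        est._build(np.random.default_rng(0))
        params = _nn.collect_params(est.layers_)
        for k, v in params.items():
            v[...] = data[k]
        for k in range(len(est.config_.conv_specs)):
            bn = est.layers_[f"bn{k}"]
            bn.running_mean = data[f"bn{k}.running_mean"]
            bn.running_var = data[f"bn{k}.running_var"]
        est.inventory_hash_ = meta["inventory_hash"]
        est.loss_history_ = []
        return est


def train_generator(
    X: Sequence[np.ndarray],
    y: Sequence,
    inventory: TokenInventory,
    config: Optional[GeneratorConfig] = None,
    train_config: Optional[TrainConfigCTC] = None,
) -> CTCTranscriber:
    """Functional wrapper: build and fit a :class:`CTCTranscriber`."""
    est = CTCTranscriber(inventory=inventory, config=config, train_config=train_config)
    return est.fit(X, y)
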