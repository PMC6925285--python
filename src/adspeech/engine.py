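"""AD Assessment Engine: recurrent classifier over Feature Sequences.

The engine realises  score = f(s_1, …, s_T) ∈ [0, 1]:  token ids are
embedded (one-hot by default), run through a single recurrent layer
(h_{t+1}, y_t = RNN(x_t, h_t); GRU with tanh outputs and sigmoid gates by
default), and the final-timestep output — the concatenation of both
directions' final outputs when bidirectional — feeds a fully-connected
layer with a sigmoid:  score = σ(W y_T + b).  Scores near 1 indicate
AD-like sequences, near 0 healthy ones.

Training minimizes the cross-entropy *sum* over each batch with Adam
(lr 0.001, batch 16, Glorot-normal init) and early-stops when validation
loss has not improved for a patience of 20 epochs, restoring the
best-validation checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _nn
from .tokens import FeatureSequence, TokenInventory

__all__ = [
    "EngineConfig",
    "TrainConfigEngine",
    "AssessmentClassifier",
    "pad_and_mask",
    "score_sequence",
    "train_engine",
]


@dataclass
class EngineConfig:
    """Architecture of the assessment engine.

    ``cells_per_direction`` defaults to 128 for bidirectional models and
    256 for unidirectional ones, so directionality comparisons keep the
    total cell budget fixed (2×128 vs 1×256).
    """

    cell_type: str = "gru"
    bidirectional: bool = True
    cells_per_direction: Optional[int] = None
    embedding: str | int = "onehot"

    def resolved_cells(self) -> int:
        if self.cells_per_direction is not None:
            return self.cells_per_direction
        return 128 if self.bidirectional else 256


@dataclass
class TrainConfigEngine:
    """Engine training recipe: Adam 1e-3, batch 16, patience 20."""

    learning_rate: float = 0.001
    batch_size: int = 16
    patience: int = 20
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("training parameters must be positive")


def pad_and_mask(batch: Sequence[FeatureSequence | Sequence[int]]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-pad token-id sequences to a common length.

    Returns (ids (B, T) with zero padding, lengths (B,), mask (B, T) bool).
    Because the forward direction's final output is read at t = len−1 and
    the backward direction consumes the reversed valid prefix only, padded
    positions can never influence y_T in either direction.
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    seqs = [b.tokens if isinstance(b, FeatureSequence) else list(b) for b in batch]
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    T = int(lengths.max())
    ids = np.zeros((len(seqs), T), dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=bool)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = True
    return ids, lengths, mask


class AssessmentClassifier(BaseEstimator, ClassifierMixin):
    """Sequence classifier scoring AD likelihood of a Feature Sequence.

    scikit-learn style: ``fit(X, y)`` on lists of
    :class:`FeatureSequence` (or raw id lists), ``predict_proba`` /
    ``decision-style`` scores via :meth:`score_samples`.

    Parameters mirror :class:`EngineConfig` and
    :class:`TrainConfigEngine`; a validation set may be passed to ``fit``
    (as the evaluation protocol does) or is split off internally.

    Fitted attributes: ``history_`` (per-epoch train/val loss),
    ``best_epoch_``, ``n_params_``, ``classes_``.
    """

    def __init__(
        self,
        cell_type: str = "gru",
        bidirectional: bool = True,
        cells_per_direction: Optional[int] = None,
        embedding: str | int = "onehot",
        vocab_size: Optional[int] = None,
        learning_rate: float = 0.001,
        batch_size: int = 16,
        patience: int = 20,
        max_epochs: int = 500,
        validation_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.cell_type = cell_type
        self.bidirectional = bidirectional
        self.cells_per_direction = cells_per_direction
        self.embedding = embedding
        self.vocab_size = vocab_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    @classmethod
    def from_configs(cls, ecfg: EngineConfig, tcfg: TrainConfigEngine,
                     vocab_size: Optional[int] = None, **kw) -> "AssessmentClassifier":
        return cls(cell_type=ecfg.cell_type, bidirectional=ecfg.bidirectional,
                   cells_per_direction=ecfg.cells_per_direction,
                   embedding=ecfg.embedding, vocab_size=vocab_size,
                   learning_rate=tcfg.learning_rate, batch_size=tcfg.batch_size,
                   patience=tcfg.patience, max_epochs=tcfg.max_epochs,
                   seed=tcfg.seed, **kw)

    def _cells(self) -> int:
        if self.cells_per_direction is not None:
            return self.cells_per_direction
        return 128 if self.bidirectional else 256

    def _build(self, rng: np.random.Generator, vocab: int) -> None:
        H = self._cells()
        layers: dict[str, _nn.Layer] = {}
        if self.embedding == "onehot":
            d_in = vocab
            self._embed = None
        else:
            d_in = int(self.embedding)
            layers["embed"] = _nn.Dense(rng, vocab, d_in)
            self._embed = layers["embed"]
        if self.bidirectional:
            layers["rnn"] = _nn.BiRecurrentLayer(rng, self.cell_type, d_in, H)
            d_head = 2 * H
        else:
            layers["rnn"] = _nn.RecurrentLayer(rng, self.cell_type, d_in, H)
            d_head = H
        layers["head"] = _nn.Dense(rng, d_head, 1)
        self.layers_ = layers
        self.vocab_size_ = vocab
        self.n_params_ = sum(
            p.size for p in _nn.collect_params(layers).values())

    def _one_hot(self, ids: np.ndarray) -> np.ndarray:
        out = np.zeros(ids.shape + (self.vocab_size_,))
        b, t = np.indices(ids.shape)
        out[b, t, ids] = 1.0
        return out

    def _forward_scores(self, ids: np.ndarray, lengths: np.ndarray
                        ) -> tuple[np.ndarray, dict]:
        """Returns per-sample sigmoid scores (B,) plus backward cache."""
        if self._embed is not None:
            x, tok_ids = self._embed.forward(self._one_hot(ids)), None
        else:
            x, tok_ids = None, ids  # one-hot handled sparsely inside the RNN
        rnn = self.layers_["rnn"]
        B = ids.shape[0]
        rows = np.arange(B)
        if self.bidirectional:
            h = rnn.forward(x, lengths, ids=tok_ids)  # (B, T, 2H) aligned
            H = rnn.d_hidden
            # forward direction's last valid output; backward direction's
            # output at t=0 (it has consumed the whole reversed sequence)
            yT = np.concatenate([h[rows, lengths - 1, :H], h[rows, 0, H:]], axis=1)
        else:
            h = rnn.forward(x, ids=tok_ids)
            yT = h[rows, lengths - 1]
        logit = self.layers_["head"].forward(yT)[:, 0]
        score = _nn.sigmoid(logit)
        cache = {"h_shape": h.shape, "lengths": lengths, "rows": rows}
        return score, cache

    def _backward_scores(self, dlogit: np.ndarray, cache: dict) -> None:
        dyT = self.layers_["head"].backward(dlogit[:, None])
        B, T, D = cache["h_shape"]
        rows, lengths = cache["rows"], cache["lengths"]
        dh = np.zeros((B, T, D))
        if self.bidirectional:
            H = D // 2
            dh[rows, lengths - 1, :H] = dyT[:, :H]
            dh[rows, 0, H:] = dyT[:, H:]
        else:
            dh[rows, lengths - 1] = dyT
        dx = self.layers_["rnn"].backward(dh)
        if self._embed is not None and dx is not None:
            self._embed.backward(dx)

    # ------------------------------------------------------------------
    @staticmethod
    def _extract(X, y):
        seqs = [x.tokens if isinstance(x, FeatureSequence) else list(x) for x in X]
        if y is None:
            y = [x.label for x in X]
            if any(lbl is None for lbl in y):
                raise ValueError("unlabeled sequences and no y given")
        y = np.asarray(y, dtype=np.int64)
        if any(len(s) == 0 for s in seqs):
            raise ValueError("empty sequences cannot be scored")
        return seqs, y

    def fit(self, X, y=None, X_val=None, y_val=None) -> "AssessmentClassifier":
        seqs, y = self._extract(X, y)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training set must contain both classes (0 and 1)")
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            # internal 85:15-style split when the caller supplies none
            n_val = max(1, int(round(self.validation_fraction * len(seqs))))
            perm = rng.permutation(len(seqs))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            vseqs = [seqs[i] for i in val_idx]
            vy = y[val_idx]
            seqs = [seqs[i] for i in tr_idx]
            y = y[tr_idx]
            if set(np.unique(y)) != {0, 1}:
                raise ValueError("internal split left a single-class training set")
        else:
            vseqs, vy = self._extract(X_val, y_val)
        if len(vseqs) == 0:
            raise ValueError("validation set is empty")

        vocab = self.vocab_size or (max(max(s) for s in seqs + vseqs) + 1)
        self._build(rng, vocab)
        params = _nn.collect_params(self.layers_)
        opt = _nn.Adam(params, self.learning_rate)

        self.history_ = {"train_loss": [], "val_loss": []}
        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = -1
        since_best = 0
        n = len(seqs)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            tr_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch = [seqs[i] for i in idx]
                ids, lengths, _ = pad_and_mask(batch)
                yb = y[idx].astype(np.float64)
                for layer in self.layers_.values():
                    layer.zero_grads()
                p, cache = self._forward_scores(ids, lengths)
                eps = 1e-12
                tr_loss += float(-np.sum(yb * np.log(p + eps)
                                         + (1 - yb) * np.log(1 - p + eps)))
                self._backward_scores(p - yb, cache)  # d(sum CE)/dlogit
                opt.step(_nn.collect_grads(self.layers_))
            val_loss = self._dataset_loss(vseqs, vy)
            self.history_["train_loss"].append(tr_loss)
            self.history_["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        for k, v in params.items():
            v[...] = best_params[k]
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_val
        self.classes_ = np.array([0, 1])
        return self

    def _dataset_loss(self, seqs, y) -> float:
        p = self._scores_of(seqs)
        y = np.asarray(y, dtype=np.float64)
        eps = 1e-12
        return float(-np.sum(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    def _scores_of(self, seqs) -> np.ndarray:
        out = np.empty(len(seqs))
        bs = max(self.batch_size, 1)
        for start in range(0, len(seqs), bs):
            batch = seqs[start:start + bs]
            ids, lengths, _ = pad_and_mask(batch)
            p, _ = self._forward_scores(ids, lengths)
            out[start:start + len(batch)] = p
        return out

    # ------------------------------------------------------------------
    def score_samples(self, X) -> np.ndarray:
        """AD-likelihood score in (0, 1) for each sequence."""
        seqs = [x.tokens if isinstance(x, FeatureSequence) else list(x) for x in X]
        if any(len(s) == 0 for s in seqs):
            raise ValueError("cannot score an empty sequence")
        if any(max(s) >= self.vocab_size_ for s in seqs):
            raise ValueError("sequence contains ids outside the trained vocabulary")
        return self._scores_of(seqs)

    def predict_proba(self, X) -> np.ndarray:
        p = self.score_samples(X)
        return np.column_stack([1 - p, p])

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.score_samples(X) >= threshold).astype(np.int64)

    # ------------------------------------------------------------------
    def save(self, path: str | Path, inventory: Optional[TokenInventory] = None) -> None:
        arrays = dict(_nn.collect_params(self.layers_))
        meta = {
            "params": self.get_params(),
            "vocab_size": int(self.vocab_size_),
            "inventory_hash": inventory.content_hash() if inventory else None,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path,
             inventory: Optional[TokenInventory] = None) -> "AssessmentClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if inventory is not None and meta["inventory_hash"] is not None \
                and inventory.content_hash() != meta["inventory_hash"]:
            raise ValueError("checkpoint was trained with a different inventory")
        est = cls(**meta["params"])
        est._build(np.random.default_rng(0), meta["vocab_size"])
        for k, v in _nn.collect_params(est.layers_).items():
            v[...] = data[k]
        est.classes_ = np.array([0, 1])
        return est


def score_sequence(seq: FeatureSequence, model: AssessmentClassifier) -> float:
    """Score one Feature Sequence with a fitted engine."""
    return float(model.score_samples([seq])[0])


def train_engine(train_set, val_set, ecfg: EngineConfig, tcfg: TrainConfigEngine,
                 vocab_size: Optional[int] = None) -> AssessmentClassifier:
    """Functional wrapper over :class:`AssessmentClassifier.fit`.

    ``train_set``/``val_set`` are (sequences, labels) pairs or lists of
    labeled :class:`FeatureSequence`.
    """
    def split(ds):
        if isinstance(ds, tuple):
            return ds
        return ds, None
    Xt, yt = split(train_set)
    Xv, yv = split(val_set)
    est = AssessmentClassifier.from_configs(ecfg, tcfg, vocab_size=vocab_size)
    return est.fit(Xt, yt, X_val=Xv, y_val=yv)
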