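"""Connectionist Temporal Classification: forward loss and gradient.

CTC scores a label sequence against per-frame class posteriors by summing
the probability of every frame-level path that collapses to the labels
(repeats merged, blanks removed).  The recursion runs over the extended
label sequence (blanks interleaved) in the log domain, so short targets
against long frame sequences stay numerically stable.

The gradient returned is with respect to the *logits* (pre-softmax),
using the standard identity  dL/du_{t,k} = y_{t,k} − γ_t(k)  where γ is
the state-posterior mass of extended states emitting class k at frame t.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ctc_forward_loss", "ctc_loss_and_grad", "min_frames_required"]

NEG_INF = -np.inf


def _extend(target: list[int], blank: int) -> np.ndarray:
    ext = np.empty(2 * len(target) + 1, dtype=np.int64)
    ext[0::2] = blank
    ext[1::2] = target
    return ext


def min_frames_required(target: list[int]) -> int:
    """Fewest frames a path collapsing to ``target`` can occupy."""
    repeats = sum(1 for a, b in zip(target, target[1:]) if a == b)
    return len(target) + repeats


def _logsumexp2(a, b):
    m = np.maximum(a, b)
    with np.errstate(invalid="ignore"):
        out = m + np.log(np.exp(a - m) + np.exp(b - m))
    return np.where(np.isneginf(m), NEG_INF, out)


def _alpha(logp: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Forward log-probabilities α[t, s] over extended states."""
    T = logp.shape[0]
    S = ext.size
    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = logp[0, ext[0]]
    if S > 1:
        alpha[0, 1] = logp[0, ext[1]]
    for t in range(1, T):
        prev = alpha[t - 1]
        stay = prev
        diag = np.full(S, NEG_INF)
        diag[1:] = prev[:-1]
        a = _logsumexp2(stay, diag)
        # skip transition s-2 → s allowed when ext[s] is a label differing
        # from ext[s-2] (never into blanks, never between equal labels)
        skip = np.full(S, NEG_INF)
        if S > 2:
            skip[2:] = prev[:-2]
        can_skip = np.zeros(S, dtype=bool)
        can_skip[2:] = (ext[2:] != ext[:-2]) & (ext[2:] != ext[0])  # ext[0] is blank
        a = np.where(can_skip, _logsumexp2(a, skip), a)
        alpha[t] = a + logp[t, ext]
    return alpha


def ctc_forward_loss(log_posteriors: np.ndarray, target, blank_id: int) -> float:
    """−log P(target | frame posteriors) under CTC path semantics.

    Parameters
    ----------
    log_posteriors : (frames, classes) log-probabilities (rows normalized).
    target : iterable of class ids, none equal to ``blank_id``.
    blank_id : the blank class index.

    Returns ``inf`` when the target cannot fit in the available frames
    (more labels, counting forced blanks between repeats, than frames).
    """
    logp = np.asarray(log_posteriors, dtype=np.float64)
    target = [int(t) for t in target]
    if any(t == blank_id for t in target):
        raise ValueError("target must not contain the blank id")
    if any(not 0 <= t < logp.shape[1] for t in target):
        raise ValueError("target id outside posterior class range")
    T = logp.shape[0]
    if T == 0:
        return 0.0 if not target else np.inf
    if min_frames_required(target) > T:
        return np.inf
    ext = _extend(target, blank_id)
    alpha = _alpha(logp, ext)
    tail = alpha[-1, -1] if ext.size == 1 else _logsumexp2(alpha[-1, -1], alpha[-1, -2])
    return float(-tail)


def ctc_loss_and_grad(logits: np.ndarray, target, blank_id: int
                      ) -> tuple[float, np.ndarray]:
    """CTC loss and gradient w.r.t. the (frames × classes) logits.

    Infeasible targets return ``(inf, zeros)`` so callers can drop the
    sample from the batch instead of propagating a non-finite gradient.
    """
    logits = np.asarray(logits, dtype=np.float64)
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    target = [int(t) for t in target]
    T, C = logp.shape
    if min_frames_required(target) > T or T == 0:
        return np.inf, np.zeros_like(logits)
    ext = _extend(target, blank_id)
    S = ext.size
    alpha = _alpha(logp, ext)

    beta = np.full((T, S), NEG_INF)
    beta[-1, -1] = 0.0
    if S > 1:
        beta[-1, -2] = 0.0
    can_skip = np.zeros(S, dtype=bool)
    can_skip[2:] = (ext[2:] != ext[:-2]) & (ext[2:] != blank_id)
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + logp[t + 1, ext]
        stay = nxt
        diag = np.full(S, NEG_INF)
        diag[:-1] = nxt[1:]
        b = _logsumexp2(stay, diag)
        skip = np.full(S, NEG_INF)
        if S > 2:
            skip[:-2] = nxt[2:]
        allow = np.zeros(S, dtype=bool)
        allow[:-2] = can_skip[2:]
        b = np.where(allow, _logsumexp2(b, skip), b)
        beta[t] = b

    log_z = alpha[-1, -1] if S == 1 else _logsumexp2(alpha[-1, -1], alpha[-1, -2])
    gamma_log = alpha + beta - log_z  # (T, S)

    grad = np.exp(logp)
    gm = np.exp(gamma_log)
    for s in range(S):
        grad[:, ext[s]] -= gm[:, s]
    return float(-log_z), grad
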