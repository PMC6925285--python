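"""Repeated cross-validation protocol for assessing the engine.

One *trial*: shuffle the dataset, walk through it taking 10 samples at a
time as the test set; for each test fold, split the remaining samples
85:15 into train and validation sets, train an engine with early
stopping, and score the held-out fold.  Scores pooled over all folds give
one AUROC (plus sensitivity and specificity at a 0.5 threshold).  Several
trials with different shuffles are averaged to damp training randomness;
the reference protocol uses six.

AUROC is the midrank (Mann–Whitney) statistic: the probability that a
random AD sample outscores a random healthy one, ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .engine import AssessmentClassifier
from .tokens import FeatureSequence

__all__ = [
    "FoldPlan",
    "TrialResult",
    "ExperimentResult",
    "make_fold_plan",
    "auroc",
    "sensitivity_specificity",
    "run_trial",
    "run_experiment",
]


@dataclass
class FoldPlan:
    """Index sets for one trial: disjoint sequential test folds after a
    seeded shuffle, each with its train/val split of the remainder."""

    seed: int
    test_folds: list[np.ndarray]
    train_sets: list[np.ndarray]
    val_sets: list[np.ndarray]

    @property
    def n_folds(self) -> int:
        return len(self.test_folds)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_fold_plan(n_samples: int, fold_size: int = 10,
                   val_ratio: float = 0.15, seed: int = 0) -> FoldPlan:
    """Shuffle, then cut sequential test folds of ``fold_size`` samples.

    For each fold the unselected samples are split train/val with
    ``val_count = round-half-up(val_ratio × remaining)``; with 120 samples
    and fold size 10 that is 110 remaining → 17 validation, 93 training.
    The last fold may be smaller when ``n_samples`` is not divisible.
    """
    if fold_size <= 0:
        raise ValueError("fold_size must be positive")
    if n_samples <= fold_size:
        raise ValueError("need more samples than one fold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    test_folds, train_sets, val_sets = [], [], []
    for start in range(0, n_samples, fold_size):
        test = order[start:start + fold_size]
        rest = np.concatenate([order[:start], order[start + fold_size:]])
        n_val = _round_half_up(val_ratio * rest.size)
        # val drawn from the tail of the shuffled remainder (seeded, disjoint)
        val = rest[rest.size - n_val:]
        train = rest[: rest.size - n_val]
        test_folds.append(test)
        train_sets.append(train)
        val_sets.append(val)
    return FoldPlan(seed=seed, test_folds=test_folds,
                    train_sets=train_sets, val_sets=val_sets)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Midrank AUROC: P(score⁺ > score⁻) + ½·P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sensitivity_specificity(scores: Sequence[float], labels: Sequence[int],
                            threshold: float = 0.5) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)) predicting AD when score ≥ threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("sensitivity/specificity need both classes present")
    pred = s >= threshold
    sens = float((pred & (y == 1)).sum() / (y == 1).sum())
    spec = float((~pred & (y == 0)).sum() / (y == 0).sum())
    return sens, spec


@dataclass
class TrialResult:
    seed: int
    scores: np.ndarray           # one pooled score per dataset sample
    labels: np.ndarray
    auroc: float
    sensitivity: float
    specificity: float
    variant_scores: dict[str, np.ndarray] = field(default_factory=dict)
    variant_auroc: dict[str, float] = field(default_factory=dict)


@dataclass
class ExperimentResult:
    trials: list[TrialResult]

    def _agg(self, vals: list[float]) -> tuple[float, float]:
        a = np.asarray(vals)
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    @property
    def auroc_mean_sd(self) -> tuple[float, float]:
        return self._agg([t.auroc for t in self.trials])

    @property
    def sensitivity_mean_sd(self) -> tuple[float, float]:
        return self._agg([t.sensitivity for t in self.trials])

    @property
    def specificity_mean_sd(self) -> tuple[float, float]:
        return self._agg([t.specificity for t in self.trials])

    def variant_auroc_mean_sd(self, name: str) -> tuple[float, float]:
        return self._agg([t.variant_auroc[name] for t in self.trials])

    def summary(self) -> dict[str, float]:
        am, asd = self.auroc_mean_sd
        sm, ssd = self.sensitivity_mean_sd
        pm, psd = self.specificity_mean_sd
        return {"auroc_mean": am, "auroc_sd": asd,
                "sensitivity_mean": sm, "sensitivity_sd": ssd,
                "specificity_mean": pm, "specificity_sd": psd,
                "n_trials": len(self.trials)}


def _sequences_labels(dataset) -> tuple[list, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
        return list(X), np.asarray(y, dtype=np.int64)
    X = list(dataset)
    y = np.asarray([s.label for s in X], dtype=np.int64)
    return X, y


def run_trial(
    dataset,
    engine_factory: Callable[[int], AssessmentClassifier],
    trial_seed: int,
    fold_size: int = 10,
    val_ratio: float = 0.15,
    threshold: float = 0.5,
    test_transforms: Optional[dict[str, Callable]] = None,
) -> TrialResult:
    """One full pass: every sample tested exactly once.

    ``engine_factory(seed)`` must return an unfitted classifier;
    ``test_transforms`` optionally maps names to per-sequence transforms
    (e.g. a corruption model) whose pooled AUROC is computed from the same
    fold models at no extra training cost.
    """
    X, y = _sequences_labels(dataset)
    plan = make_fold_plan(len(X), fold_size, val_ratio, trial_seed)
    pooled = np.full(len(X), np.nan)
    variants = {name: np.full(len(X), np.nan) for name in (test_transforms or {})}
    for k in range(plan.n_folds):
        tr, va, te = plan.train_sets[k], plan.val_sets[k], plan.test_folds[k]
        est = engine_factory(trial_seed * 1009 + k)
        est.fit([X[i] for i in tr], y[tr],
                X_val=[X[i] for i in va], y_val=y[va])
        pooled[te] = est.score_samples([X[i] for i in te])
        for name, tf in (test_transforms or {}).items():
            variants[name][te] = est.score_samples([tf(X[i]) for i in te])
    assert not np.isnan(pooled).any()
    sens, spec = sensitivity_specificity(pooled, y, threshold)
    result = TrialResult(
        seed=trial_seed, scores=pooled, labels=y,
        auroc=auroc(pooled, y), sensitivity=sens, specificity=spec,
        variant_scores=variants,
        variant_auroc={n: auroc(v, y) for n, v in variants.items()},
    )
    return result


def run_experiment(
    dataset,
    engine_factory: Callable[[int], AssessmentClassifier],
    n_trials: int = 6,
    base_seed: int = 0,
    fold_size: int = 10,
    val_ratio: float = 0.15,
    threshold: float = 0.5,
    test_transforms: Optional[dict[str, Callable]] = None,
) -> ExperimentResult:
    """Average the cross-validation protocol over ``n_trials`` shuffles."""
    trials = [
        run_trial(dataset, engine_factory, base_seed + 7919 * t,
                  fold_size, val_ratio, threshold, test_transforms)
        for t in range(n_trials)
    ]
    return ExperimentResult(trials)
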