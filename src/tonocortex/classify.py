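"""Frequency-selective processing via one-vs-one linear SVM decoding.

Single-trial scalp EEG (all channels, the full 350 ms poststimulus window,
raw microvolts) is classified with pairwise linear SVMs (SMO-family solver,
C = 1, gradient tolerance 1e-3) and majority voting.  Performance is the
mean over repeated random equal-size 4-fold cross-validation; significance
comes from a permutation test on the class labels.  Chance level is 1/K.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Hashable, Sequence

import numpy as np
from sklearn.svm import SVC

from . import protocol as proto
from .preprocess import EpochSet
from .protocol import StimulusType

logger = logging.getLogger("tonocortex")

POSTSTIM_WINDOW_MS = (0.0, 350.0)      # half-open [0, 350)
SVM_C = 1.0
SVM_TOL = 1e-3


@dataclasses.dataclass
class FeatureMatrix:
    """Trials x features design matrix with class labels.

    Features are the flattened channels x poststimulus-samples block,
    channel-major (all time points of channel 0, then channel 1, ...).
    """

    X: np.ndarray
    y: np.ndarray                       # integer-coded classes
    class_names: list[Hashable]         # code -> original label
    feature_layout: tuple[int, int]     # (n_channels, n_times)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def chance_level(self) -> float:
        return 1.0 / self.n_classes


@dataclasses.dataclass
class CVConfig:
    """Cross-validation / permutation-test settings (defaults = full protocol)."""

    n_folds: int = 4
    n_repetitions: int = 1000
    n_permutations: int = 1000
    svm_c: float = SVM_C
    svm_tolerance: float = SVM_TOL
    standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_folds, self.n_repetitions, self.n_permutations) < 1:
            raise ValueError("CV configuration values must be positive")


@dataclasses.dataclass
class ClassificationOutcome:
    """Decoding result for one task (global + per-class, with p-values)."""

    task: str
    global_accuracy: float
    per_class_accuracy: dict
    p_global: float
    p_global_plus_one: float            # (k+1)/(n+1) variant, never exactly 0
    p_per_class: dict
    n_trials_used: int
    chance_level: float
    n_permutations: int
    null_accuracies: np.ndarray | None = None
    repetition_accuracies: np.ndarray | None = None
    error: str | None = None

    def significant(self, alpha: float = 0.01) -> bool:
        return self.error is None and self.p_global < alpha

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "global_accuracy": self.global_accuracy,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "p_global": self.p_global,
            "p_global_plus_one": self.p_global_plus_one,
            "p_per_class": {str(k): v for k, v in self.p_per_class.items()},
            "n_trials_used": self.n_trials_used,
            "chance_level": self.chance_level,
            "n_permutations": self.n_permutations,
            "null_accuracies": None if self.null_accuracies is None
            else list(map(float, self.null_accuracies)),
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# feature construction

def build_feature_matrix(ep: EpochSet, task: str,
                         modality: str | None = None,
                         window_ms: tuple[float, float] = POSTSTIM_WINDOW_MS
                         ) -> FeatureMatrix:
    """Flatten epochs into a trials x (channels*times) matrix for one task.

    ``task`` is ``"frequency"`` (4 classes within one ``modality``) or
    ``"modality"`` (3 classes over all trials).  Voltages stay in raw uV.
    """
    tmask = (ep.time_axis_ms >= window_ms[0]) & (ep.time_axis_ms < window_ms[1])
    if task == "frequency":
        if modality not in proto.MODALITIES:
            raise ValueError(f"frequency task needs a modality, got {modality!r}")
        keep = np.array([l.modality == modality for l in ep.labels])
        classes: list[Hashable] = list(proto.FREQUENCIES_HZ)
        raw = [ep.labels[i].frequency_hz for i in np.flatnonzero(keep)]
    elif task == "modality":
        keep = np.ones(ep.n_trials, dtype=bool)
        classes = list(proto.MODALITIES)
        raw = [l.modality for l in ep.labels]
    else:
        raise ValueError(f"unknown task {task!r}")

    if not keep.any():
        raise ValueError(f"no trials selected for task {task!r} ({modality})")
    data = ep.data[keep][:, :, tmask]
    X = data.reshape(data.shape[0], -1)              # channel-major, time-minor
    code = {c: i for i, c in enumerate(classes)}
    y = np.array([code[r] for r in raw], dtype=int)
    counts = np.bincount(y, minlength=len(classes))
    if counts.min() < 4:
        raise ValueError(f"every class needs >= n_folds trials; counts={counts.tolist()}")
    return FeatureMatrix(X=X, y=y, class_names=classes,
                         feature_layout=(data.shape[1], data.shape[2]))


# ---------------------------------------------------------------------------
# one-vs-one SVM

def svm_ovo_fit_predict(X_train: np.ndarray, y_train: np.ndarray,
                        X_test: np.ndarray,
                        C: float = SVM_C, tol: float = SVM_TOL) -> np.ndarray:
    """Fit all pairwise linear SVMs and majority-vote the test labels.

    Voting ties are broken by the lowest class index.  The binary problems
    are solved by libsvm's SMO-type optimizer with the given tolerance.
    """
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    votes = np.zeros((X_test.shape[0], int(classes.max()) + 1), dtype=int)
    for a, b in itertools.combinations(classes, 2):
        mask = (y_train == a) | (y_train == b)
        clf = SVC(kernel="linear", C=C, tol=tol)
        clf.fit(X_train[mask], y_train[mask])
        pred = clf.predict(X_test)
        for cls in (a, b):
            votes[:, cls] += pred == cls
    return np.argmax(votes, axis=1)                  # first max = lowest index


# ---------------------------------------------------------------------------
# repeated random 4-fold cross-validation

def _one_repetition(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                    cfg: CVConfig, n_classes: int
                    ) -> tuple[float, np.ndarray]:
    """One repetition: permute, drop n mod k at random, k equal test folds.

    Returns (mean fold accuracy, per-class recall pooled over the folds).
    """
    n = len(y)
    k = cfg.n_folds
    perm = rng.permutation(n)
    usable = n - (n % k)
    perm = perm[:usable]                              # remainder dropped at random
    folds = perm.reshape(k, usable // k)

    fold_acc = np.empty(k)
    correct = np.zeros(n_classes)
    total = np.zeros(n_classes)
    for f in range(k):
        test = folds[f]
        train = np.concatenate([folds[g] for g in range(k) if g != f])
        pred = svm_ovo_fit_predict(X[train], y[train], X[test],
                                   C=cfg.svm_c, tol=cfg.svm_tolerance)
        fold_acc[f] = float(np.mean(pred == y[test]))
        for c in range(n_classes):
            m = y[test] == c
            total[c] += m.sum()
            correct[c] += (pred[m] == c).sum()
    with np.errstate(invalid="ignore"):
        recall = np.where(total > 0, correct / np.maximum(total, 1), np.nan)
    return float(fold_acc.mean()), recall


def cross_validated_accuracy(fm: FeatureMatrix, cfg: CVConfig
                             ) -> tuple[float, dict, np.ndarray, np.ndarray]:
    """Mean accuracy over repeated random equal-size k-fold CV.

    Returns (global accuracy, per-class recall dict, per-repetition
    accuracies, per-repetition per-class recalls).  Deterministic for a
    fixed ``cfg.seed``.
    """
    if len(fm.y) < 2 * fm.n_classes:
        raise ValueError("too few trials for cross-validation")
    X = fm.X
    if cfg.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    rng = np.random.default_rng(cfg.seed)
    accs = np.empty(cfg.n_repetitions)
    recalls = np.empty((cfg.n_repetitions, fm.n_classes))
    for r in range(cfg.n_repetitions):
        accs[r], recalls[r] = _one_repetition(X, fm.y, rng, cfg, fm.n_classes)
    per_class = {fm.class_names[c]: float(np.nanmean(recalls[:, c]))
                 for c in range(fm.n_classes)}
    return float(accs.mean()), per_class, accs, recalls


# ---------------------------------------------------------------------------
# permutation test

def permutation_pvalue(fm: FeatureMatrix, observed: float, cfg: CVConfig,
                       observed_per_class: dict | None = None
                       ) -> tuple[float, dict, np.ndarray]:
    """Label-shuffling null for the CV accuracy (one CV repetition per draw).

    p = #{null >= observed} / n_permutations, which can be exactly 0 for
    effects stronger than every permutation.  Per-class p-values are
    computed the same way from the null per-class recalls.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    one_rep = dataclasses.replace(cfg, n_repetitions=1)
    null_acc = np.empty(cfg.n_permutations)
    null_recalls = np.empty((cfg.n_permutations, fm.n_classes))
    for i in range(cfg.n_permutations):
        y_perm = rng.permutation(fm.y)
        perm_fm = dataclasses.replace(fm, y=y_perm)
        seed_i = int(rng.integers(0, 2**31 - 1))
        acc, _, _, recalls = cross_validated_accuracy(
            perm_fm, dataclasses.replace(one_rep, seed=seed_i))
        null_acc[i] = acc
        null_recalls[i] = recalls[0]
    p_global = float(np.mean(null_acc >= observed))
    p_per_class: dict = {}
    if observed_per_class is not None:
        for c, name in enumerate(fm.class_names):
            obs_c = observed_per_class[name]
            nulls_c = null_recalls[:, c]
            valid = ~np.isnan(nulls_c)
            p_per_class[name] = float(np.mean(nulls_c[valid] >= obs_c)) \
                if valid.any() else float("nan")
    return p_global, p_per_class, null_acc


# ---------------------------------------------------------------------------
# full suite

def classify_task(ep: EpochSet, task: str, cfg: CVConfig,
                  modality: str | None = None) -> ClassificationOutcome:
    """CV accuracy + permutation significance for one decoding task."""
    name = task if modality is None else f"{task}:{modality}"
    fm = build_feature_matrix(ep, task, modality=modality)
    acc, per_class, accs, _ = cross_validated_accuracy(fm, cfg)
    p_global, p_per_class, null_acc = permutation_pvalue(fm, acc, cfg, per_class)
    k = int(np.sum(null_acc >= acc))
    return ClassificationOutcome(
        task=name, global_accuracy=acc, per_class_accuracy=per_class,
        p_global=p_global,
        p_global_plus_one=(k + 1) / (cfg.n_permutations + 1),
        p_per_class=p_per_class, n_trials_used=len(fm.y),
        chance_level=fm.chance_level, n_permutations=cfg.n_permutations,
        null_accuracies=null_acc, repetition_accuracies=accs)


def run_classification_suite(ep: EpochSet, cfg: CVConfig
                             ) -> dict[str, ClassificationOutcome]:
    """All four tasks: 3-class modality + 4-class frequency per modality.

    A failure in one task is recorded in its outcome; the others still run.
    """
    tasks: list[tuple[str, str | None]] = [("modality", None)] + \
        [("frequency", m) for m in proto.MODALITIES]
    out: dict[str, ClassificationOutcome] = {}
    for task, modality in tasks:
        name = task if modality is None else f"{task}:{modality}"
        try:
            out[name] = classify_task(ep, task, cfg, modality=modality)
        except Exception as exc:                      # noqa: BLE001 - recorded
            logger.warning("task %s failed: %s", name, exc)
            out[name] = ClassificationOutcome(
                task=name, global_accuracy=float("nan"), per_class_accuracy={},
                p_global=float("nan"), p_global_plus_one=float("nan"),
                p_per_class={}, n_trials_used=0, chance_level=float("nan"),
                n_permutations=cfg.n_permutations, error=str(exc))
    return out
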