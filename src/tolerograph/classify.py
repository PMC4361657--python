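"""Cross-validated tolerant vs non-tolerant classification.

A stratified leave-10%-out scheme: patients (controls excluded) are
partitioned into folds balanced across the two phenotype classes; within
each fold's training samples only, the top-k most discriminative probe
sets are selected (by the SAM d-statistic or signal-to-noise), features
are standardized, and a small feed-forward network (one hidden layer of
three logistic units) is trained. Held-out predictions are pooled into a
confusion matrix, an overall weighted accuracy (total correct / total
classified), per-feature selection-stability counts, and an ROC curve
with a bootstrap AUC confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core import (NONTOL, TOL, DataError, ExpressionMatrix, Sample)
from .sam import choose_s0, compute_dstat


@dataclass
class CvConfig:
    n_folds: int = 10
    k_features: int = 20
    selector: str = "sam_d"            # or "snr"
    hidden_units: int = 3
    max_epochs: int = 500
    bootstrap_ci_reps: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2:
            raise DataError("n_folds must be >= 2")
        if self.k_features < 1:
            raise DataError("k_features must be >= 1")
        if self.selector not in ("sam_d", "snr"):
            raise DataError(f"unknown selector {self.selector!r}")


@dataclass
class FoldResult:
    held_out: List[str]
    features: List[str]
    truth: List[str]
    predicted: List[str]
    scores: List[float]                # P(TOL) for each held-out sample

    @property
    def n_correct(self) -> int:
        return sum(t == p for t, p in zip(self.truth, self.predicted))


@dataclass
class CvReport:
    folds: List[FoldResult]
    confusion: Dict[str, Dict[str, int]]   # true class -> predicted class -> n
    weighted_accuracy: float
    per_class_accuracy: Dict[str, float]
    balanced_accuracy: float
    stability: Dict[str, int]
    roc: List[Tuple[float, float]]
    auc: float
    auc_ci: Tuple[float, float]


def make_folds(samples: Sequence[Sample], cfg: CvConfig) -> List[List[str]]:
    """Stratified partition of the patient samples into hold-out folds.

    Every patient appears in exactly one fold; within each class, fold
    sizes differ by at most one. Controls are excluded. Deterministic
    for a fixed seed.
    """
    cfg.validate()
    patients = [s for s in samples if s.group in (TOL, NONTOL)]
    if len(patients) < cfg.n_folds:
        raise DataError("fewer patient samples than folds")
    rng = np.random.default_rng(cfg.seed)
    folds: List[List[str]] = [[] for _ in range(cfg.n_folds)]
    cursor = 0   # carried across classes so total fold sizes differ by <= 1
    for group in (TOL, NONTOL):
        ids = [s.sample_id for s in patients if s.group == group]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for sid in ids:
            folds[cursor % cfg.n_folds].append(sid)
            cursor += 1
    return folds


def select_features(x: ExpressionMatrix, labels: Sequence[int], k: int,
                    selector: str = "sam_d") -> List[str]:
    """Top-k discriminative probe sets from training data only.

    ``sam_d`` ranks by |d| with the fudge factor chosen on the training
    fold; ``snr`` ranks by |signal-to-noise|. Ties break to the
    lexicographically smaller probe id. If k exceeds the probe count,
    all probes are returned with a warning.
    """
    labels = np.asarray(labels)
    if k > x.n_probes:
        import warnings
        warnings.warn(f"k={k} exceeds {x.n_probes} probes; returning all")
        k = x.n_probes
    if selector == "sam_d":
        _, s, diff = compute_dstat(x, labels, s0=1e-12)
        s0 = choose_s0(s, diff)
        d, _, _ = compute_dstat(x, labels, s0=s0)
        strength = np.abs(d)
    elif selector == "snr":
        mask_a, mask_b = labels == 1, labels == 0
        mu_a = x.values[:, mask_a].mean(axis=1)
        mu_b = x.values[:, mask_b].mean(axis=1)
        sd_a = x.values[:, mask_a].std(axis=1, ddof=1)
        sd_b = x.values[:, mask_b].std(axis=1, ddof=1)
        strength = np.abs((mu_a - mu_b) / np.maximum(sd_a + sd_b, 1e-12))
    else:
        raise DataError(f"unknown selector {selector!r}")
    order = sorted(range(x.n_probes), key=lambda i: (-strength[i], x.probe_ids[i]))
    return [x.probe_ids[i] for i in order[:k]]


class AnnModel:
    """Default classifier: 1 hidden layer of 3 logistic units, fixed-seed
    initialization, trained for at most ``max_epochs`` iterations.

    Any object exposing fit(X, y) / score_samples(X) -> P(TOL) /
    classify(X) -> labels can stand in.
    """

    def __init__(self, hidden_units: int = 3, max_epochs: int = 500, seed: int = 0):
        self.scaler = StandardScaler()
        self.net = MLPClassifier(
            hidden_layer_sizes=(hidden_units,), activation="logistic",
            solver="lbfgs", max_iter=max_epochs, random_state=seed)

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "AnnModel":
        Xs = self.scaler.fit_transform(X)
        self.net.fit(Xs, list(y))
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler.transform(X)
        proba = self.net.predict_proba(Xs)
        tol_col = list(self.net.classes_).index(TOL)
        return proba[:, tol_col]

    def classify(self, X: np.ndarray) -> List[str]:
        return list(self.net.predict(self.scaler.transform(X)))


def roc_auc(scores: Sequence[float], truth: Sequence[str],
            bootstrap_reps: int = 2000, seed: int = 0,
            positive: str = TOL) -> Tuple[List[Tuple[float, float]], float,
                                          Tuple[float, float]]:
    """Empirical ROC points, trapezoid AUC, and a stratified percentile
    bootstrap confidence interval."""
    from sklearn.metrics import roc_curve, roc_auc_score
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if t == positive else 0 for t in truth])
    if y.min() == y.max():
        raise DataError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    boots = []
    for _ in range(bootstrap_reps):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        ys, ss = y[idx], scores[idx]
        if np.unique(ss).size == 1:
            boots.append(0.5)
        else:
            boots.append(roc_auc_score(ys, ss))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return list(zip(fpr.tolist(), tpr.tolist())), auc, (float(lo), float(hi))


def cross_validate(x: ExpressionMatrix, samples: Sequence[Sample],
                   cfg: CvConfig | None = None,
                   model_factory=None) -> CvReport:
    """Leave-10%-out cross-validation with per-fold feature selection.

    Feature selection, scaling, and model fitting all see training-fold
    samples only, so held-out performance is leakage-free. Returns the
    pooled confusion matrix, weighted and balanced accuracy, feature
    stability tallies, and ROC/AUC over pooled held-out scores.
    """
    cfg = cfg or CvConfig()
    cfg.validate()
    patients = [s for s in samples if s.group in (TOL, NONTOL)]
    group_of = {s.sample_id: s.group for s in patients}
    for g in (TOL, NONTOL):
        if sum(1 for s in patients if s.group == g) < 2:
            raise DataError(f"need >= 2 {g} samples")
    if model_factory is None:
        model_factory = lambda seed: AnnModel(cfg.hidden_units, cfg.max_epochs, seed)

    folds = make_folds(samples, cfg)
    probe_pos = {p: i for i, p in enumerate(x.probe_ids)}
    fold_results: List[FoldResult] = []
    stability: Dict[str, int] = {}

    for f, held in enumerate(folds):
        train_ids = [s.sample_id for s in patients if s.sample_id not in held]
        train_x = x.subset_samples(train_ids)
        train_labels = np.array([1 if group_of[sid] == TOL else 0
                                 for sid in train_ids])
        feats = select_features(train_x, train_labels, cfg.k_features,
                                cfg.selector)
        for p in feats:
            stability[p] = stability.get(p, 0) + 1
        rows = [probe_pos[p] for p in feats]
        Xtr = train_x.values[rows].T
        ytr = [group_of[sid] for sid in train_ids]
        Xte = x.subset_samples(held).values[rows].T

        model = model_factory(cfg.seed + f)
        try:
            model.fit(Xtr, ytr)
        except Exception:
            model = model_factory(cfg.seed + f + 10007)  # one perturbed retry
            model.fit(Xtr, ytr)
        preds = model.classify(Xte)
        scores = list(np.asarray(model.score_samples(Xte), dtype=float))
        fold_results.append(FoldResult(
            held_out=list(held), features=list(feats),
            truth=[group_of[sid] for sid in held],
            predicted=preds, scores=scores))

    confusion = {TOL: {TOL: 0, NONTOL: 0}, NONTOL: {TOL: 0, NONTOL: 0}}
    all_truth: List[str] = []
    all_scores: List[float] = []
    for fr in fold_results:
        for t, p, sc in zip(fr.truth, fr.predicted, fr.scores):
            confusion[t][p] += 1
            all_truth.append(t)
            all_scores.append(sc)
    total = sum(sum(row.values()) for row in confusion.values())
    correct = confusion[TOL][TOL] + confusion[NONTOL][NONTOL]
    per_class = {g: (confusion[g][g] / sum(confusion[g].values())
                     if sum(confusion[g].values()) else float("nan"))
                 for g in (TOL, NONTOL)}
    roc, auc, ci = roc_auc(all_scores, all_truth,
                           bootstrap_reps=cfg.bootstrap_ci_reps, seed=cfg.seed)
    return CvReport(
        folds=fold_results, confusion=confusion,
        weighted_accuracy=correct / total,
        per_class_accuracy=per_class,
        balanced_accuracy=float(np.mean([per_class[TOL], per_class[NONTOL]])),
        stability=stability, roc=roc, auc=auc, auc_ci=ci)


def feature_stability(report: CvReport, min_count: int = 9
                      ) -> List[Tuple[str, int]]:
    """Features selected at least ``min_count`` times across folds,
    sorted by count descending then id."""
    items = [(p, c) for p, c in report.stability.items() if c >= min_count]
    return sorted(items, key=lambda pc: (-pc[1], pc[0]))
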