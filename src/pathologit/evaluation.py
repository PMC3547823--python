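"""Cross-validated evaluation of variant scoring methods.

Any scorer that maps variants to a [0, 1] score — a single upstream tool, the
logistic combiner, or the weighted-average comparator — is evaluated the same
way: stratified K-fold cross-validation, a cutoff sweep from 0 to 1 recording
sensitivity/specificity/precision at each cutoff, fold-averaged ROC and PR
curves, trapezoidal ROC AUC, PR AUC with nonlinear interpolation in
confusion-count space, and the Matthews correlation coefficient with
MCC-maximizing cutoffs selected on the training folds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .tables_io import TOOLS, BenchmarkDataset
from .combiner import fit_logit, predict_posterior

logger = logging.getLogger(__name__)

#: Default cutoff grid: 1001 evenly spaced cutoffs covering [0, 1].
DEFAULT_GRID = np.linspace(0.0, 1.0, 1001)


# ---------------------------------------------------------------------------
# Confusion counts and MCC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def mcc(self) -> float:
        return float(mcc(self.tp, self.fp, self.tn, self.fn))


def mcc(tp, fp=None, tn=None, fn=None):
    """Matthews correlation coefficient; 0 whenever a marginal is zero.

    Accepts a :class:`ConfusionCounts` or four (optionally array) counts.
    """
    if isinstance(tp, ConfusionCounts):
        tp, fp, tn, fn = tp.tp, tp.fp, tp.tn, tp.fn
    tp, fp, tn, fn = (np.asarray(v, dtype=float) for v in (tp, fp, tn, fn))
    num = tp * tn - fp * fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out = np.zeros(np.broadcast(tp, fp, tn, fn).shape)
    nz = denom > 0
    np.divide(num, np.sqrt(denom, where=nz, out=np.ones_like(denom)), where=nz, out=out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Cutoff sweep
# ---------------------------------------------------------------------------

@dataclass
class CutoffSweep:
    """Confusion counts and derived rates along an ascending cutoff grid.

    At cutoff c a variant is predicted positive iff its score >= c, so at
    c = 0 everything is predicted positive (sensitivity 1, specificity 0).
    Precision is NaN where no variant is predicted positive.
    """

    grid: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def sensitivity(self) -> np.ndarray:
        return _safe_ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> np.ndarray:
        return _safe_ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> np.ndarray:
        return _safe_ratio(self.tp, self.tp + self.fp)

    @property
    def mcc(self) -> np.ndarray:
        return mcc(self.tp, self.fp, self.tn, self.fn)

    def counts_at(self, index: int) -> ConfusionCounts:
        return ConfusionCounts(
            int(self.tp[index]), int(self.fp[index]), int(self.tn[index]), int(self.fn[index])
        )

    def optimal_cutoff(self) -> tuple[float, float]:
        """Smallest grid cutoff maximizing MCC, and that maximal MCC."""
        values = self.mcc
        idx = int(np.argmax(values))  # argmax returns the first (smallest) maximizer
        return float(self.grid[idx]), float(values[idx])


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.shape(num), np.nan)
    nz = den > 0
    np.divide(num, den, where=nz, out=out)
    return out


def sweep_cutoffs(labels, scores, grid: np.ndarray | None = None) -> CutoffSweep:
    """Confusion counts at every grid cutoff (predicted positive iff score >= c)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    tp = pos.size - np.searchsorted(pos, grid, side="left")
    fp = neg.size - np.searchsorted(neg, grid, side="left")
    return CutoffSweep(
        grid=grid,
        tp=tp.astype(float),
        fp=fp.astype(float),
        tn=(neg.size - fp).astype(float),
        fn=(pos.size - tp).astype(float),
    )


# ---------------------------------------------------------------------------
# ROC / PR areas
# ---------------------------------------------------------------------------

def roc_auc(sensitivities, specificities) -> float:
    """Trapezoidal area under sensitivity vs (1 - specificity).

    Endpoints (0, 0) and (1, 1) are appended; NaN points are dropped.
    """
    sens = np.asarray(sensitivities, dtype=float)
    spec = np.asarray(specificities, dtype=float)
    ok = ~(np.isnan(sens) | np.isnan(spec))
    fpr = np.concatenate([[0.0], 1.0 - spec[ok], [1.0]])
    tpr = np.concatenate([[0.0], sens[ok], [1.0]])
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def _threshold_counts(labels, scores) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Cumulative (tp, fp) at each distinct score threshold, descending."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    # last index of each tied block marks a distinct achievable threshold
    distinct = np.nonzero(np.diff(s))[0]
    idx = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(y == 1)[idx].astype(float)
    fp = np.cumsum(y == 0)[idx].astype(float)
    return tp, fp, int((labels == 1).sum()), int((labels == 0).sum())


def roc_auc_from_scores(labels, scores) -> float:
    """ROC AUC at exact score thresholds (ties handled by the trapezoid)."""
    tp, fp, n_pos, n_neg = _threshold_counts(labels, scores)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes")
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return float(np.trapezoid(tpr, fpr))


def pr_auc_from_counts(tp, fp, n_pos: float) -> float:
    """Area under precision vs recall with interpolation in count space.

    Between consecutive achievable confusion points (tp_a, fp_a) and
    (tp_b, fp_b) the false positives are interpolated linearly in the true
    positives, giving the hyperbolic precision segment

        precision(t) = t / (t + fp_a + s (t - tp_a)),  s = dfp/dtp,

    whose exact integral over recall is accumulated segment by segment.
    Points must be sorted by ascending tp (a (0, 0) origin is prepended).
    Counts may be non-integer (fold-averaged curves).
    """
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    if n_pos <= 0:
        raise ValueError("PR AUC requires at least one positive label")
    if tp.size == 0:
        raise ValueError("no curve points supplied")
    order = np.lexsort((fp, tp))  # ascending tp, ties broken by ascending fp
    tp, fp = tp[order], fp[order]
    if tp[0] > 0.0 or fp[0] > 0.0:
        tp = np.concatenate([[0.0], tp])
        fp = np.concatenate([[0.0], fp])
    area = 0.0
    for (ta, fa), (tb, fb) in zip(zip(tp[:-1], fp[:-1]), zip(tp[1:], fp[1:])):
        dt = tb - ta
        if dt <= 0.0:
            continue
        slope = (fb - fa) / dt
        a = 1.0 + slope
        c = ta + fa
        if c == 0.0:
            area += dt / a
        else:
            coef = ta - c / a
            area += dt / a + (coef / a) * np.log((a * dt + c) / c)
    return float(area / n_pos)


def pr_auc_from_scores(labels, scores) -> float:
    """PR AUC at exact score thresholds via :func:`pr_auc_from_counts`."""
    tp, fp, n_pos, _ = _threshold_counts(labels, scores)
    if n_pos == 0:
        raise ValueError("PR AUC requires at least one positive label")
    return pr_auc_from_counts(tp, fp, n_pos)


# ---------------------------------------------------------------------------
# K-fold machinery
# ---------------------------------------------------------------------------

def kfold_split(dataset, K: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition into K folds (test-index arrays).

    Each fold's positive count is within one variant of proportionality.
    """
    labels = dataset.labels if isinstance(dataset, BenchmarkDataset) else np.asarray(dataset)
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > labels.size:
        raise ValueError(f"K={K} exceeds dataset size {labels.size}")
    splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(labels.size), labels)]


@dataclass
class EvaluationResult:
    """Fold-averaged evaluation of one scoring method.

    ``roc_auc``/``pr_auc`` are computed on the fold-averaged curves (the
    primary values); ``roc_auc_folds``/``pr_auc_folds`` average per-fold
    exact-threshold AUCs instead.  ``max_mcc`` averages each fold's test MCC
    at its training-optimal cutoff (the deployable quantity); ``max_mcc_test``
    averages each fold's maximal test-sweep MCC.
    """

    method: str
    tools: tuple[str, ...]
    K: int
    seed: int
    n_used: int
    grid: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    roc_auc: float
    pr_auc: float
    roc_auc_folds: float
    pr_auc_folds: float
    max_mcc: float
    max_mcc_test: float
    optimal_cutoff: float
    fold_cutoffs: list[float] = field(default_factory=list)
    fold_sensitivity: list[float] = field(default_factory=list)
    fold_specificity: list[float] = field(default_factory=list)
    fold_mcc: list[float] = field(default_factory=list)
    n_unpredicted: int = 0

    def metrics(self) -> dict:
        return {
            "method": self.method,
            "tools": list(self.tools),
            "K": self.K,
            "seed": self.seed,
            "n_used": self.n_used,
            "n_unpredicted": self.n_unpredicted,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "roc_auc_folds": self.roc_auc_folds,
            "pr_auc_folds": self.pr_auc_folds,
            "max_mcc": self.max_mcc,
            "max_mcc_test": self.max_mcc_test,
            "optimal_cutoff": self.optimal_cutoff,
            "fold_cutoffs": self.fold_cutoffs,
            "fold_sensitivity": self.fold_sensitivity,
            "fold_specificity": self.fold_specificity,
            "fold_mcc": self.fold_mcc,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metrics(), fh, indent=2)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.grid,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
            }
        )


def _method_subset(dataset: BenchmarkDataset, method: str, tools) -> tuple[BenchmarkDataset, tuple[str, ...]]:
    if method == "logit":
        tools = tuple(tools) if tools is not None else dataset.tool_columns
        return dataset.complete_cases(tools), tools
    if method == "condel":
        tools = tuple(tools) if tools is not None else dataset.tool_columns
        any_present = dataset.frame[list(tools)].notna().any(axis=1)
        return BenchmarkDataset(dataset.frame[any_present].reset_index(drop=True)), tools
    if method in TOOLS:
        return dataset.complete_cases([method]), (method,)
    raise ValueError(f"unknown method {method!r}; expected 'logit', 'condel' or one of {TOOLS}")


def _fold_scores(method, tools, train: BenchmarkDataset, test: BenchmarkDataset, condel_strategy):
    """Train on the training folds (when the method needs it) and score both."""
    if method == "logit":
        model = fit_logit(train, tools)
        return predict_posterior(model, train.frame), predict_posterior(model, test.frame)
    if method == "condel":
        from . import condel as _condel

        model = _condel.fit_condel(train, tools=tools, strategy=condel_strategy)
        return _condel.condel_score_frame(model, train.frame), _condel.condel_score_frame(model, test.frame)
    tool = tools[0]
    return train.frame[tool].to_numpy(dtype=float), test.frame[tool].to_numpy(dtype=float)


def cross_validate(
    dataset: BenchmarkDataset,
    method: str = "logit",
    tools: Sequence[str] | None = None,
    K: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
    condel_strategy: str = "score",
) -> EvaluationResult:
    """Stratified K-fold cross-validation of a scoring method.

    Per fold the method is trained on the K-1 training folds, the held-out
    fold is scored, and cutoffs are swept over the grid.  Confusion counts
    are averaged across folds at each grid cutoff; the ROC/PR AUCs of the
    averaged curve are the primary AUCs.  The MCC-maximizing cutoff is
    selected per fold on the training folds.  A training fold that loses a
    class triggers one re-split with a fresh seed, then an error.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    subset, tools = _method_subset(dataset, method, tools)

    folds = kfold_split(subset, K, seed)
    labels = subset.labels
    if any(len(np.unique(labels[np.setdiff1d(np.arange(len(subset)), f)])) < 2 for f in folds):
        logger.warning("a training fold lost a class; re-splitting with seed %d", seed + 1)
        folds = kfold_split(subset, K, seed + 1)
        if any(len(np.unique(labels[np.setdiff1d(np.arange(len(subset)), f)])) < 2 for f in folds):
            raise ValueError("training folds keep collapsing to a single class")

    sum_counts = {k: np.zeros(grid.size) for k in ("tp", "fp", "tn", "fn")}
    fold_cutoffs, fold_sens, fold_spec, fold_mcc = [], [], [], []
    fold_max_test_mcc, fold_roc, fold_pr = [], [], []
    n_unpredicted = 0

    all_idx = np.arange(len(subset))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = BenchmarkDataset(subset.frame.iloc[train_idx].reset_index(drop=True))
        test = BenchmarkDataset(subset.frame.iloc[test_idx].reset_index(drop=True))
        train_scores, test_scores = _fold_scores(method, tools, train, test, condel_strategy)

        train_ok = ~np.isnan(np.asarray(train_scores, dtype=float))
        test_ok = ~np.isnan(np.asarray(test_scores, dtype=float))
        n_unpredicted += int((~test_ok).sum())

        train_sweep = sweep_cutoffs(train.labels[train_ok], np.asarray(train_scores)[train_ok], grid)
        test_sweep = sweep_cutoffs(test.labels[test_ok], np.asarray(test_scores)[test_ok], grid)
        for k in sum_counts:
            sum_counts[k] += getattr(test_sweep, k)

        cutoff, _ = train_sweep.optimal_cutoff()
        at = int(np.searchsorted(grid, cutoff))
        fold_cutoffs.append(cutoff)
        fold_sens.append(float(test_sweep.sensitivity[at]))
        fold_spec.append(float(test_sweep.specificity[at]))
        fold_mcc.append(float(test_sweep.mcc[at]))
        fold_max_test_mcc.append(float(np.max(test_sweep.mcc)))
        y, s = test.labels[test_ok], np.asarray(test_scores, dtype=float)[test_ok]
        fold_roc.append(roc_auc_from_scores(y, s))
        fold_pr.append(pr_auc_from_scores(y, s))

    avg = CutoffSweep(grid=grid, **{k: v / K for k, v in sum_counts.items()})
    averaged_pr = pr_auc_from_counts(avg.tp, avg.fp, n_pos=float(avg.tp.max()))

    return EvaluationResult(
        method=method,
        tools=tools,
        K=K,
        seed=seed,
        n_used=len(subset),
        grid=grid,
        sensitivity=avg.sensitivity,
        specificity=avg.specificity,
        precision=avg.precision,
        roc_auc=roc_auc(avg.sensitivity, avg.specificity),
        pr_auc=averaged_pr,
        roc_auc_folds=float(np.mean(fold_roc)),
        pr_auc_folds=float(np.mean(fold_pr)),
        max_mcc=float(np.mean(fold_mcc)),
        max_mcc_test=float(np.mean(fold_max_test_mcc)),
        optimal_cutoff=float(np.mean(fold_cutoffs)),
        fold_cutoffs=fold_cutoffs,
        fold_sensitivity=fold_sens,
        fold_specificity=fold_spec,
        fold_mcc=fold_mcc,
        n_unpredicted=n_unpredicted,
    )


# ---------------------------------------------------------------------------
# Distribution comparison
# ---------------------------------------------------------------------------

def mann_whitney(scores_a, scores_b) -> tuple[float, float]:
    """Mann–Whitney U (for the first sample) with a two-sided p-value.

    Exact enumeration when both samples have at most 20 observations and no
    ties; otherwise the normal approximation with continuity and tie-variance
    corrections.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and tie_free) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Optional external-benchmark comparison harness
# ---------------------------------------------------------------------------

def benchmark_comparison(
    dataset: BenchmarkDataset,
    K: int = 10,
    seed: int = 0,
    tools: Sequence[str] | None = None,
    expected: dict | None = None,
) -> dict:
    """Head-to-head logit vs weighted-average comparator on a labeled benchmark.

    Intended for externally supplied benchmark tables.  When ``expected``
    maps metric names (e.g. ``logit.max_mcc``) to reference values, the
    returned dict includes ``deltas`` = computed - expected for each.
    """
    out: dict = {}
    for method in ("logit", "condel"):
        res = cross_validate(dataset, method=method, tools=tools, K=K, seed=seed)
        out[method] = {
            "max_mcc": res.max_mcc,
            "max_mcc_test": res.max_mcc_test,
            "roc_auc": res.roc_auc,
            "pr_auc": res.pr_auc,
        }
    if expected:
        deltas = {}
        for key, ref in expected.items():
            method, _, metric = key.partition(".")
            if method in out and metric in out[method]:
                deltas[key] = out[method][metric] - float(ref)
        out["deltas"] = deltas
    return out
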