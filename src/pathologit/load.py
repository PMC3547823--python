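"""Per-genome pathogenic-load estimation and consanguinity risk arithmetic.

Starting from an individual's rare-variant score table, the fitted logistic
combiner classifies each fully scored variant at an MCC-optimal cutoff, giving
the *predicted* pathogenic fraction P*.  Because the classifier is imperfect,
P* mixes true and false positives:

    P* = sensitivity * P + (1 - specificity) * (1 - P),

which inverts (the classic misclassification / Rogan-Gladen adjustment) to

    P = (P* + specificity - 1) / (sensitivity + specificity - 1),

clamped to [0, 1].  The total load of pathogenic derived alleles is then
N = round(n_used * P) (heterozygous-genotype counting: homozygous derived
genotypes are rare enough that each pathogenic variant contributes one
allele).  Repeating the cross-validation that estimates (sensitivity,
specificity) yields an empirical 95% confidence interval for the load.

For consanguineous matings, a child of a union with inbreeding coefficient F
is expected to be homozygous for F * N / 2 of an ancestor's N pathogenic
derived alleles.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .tables_io import BenchmarkDataset
from .combiner import LogitModel, fit_logit, predict_posterior, unbiased_posterior
from . import evaluation

logger = logging.getLogger(__name__)


class UninformativeClassifierError(ValueError):
    """sensitivity + specificity <= 1: the prevalence inversion is undefined."""


def _round_half_away(x: float, decimals: int = 0) -> float:
    f = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * f + 0.5), x) / f


@dataclass
class PrevalenceEstimate:
    """Per-individual estimate: predicted and true pathogenic fractions plus load."""

    n_rare_used: int
    p_star: float
    sensitivity: float
    specificity: float
    p_true: float
    load: int
    ci_low: int
    ci_high: int

    def as_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Point estimation
# ---------------------------------------------------------------------------

def predicted_fraction(
    frame: pd.DataFrame, model: LogitModel, cutoff: float
) -> tuple[int, float]:
    """Fraction of an individual's fully scored rare variants called pathogenic.

    Variants missing any model score are excluded from the denominator.
    """
    complete = frame.dropna(subset=list(model.tools))
    n_used = len(complete)
    if n_used == 0:
        raise ValueError("no variant has complete scores on the model tools")
    post = predict_posterior(model, complete)
    p_star = float(np.mean(post >= cutoff))
    return n_used, p_star


def invert_prevalence(p_star: float, sensitivity: float, specificity: float) -> float:
    """Recover the true pathogenic fraction from the predicted one.

    Solves P* = sens*P + (1-spec)*(1-P); result clamped to [0, 1] (a raw
    inversion below 0 occurs when P* is smaller than the false-positive
    rate).  Requires an informative classifier (sens + spec > 1).
    """
    if sensitivity + specificity <= 1.0:
        raise UninformativeClassifierError(
            f"sensitivity + specificity must exceed 1, got {sensitivity} + {specificity}"
        )
    p = (p_star + specificity - 1.0) / (sensitivity + specificity - 1.0)
    return float(min(1.0, max(0.0, p)))


def total_load(n_rare_used: int, p_true: float) -> int:
    """Total load of pathogenic derived alleles: round(n_used * P), half away from zero."""
    if not 0.0 <= p_true <= 1.0:
        raise ValueError(f"p_true must lie in [0, 1], got {p_true}")
    return int(_round_half_away(n_rare_used * p_true))


# ---------------------------------------------------------------------------
# Repeated-CV confidence interval
# ---------------------------------------------------------------------------

def cv_operating_point(
    benchmark: BenchmarkDataset,
    tools: Sequence[str],
    K: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
    cutoff: float | None = None,
) -> tuple[float, float]:
    """Fold-averaged (sensitivity, specificity) of the logistic combiner.

    Per fold a combiner is refitted on the training folds and sensitivity/
    specificity are measured on the held-out fold at ``cutoff``.  When no
    cutoff is given, each fold re-selects the MCC-maximizing cutoff on its
    training folds; for load estimation the *deployed* cutoff should be
    passed instead, so the CV estimates refer to the operating point actually
    used for prediction (the MCC plateau leaves the cutoff ill-determined,
    and specificity is steep in the cutoff).
    """
    grid = evaluation.DEFAULT_GRID if grid is None else grid
    subset = benchmark.complete_cases(tools)
    folds = evaluation.kfold_split(subset, K, seed)
    all_idx = np.arange(len(subset))
    sens, spec = [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = BenchmarkDataset(subset.frame.iloc[train_idx].reset_index(drop=True))
        test = BenchmarkDataset(subset.frame.iloc[test_idx].reset_index(drop=True))
        model = fit_logit(train, tools)
        if cutoff is None:
            fold_cutoff, _ = evaluation.sweep_cutoffs(
                train.labels, predict_posterior(model, train.frame), grid
            ).optimal_cutoff()
        else:
            fold_cutoff = cutoff
        test_post = predict_posterior(model, test.frame)
        calls = test_post >= fold_cutoff
        labels = test.labels
        sens.append(float(calls[labels == 1].mean()))
        spec.append(float((~calls[labels == 0]).mean()))
    return float(np.mean(sens)), float(np.mean(spec))


def _repeat_operating_points(
    benchmark: BenchmarkDataset,
    tools: Sequence[str],
    repeats: int,
    K: int,
    seed: int,
    grid: np.ndarray | None,
    cutoff: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-averaged (sensitivity, specificity) for each CV repeat.

    A failing repeat is re-seeded once before an error is raised.
    """
    sens = np.empty(repeats)
    spec = np.empty(repeats)
    for r in range(repeats):
        try:
            sens[r], spec[r] = cv_operating_point(
                benchmark, tools, K=K, seed=seed + 1 + r, grid=grid, cutoff=cutoff
            )
        except Exception:
            logger.warning("CV repeat %d failed; re-seeding once", r)
            sens[r], spec[r] = cv_operating_point(
                benchmark, tools, K=K, seed=seed + 100_003 + r, grid=grid, cutoff=cutoff
            )
    return sens, spec


def load_confidence_interval(
    benchmark: BenchmarkDataset,
    individual: pd.DataFrame,
    tools: Sequence[str],
    repeats: int = 200,
    K: int = 10,
    seed: int = 0,
    model: LogitModel | None = None,
    cutoff: float | None = None,
    grid: np.ndarray | None = None,
) -> tuple[int, int, np.ndarray]:
    """Empirical 95% CI of the total load from repeated cross-validation.

    Each repeat re-splits the benchmark, yielding a fold-averaged
    (sensitivity, specificity) pair at the per-fold training-optimal MCC
    cutoffs, which is pushed through the prevalence inversion and load
    counting.  The CI is the 2.5/97.5 percentile of the ``repeats`` loads,
    lower bound clamped at zero.  Returns (ci_low, ci_high, loads).

    Interpretation caveat: the interval quantifies the cross-validation
    variability of the classifier's operating characteristics only.  The
    sampling noise of the individual's own variant draw (the realized
    false-positive count behind ``p_star``) is *not* represented, so for
    small rare-variant counts the interval is anti-conservative relative to
    the realized load.
    """
    tools = tuple(tools)
    if model is None:
        model = fit_logit(benchmark, tools)
    if cutoff is None:
        cutoff = training_cutoff(benchmark, model, grid)
    n_used, p_star = predicted_fraction(individual, model, cutoff)
    sens, spec = _repeat_operating_points(benchmark, tools, repeats, K, seed, grid)
    loads = np.array(
        [total_load(n_used, invert_prevalence(p_star, s, c)) for s, c in zip(sens, spec)]
    )
    low, high = np.percentile(loads, [2.5, 97.5])
    ci_low = max(0, int(_round_half_away(low)))
    ci_high = int(_round_half_away(high))
    return ci_low, ci_high, loads


def training_cutoff(
    benchmark: BenchmarkDataset, model: LogitModel, grid: np.ndarray | None = None
) -> float:
    """MCC-maximizing posterior cutoff of the model on its training benchmark."""
    complete = benchmark.complete_cases(model.tools)
    sweep = evaluation.sweep_cutoffs(
        complete.labels, predict_posterior(model, complete.frame), grid
    )
    return sweep.optimal_cutoff()[0]


def estimate_load(
    benchmark: BenchmarkDataset,
    individual: pd.DataFrame,
    tools: Sequence[str] = ("SIFT", "MutationTaster"),
    repeats: int = 200,
    K: int = 10,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> PrevalenceEstimate:
    """Full per-individual estimation pipeline.

    Fits the combiner on the benchmark, selects the training MCC-optimal
    cutoff, measures the predicted pathogenic fraction on the individual's
    fully scored rare variants, inverts it with the repeat-averaged CV
    sensitivity/specificity, and attaches the repeated-CV 95% CI.
    """
    tools = tuple(tools)
    model = fit_logit(benchmark, tools)
    cutoff = training_cutoff(benchmark, model, grid)
    n_used, p_star = predicted_fraction(individual, model, cutoff)
    sens_r, spec_r = _repeat_operating_points(benchmark, tools, repeats, K, seed, grid)
    loads = np.array(
        [total_load(n_used, invert_prevalence(p_star, s, c)) for s, c in zip(sens_r, spec_r)]
    )
    low, high = np.percentile(loads, [2.5, 97.5])
    ci_low = max(0, int(_round_half_away(low)))
    ci_high = int(_round_half_away(high))
    # point operating characteristics: the repeat-averaged pair (a single CV
    # run is noisy; the mean keeps the point estimate inside its own CI)
    sens = float(np.mean(sens_r))
    spec = float(np.mean(spec_r))
    p_true = invert_prevalence(p_star, sens, spec)
    load = total_load(n_used, p_true)
    return PrevalenceEstimate(
        n_rare_used=n_used,
        p_star=p_star,
        sensitivity=sens,
        specificity=spec,
        p_true=p_true,
        load=load,
        ci_low=ci_low,
        ci_high=ci_high,
    )


# ---------------------------------------------------------------------------
# Consanguinity arithmetic
# ---------------------------------------------------------------------------

#: Relationships with their theoretical inbreeding coefficients F.
RELATIONSHIPS: tuple[tuple[str, float], ...] = (
    ("Siblings", 1 / 4),
    ("Half siblings", 1 / 8),
    ("Uncle-niece, aunt-nephew", 1 / 8),
    ("First cousins", 1 / 16),
    ("First cousins once removed", 1 / 32),
    ("Second cousins", 1 / 64),
    ("Double first cousins", 1 / 8),
    ("Double second cousins", 1 / 32),
)


@dataclass(frozen=True)
class ConsanguinityEntry:
    relationship: str
    F: float
    expected_homozygous: float


def consanguinity_expectation(F: float, N: float) -> float:
    """Expected homozygous pathogenic variants in a child: F * N / 2."""
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"inbreeding coefficient must lie in [0, 1], got {F}")
    if N < 0:
        raise ValueError(f"load must be non-negative, got {N}")
    return F * N / 2.0


def consanguinity_table(N: float) -> list[ConsanguinityEntry]:
    """Expected homozygous pathogenic counts for the standard relationships.

    Expectations are rounded to one decimal (half away from zero).
    """
    return [
        ConsanguinityEntry(name, F, _round_half_away(consanguinity_expectation(F, N), 1))
        for name, F in RELATIONSHIPS
    ]


def consanguinity_frame(N: float) -> pd.DataFrame:
    return pd.DataFrame([asdict(e) for e in consanguinity_table(N)])


# ---------------------------------------------------------------------------
# Prior-posterior surface
# ---------------------------------------------------------------------------

def posterior_surface(
    model: LogitModel, priors: Sequence[float], score_grid: Sequence[float]
) -> np.ndarray:
    """Unbiased posterior over a (prior, common score) grid.

    Entry [i, j] is the bias-corrected posterior at prior ``priors[i]`` when
    every model tool reports the same score ``score_grid[j]`` — the summary
    surface showing how the prior caps attainable posteriors.
    """
    priors = np.asarray(priors, dtype=float)
    score_grid = np.asarray(score_grid, dtype=float)
    out = np.empty((priors.size, score_grid.size))
    X = np.repeat(score_grid[:, None], len(model.tools), axis=1)
    for i, prior in enumerate(priors):
        out[i] = unbiased_posterior(model, X, float(prior))
    return out
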