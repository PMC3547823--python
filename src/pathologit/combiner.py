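"""Logistic combination of functional prediction scores with bias correction.

The combiner fits, on a labeled benchmark, a logistic regression of the
pathogenic/control label on the standardized scores of a chosen tool subset:

    P(Y = 1 | X) = 1 / (1 + exp(-(alpha + beta . X)))

Benchmarks are case-control *selected* samples, so the fitted intercept
reflects the benchmark's positive fraction rather than the prevalence of
pathogenic variants among rare nsSNVs in a genome.  The sample posterior
odds are therefore divided by the sampling odds ratio

    R = odds(pathogenic | benchmark) / odds(pathogenic | population)

to obtain an unbiased posterior.  R is a constant per model+prior, so
variant *ranking* (and any cutoff-based classification applied on the same
scale) is unaffected; only the probability scale changes.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .tables_io import TOOLS, BenchmarkDataset

logger = logging.getLogger(__name__)


class MissingScoreError(ValueError):
    """A required tool score is missing, so no prediction can be made."""


class SingleClassError(ValueError):
    """Training data contain only one class."""


class SeparationWarning(UserWarning):
    """Perfect separation detected; a ridge-stabilized fit was returned."""


UNPREDICTED = "unpredicted"
PATHOGENIC = "pathogenic"
NON_PATHOGENIC = "non_pathogenic"


@dataclass(frozen=True)
class PriorSpec:
    """Prior proportion of pathogenic variants among rare nsSNVs in a genome."""

    p_disease_population: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_disease_population < 1.0:
            raise ValueError(
                f"prior must lie strictly inside (0, 1), got {self.p_disease_population}"
            )


@dataclass
class LogitModel:
    """Fitted logistic combiner: intercept, per-tool coefficients, and the
    training-sample positive fraction needed for the bias correction."""

    tools: tuple[str, ...]
    alpha: float
    beta: np.ndarray
    p_disease_sample: float
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.tools = tuple(self.tools)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.tools),):
            raise ValueError("beta must have one coefficient per tool")
        if not 0.0 < self.p_disease_sample < 1.0:
            raise ValueError("p_disease_sample must lie in (0, 1)")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.alpha + np.asarray(X, dtype=float) @ self.beta

    def to_json(self, path=None) -> dict:
        payload = {
            "tools": list(self.tools),
            "alpha": self.alpha,
            "beta": self.beta.tolist(),
            "p_disease_sample": self.p_disease_sample,
            "cutoff": self.cutoff,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2)
        return payload

    @classmethod
    def from_json(cls, source) -> "LogitModel":
        if isinstance(source, (str, bytes)) or hasattr(source, "read"):
            payload = json.load(open(source)) if isinstance(source, (str, bytes)) else json.load(source)
        else:
            payload = dict(source)
        return cls(
            tools=tuple(payload["tools"]),
            alpha=float(payload["alpha"]),
            beta=np.asarray(payload["beta"], dtype=float),
            p_disease_sample=float(payload["p_disease_sample"]),
            cutoff=payload.get("cutoff"),
        )


# ---------------------------------------------------------------------------
# Fitting (IRLS)
# ---------------------------------------------------------------------------

def _irls(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for (optionally ridge-penalized) logistic log-likelihood.

    Converged when the largest absolute coefficient update drops below
    ``tol``.  With ``ridge > 0`` the working weights are floored so the
    normal equations stay solvable under separation.
    """
    n, p = X.shape
    coef = np.zeros(p)
    eye = np.eye(p)
    for _ in range(max_iter):
        eta = X @ coef
        mu = expit(eta)
        w = mu * (1.0 - mu)
        if ridge > 0.0:
            w = np.maximum(w, 1e-10)
        xtwx = X.T @ (X * w[:, None]) + ridge * eye
        grad = X.T @ (y - mu) - ridge * coef
        step = np.linalg.solve(xtwx, grad)
        coef = coef + step
        if np.max(np.abs(step)) < tol:
            return coef, True
    return coef, False


def fit_logit(
    dataset: BenchmarkDataset,
    tools: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge_fallback: float = 1e-6,
) -> LogitModel:
    """Maximum-likelihood logistic fit of label on the given tool subset.

    Variants missing any subset score are dropped first (complete-case
    training); the recorded ``p_disease_sample`` refers to that complete-case
    training set.  Under perfect separation (or a singular IRLS step) the fit
    falls back to a ridge-stabilized estimate with :class:`SeparationWarning`.
    """
    tools = tuple(tools) if tools is not None else dataset.tool_columns
    if not tools:
        raise ValueError("at least one tool is required")
    complete = dataset.complete_cases(tools)
    y = complete.labels.astype(float)
    if complete.n_positive == 0 or complete.n_negative == 0:
        raise SingleClassError("training data contain a single class after complete-case restriction")
    X = np.column_stack([np.ones(len(complete)), complete.scores(tools).to_numpy(dtype=float)])

    coef, converged = None, False
    try:
        coef, converged = _irls(X, y, tol=tol, max_iter=max_iter)
    except np.linalg.LinAlgError:
        pass
    if coef is None or not converged or np.max(np.abs(coef)) > 50.0:
        warnings.warn(
            "logistic fit did not converge (likely separation); "
            f"returning ridge-stabilized estimate (penalty {ridge_fallback:g})",
            SeparationWarning,
            stacklevel=2,
        )
        coef, _ = _irls(X, y, tol=tol, max_iter=max_iter, ridge=ridge_fallback)

    return LogitModel(
        tools=tools,
        alpha=float(coef[0]),
        beta=coef[1:].copy(),
        p_disease_sample=complete.p_disease_sample,
    )


# ---------------------------------------------------------------------------
# Posteriors
# ---------------------------------------------------------------------------

def _score_matrix(model: LogitModel, scores) -> tuple[np.ndarray, np.ndarray, bool]:
    """Extract the (n, k) score matrix on ``model.tools`` plus completeness mask.

    Accepts a DataFrame, a Series/Mapping (single variant), or a plain
    sequence ordered like ``model.tools``.  Returns (X, complete, scalar).
    """
    if isinstance(scores, pd.DataFrame):
        X = scores[list(model.tools)].to_numpy(dtype=float)
        return X, ~np.isnan(X).any(axis=1), False
    if isinstance(scores, (pd.Series, Mapping)):
        row = [scores.get(t, np.nan) if isinstance(scores, Mapping) else scores.get(t) for t in model.tools]
        X = np.asarray([[np.nan if v is None else float(v) for v in row]])
        return X, ~np.isnan(X).any(axis=1), True
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != len(model.tools):
        raise ValueError(f"expected {len(model.tools)} scores, got {X.shape[1]}")
    return X, ~np.isnan(X).any(axis=1), np.asarray(scores).ndim == 1


def posterior_sample(model: LogitModel, scores) -> float | np.ndarray:
    """Sample-space posterior P(pathogenic | scores) under the fitted model."""
    X, complete, scalar = _score_matrix(model, scores)
    if scalar and not complete.all():
        raise MissingScoreError(f"missing score for model tools {model.tools}")
    post = np.where(complete, expit(model.linear_predictor(np.nan_to_num(X))), np.nan)
    return float(post[0]) if scalar else post


def sampling_odds_ratio(p_sample: float, p_population: float) -> float:
    """Odds of pathogenicity in the selected sample over that in the population."""
    for name, p in (("p_sample", p_sample), ("p_population", p_population)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} must lie strictly inside (0, 1), got {p}")
    return (p_sample / (1.0 - p_sample)) / (p_population / (1.0 - p_population))


def unbiased_posterior(model: LogitModel, scores, prior: PriorSpec | float) -> float | np.ndarray:
    """Bias-corrected posterior: sample posterior odds divided by R.

    With the prior equal to the training positive fraction, R = 1 and this
    reduces to :func:`posterior_sample`.  R rescales all posteriors by the
    same factor on the odds scale, so rankings are invariant to the prior.
    """
    p_pop = prior.p_disease_population if isinstance(prior, PriorSpec) else float(prior)
    R = sampling_odds_ratio(model.p_disease_sample, p_pop)
    X, complete, scalar = _score_matrix(model, scores)
    if scalar and not complete.all():
        raise MissingScoreError(f"missing score for model tools {model.tools}")
    eta = model.linear_predictor(np.nan_to_num(X)) - np.log(R)
    post = np.where(complete, expit(eta), np.nan)
    return float(post[0]) if scalar else post


def predict_posterior(model: LogitModel, frame: pd.DataFrame, prior=None) -> np.ndarray:
    """Vectorized posterior over a score table; NaN where scores are missing."""
    if prior is None:
        X, complete, _ = _score_matrix(model, frame)
        return np.where(complete, expit(model.linear_predictor(np.nan_to_num(X))), np.nan)
    return unbiased_posterior(model, frame, prior)


def classify(model: LogitModel, scores, cutoff: float, prior=None):
    """Classify variants at a posterior cutoff (>= cutoff -> pathogenic).

    Variants missing a required score are reported ``unpredicted``.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    X, complete, scalar = _score_matrix(model, scores)
    eta = model.linear_predictor(np.nan_to_num(X))
    if prior is not None:
        p_pop = prior.p_disease_population if isinstance(prior, PriorSpec) else float(prior)
        eta = eta - np.log(sampling_odds_ratio(model.p_disease_sample, p_pop))
    post = expit(eta)
    out = np.where(~complete, UNPREDICTED, np.where(post >= cutoff, PATHOGENIC, NON_PATHOGENIC))
    return str(out[0]) if scalar else out


def calibration_gap(model: LogitModel, dataset: BenchmarkDataset) -> float:
    """Mean training posterior minus training positive fraction.

    At the (unpenalized) maximum likelihood the intercept score equation
    forces this to zero; useful as a fit diagnostic.
    """
    complete = dataset.complete_cases(model.tools)
    post = predict_posterior(model, complete.frame)
    return float(np.nanmean(post) - complete.p_disease_sample)


def enumerate_subsets(
    dataset: BenchmarkDataset,
    K: int = 10,
    seed: int = 0,
    tools: Sequence[str] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cross-validate the logistic combiner on every non-empty tool subset.

    Returns a table of (tools, n_tools, roc_auc, pr_auc, max_mcc) sorted by
    ROC AUC descending (31 rows for the full five-tool vocabulary).
    """
    from . import evaluation  # local import: evaluation depends on this module

    vocabulary = tuple(tools) if tools is not None else tuple(
        t for t in TOOLS if t in dataset.frame.columns
    )
    rows = []
    for k in range(1, len(vocabulary) + 1):
        for subset in itertools.combinations(vocabulary, k):
            result = evaluation.cross_validate(
                dataset, method="logit", tools=subset, K=K, seed=seed, grid=grid
            )
            rows.append(
                {
                    "tools": "+".join(subset),
                    "n_tools": k,
                    "roc_auc": result.roc_auc,
                    "pr_auc": result.pr_auc,
                    "max_mcc": result.max_mcc,
                }
            )
    table = pd.DataFrame(rows).sort_values("roc_auc", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


def no_signal_reference(dataset: BenchmarkDataset) -> tuple[float, np.ndarray]:
    """Expected coefficients when scores carry no signal: (logit(p), zeros)."""
    return float(logit(dataset.p_disease_sample)), np.zeros(len(dataset.tool_columns))
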