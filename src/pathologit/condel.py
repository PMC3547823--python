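"""Weighted-average-of-normalized-scores (WAS) comparator.

Re-implementation of the CONDEL-style consensus score used as the head-to-head
comparator for the logistic combiner.  Per tool, the training data supply an
MCC-optimal cutoff and the empirical complementary cumulative distributions
(CCDFs, P(S >= s)) of the positive- and negative-class scores.  A variant's
consensus score is a weighted average of its available tool scores, where a
score above the tool's cutoff is weighted by the confidence that it was *not*
drawn from the negative class (1 - CCDF_neg(s)), and a score below the cutoff
by the confidence that it was not drawn from the positive class
(1 - CCDF_pos(s)).

The original WAS publication is ambiguous about whether below-cutoff tools
contribute the score itself or its complement to the average; both are
selectable via ``strategy`` ("score", the default, averages the scores
themselves; "complement" lets below-cutoff tools contribute 1 - s).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import TOOLS, BenchmarkDataset
from .combiner import MissingScoreError
from . import evaluation

logger = logging.getLogger(__name__)

STRATEGIES = ("score", "complement")


def _ccdf(knots: np.ndarray, s) -> np.ndarray:
    """Empirical P(S >= s): right-continuous step function on sorted knots."""
    s = np.asarray(s, dtype=float)
    return (knots.size - np.searchsorted(knots, s, side="left")) / knots.size


@dataclass
class ToolCondel:
    """Per-tool pieces of the comparator: cutoff plus class-wise CCDF knots."""

    cutoff: float
    pos_knots: np.ndarray
    neg_knots: np.ndarray

    def __post_init__(self) -> None:
        self.pos_knots = np.sort(np.asarray(self.pos_knots, dtype=float))
        self.neg_knots = np.sort(np.asarray(self.neg_knots, dtype=float))

    def ccdf_pos(self, s):
        return _ccdf(self.pos_knots, s)

    def ccdf_neg(self, s):
        return _ccdf(self.neg_knots, s)


@dataclass
class CondelModel:
    tools: dict[str, ToolCondel] = field(default_factory=dict)
    strategy: str = "score"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")

    def to_json(self, path=None) -> dict:
        payload = {
            "strategy": self.strategy,
            "tools": {
                name: {
                    "cutoff": tc.cutoff,
                    "pos_knots": tc.pos_knots.tolist(),
                    "neg_knots": tc.neg_knots.tolist(),
                }
                for name, tc in self.tools.items()
            },
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(payload, fh)
        return payload

    @classmethod
    def from_json(cls, source) -> "CondelModel":
        payload = json.load(open(source)) if isinstance(source, (str, bytes)) else dict(source)
        return cls(
            tools={
                name: ToolCondel(
                    cutoff=float(spec["cutoff"]),
                    pos_knots=np.asarray(spec["pos_knots"], dtype=float),
                    neg_knots=np.asarray(spec["neg_knots"], dtype=float),
                )
                for name, spec in payload["tools"].items()
            },
            strategy=payload.get("strategy", "score"),
        )


def fit_condel(
    dataset: BenchmarkDataset,
    tools: Sequence[str] | None = None,
    grid: np.ndarray | None = None,
    strategy: str = "score",
) -> CondelModel:
    """Fit per-tool cutoffs and class CCDFs from a labeled benchmark.

    Each tool's cutoff is the smallest grid cutoff maximizing the MCC of
    that tool's score alone (per-tool complete cases).  Tools with fewer
    than two distinct scores in either class are excluded with a warning.
    """
    tools = tuple(tools) if tools is not None else dataset.tool_columns
    model = CondelModel(strategy=strategy)
    for tool in tools:
        col = dataset.frame[tool]
        present = col.notna().to_numpy()
        scores = col.to_numpy(dtype=float)[present]
        labels = dataset.labels[present]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        if np.unique(pos).size < 2 or np.unique(neg).size < 2:
            warnings.warn(
                f"tool {tool} has fewer than two distinct scores in a class; excluded",
                stacklevel=2,
            )
            continue
        sweep = evaluation.sweep_cutoffs(labels, scores, grid)
        cutoff, _ = sweep.optimal_cutoff()
        model.tools[tool] = ToolCondel(cutoff=cutoff, pos_knots=pos, neg_knots=neg)
    if not model.tools:
        raise ValueError("no usable tool remained after per-tool screening")
    return model


def _tool_terms(tc: ToolCondel, s: np.ndarray, strategy: str) -> tuple[np.ndarray, np.ndarray]:
    """Weight and averaged value for one tool's scores (vectorized)."""
    above = s >= tc.cutoff
    weight = np.where(above, 1.0 - tc.ccdf_neg(s), 1.0 - tc.ccdf_pos(s))
    value = s if strategy == "score" else np.where(above, s, 1.0 - s)
    return weight, value


def condel_score(model: CondelModel, scores: Mapping[str, float] | pd.Series) -> float:
    """WAS consensus score for a single variant (>= 1 tool score required)."""
    frame = pd.DataFrame([dict(scores)])
    out = condel_score_frame(model, frame)
    if np.isnan(out[0]):
        raise MissingScoreError("all tool scores are missing")
    return float(out[0])


def condel_score_frame(model: CondelModel, frame: pd.DataFrame) -> np.ndarray:
    """Vectorized WAS over a score table; NaN where every tool is missing.

    WAS = sum_i w_i v_i / sum_i w_i over present tools.  If every present
    tool has zero weight the unweighted mean of the values is returned
    (degenerate but keeps the score in [0, 1]).
    """
    n = len(frame)
    num = np.zeros(n)
    den = np.zeros(n)
    fallback_sum = np.zeros(n)
    n_present = np.zeros(n)
    for tool, tc in model.tools.items():
        if tool not in frame.columns:
            continue
        col = frame[tool].to_numpy(dtype=float)
        present = ~np.isnan(col)
        if not present.any():
            continue
        s = col[present]
        weight, value = _tool_terms(tc, s, model.strategy)
        num[present] += weight * value
        den[present] += weight
        fallback_sum[present] += value
        n_present[present] += 1
    out = np.full(n, np.nan)
    weighted = den > 0
    out[weighted] = num[weighted] / den[weighted]
    degenerate = (~weighted) & (n_present > 0)
    if degenerate.any():
        out[degenerate] = fallback_sum[degenerate] / n_present[degenerate]
    return out
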