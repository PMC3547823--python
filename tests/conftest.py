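import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pathologit as pl

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def signal_benchmark() -> pl.BenchmarkDataset:
    """Medium benchmark with informative, correlated tool scores."""
    return pl.generate_benchmark(pl.GeneratorConfig(n_positive=900, n_negative=800, seed=11))


@pytest.fixture(scope="session")
def complete_benchmark(signal_benchmark) -> pl.BenchmarkDataset:
    """Same benchmark restricted to variants scored by all five tools."""
    return signal_benchmark.complete_cases(pl.TOOLS)


@pytest.fixture()
def toy_table(tmp_path):
    """Write a small TSV score table and return its path."""

    def _write(rows, header=None, name="table.tsv"):
        header = header or (
            "chrom\tpos\tref\talt\tSIFT\tPolyPhen2\tLRT\tMutationTaster\tPhyloP"
        )
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + ("\n" if rows else "\n"))
        return path

    return _write


def pair_count_auc(labels, scores) -> float:
    """Mann-Whitney pair-counting ROC AUC oracle (ties get half credit)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size / 1))


def brute_force_pr_auc(labels, scores, steps: int = 4000) -> float:
    """Numeric PR-AUC oracle: enumerate achievable confusion matrices at every
    distinct threshold and integrate precision over recall with fine linear
    interpolation of the counts between consecutive achievable points."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    thresholds = np.unique(scores)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        called = scores >= t
        points.append((float((called & (labels == 1)).sum()), float((called & (labels == 0)).sum())))
    area = 0.0
    for (ta, fa), (tb, fb) in zip(points[:-1], points[1:]):
        if tb <= ta:
            continue
        x = np.linspace(0.0, tb - ta, steps)
        tp = ta + x
        fp = fa + (fb - fa) * x / (tb - ta)
        with np.errstate(invalid="ignore"):
            precision = tp / (tp + fp)
        if ta == 0.0 and fa == 0.0:
            precision[0] = precision[1]  # constant along a segment through the origin
        area += np.trapezoid(precision, tp)
    return float(area / n_pos)
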