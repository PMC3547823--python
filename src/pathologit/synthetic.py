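"""Synthetic benchmark, per-individual, and VCF generators.

Everything the pipeline consumes can be simulated with the statistical
structure the combiner exploits: per-variant scores from several tools that
are individually informative (single-tool ROC AUC roughly 0.75-0.90) and
mutually correlated through a shared latent severity variable, with
weak-to-moderate inter-tool correlations and per-tool missingness.

Per variant a latent severity z is drawn from a class-specific Beta
distribution; each tool's score is Beta-distributed around a mixture of z and
a tool- and class-specific mean, then mapped into an optional class-specific
range (disjoint ranges give a perfectly separable fixture).  All draws are
deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .tables_io import TOOLS, BenchmarkDataset

_EPS = 1e-3

#: Default per-tool mean scores per class.  MutationTaster separates classes
#: best and PhyloP (conservation only) worst, mirroring the typical ordering
#: of these tools on rare-variant benchmarks.
DEFAULT_MU_POS: dict[str, float] = {
    "SIFT": 0.66,
    "PolyPhen2": 0.65,
    "LRT": 0.62,
    "MutationTaster": 0.70,
    "PhyloP": 0.61,
}
DEFAULT_MU_NEG: dict[str, float] = {
    "SIFT": 0.36,
    "PolyPhen2": 0.37,
    "LRT": 0.40,
    "MutationTaster": 0.32,
    "PhyloP": 0.43,
}


def _as_tool_map(value, default: float | Mapping[str, float]) -> dict[str, float]:
    if value is None:
        value = default
    if isinstance(value, Mapping):
        return {t: float(value[t]) for t in TOOLS}
    return {t: float(value) for t in TOOLS}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults emulate an ExoVar-like benchmark: 5,340 positive and 4,752
    negative variants, five correlated tools, and ~15% missing scores per
    tool (rare variants often lack scores for some tools).
    """

    n_positive: int = 5340
    n_negative: int = 4752
    latent_pos: tuple[float, float] = (3.0, 2.0)
    latent_neg: tuple[float, float] = (2.0, 3.0)
    mu_pos: dict[str, float] | None = None
    mu_neg: dict[str, float] | None = None
    latent_weight: float | dict[str, float] = 0.6
    concentration: float = 8.0
    missingness: float | dict[str, float] = 0.15
    pos_range: tuple[float, float] = (0.0, 1.0)
    neg_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("class sizes must be non-negative")
        for name, (a, b) in (("latent_pos", self.latent_pos), ("latent_neg", self.latent_neg)):
            if a <= 0 or b <= 0:
                raise ValueError(f"{name} Beta shapes must be positive, got {(a, b)}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        self.mu_pos = _as_tool_map(self.mu_pos, DEFAULT_MU_POS)
        self.mu_neg = _as_tool_map(self.mu_neg, DEFAULT_MU_NEG)
        self.latent_weight = _as_tool_map(self.latent_weight, 0.6)
        self.missingness = _as_tool_map(self.missingness, 0.15)
        for t, w in self.latent_weight.items():
            if not 0.0 <= w < 1.0:
                raise ValueError(f"latent weight for {t} must lie in [0, 1), got {w}")
        for t, m in self.missingness.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"missingness for {t} must lie in [0, 1], got {m}")
        for name, (lo, hi) in (("pos_range", self.pos_range), ("neg_range", self.neg_range)):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= lo < hi <= 1, got {(lo, hi)}")

    # -- alternative study conditions -------------------------------------
    @classmethod
    def null(cls, n_positive: int, n_negative: int, seed: int = 0) -> "GeneratorConfig":
        """No-signal conditions: identical score distributions in both classes."""
        mu = {t: 0.5 for t in TOOLS}
        return cls(
            n_positive=n_positive,
            n_negative=n_negative,
            latent_pos=(2.0, 2.0),
            latent_neg=(2.0, 2.0),
            mu_pos=mu,
            mu_neg=mu,
            missingness=0.0,
            seed=seed,
        )

    @classmethod
    def separable(cls, n_positive: int, n_negative: int, seed: int = 0) -> "GeneratorConfig":
        """Perfectly separable conditions: disjoint class score supports."""
        return cls(
            n_positive=n_positive,
            n_negative=n_negative,
            pos_range=(0.55, 1.0),
            neg_range=(0.0, 0.45),
            missingness=0.0,
            seed=seed,
        )

    # -- (de)serialization --------------------------------------------------
    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["latent_pos"] = list(self.latent_pos)
        d["latent_neg"] = list(self.latent_neg)
        d["pos_range"] = list(self.pos_range)
        d["neg_range"] = list(self.neg_range)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Load a config from YAML or JSON."""
        text = open(path).read()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        for key in ("latent_pos", "latent_neg", "pos_range", "neg_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Score generation
# ---------------------------------------------------------------------------

def _class_scores(
    rng: np.random.Generator, n: int, config: GeneratorConfig, positive: bool
) -> dict[str, np.ndarray]:
    a, b = config.latent_pos if positive else config.latent_neg
    mu = config.mu_pos if positive else config.mu_neg
    lo, hi = config.pos_range if positive else config.neg_range
    z = rng.beta(a, b, size=n)
    out = {}
    for tool in TOOLS:
        w = config.latent_weight[tool]
        m = np.clip(w * z + (1.0 - w) * mu[tool], _EPS, 1.0 - _EPS)
        s = rng.beta(config.concentration * m, config.concentration * (1.0 - m))
        out[tool] = lo + s * (hi - lo)
    return out


def _apply_missingness(rng: np.random.Generator, scores: dict[str, np.ndarray], config) -> None:
    for tool in TOOLS:
        rate = config.missingness[tool]
        if rate > 0.0:
            mask = rng.random(scores[tool].size) < rate
            scores[tool][mask] = np.nan


def _keys_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    alts = {"A": "GCT", "C": "AGT", "G": "ACT", "T": "ACG"}
    refs = rng.choice(list("ACGT"), size=n)
    alt = [alts[r][i] for r, i in zip(refs, rng.integers(0, 3, size=n))]
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n + 1, dtype=np.int64) * 3,
            "ref": refs,
            "alt": alt,
            "derived_is_alt": True,
        }
    )


def generate_benchmark(config: GeneratorConfig) -> BenchmarkDataset:
    """Labeled benchmark with the configured class sizes and score structure."""
    rng = np.random.default_rng(config.seed)
    n = config.n_positive + config.n_negative
    frame = _keys_frame(rng, n)
    labels = np.concatenate(
        [np.ones(config.n_positive, dtype=np.int8), np.zeros(config.n_negative, dtype=np.int8)]
    )
    pos_scores = _class_scores(rng, config.n_positive, config, positive=True)
    neg_scores = _class_scores(rng, config.n_negative, config, positive=False)
    for tool in TOOLS:
        frame[tool] = np.concatenate([pos_scores[tool], neg_scores[tool]])
    scores = {t: frame[t].to_numpy() for t in TOOLS}
    _apply_missingness(rng, scores, config)
    for tool in TOOLS:
        frame[tool] = scores[tool]
    frame["label"] = labels
    perm = rng.permutation(n)
    return BenchmarkDataset(frame.iloc[perm].reset_index(drop=True))


def generate_individual(
    n_rare: int, true_fraction: float, config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """An individual's rare-variant score table with known pathogenic content.

    ``round(n_rare * true_fraction)`` variants are drawn from the
    positive-class generator, the rest from the negative-class one.  The
    returned table carries *no* label column; the truth labels come back
    separately for oracle tests and coverage studies only.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError(f"true_fraction must lie in [0, 1], got {true_fraction}")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_rare * true_fraction))
    n_neg = n_rare - n_pos
    frame = _keys_frame(rng, n_rare)
    pos_scores = _class_scores(rng, n_pos, config, positive=True)
    neg_scores = _class_scores(rng, n_neg, config, positive=False)
    scores = {t: np.concatenate([pos_scores[t], neg_scores[t]]) for t in TOOLS}
    _apply_missingness(rng, scores, config)
    labels = np.concatenate([np.ones(n_pos, dtype=np.int8), np.zeros(n_neg, dtype=np.int8)])
    perm = rng.permutation(n_rare)
    for tool in TOOLS:
        frame[tool] = scores[tool][perm]
    return frame, labels[perm]


def generate_logistic_benchmark(
    alpha: float, beta, tools=None, n: int = 10000, seed: int = 0
) -> BenchmarkDataset:
    """Benchmark drawn exactly from a logistic model (for parameter recovery).

    Tool scores are i.i.d. Uniform(0, 1); labels are Bernoulli with
    P(Y=1) = expit(alpha + beta . X).  No missingness.
    """
    from scipy.special import expit

    beta = np.asarray(beta, dtype=float)
    tools = tuple(tools) if tools is not None else TOOLS[: beta.size]
    if len(tools) != beta.size:
        raise ValueError("one coefficient per tool required")
    rng = np.random.default_rng(seed)
    frame = _keys_frame(rng, n)
    X = rng.random((n, beta.size))
    for j, tool in enumerate(tools):
        frame[tool] = X[:, j]
    for tool in TOOLS:
        if tool not in tools:
            frame[tool] = np.nan
    frame["label"] = (rng.random(n) < expit(alpha + X @ beta)).astype(np.int8)
    return BenchmarkDataset(frame)


# ---------------------------------------------------------------------------
# VCF generation
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=249250621>
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE1
"""


def generate_vcf(path, n_records: int, fail_fractions=None, seed: int = 0):
    """Write a single-sample VCF of biallelic SNVs with controlled quality failures.

    ``fail_fractions`` maps criteria (``dp``, ``qual``, ``gq``) to the
    fraction of records whose corresponding field is drawn from the failing
    side of the default exclusion boundary (DP <= 4, QUAL <= 50, GQ <= 20);
    each criterion fails independently.
    """
    fail = {"dp": 0.0, "qual": 0.0, "gq": 0.0, **(fail_fractions or {})}
    for key, frac in fail.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fail fraction for {key} must lie in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    alts = {"A": "GCT", "C": "AGT", "G": "ACT", "T": "ACG"}
    lines = [_VCF_HEADER]
    for i in range(n_records):
        ref = "ACGT"[rng.integers(0, 4)]
        alt = alts[ref][rng.integers(0, 3)]
        dp = int(rng.integers(0, 5)) if rng.random() < fail["dp"] else int(rng.integers(5, 100))
        qual = (
            float(rng.uniform(0.0, 50.0))
            if rng.random() < fail["qual"]
            else float(rng.uniform(50.5, 500.0))
        )
        gq = int(rng.integers(0, 21)) if rng.random() < fail["gq"] else int(rng.integers(21, 100))
        gt = "0/1" if rng.random() < 0.9 else "1/1"
        lines.append(
            f"1\t{(i + 1) * 17}\t.\t{ref}\t{alt}\t{qual:.2f}\tPASS\tNS=1\tGT:DP:GQ\t{gt}:{dp}:{gq}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path
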