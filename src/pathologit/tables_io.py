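"""Score-table and VCF input/output, score standardization, and hard filters.

This module is the plumbing layer for exome hard-filtering pipelines: it
reads dbNSFP-style tab-separated score tables (one row per nsSNV, one column
per functional prediction tool), rescales raw tool scores onto a common
[0, 1] pathogenicity orientation, and applies the usual pre-prioritization
filters (genotype/site quality, minor allele frequency, derived-allele
orientation).  Every filter returns a :class:`FilterReport` so that a
Table-4-style funnel of per-stage record counts can be assembled.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: Fixed, ordered vocabulary of upstream prediction tools whose scores are
#: consumed (never re-trained) by the combiners.
TOOLS: tuple[str, ...] = ("SIFT", "PolyPhen2", "LRT", "MutationTaster", "PhyloP")

KEY_COLUMNS: tuple[str, ...] = ("chrom", "pos", "ref", "alt")

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """A table or file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


class ConfigurationError(ValueError):
    """An unknown tool or invalid scale/threshold configuration."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of a biallelic SNV: 1-based position plus ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele not in _NUCLEOTIDES:
                raise ValidationError(f"alleles must be single A/C/G/T bases, got {allele!r}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical ({self.ref})")


# ---------------------------------------------------------------------------
# Score standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreScale:
    """Native range and orientation of one tool's raw score.

    ``flip`` marks tools whose *low* native scores indicate damage (SIFT),
    so that after rescaling larger always means more likely pathogenic.
    """

    native_min: float
    native_max: float
    flip: bool = False

    def __post_init__(self) -> None:
        if not self.native_max > self.native_min:
            raise ConfigurationError(
                f"native_max must exceed native_min ({self.native_min}, {self.native_max})"
            )


#: Default per-tool scales.  SIFT is orientation-flipped (0 = damaging).
#: PhyloP has no canonical [0, 1] range; the default covers the usual
#: vertebrate conservation range and :func:`standardize_table` can instead
#: fit it by min-max over the observed input.
DEFAULT_SCALES: dict[str, ScoreScale] = {
    "SIFT": ScoreScale(0.0, 1.0, flip=True),
    "PolyPhen2": ScoreScale(0.0, 1.0),
    "LRT": ScoreScale(0.0, 1.0),
    "MutationTaster": ScoreScale(0.0, 1.0),
    "PhyloP": ScoreScale(-14.0, 6.0),
}


def standardize_score(raw, tool: str, scales: Mapping[str, ScoreScale] | None = None):
    """Min-max rescale a raw tool score to [0, 1], flipping orientation if needed.

    Accepts scalars or arrays; output is clamped to [0, 1].
    """
    scales = DEFAULT_SCALES if scales is None else scales
    try:
        scale = scales[tool]
    except KeyError:
        raise ConfigurationError(f"no score scale configured for tool {tool!r}") from None
    x = (np.asarray(raw, dtype=float) - scale.native_min) / (scale.native_max - scale.native_min)
    if scale.flip:
        x = 1.0 - x
    out = np.clip(x, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def standardize_table(
    frame: pd.DataFrame,
    scales: Mapping[str, ScoreScale] | None = None,
    fit_phylop: bool = True,
) -> tuple[pd.DataFrame, dict[str, ScoreScale]]:
    """Standardize every tool column present in ``frame``.

    When ``fit_phylop`` is true and the table carries at least two distinct
    PhyloP values, the PhyloP scale is fitted min-max over the input table
    (larger = more conserved); otherwise the configured scale applies.
    Returns the rescaled copy and the scales actually used.
    """
    scales = dict(DEFAULT_SCALES if scales is None else scales)
    out = frame.copy()
    for tool in TOOLS:
        if tool not in out.columns:
            continue
        col = out[tool].astype(float)
        if tool == "PhyloP" and fit_phylop:
            observed = col.dropna()
            if observed.nunique() >= 2:
                scales[tool] = ScoreScale(float(observed.min()), float(observed.max()))
        out[tool] = standardize_score(col.to_numpy(), tool, scales)
        out.loc[col.isna(), tool] = np.nan
    return out, scales


# ---------------------------------------------------------------------------
# Labeled benchmark container
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkDataset:
    """A labeled benchmark of variants: key columns, tool scores, 0/1 label.

    ``label`` is 1 for positive (pathogenic) control variants and 0 for
    negative controls.  The class proportion of the sample is exposed as
    :attr:`p_disease_sample`, the training-set positive fraction that the
    bias correction of the logistic combiner needs.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "label" not in self.frame.columns:
            raise ValidationError("benchmark frame requires a 'label' column")
        if len(self.frame) == 0:
            raise ValidationError("benchmark dataset is empty; class proportion undefined")
        labels = set(pd.unique(self.frame["label"]))
        if not labels <= {0, 1}:
            raise ValidationError(f"labels must be 0/1, got {sorted(labels)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=np.int8)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive

    @property
    def p_disease_sample(self) -> float:
        return self.n_positive / len(self)

    @property
    def tool_columns(self) -> tuple[str, ...]:
        return tuple(t for t in TOOLS if t in self.frame.columns)

    def scores(self, tools: Sequence[str] | None = None) -> pd.DataFrame:
        return self.frame[list(tools or self.tool_columns)]

    def complete_cases(self, tools: Sequence[str]) -> "BenchmarkDataset":
        """Restrict to variants with non-missing scores on every given tool."""
        kept = self.frame.dropna(subset=list(tools))
        logger.debug("complete-case restriction on %s: %d -> %d", tools, len(self), len(kept))
        return BenchmarkDataset(kept.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Table reading / writing
# ---------------------------------------------------------------------------

_POSITIVE_LABELS = {"positive", "pathogenic", "1"}
_NEGATIVE_LABELS = {"negative", "neutral", "0"}


def read_score_table(path, has_labels: bool = False):
    """Read a tab-separated score table.

    The header must name ``chrom, pos, ref, alt`` and the five tool columns;
    a ``label`` column (positive/negative) is required when ``has_labels``.
    Missing scores are encoded as ``.`` or empty cells and preserved as NaN.
    Extra columns (``maf``, ``derived_is_alt``, posterior columns written by
    :func:`write_predictions`, ...) ride along untouched.

    Returns a :class:`BenchmarkDataset` when ``has_labels``, else the raw
    :class:`pandas.DataFrame`.
    """
    frame = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    required = list(KEY_COLUMNS) + list(TOOLS) + (["label"] if has_labels else [])
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"score table is missing required column(s): {', '.join(missing)}")

    if len(frame) and has_labels is False and frame[list(TOOLS)].isna().all(axis=None):
        logger.warning("score table %s has no scores at all", path)

    _validate_keys(frame)
    _validate_scores(frame)

    if "derived_is_alt" in frame.columns:
        frame["derived_is_alt"] = frame["derived_is_alt"].astype(bool)

    if not has_labels:
        return frame

    if len(frame) == 0:
        raise ValidationError("labeled table is empty; p_disease_sample undefined")
    raw = frame["label"].astype(str).str.strip().str.lower()
    unknown = raw[~raw.isin(_POSITIVE_LABELS | _NEGATIVE_LABELS)]
    if len(unknown):
        row = int(unknown.index[0]) + 2  # 1-based file line, counting header
        raise ValidationError(f"unrecognized label {unknown.iloc[0]!r} at line {row}")
    frame["label"] = raw.isin(_POSITIVE_LABELS).astype(np.int8)
    return BenchmarkDataset(frame)


def _validate_keys(frame: pd.DataFrame) -> None:
    if len(frame) == 0:
        return
    pos = pd.to_numeric(frame["pos"], errors="coerce")
    bad = pos.isna() | (pos < 1)
    for col in ("ref", "alt"):
        allele = frame[col].astype(str)
        bad |= (allele.str.len() != 1) | ~allele.isin(list(_NUCLEOTIDES))
    bad |= frame["ref"].astype(str) == frame["alt"].astype(str)
    if bad.any():
        row = int(frame.index[bad][0]) + 2
        raise ValidationError(f"invalid variant key at line {row}")
    frame["pos"] = pos.astype(np.int64)


def _validate_scores(frame: pd.DataFrame) -> None:
    for tool in TOOLS:
        col = pd.to_numeric(frame[tool], errors="coerce")
        present = frame[tool].notna()
        out_of_range = present & (col.isna() | (col < 0.0) | (col > 1.0))
        if out_of_range.any():
            row = int(frame.index[out_of_range][0]) + 2
            raise ValidationError(
                f"{tool} score outside [0, 1] at line {row}: {frame[tool][out_of_range].iloc[0]!r}"
            )
        frame[tool] = col


def variant_keys(frame: pd.DataFrame) -> list[VariantKey]:
    """Materialize :class:`VariantKey` objects for each row."""
    return [
        VariantKey(str(c), int(p), str(r), str(a))
        for c, p, r, a in frame[list(KEY_COLUMNS)].itertuples(index=False)
    ]


def write_predictions(frame: pd.DataFrame, path) -> None:
    """Write a prediction table as TSV (missing cells as ``.``).

    Floats are written with 12 significant digits so that the table
    round-trips through :func:`read_score_table`.
    """
    frame.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.12g")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterReport:
    """Per-stage record accounting: ``n_kept + n_removed == n_in`` always."""

    name: str
    n_in: int
    n_kept: int
    detail: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_kept

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_in if self.n_in else 0.0

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "n_in": self.n_in,
            "n_kept": self.n_kept,
            "n_removed": self.n_removed,
            "fraction_removed": self.fraction_removed,
            **self.detail,
        }


def filter_derived_orientation(frame: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop variants whose alternative allele is not the derived allele.

    Upstream tools disagree on whether predictions refer to alternative or
    derived alleles; keeping only alt==derived variants removes the
    inconsistency.  Requires a boolean ``derived_is_alt`` column.
    """
    if "derived_is_alt" not in frame.columns:
        raise FormatError("filter_derived_orientation requires a 'derived_is_alt' column")
    mask = frame["derived_is_alt"].astype(bool).to_numpy()
    kept = frame[mask].reset_index(drop=True)
    report = FilterReport("derived_orientation", n_in=len(frame), n_kept=len(kept))
    if len(frame) and not len(kept):
        warnings.warn("derived-orientation filter removed every record", stacklevel=2)
    logger.info("derived-orientation filter removed %d of %d records", report.n_removed, report.n_in)
    return kept, report


def maf_filter(
    frame: pd.DataFrame,
    maf: Mapping[VariantKey, float] | pd.Series | np.ndarray | None = None,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Hard-filter common variants: remove records with MAF strictly > threshold.

    ``maf`` may be a mapping keyed by :class:`VariantKey`, an array aligned
    with the rows, or None to use the table's ``maf`` column (if any).
    Variants absent from the lookup are treated as rare and kept: hard
    filtering discards only variants *found* common in databases.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"MAF threshold must be in (0, 1), got {threshold}")
    n = len(frame)
    if maf is None:
        values = frame["maf"].to_numpy(dtype=float) if "maf" in frame.columns else np.full(n, np.nan)
    elif isinstance(maf, Mapping):
        values = np.array([maf.get(k, np.nan) for k in variant_keys(frame)], dtype=float)
    else:
        values = np.asarray(maf, dtype=float)
        if values.shape != (n,):
            raise ValidationError("maf array must align with the table rows")
    with np.errstate(invalid="ignore"):
        common = values > threshold  # NaN compares False -> absent kept
    kept = frame[~common].reset_index(drop=True)
    report = FilterReport(
        "maf", n_in=n, n_kept=len(kept), detail={"threshold": threshold}
    )
    logger.info(
        "MAF>%g filter removed %d of %d records (%.1f%%)",
        threshold, report.n_removed, n, 100 * report.fraction_removed,
    )
    return kept, report


def vcf_quality_filter(
    path,
    coverage_min: int = 5,
    base_qual_min: float = 50.0,
    gq_min: float = 20.0,
    sample: str | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Exclude low-quality VCF genotypes and sites.

    A biallelic SNV record passes iff read depth ``DP >= coverage_min``,
    site quality ``QUAL > base_qual_min`` and genotype quality
    ``GQ > gq_min`` — i.e. with the defaults, records with DP<=4, QUAL<=50
    or GQ<=20 are excluded.  Records lacking DP/GQ/QUAL are excluded
    conservatively (absence of evidence of quality fails an exclusion
    filter) with a logged warning; non-SNV or multiallelic records are
    skipped and counted separately.
    """
    rows = []
    n_seen = 0
    n_missing_fields = 0
    n_non_snv = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if sample is None:
            sample = sample_names[0] if sample_names else None
        for rec in vcf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.ref not in _NUCLEOTIDES
                or rec.alts[0] not in _NUCLEOTIDES
            ):
                n_non_snv += 1
                continue
            n_seen += 1
            fmt = rec.samples[sample] if sample is not None else {}
            dp = fmt.get("DP")
            gq = fmt.get("GQ")
            qual = rec.qual
            if dp is None or gq is None or qual is None:
                n_missing_fields += 1
                continue
            if dp >= coverage_min and qual > base_qual_min and gq > gq_min:
                rows.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": rec.alts[0],
                        "qual": float(qual),
                        "dp": int(dp),
                        "gq": float(gq),
                    }
                )
    if n_missing_fields:
        warnings.warn(
            f"{n_missing_fields} VCF record(s) lacked DP/GQ/QUAL and were excluded",
            stacklevel=2,
        )
    kept = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual", "dp", "gq"])
    report = FilterReport(
        "vcf_quality",
        n_in=n_seen,
        n_kept=len(kept),
        detail={
            "n_non_snv_skipped": n_non_snv,
            "n_missing_fields": n_missing_fields,
            "coverage_min": coverage_min,
            "base_qual_min": base_qual_min,
            "gq_min": gq_min,
        },
    )
    return kept, report


def filter_summary(reports: Iterable[FilterReport], path=None) -> dict:
    """Assemble (and optionally write as JSON) a per-stage filtering funnel."""
    stages = [r.as_dict() for r in reports]
    summary = {
        "stages": stages,
        "n_in": stages[0]["n_in"] if stages else 0,
        "n_out": stages[-1]["n_kept"] if stages else 0,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
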