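"""Plasma-vs-child callset concordance statistics.

For each sample and inheritance category the child/fetus callset (the
"truth" side) is compared with the plasma low-frequency callset: variants
found in both are *common*, truth variants missed in plasma are
*uncommon*. The headline statistic is the percentage of common variants,
with the mean plasma coverage at the uncommon sites as the companion
diagnostic — poorly covered truth variants are the ones plasma calling
tends to miss.

Percentages are rounded half-up to integers; 100% is only reported when
the overlap is complete (a 99.6% overlap with remaining misses prints as
99), matching diagnostic reporting practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

FATHER_INHERITED = "father_inherited"
DE_NOVO = "de_novo"
CATEGORIES = (FATHER_INHERITED, DE_NOVO)

VariantKey = tuple  # (chrom, pos, ref, alt)


class EmptyCategoryError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapReport:
    """Concordance of one sample x inheritance category."""

    sample_id: str
    category: str
    total: int
    common: int
    uncommon: int
    pct_common: int
    mean_cov_uncommon: float

    def __post_init__(self) -> None:
        if self.common + self.uncommon != self.total:
            raise ValueError("common + uncommon must equal total")
        if not 0 <= self.pct_common <= 100:
            raise ValueError("pct_common must be a percentage")


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    n: int
    predictor: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must be in [0, 1]")
        if self.n < 2:
            raise ValueError("need n >= 2")


def normalize_key(chrom, pos, ref, alt) -> VariantKey:
    return (str(chrom), int(pos), str(ref).upper(), str(alt).upper())


def match_callsets(plasma, truth):
    """Partition two variant key sets into common / plasma-only / truth-only.

    Duplicate keys within a set are collapsed with a warning.
    """
    plasma = list(plasma)
    truth = list(truth)
    plasma_set = set(plasma)
    truth_set = set(truth)
    if len(plasma_set) < len(plasma):
        warnings.warn(f"collapsed {len(plasma) - len(plasma_set)} duplicate plasma keys")
    if len(truth_set) < len(truth):
        warnings.warn(f"collapsed {len(truth) - len(truth_set)} duplicate truth keys")
    common = plasma_set & truth_set
    return common, plasma_set - common, truth_set - common


def percent_common(common: int, total: int) -> int:
    """Integer percentage, rounded half-up; 100 only for a complete overlap."""
    if total <= 0:
        raise EmptyCategoryError("total must be > 0")
    if common == total:
        return 100
    return min(math.floor(100.0 * common / total + 0.5), 99)


def overlap_report(
    sample_id,
    category: str,
    common_keys,
    truth_only_keys,
    coverage: dict | None = None,
) -> OverlapReport:
    """Build the concordance report for one sample x category.

    ``total`` is the truth-side count (common + truth-only);
    ``coverage`` maps uncommon variant keys to their plasma read coverage
    (uncovered keys count as 0 reads).
    """
    common = len(set(common_keys))
    uncommon_keys = set(truth_only_keys)
    uncommon = len(uncommon_keys)
    total = common + uncommon
    if total == 0:
        raise EmptyCategoryError(f"no truth variants for {sample_id}/{category}")
    coverage = coverage or {}
    mean_cov = (
        float(np.mean([float(coverage.get(k, 0.0)) for k in sorted(uncommon_keys)]))
        if uncommon
        else float("nan")
    )
    return OverlapReport(
        sample_id=str(sample_id),
        category=category,
        total=total,
        common=common,
        uncommon=uncommon,
        pct_common=percent_common(common, total),
        mean_cov_uncommon=mean_cov,
    )


def apply_coverage_filter(
    report: OverlapReport, coverage: dict, threshold: float = 5.0
) -> OverlapReport:
    """Re-filter: drop uncommon variants at plasma coverage <= threshold.

    Poorly covered truth variants cannot be expected in the plasma
    callset, so they leave the denominator; the percentage of common
    variants is monotone non-decreasing under this filter.
    """
    surviving = {k: c for k, c in coverage.items() if float(c) > threshold}
    uncommon = len(surviving)
    total = report.common + uncommon
    mean_cov = float(np.mean(sorted(surviving.values()))) if uncommon else float("nan")
    return OverlapReport(
        sample_id=report.sample_id,
        category=report.category,
        total=total,
        common=report.common,
        uncommon=uncommon,
        pct_common=percent_common(report.common, total) if total else 100,
        mean_cov_uncommon=mean_cov,
    )


def pearson_r2(x, y, predictor: str = "coverage") -> CorrelationResult:
    """Squared Pearson correlation (affine-invariant, symmetric)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need two equal-length series with n >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r = pearsonr(x, y)[0]
    return CorrelationResult(r2=float(r**2), n=len(x), predictor=predictor)


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id, "category": r.category,
                "total": r.total, "common": r.common, "uncommon": r.uncommon,
                "pct_common": r.pct_common, "mean_cov_uncommon": r.mean_cov_uncommon,
            }
            for r in reports
        ]
    )


def cohort_summary(reports) -> pd.DataFrame:
    """Arithmetic mean of pct_common per inheritance category."""
    frame = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    if frame.empty:
        raise EmptyCategoryError("no reports to summarize")
    return (
        frame.groupby("category")
        .agg(n=("pct_common", "size"), mean_pct_common=("pct_common", "mean"))
        .reset_index()
    )


def correlation_analysis(
    concordance: pd.DataFrame, ff_by_sample: pd.Series | None = None
) -> pd.DataFrame:
    """r² of overlap percentage against coverage and fetal fraction.

    Emits the pooled (both categories) result plus per-category results,
    and — because the axes pairing of published scatter summaries is often
    ambiguous — also the coverage-vs-FF pairing. ``concordance`` needs
    columns ``sample_id, category, pct_common, mean_cov_uncommon``.
    """
    frame = concordance.copy()
    if ff_by_sample is not None:
        frame = frame.merge(
            ff_by_sample.rename("ff").rename_axis("sample_id").reset_index(),
            on="sample_id",
        )
    rows = []

    def _add(name, sub, xcol, ycol):
        sub = sub.dropna(subset=[xcol, ycol])
        if len(sub) >= 2:
            res = pearson_r2(sub[xcol], sub[ycol], predictor=name)
            rows.append({"comparison": name, "r2": res.r2, "n": res.n})

    _add("pct_common~coverage[pooled]", frame, "pct_common", "mean_cov_uncommon")
    for cat, sub in frame.groupby("category"):
        _add(f"pct_common~coverage[{cat}]", sub, "pct_common", "mean_cov_uncommon")
    if "ff" in frame.columns:
        _add("pct_common~ff[pooled]", frame, "pct_common", "ff")
        for cat, sub in frame.groupby("category"):
            _add(f"pct_common~ff[{cat}]", sub, "pct_common", "ff")
        _add("coverage~ff[pooled]", frame, "mean_cov_uncommon", "ff")
    return pd.DataFrame(rows)


def scatter_plots(concordance: pd.DataFrame, ff_by_sample: pd.Series, out_prefix: str) -> list[str]:
    """Overlap-vs-coverage and overlap-vs-FF scatter plots (PNG files)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = concordance.merge(
        ff_by_sample.rename("ff").rename_axis("sample_id").reset_index(), on="sample_id"
    )
    paths = []
    for xcol, xlabel, suffix in [
        ("mean_cov_uncommon", "mean coverage of uncommon variants", "coverage"),
        ("ff", "fetal fraction (%)", "fetal_fraction"),
    ]:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cat, sub in frame.groupby("category"):
            ax.scatter(sub[xcol], sub["pct_common"], label=cat, alpha=0.7)
        ax.set_xlabel(xlabel)
        ax.set_ylabel("% common variants")
        ax.legend()
        fig.tight_layout()
        path = f"{out_prefix}_{suffix}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
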