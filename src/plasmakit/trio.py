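"""Artifact filtering and trio-based inheritance classification.

Child/fetal gDNA callsets are pre-filtered before any plasma comparison:

1. allele-fraction band: variants with AF at or below ``af_low`` (default
   0.20) or above ``af_high`` (default 0.80) are removed as likely
   artifacts (the literal band also removes true homozygous calls; a
   config switch can exempt them);
2. blacklist: variants inside curated low-mappability/repeat regions
   (ENCODE-style BED) are removed;
3. depth: variants below ``min_depth`` (default 100x) are removed.

Surviving variants are then classified against the parental genotypes:
an alt allele absent from the mother and present in the father is
paternally inherited; absent from both parents, de novo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GenomicIntervals

PATERNAL_INHERITED = "paternal_inherited"
DE_NOVO = "de_novo"
MATERNAL_OR_SHARED = "maternal_or_shared"
UNCLASSIFIABLE = "unclassifiable"
TRIO_LABELS = (PATERNAL_INHERITED, DE_NOVO, MATERNAL_OR_SHARED, UNCLASSIFIABLE)


@dataclass
class FilterConfig:
    af_low: float = 0.20
    af_high: float = 0.80
    min_depth: int = 100
    blacklist: GenomicIntervals = field(default_factory=GenomicIntervals)
    exempt_hom_alt: bool = False  # keep AF > af_high calls (true homozygotes)

    def __post_init__(self) -> None:
        if not 0.0 <= self.af_low < self.af_high <= 1.0:
            raise ValueError("need 0 <= af_low < af_high <= 1")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def _split(variants: pd.DataFrame, keep_mask, reason: str):
    keep_mask = keep_mask.fillna(False) if hasattr(keep_mask, "fillna") else keep_mask
    kept = variants[keep_mask]
    removed = variants[~keep_mask].copy()
    removed["exclusion_reason"] = reason
    return kept, removed


def allele_fraction_filter(variants: pd.DataFrame, config: FilterConfig | None = None):
    """Keep variants with af_low < AF <= af_high.

    The boundary semantics are literal: AF exactly at the lower bound is
    excluded ("at or below"), AF exactly at the upper bound is kept.
    Variants with a missing AF go to the exclusion log with reason
    ``missing-field``.
    """
    config = config or FilterConfig()
    af = pd.to_numeric(
        variants.get("allele_fraction", pd.Series(index=variants.index, dtype=float)),
        errors="coerce",
    )
    missing = af.isna()
    in_band = (af > config.af_low) & (af <= config.af_high)
    if config.exempt_hom_alt:
        in_band |= af > config.af_high
    kept, removed = _split(variants, in_band.fillna(False), "allele_fraction")
    removed.loc[missing.reindex(removed.index, fill_value=False), "exclusion_reason"] = (
        "missing-field"
    )
    return kept, removed


def blacklist_filter(variants: pd.DataFrame, blacklist: GenomicIntervals):
    """Remove variants whose 1-based position falls in a blacklist interval.

    BED intervals are 0-based half-open: ``[100, 200)`` covers 1-based
    positions 101..200, so a variant at pos 100 is kept and one at 101
    removed. Idempotent.
    """
    in_blacklist = variants.apply(
        lambda r: blacklist.covers_position(str(r["chrom"]), int(r["pos"])), axis=1
    ) if len(variants) else pd.Series([], dtype=bool, index=variants.index)
    return _split(variants, ~in_blacklist, "blacklist")


def depth_filter(variants: pd.DataFrame, config: FilterConfig | None = None):
    """Keep variants with depth >= min_depth (boundary kept)."""
    config = config or FilterConfig()
    depth = pd.to_numeric(
        variants.get("depth", pd.Series(index=variants.index, dtype=float)),
        errors="coerce",
    )
    return _split(variants, depth >= config.min_depth, "depth")


def classify_trio_variant(
    proband_copies, mother_copies, father_copies
) -> str:
    """Inheritance class of one proband variant from the trio genotypes.

    Rules (alt-allele presence means called copies >= 1):

    * proband alt, mother 0, father >= 1 -> paternal_inherited
    * proband alt, mother 0, father 0    -> de_novo
    * proband alt, mother >= 1           -> maternal_or_shared
    * proband without the alt            -> maternal_or_shared (complement)
    * any required genotype unknown      -> unclassifiable

    A missing proband genotype raises.
    """
    if proband_copies is None or pd.isna(proband_copies):
        raise ValueError("proband genotype is required")
    if int(proband_copies) == 0:
        return MATERNAL_OR_SHARED
    if mother_copies is None or pd.isna(mother_copies):
        return UNCLASSIFIABLE
    if int(mother_copies) >= 1:
        return MATERNAL_OR_SHARED
    if father_copies is None or pd.isna(father_copies):
        return UNCLASSIFIABLE
    return PATERNAL_INHERITED if int(father_copies) >= 1 else DE_NOVO


def classify_trio_table(variants: pd.DataFrame) -> pd.Series:
    """Vector version of :func:`classify_trio_variant` over a variant table."""
    return pd.Series(
        [
            classify_trio_variant(r.gt_proband, r.gt_mother, r.gt_father)
            for r in variants.itertuples()
        ],
        index=variants.index,
        dtype=object,
    )


@dataclass
class PipelineReport:
    """Removal counts per stage, in application order."""

    n_input: int
    removed: dict[str, int]
    n_kept: int
    stage_order: tuple[str, ...] = ("allele_fraction", "blacklist", "depth")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(stage, self.removed.get(stage, 0)) for stage in self.stage_order]
        rows.append(("kept", self.n_kept))
        return pd.DataFrame(rows, columns=["stage", "count"])


def run_artifact_pipeline(
    variants: pd.DataFrame, config: FilterConfig | None = None
):
    """AF band, blacklist and depth filters in order, then classification.

    Returns ``(kept, exclusion_log, report)``. ``kept`` gains a
    ``trio_class`` column where the trio genotype columns
    (``gt_proband/gt_mother/gt_father``) are present. Removals are
    attributed to the first failing stage.
    """
    config = config or FilterConfig()
    kept, removed_af = allele_fraction_filter(variants, config)
    kept, removed_bl = blacklist_filter(kept, config.blacklist)
    kept, removed_dp = depth_filter(kept, config)
    exclusion_log = pd.concat([removed_af, removed_bl, removed_dp])
    report = PipelineReport(
        n_input=len(variants),
        removed={
            "allele_fraction": len(removed_af),
            "blacklist": len(removed_bl),
            "depth": len(removed_dp),
        },
        n_kept=len(kept),
    )
    kept = kept.copy()
    if {"gt_proband", "gt_mother", "gt_father"} <= set(kept.columns):
        kept["trio_class"] = classify_trio_table(kept)
    return kept, exclusion_log, report


class ArtifactFilter(BaseEstimator, TransformerMixin):
    """The three artifact filters as a stateless sklearn transformer."""

    def __init__(
        self,
        af_low: float = 0.20,
        af_high: float = 0.80,
        min_depth: int = 100,
        blacklist: GenomicIntervals | None = None,
        exempt_hom_alt: bool = False,
    ):
        self.af_low = af_low
        self.af_high = af_high
        self.min_depth = min_depth
        self.blacklist = blacklist
        self.exempt_hom_alt = exempt_hom_alt

    def _config(self) -> FilterConfig:
        return FilterConfig(
            af_low=self.af_low,
            af_high=self.af_high,
            min_depth=self.min_depth,
            blacklist=self.blacklist or GenomicIntervals(),
            exempt_hom_alt=self.exempt_hom_alt,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ArtifactFilter":
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        kept, _, _ = run_artifact_pipeline(X, self._config())
        return kept
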