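"""Bundled validation-cohort tables.

The package ships the summary tables of the 36-family clinical validation
cohort the method was developed on: per-sample gestational age, fetal
fraction and screening outcome, and the plasma-vs-child concordance
counts per inheritance category for two child-side variant callers (GATK
and ISAAC). These are the worked-example inputs for the concordance and
correlation analyses.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_CALLERS = ("gatk", "isaac")


def _read(name: str) -> pd.DataFrame:
    with resources.files("plasmakit").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_cohort_summary() -> pd.DataFrame:
    """Per-sample cohort table.

    Columns: ``sample_id``; ``gestational_age`` (weeks+days, e.g. "12+3");
    ``ff_percent`` (fetal fraction, percent); ``snv_acmg`` (worst ACMG
    class of any panel SNV call: P, LP, VUS or none); ``panel_cnv``
    (del/dup/none for panel CNV calls).
    """
    return _read("cohort_summary.tsv")


def load_validation_concordance(caller: str = "gatk") -> pd.DataFrame:
    """Plasma-vs-child concordance counts, one row per sample x category.

    Columns: ``sample_id, category, total, common, uncommon,
    pct_common_printed, mean_cov_uncommon``. ``total`` is the child-side
    (truth) count; ``pct_common_printed`` is the percentage as published,
    kept verbatim for cross-checks.
    """
    if caller not in _CALLERS:
        raise ValueError(f"caller must be one of {_CALLERS}")
    return _read(f"concordance_{caller}.tsv")


def gestational_age_weeks(value: str) -> float:
    """Decimal weeks from a 'weeks+days' gestational-age string."""
    weeks, _, days = str(value).partition("+")
    return int(weeks) + (int(days) if days else 0) / 7.0


def cohort_statistics(cohort: pd.DataFrame | None = None) -> dict:
    """Headline cohort numbers recomputed from the per-sample table.

    Counts of samples with at least one pathogenic/likely-pathogenic SNV
    (VUS-only and CNV-only samples excluded), panel deletions and
    duplications, the fetal-fraction range and the mean gestational age
    in decimal weeks.
    """
    cohort = load_cohort_summary() if cohort is None else cohort
    ga = cohort["gestational_age"].map(gestational_age_weeks)
    return {
        "n_samples": int(len(cohort)),
        "n_pathogenic_snv_samples": int(cohort["snv_acmg"].isin(["P", "LP"]).sum()),
        "n_deletions": int((cohort["panel_cnv"] == "del").sum()),
        "n_duplications": int((cohort["panel_cnv"] == "dup").sum()),
        "ff_min": int(cohort["ff_percent"].min()),
        "ff_max": int(cohort["ff_percent"].max()),
        "mean_gestational_weeks": round(float(ga.mean()), 1),
    }
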