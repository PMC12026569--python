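"""Synthetic trio-cohort generator.

Generates everything the pipeline consumes, at desk scale: trio genotypes
at biallelic SNP sites (Hardy-Weinberg parents, Mendelian transmission,
a small de novo rate), plasma allele counts from the same binomial
mixture the caller inverts, cfDNA fragments with origin-specific length
distributions (fetal fragments shorter than maternal), per-bin fragment
counts with injected fetal CNVs, and diploid reference control bins.

Defaults emulate the study conditions the method targets: fetal fraction
0.10 (the middle of the observed 5-20% range, swept in tests), ~200x
plasma depth at 2000 SNP sites, fragment-length modes 143 bp (fetal) and
166 bp (maternal) with sd 20 — conventional cfDNA values — and 50 bins of
100 kb for the CNV arm. Every draw flows from one seeded generator, so a
cohort is byte-reproducible from its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from . import io as pio
from .cnv import (
    COPY_STATES, DIPLOID, FETAL_DEL, FETAL_DUP, ReferenceBinSet,
    expected_short_fraction, _STATE_COPIES,
)
from .fragments import (
    DEFAULT_BIN_WIDTH, DEFAULT_MAX_EDGE, DEFAULT_MIN_EDGE, SizeDistribution,
)
from .genotype import expected_alt_fraction


@dataclass(frozen=True)
class CNVEvent:
    chrom: str
    start: int
    end: int
    state: str

    def __post_init__(self) -> None:
        if self.state not in (FETAL_DEL, FETAL_DUP):
            raise ValueError("event state must be fetal_del or fetal_dup")
        if self.end <= self.start:
            raise ValueError("event end must exceed start")


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort."""

    n_sites: int = 2000
    alt_freq_range: tuple[float, float] = (0.05, 0.95)
    fetal_fraction: float = 0.10
    mean_depth: float = 200.0
    error_rate: float = 0.01
    de_novo_rate: float = 1e-3
    fetal_length_mode: float = 143.0
    maternal_length_mode: float = 166.0
    length_sd: float = 20.0
    short_threshold: float = 150.0
    n_bins: int = 50
    bin_size: int = 100_000
    fragments_per_bin: float = 500.0
    fragments_per_site: float = 50.0
    snp_chrom: str = "chr1"
    bin_chrom: str = "chr2"
    cnv_events: tuple[CNVEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.fetal_fraction, self.error_rate, self.de_novo_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        events = sorted(self.cnv_events, key=lambda e: (e.chrom, e.start))
        for a, b in zip(events, events[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping CNV events: {a} / {b}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def nominal_size_distribution(
    mode: float, sd: float,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_edge: int = DEFAULT_MIN_EDGE,
    max_edge: int = DEFAULT_MAX_EDGE,
) -> SizeDistribution:
    """The model (noise-free) size histogram of a Gaussian length law."""
    edges = np.arange(min_edge, max_edge + bin_width, bin_width, dtype=float)
    cdf = norm.cdf(edges, loc=mode, scale=sd)
    dens = np.diff(cdf)
    return SizeDistribution(bin_edges=edges, densities=dens / dens.sum(), n_fragments=0)


def simulate_trio_genotypes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Parental genotypes from Hardy-Weinberg, child by Mendelian transmission.

    De novo alt alleles are injected at ``de_novo_rate`` at sites where
    neither parent carries the alt (so the label is unambiguous).
    """
    lo, hi = config.alt_freq_range
    q = rng.uniform(lo, hi, config.n_sites)
    m = rng.binomial(2, q)
    p = rng.binomial(2, q)
    k = rng.binomial(1, m / 2.0) + rng.binomial(1, p / 2.0)
    de_novo = (m == 0) & (p == 0) & (rng.random(config.n_sites) < config.de_novo_rate)
    k = np.where(de_novo, 1, k)
    return pd.DataFrame(
        {
            "chrom": config.snp_chrom,
            "pos": 1000 * (np.arange(config.n_sites) + 1) + 1,
            "ref": "A",
            "alt": "G",
            "alt_freq": q,
            "maternal_copies": m,
            "paternal_copies": p,
            "fetal_copies": k,
            "is_de_novo": de_novo,
        }
    )


def simulate_plasma_counts(
    genotypes: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Plasma allele counts: Poisson depth, binomial alt counts.

    The alt probability is the same error-adjusted mixture the genotype
    model inverts.
    """
    p_alt = expected_alt_fraction(
        genotypes["maternal_copies"].to_numpy(),
        genotypes["fetal_copies"].to_numpy(),
        config.fetal_fraction,
        config.error_rate,
    )
    depth = rng.poisson(config.mean_depth, len(genotypes))
    alt = rng.binomial(depth, p_alt)
    out = genotypes.copy()
    out["depth"] = depth
    out["alt_count"] = alt
    return out


def _draw_lengths(origins: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    modes = np.where(origins == "fetal", config.fetal_length_mode, config.maternal_length_mode)
    lengths = rng.normal(modes, config.length_sd)
    return np.clip(np.round(lengths), DEFAULT_MIN_EDGE + 1, DEFAULT_MAX_EDGE - 1).astype(int)


def _bin_copy_states(config: SimConfig) -> np.ndarray:
    states = np.full(config.n_bins, DIPLOID, dtype=object)
    starts = np.arange(config.n_bins) * config.bin_size
    ends = starts + config.bin_size
    for ev in config.cnv_events:
        if ev.chrom != config.bin_chrom:
            continue
        hit = (starts < ev.end) & (ends > ev.start)
        states[hit] = ev.state
    return states


def simulate_fragments_and_bins(
    genotypes: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """cfDNA fragments at SNP sites and in CNV bins, plus bin counts.

    SNP-site fragments carry an observed allele (with read error) so they
    can be origin-tagged; bin fragments carry no allele but respond to the
    injected CNV events — a fetal event scales the fetal fragment rate by
    copies/2 in its bins.
    """
    frag_tables = []

    # fragments covering tagging-capable SNP sites (mother hom-ref or hom-alt)
    tagging = genotypes[genotypes["maternal_copies"].isin([0, 2])]
    if len(tagging) and config.fragments_per_site > 0:
        counts = rng.poisson(config.fragments_per_site, len(tagging))
        site_idx = np.repeat(np.arange(len(tagging)), counts)
        sites = tagging.iloc[site_idx]
        n = len(sites)
        origins = np.where(rng.random(n) < config.fetal_fraction, "fetal", "maternal")
        copies = np.where(
            origins == "fetal",
            sites["fetal_copies"].to_numpy(),
            sites["maternal_copies"].to_numpy(),
        )
        carries_alt = rng.random(n) < copies / 2.0
        miscalled = rng.random(n) < config.error_rate
        observed_alt = carries_alt ^ miscalled
        lengths = _draw_lengths(origins, config, rng)
        offset = rng.integers(0, lengths)
        pos = sites["pos"].to_numpy()
        start = pos - 1 - offset
        frag_tables.append(
            pd.DataFrame(
                {
                    "chrom": sites["chrom"].to_numpy(),
                    "start": start,
                    "end": start + lengths,
                    "length": lengths,
                    "site_pos": pos.astype(float),
                    "allele": np.where(
                        observed_alt, sites["alt"].to_numpy(), sites["ref"].to_numpy()
                    ),
                    "true_origin": origins,
                }
            )
        )

    # bin fragments driving the CNV arm
    states = _bin_copy_states(config)
    starts = np.arange(config.n_bins) * config.bin_size
    f = config.fetal_fraction
    copies = np.array([_STATE_COPIES[s] for s in states], dtype=float)
    n_fetal = rng.poisson(config.fragments_per_bin * f * copies / 2.0)
    n_maternal = rng.poisson(config.fragments_per_bin * (1.0 - f), config.n_bins)
    rows = []
    for b in range(config.n_bins):
        total = n_fetal[b] + n_maternal[b]
        if total == 0:
            continue
        origins = np.array(["fetal"] * n_fetal[b] + ["maternal"] * n_maternal[b])
        lengths = _draw_lengths(origins, config, rng)
        frag_start = starts[b] + rng.integers(0, config.bin_size, total)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": config.bin_chrom,
                    "start": frag_start,
                    "end": frag_start + lengths,
                    "length": lengths,
                    "site_pos": np.nan,
                    "allele": "",
                    "true_origin": origins,
                }
            )
        )
    frag_tables.extend(rows)
    fragments = (
        pd.concat(frag_tables, ignore_index=True)
        if frag_tables
        else pd.DataFrame(
            columns=["chrom", "start", "end", "length", "site_pos", "allele", "true_origin"]
        )
    )

    bin_frags = fragments[fragments["chrom"] == config.bin_chrom]
    bin_index = np.minimum(
        bin_frags["start"].to_numpy() // config.bin_size, config.n_bins - 1
    )
    count = np.bincount(bin_index, minlength=config.n_bins)
    n_short = np.bincount(
        bin_index,
        weights=(bin_frags["length"].to_numpy() < config.short_threshold),
        minlength=config.n_bins,
    )
    with np.errstate(invalid="ignore"):
        short_fraction = np.where(count > 0, n_short / np.maximum(count, 1), np.nan)
    bins = pd.DataFrame(
        {
            "chrom": config.bin_chrom,
            "start": starts,
            "end": starts + config.bin_size,
            "count": count,
            "n_short": n_short.astype(int),
            "short_fraction": short_fraction,
            "true_state": states,
        }
    )
    return fragments, bins


def simulate_reference(
    config: SimConfig, rng: np.random.Generator, n_controls: int = 20
) -> ReferenceBinSet:
    """Diploid control samples -> reference bins plus pooled noise terms.

    Controls are plasma-like (same fetal fraction, no events). The
    reference count per bin is the control mean; ``ratio_sigma`` is the
    pooled sd of control log2 ratios against that mean, and the
    short-fraction mean/sd pool all control bins.
    """
    lam = config.fragments_per_bin
    counts = rng.poisson(lam, size=(n_controls, config.n_bins)).astype(float)
    s_f = nominal_size_distribution(config.fetal_length_mode, config.length_sd).mass_below(
        config.short_threshold
    )
    s_m = nominal_size_distribution(config.maternal_length_mode, config.length_sd).mass_below(
        config.short_threshold
    )
    p_short = (1 - config.fetal_fraction) * s_m + config.fetal_fraction * s_f
    n_short = rng.binomial(np.maximum(counts.astype(int), 1), p_short)
    ref_counts = counts.mean(axis=0)
    sample_medians = np.median(counts, axis=1, keepdims=True)
    ratios = (counts / sample_medians) / (ref_counts / np.median(ref_counts))
    log2r = np.log2(np.maximum(ratios, 1e-6))
    short_fractions = n_short / np.maximum(counts, 1)
    starts = np.arange(config.n_bins) * config.bin_size
    bins = pd.DataFrame(
        {
            "chrom": config.bin_chrom,
            "start": starts,
            "end": starts + config.bin_size,
            "count": ref_counts,
        }
    )
    return ReferenceBinSet(
        bins=bins,
        ratio_sigma=float(log2r.std(ddof=1)),
        short_fraction_mean=float(short_fractions.mean()),
        short_fraction_sd=float(short_fractions.std(ddof=1)),
    )


def simulate_ratio_bins(
    n_bins: int,
    sigma: float,
    f: float,
    rng: np.random.Generator,
    event_bins: tuple[int, int] | None = None,
    event_state: str = FETAL_DEL,
    short_fraction_sd: float = 0.02,
    config: SimConfig | None = None,
) -> tuple[pd.DataFrame, ReferenceBinSet]:
    """Bin-level generator for caller validation at a chosen noise level.

    Draws log2 ratios directly from the Gaussian observation model at a
    given sigma (bypassing fragment counting, which fixes sigma at the
    Poisson level) and short fractions around their state expectation.
    Returns the normalized bin table and a matching reference.
    """
    config = config or SimConfig()
    states = np.full(n_bins, DIPLOID, dtype=object)
    if event_bins is not None:
        states[event_bins[0]:event_bins[1]] = event_state
    fetal_dist = nominal_size_distribution(config.fetal_length_mode, config.length_sd)
    maternal_dist = nominal_size_distribution(config.maternal_length_mode, config.length_sd)
    mu = np.array(
        [np.log2(1.0 + f * (_STATE_COPIES[s] - 2) / 2.0) for s in states], dtype=float
    )
    ratios = 2.0 ** rng.normal(mu, sigma)
    sf_mu = np.array(
        [
            expected_short_fraction(s, f, fetal_dist, maternal_dist, config.short_threshold)
            for s in states
        ]
    )
    sf = rng.normal(sf_mu, short_fraction_sd)
    starts = np.arange(n_bins) * config.bin_size
    bins = pd.DataFrame(
        {
            "chrom": config.bin_chrom,
            "start": starts,
            "end": starts + config.bin_size,
            "ratio": ratios,
            "short_fraction": sf,
            "true_state": states,
        }
    )
    diploid_sf = expected_short_fraction(
        DIPLOID, f, fetal_dist, maternal_dist, config.short_threshold
    )
    reference = ReferenceBinSet(
        bins=bins[["chrom", "start", "end"]].assign(count=config.fragments_per_bin),
        ratio_sigma=sigma,
        short_fraction_mean=diploid_sf,
        short_fraction_sd=short_fraction_sd,
    )
    return bins, reference


@dataclass
class SimulatedCohort:
    """One simulated family: all tables plus the config echo."""

    config: SimConfig
    genotypes: pd.DataFrame
    sites: pd.DataFrame
    fragments: pd.DataFrame
    bins: pd.DataFrame
    reference: ReferenceBinSet

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["cnv_events"] = [dataclasses.asdict(e) for e in self.config.cnv_events]
        cfg["alt_freq_range"] = list(self.config.alt_freq_range)
        return {
            "seed": self.config.seed,
            "config": cfg,
            "n_sites": int(len(self.sites)),
            "n_fragments": int(len(self.fragments)),
            "n_bins": int(len(self.bins)),
        }


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run the full generator in a fixed draw order from the config seed."""
    rng = config.rng()
    genotypes = simulate_trio_genotypes(config, rng)
    sites = simulate_plasma_counts(genotypes, config, rng)
    fragments, bins = simulate_fragments_and_bins(genotypes, config, rng)
    reference = simulate_reference(config, rng)
    return SimulatedCohort(
        config=config,
        genotypes=genotypes,
        sites=sites,
        fragments=fragments,
        bins=bins,
        reference=reference,
    )


def emit_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk (VCF/TSV/BED + YAML manifest).

    Output is re-readable by the module interfaces; two runs with the
    same seed produce identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _tsv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[name] = path

    _tsv("sites", cohort.sites)
    _tsv("fragments", cohort.fragments)
    _tsv("bins", cohort.bins)
    _tsv("reference_bins", cohort.reference.bins)

    trio = cohort.genotypes.rename(
        columns={
            "fetal_copies": "gt_proband",
            "maternal_copies": "gt_mother",
            "paternal_copies": "gt_father",
        }
    )
    trio_path = outdir / "trio.vcf"
    pio.write_vcf(trio, trio_path, samples=["proband", "mother", "father"])
    paths["trio_vcf"] = trio_path

    plasma = cohort.sites[cohort.sites["alt_count"] > 0].copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        plasma["allele_fraction"] = plasma["alt_count"] / plasma["depth"]
    plasma_path = outdir / "plasma.vcf"
    pio.write_vcf(plasma, plasma_path)
    paths["plasma_vcf"] = plasma_path

    bed_path = outdir / "bins.bed"
    pio.write_bed(cohort.bins[["chrom", "start", "end"]], bed_path)
    paths["bins_bed"] = bed_path

    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(cohort.manifest(), fh, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
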