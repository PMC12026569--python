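"""Maximum-likelihood fetal CNV calling on targeted bins.

A heterozygous fetal CNV changes plasma depth only through the fetal share
of the mixture: at fetal fraction ``f`` the expected normalized depth
ratio of an event bin is

    diploid   -> 1
    fetal del -> 1 - f/2        (one fetal copy lost)
    fetal dup -> 1 + f/2        (one fetal copy gained)

log2 ratios are modelled as Gaussian around log2 of the expected ratio
with a standard deviation taken from presumed-diploid reference control
bins. A second, optional evidence channel uses the fragment-size shift: a
fetal duplication adds short (fetal) fragments to the bin, a deletion
removes them, so the fraction of sub-threshold fragments moves with the
event direction. The two channels combine additively in log space.

Candidate events are scored by an exhaustive scan over contiguous bin runs
up to a configured span; maximal non-overlapping segments whose
log-likelihood ratio against the diploid model exceeds a threshold are
emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .fragments import SizeDistribution

FETAL_DEL = "fetal_del"
DIPLOID = "diploid"
FETAL_DUP = "fetal_dup"
COPY_STATES = (FETAL_DEL, DIPLOID, FETAL_DUP)

_STATE_COPIES = {FETAL_DEL: 1, DIPLOID: 2, FETAL_DUP: 3}


class DegenerateReferenceError(ValueError):
    pass


@dataclass
class ReferenceBinSet:
    """Presumed-diploid control bins used for normalization and noise.

    ``bins`` carries one row per bin with at least ``chrom, start, end,
    count``; ``ratio_sigma`` is the pooled standard deviation of control
    log2 ratios; ``short_fraction_mean``/``short_fraction_sd`` summarize
    the sub-threshold fragment fraction of diploid bins.
    """

    bins: pd.DataFrame
    ratio_sigma: float
    short_fraction_mean: float | None = None
    short_fraction_sd: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_sigma <= 0:
            raise DegenerateReferenceError("ratio_sigma must be > 0")


@dataclass(frozen=True)
class CNVCall:
    """A called fetal copy-number event."""

    chrom: str
    start: int
    end: int
    copy_state: str
    log_lr: float
    n_bins: int
    f_used: float

    def __post_init__(self) -> None:
        if self.copy_state not in (FETAL_DEL, FETAL_DUP):
            raise ValueError("calls are non-diploid states")
        if not np.isfinite(self.log_lr):
            raise ValueError("log_lr must be finite")


def expected_ratio(copy_state: str, f: float) -> float:
    """Expected normalized depth ratio of a bin under a fetal copy state."""
    if copy_state not in COPY_STATES:
        raise ValueError(f"unknown copy state {copy_state!r}")
    if not 0.0 <= f <= 1.0:
        raise ValueError("fetal fraction must be in [0, 1]")
    c = _STATE_COPIES[copy_state]
    return 1.0 + f * (c - 2) / 2.0


def expected_short_fraction(
    copy_state: str,
    f: float,
    fetal_dist: SizeDistribution,
    maternal_dist: SizeDistribution,
    short_threshold: float,
) -> float:
    """Expected sub-threshold fragment fraction of a bin under a copy state.

    Mixture of the maternal and fetal short-fragment probabilities with
    the fetal weight scaled by the event's fetal copy number.
    """
    s_f = fetal_dist.mass_below(short_threshold)
    s_m = maternal_dist.mass_below(short_threshold)
    w_f = f * _STATE_COPIES[copy_state] / 2.0
    w_m = 1.0 - f
    return (w_m * s_m + w_f * s_f) / (w_m + w_f)


def normalize_bins(raw_counts: pd.DataFrame, reference: ReferenceBinSet) -> pd.DataFrame:
    """Median-of-medians depth normalization against reference bins.

    ratio_i = (count_i / median sample count) / (ref_i / median ref count).
    Bins without a usable (positive-count) reference bin are masked
    (``ratio`` NaN) and excluded downstream. A missing reference row
    raises.
    """
    ref = reference.bins.set_index(["chrom", "start", "end"])["count"]
    idx = pd.MultiIndex.from_frame(raw_counts[["chrom", "start", "end"]])
    missing = ~idx.isin(ref.index)
    if missing.any():
        first = raw_counts[missing].iloc[0]
        raise KeyError(
            f"no reference bin for {first.chrom}:{first.start}-{first.end}"
        )
    ref_counts = ref.loc[idx].to_numpy(dtype=float)
    counts = raw_counts["count"].to_numpy(dtype=float)
    sample_median = np.median(counts)
    ref_median = np.median(ref_counts)
    if sample_median <= 0 or ref_median <= 0:
        raise DegenerateReferenceError("median counts must be positive")
    out = raw_counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (counts / sample_median) / (ref_counts / ref_median)
    ratio[ref_counts <= 0] = np.nan  # degenerate reference bins are masked
    out["ratio"] = ratio
    if "n_short" in out.columns and "short_fraction" not in out.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            out["short_fraction"] = out["n_short"] / out["count"]
    return out


def size_shift_statistic(short_fraction: float, reference: ReferenceBinSet) -> float:
    """Z-score of a bin's short-fragment fraction against the reference."""
    if reference.short_fraction_sd is None or reference.short_fraction_mean is None:
        raise DegenerateReferenceError("reference lacks short-fraction summary")
    if reference.short_fraction_sd <= 0:
        raise DegenerateReferenceError("reference short-fraction sd must be > 0")
    return (short_fraction - reference.short_fraction_mean) / reference.short_fraction_sd


def _per_bin_log_likelihood(
    bins: pd.DataFrame,
    copy_state: str,
    f: float,
    reference: ReferenceBinSet,
    use_size_channel: bool,
    size_params: tuple[SizeDistribution, SizeDistribution, float] | None,
    ratio_floor: float,
) -> np.ndarray:
    ratios = np.maximum(bins["ratio"].to_numpy(dtype=float), ratio_floor)
    mu = np.log2(expected_ratio(copy_state, f))
    ll = norm.logpdf(np.log2(ratios), loc=mu, scale=reference.ratio_sigma)
    if (
        use_size_channel
        and size_params is not None
        and "short_fraction" in bins.columns
        and reference.short_fraction_sd is not None
        and reference.short_fraction_sd > 0
    ):
        fetal_dist, maternal_dist, threshold = size_params
        sf_mu = expected_short_fraction(copy_state, f, fetal_dist, maternal_dist, threshold)
        sf = bins["short_fraction"].to_numpy(dtype=float)
        ll = ll + norm.logpdf(sf, loc=sf_mu, scale=reference.short_fraction_sd)
    return ll


def segment_log_likelihood(
    bins: pd.DataFrame,
    copy_state: str,
    f: float,
    reference: ReferenceBinSet,
    use_size_channel: bool = False,
    size_params: tuple[SizeDistribution, SizeDistribution, float] | None = None,
    ratio_floor: float = 1e-3,
) -> float:
    """Sum of per-bin Gaussian log-densities over a contiguous bin run."""
    if len(bins) == 0:
        raise ValueError("need at least one bin")
    return float(
        np.sum(
            _per_bin_log_likelihood(
                bins, copy_state, f, reference, use_size_channel, size_params, ratio_floor
            )
        )
    )


@dataclass
class CNVCallerConfig:
    min_bins: int = 3
    log_lr_threshold: float = 10.0
    max_span_bins: int = 25
    use_size_channel: bool = True
    ratio_floor: float = 1e-3
    short_threshold: float = 150.0
    gross_deviation_log2: float = 0.75  # flags likely maternal-origin shifts


def call_cnvs(
    bins: pd.DataFrame,
    f: float,
    reference: ReferenceBinSet,
    config: CNVCallerConfig | None = None,
    size_params: tuple[SizeDistribution, SizeDistribution, float] | None = None,
) -> list[CNVCall]:
    """Scan contiguous bin runs and emit maximal non-overlapping CNV calls.

    Bins must be coordinate-sorted within each chromosome; masked bins
    (NaN ratio) are dropped. With f = 0 the three states are
    indistinguishable: a warning is issued and no calls made. Candidate
    segments (min_bins..max_span_bins long) are ranked by their best
    non-diploid log-likelihood ratio and greedily accepted without
    overlap. Deterministic given its input.
    """
    config = config or CNVCallerConfig()
    if f == 0:
        warnings.warn("fetal fraction is 0: copy states are indistinguishable")
        return []
    usable = bins.dropna(subset=["ratio"]).reset_index(drop=True)
    calls: list[CNVCall] = []
    for chrom, group in usable.groupby("chrom", sort=False):
        group = group.sort_values("start").reset_index(drop=True)
        n = len(group)
        if n < config.min_bins:
            continue
        per_bin = {
            state: _per_bin_log_likelihood(
                group, state, f, reference,
                config.use_size_channel, size_params, config.ratio_floor,
            )
            for state in COPY_STATES
        }
        cum = {state: np.concatenate([[0.0], np.cumsum(ll)]) for state, ll in per_bin.items()}
        candidates = []
        for i in range(n):
            for j in range(i + config.min_bins, min(i + config.max_span_bins, n) + 1):
                base = cum[DIPLOID][j] - cum[DIPLOID][i]
                for state in (FETAL_DEL, FETAL_DUP):
                    lr = (cum[state][j] - cum[state][i]) - base
                    if lr > config.log_lr_threshold:
                        candidates.append((lr, i, j, state))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        taken = np.zeros(n, dtype=bool)
        for lr, i, j, state in candidates:
            if taken[i:j].any():
                continue
            taken[i:j] = True
            calls.append(
                CNVCall(
                    chrom=str(chrom),
                    start=int(group.loc[i, "start"]),
                    end=int(group.loc[j - 1, "end"]),
                    copy_state=state,
                    log_lr=float(lr),
                    n_bins=j - i,
                    f_used=float(f),
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def flag_gross_deviations(
    bins: pd.DataFrame, config: CNVCallerConfig | None = None
) -> pd.Series:
    """Bins whose |log2 ratio| exceeds the gross-deviation guard.

    Shifts of this size (about +/-0.5 in ratio) indicate maternal-origin
    events or technical failures, outside the fetal three-state space.
    """
    config = config or CNVCallerConfig()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(np.maximum(bins["ratio"].to_numpy(dtype=float), 1e-12))
    return pd.Series(np.abs(log2r) > config.gross_deviation_log2, index=bins.index)


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom, "start": c.start, "end": c.end,
                "copy_state": c.copy_state, "log_lr": c.log_lr,
                "n_bins": c.n_bins, "f_used": c.f_used,
            }
            for c in calls
        ],
        columns=["chrom", "start", "end", "copy_state", "log_lr", "n_bins", "f_used"],
    )


def write_calls_vcf(calls: list[CNVCall], path) -> None:
    """Emit calls as symbolic <DEL>/<DUP> VCF records (END in INFO)."""
    from .io import _VCF_HEADER  # shared minimal header

    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(c.chrom for c in calls):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            svtype = "DEL" if c.copy_state == FETAL_DEL else "DUP"
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t<{svtype}>\t.\tPASS\t"
                f"END={c.end};SVTYPE={svtype}\n"
            )


class CNVCaller(BaseEstimator):
    """Fetal CNV caller over targeted bins (fit on reference, predict calls).

    Parameters mirror :class:`CNVCallerConfig`; ``fetal_fraction`` is the
    sample's fetal fraction used to scale the expected depth shifts.
    ``fit`` takes a :class:`ReferenceBinSet` (optionally with fetal and
    maternal :class:`SizeDistribution` objects for the size channel);
    ``predict`` takes raw per-bin counts, normalizes them against the
    reference and returns the call list.
    """

    def __init__(
        self,
        fetal_fraction: float = 0.1,
        min_bins: int = 3,
        log_lr_threshold: float = 10.0,
        max_span_bins: int = 25,
        use_size_channel: bool = True,
        short_threshold: float = 150.0,
    ):
        self.fetal_fraction = fetal_fraction
        self.min_bins = min_bins
        self.log_lr_threshold = log_lr_threshold
        self.max_span_bins = max_span_bins
        self.use_size_channel = use_size_channel
        self.short_threshold = short_threshold

    def _config(self) -> CNVCallerConfig:
        return CNVCallerConfig(
            min_bins=self.min_bins,
            log_lr_threshold=self.log_lr_threshold,
            max_span_bins=self.max_span_bins,
            use_size_channel=self.use_size_channel,
            short_threshold=self.short_threshold,
        )

    def fit(
        self,
        reference: ReferenceBinSet,
        y=None,
        fetal_dist: SizeDistribution | None = None,
        maternal_dist: SizeDistribution | None = None,
    ) -> "CNVCaller":
        self.reference_ = reference
        if fetal_dist is not None and maternal_dist is not None:
            self.size_params_ = (fetal_dist, maternal_dist, self.short_threshold)
        else:
            self.size_params_ = None
        return self

    def predict(self, raw_counts: pd.DataFrame) -> list[CNVCall]:
        if not hasattr(self, "reference_"):
            raise RuntimeError("call fit() first")
        bins = (
            raw_counts
            if "ratio" in raw_counts.columns
            else normalize_bins(raw_counts, self.reference_)
        )
        return call_cnvs(
            bins,
            self.fetal_fraction,
            self.reference_,
            config=self._config(),
            size_params=self.size_params_,
        )
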