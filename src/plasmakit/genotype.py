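"""Fetal genotype inference from maternal-plasma allele counts.

Plasma cfDNA is a mixture of maternal and fetal fragments. At a biallelic
SNP the expected alt-allele fraction of plasma reads is a linear mixture of
the two genotypes,

    p = (1 - f) * m / 2 + f * k / 2,

where ``f`` is the fetal fraction, ``m`` the maternal and ``k`` the fetal
alt-allele copy number (each in {0, 1, 2}). A symmetric per-read miscall
probability ``eps`` maps this to the observed alt probability

    p' = p * (1 - eps) + (1 - p) * eps.

Observed alt counts are modelled as Binomial(depth, p'), which yields a
log-likelihood per candidate fetal genotype and, with a prior over k, a
posterior. The fetal fraction itself is estimated from sites where the
mother is homozygous reference and the father homozygous alternate, so the
fetus is an obligate heterozygote and the alt-read fraction has expectation
f/2 (after inverting the error mixture).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom
from sklearn.base import BaseEstimator

GENOTYPE_STATES = (0, 1, 2)

#: Site categories produced by :func:`flag_informative_sites`.
FF_INFORMATIVE = "ff_informative"
FETAL_TAGGING = "fetal_tagging"
UNINFORMATIVE = "uninformative"


class InsufficientDataError(ValueError):
    """Raised when an estimator has no usable sites."""


@dataclass(frozen=True)
class SNPSite:
    """Per-site plasma allele counts plus (optionally) parental genotypes."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_count: int
    depth: int
    maternal_copies: int | None = None
    paternal_copies: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("need 0 <= alt_count <= depth")
        for copies in (self.maternal_copies, self.paternal_copies):
            if copies is not None and copies not in GENOTYPE_STATES:
                raise ValueError("genotype copies must be in {0, 1, 2} or None")


@dataclass(frozen=True)
class FetalFraction:
    """A fetal-fraction estimate with its provenance."""

    f: float
    n_informative_sites: int
    stderr: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("fetal fraction must be in [0, 1]")


@dataclass(frozen=True)
class GenotypePosterior:
    """Posterior over fetal alt-allele copies at one site."""

    site: SNPSite | None
    probs: dict[int, float]
    ml_call: int
    log_likelihoods: dict[int, float] = field(default_factory=dict)


def _validate_mixture_args(m, k, f) -> None:
    m = np.asarray(m)
    k = np.asarray(k)
    f = np.asarray(f, dtype=float)
    if not (np.isin(m, GENOTYPE_STATES).all() and np.isin(k, GENOTYPE_STATES).all()):
        raise ValueError("m and k must be in {0, 1, 2}")
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fetal fraction must be in [0, 1]")


def expected_alt_fraction(m, k, f, error_rate: float = 0.0):
    """Expected plasma alt-read probability for maternal/fetal genotypes.

    Parameters are the maternal alt copies ``m``, fetal alt copies ``k``
    (each in {0, 1, 2}, scalars or arrays), the fetal fraction ``f`` and a
    symmetric per-read miscall probability. Strictly increasing in ``k``
    for f > 0 and error_rate < 0.5.
    """
    _validate_mixture_args(m, k, f)
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    m = np.asarray(m, dtype=float)
    k = np.asarray(k, dtype=float)
    f = np.asarray(f, dtype=float)
    p = (1.0 - f) * m / 2.0 + f * k / 2.0
    p_err = p * (1.0 - error_rate) + (1.0 - p) * error_rate
    if p_err.ndim == 0:
        return float(p_err)
    return p_err


def genotype_log_likelihood(
    alt_count, depth, maternal_copies, k, f, error_rate: float = 0.0
):
    """log Binomial(alt_count | depth, p'(m, k, f, eps)).

    Vectorized over all arguments; ``depth`` must be >= 1 and the maternal
    genotype known.
    """
    depth_arr = np.asarray(depth)
    if np.any(depth_arr < 1):
        raise ValueError("depth must be >= 1 for a likelihood")
    m_arr = np.asarray(maternal_copies, dtype=object)
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in np.atleast_1d(m_arr)):
        raise ValueError("maternal genotype is required")
    p = expected_alt_fraction(maternal_copies, k, f, error_rate)
    ll = binom.logpmf(alt_count, depth, p)
    if np.ndim(ll) == 0:
        return float(ll)
    return ll


def site_log_likelihoods(site: SNPSite, f: float, error_rate: float = 0.0) -> dict[int, float]:
    """Log-likelihood of the site's counts under each fetal genotype."""
    return {
        k: genotype_log_likelihood(
            site.alt_count, site.depth, site.maternal_copies, k, f, error_rate
        )
        for k in GENOTYPE_STATES
    }


def mendelian_prior(maternal_copies: int, paternal_copies: int) -> dict[int, float]:
    """Prior over fetal alt copies from parental genotypes (no de novo).

    Each parent transmits an alt allele with probability copies/2; the two
    transmissions are independent Bernoulli draws.
    """
    pm = maternal_copies / 2.0
    pp = paternal_copies / 2.0
    return {
        0: (1 - pm) * (1 - pp),
        1: pm * (1 - pp) + (1 - pm) * pp,
        2: pm * pp,
    }


def call_fetal_genotype(
    site: SNPSite,
    f: float,
    prior: dict[int, float] | None = None,
    error_rate: float = 0.0,
) -> GenotypePosterior:
    """Posterior over fetal genotypes at one site.

    Computed in log space (max-subtraction normalization), so deep sites do
    not underflow. Ties in the maximum-likelihood call break to the
    smallest k. With f = 0 the likelihood is identical for every k and the
    posterior returns the prior.
    """
    if prior is None:
        prior = {k: 1.0 / 3.0 for k in GENOTYPE_STATES}
    total = sum(prior.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("prior must sum to 1")
    logliks = site_log_likelihoods(site, f, error_rate)
    logpost = np.array(
        [np.log(prior[k]) if prior[k] > 0 else -np.inf for k in GENOTYPE_STATES]
    ) + np.array([logliks[k] for k in GENOTYPE_STATES])
    norm = logsumexp(logpost)
    if not np.isfinite(norm):
        raise FloatingPointError("posterior has no support (all-zero prior x likelihood)")
    probs = np.exp(logpost - norm)
    ml_call = int(np.argmax(np.round(probs, 12)))  # argmax ties -> smallest k
    return GenotypePosterior(
        site=site,
        probs={k: float(probs[k]) for k in GENOTYPE_STATES},
        ml_call=ml_call,
        log_likelihoods=logliks,
    )


def flag_informative_sites(sites: pd.DataFrame) -> pd.Series:
    """Partition sites into FF-informative / fetal-allele-tagging / uninformative.

    * FF-informative: mother homozygous reference, father carries the alt
      (used for fetal-fraction estimation).
    * Fetal-allele-tagging: an allele is absent from the maternal genotype
      (mother hom-ref or hom-alt) so reads carrying it can only be fetal,
      up to error; sites already counted FF-informative are not repeated.
    * Uninformative: maternal heterozygotes and sites with unknown
      genotypes.
    """
    m = pd.to_numeric(sites["maternal_copies"], errors="coerce")
    p = pd.to_numeric(sites["paternal_copies"], errors="coerce")
    ff = (m == 0) & (p >= 1)
    tagging = m.isin([0, 2]) & ~ff
    out = pd.Series(UNINFORMATIVE, index=sites.index, dtype=object)
    out[tagging] = FETAL_TAGGING
    out[ff] = FF_INFORMATIVE
    return out


def estimate_fetal_fraction(
    sites: pd.DataFrame,
    error_rate: float = 0.0,
    include_het_fathers: bool = False,
) -> FetalFraction:
    """Moment estimate of the fetal fraction from plasma allele counts.

    Uses sites where the mother is homozygous reference and the father
    homozygous alternate: the fetus is then an obligate heterozygote, so
    the alt-read fraction has expectation f/2 (before read error) and
    f_hat = 2 x mean alt fraction. The symmetric error mixture
    E[r] = p (1 - 2 eps) + eps is inverted before doubling. With
    ``include_het_fathers`` the working set widens to any alt-carrying
    father and the Mendelian expectation E[k | father] = copies/2 rescales
    each site's contribution (f_hat = 4 * sum r_i / sum copies_i).

    The standard error comes from the delta method on the mean alt
    fraction. Raises :class:`InsufficientDataError` with no usable sites.
    """
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    m = pd.to_numeric(sites["maternal_copies"], errors="coerce")
    p = pd.to_numeric(sites["paternal_copies"], errors="coerce")
    depth = sites["depth"].to_numpy(dtype=float)
    wanted = (m == 0) & ((p >= 1) if include_het_fathers else (p == 2)) & (depth > 0)
    sub = sites[wanted]
    if len(sub) == 0:
        raise InsufficientDataError("no FF-informative sites with coverage")
    ratios = sub["alt_count"].to_numpy(dtype=float) / sub["depth"].to_numpy(dtype=float)
    # invert the symmetric error mixture per site, then take moments
    p_hat = (ratios - error_rate) / (1.0 - 2.0 * error_rate)
    if include_het_fathers:
        copies = p[wanted].to_numpy(dtype=float)
        scale = 4.0 / copies.mean()
    else:
        scale = 2.0
    f_hat = float(np.clip(scale * p_hat.mean(), 0.0, 1.0))
    n = len(sub)
    stderr = float(scale * p_hat.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return FetalFraction(f=f_hat, n_informative_sites=n, stderr=stderr)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class FetalFractionEstimator(BaseEstimator):
    """Estimate the fetal fraction from a table of SNP sites.

    Parameters
    ----------
    error_rate : float
        Symmetric per-read miscall probability inverted before the moment
        estimate.
    include_het_fathers : bool
        Widen the working set from hom-alt fathers to any alt-carrying
        father (Mendelian rescaling applied).

    Attributes (after ``fit``)
    --------------------------
    fetal_fraction_ : float
    stderr_ : float or None
    n_informative_sites_ : int
    """

    def __init__(self, error_rate: float = 0.01, include_het_fathers: bool = False):
        self.error_rate = error_rate
        self.include_het_fathers = include_het_fathers

    def fit(self, sites: pd.DataFrame, y=None) -> "FetalFractionEstimator":
        est = estimate_fetal_fraction(
            sites, error_rate=self.error_rate, include_het_fathers=self.include_het_fathers
        )
        self.fetal_fraction_ = est.f
        self.stderr_ = est.stderr
        self.n_informative_sites_ = est.n_informative_sites
        return self

    def result_(self) -> FetalFraction:
        return FetalFraction(
            f=self.fetal_fraction_,
            n_informative_sites=self.n_informative_sites_,
            stderr=self.stderr_,
        )


class FetalGenotypeCaller(BaseEstimator):
    """Binomial-mixture fetal genotype caller.

    Parameters
    ----------
    fetal_fraction : float or None
        Externally supplied fetal fraction (e.g. from a screening assay).
        When None, ``fit`` estimates it from the sites themselves.
    error_rate : float
        Symmetric per-read miscall probability.
    prior : {"uniform", "mendelian"}
        Prior over fetal alt copies; "mendelian" uses parental genotypes
        where both are known and falls back to uniform otherwise.

    After ``fit``, ``fetal_fraction_`` holds the fraction in use;
    ``predict`` returns maximum-posterior fetal genotypes and
    ``predict_proba`` the (n_sites, 3) posterior matrix.
    """

    def __init__(
        self,
        fetal_fraction: float | None = None,
        error_rate: float = 0.01,
        prior: str = "uniform",
    ):
        self.fetal_fraction = fetal_fraction
        self.error_rate = error_rate
        self.prior = prior

    def fit(self, sites: pd.DataFrame, y=None) -> "FetalGenotypeCaller":
        if self.prior not in ("uniform", "mendelian"):
            raise ValueError("prior must be 'uniform' or 'mendelian'")
        if self.fetal_fraction is None:
            self.fetal_fraction_ = estimate_fetal_fraction(
                sites, error_rate=self.error_rate
            ).f
        else:
            if not 0.0 <= self.fetal_fraction <= 1.0:
                raise ValueError("fetal fraction must be in [0, 1]")
            self.fetal_fraction_ = float(self.fetal_fraction)
        return self

    def _prior_for(self, m, p) -> dict[int, float]:
        if self.prior == "mendelian" and m is not None and p is not None:
            return mendelian_prior(int(m), int(p))
        return {k: 1.0 / 3.0 for k in GENOTYPE_STATES}

    def call_table(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Per-site posteriors and calls as a table."""
        if not hasattr(self, "fetal_fraction_"):
            raise RuntimeError("call fit() first")
        records = []
        for row in sites.itertuples():
            m = row.maternal_copies
            if m is None or pd.isna(m):
                records.append((np.nan, np.nan, np.nan, -1))
                continue
            p = row.paternal_copies
            if p is not None and pd.isna(p):
                p = None
            site = SNPSite(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(getattr(row, "ref", "N")),
                alt_allele=str(getattr(row, "alt", "A")),
                alt_count=int(row.alt_count),
                depth=int(row.depth),
                maternal_copies=int(m),
                paternal_copies=None if p is None else int(p),
            )
            post = call_fetal_genotype(
                site,
                self.fetal_fraction_,
                prior=self._prior_for(m, p),
                error_rate=self.error_rate,
            )
            records.append((post.probs[0], post.probs[1], post.probs[2], post.ml_call))
        out = sites.copy()
        out[["p_hom_ref", "p_het", "p_hom_alt"]] = np.array(
            [r[:3] for r in records], dtype=float
        )
        out["fetal_genotype"] = [r[3] for r in records]
        return out

    def predict_proba(self, sites: pd.DataFrame) -> np.ndarray:
        table = self.call_table(sites)
        return table[["p_hom_ref", "p_het", "p_hom_alt"]].to_numpy()

    def predict(self, sites: pd.DataFrame) -> np.ndarray:
        return self.call_table(sites)["fetal_genotype"].to_numpy()
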