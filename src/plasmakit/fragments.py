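"""Fragment tagging and cfDNA fragment-size distributions.

Fetal (placental) cfDNA fragments are characteristically shorter than
maternal ones. Fragments that carry an allele absent from the maternal
genotype can only have come from the fetus (up to sequencing error); such
"tagged" fragments give a pure sample of the fetal size distribution,
which the CNV caller uses as a second evidence channel.

Size distributions are fixed-edge normalized histograms (default 50-400 bp
in 5 bp bins) so they are directly comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FETAL = "fetal"
MATERNAL = "maternal"
UNTAGGED = "untagged"

DEFAULT_MIN_EDGE = 50
DEFAULT_MAX_EDGE = 400
DEFAULT_BIN_WIDTH = 5


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced cfDNA fragment (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    allele_tag: str = UNTAGGED

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeDistribution:
    """A normalized fragment-length histogram with fixed bin edges."""

    bin_edges: np.ndarray
    densities: np.ndarray
    n_fragments: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(dens) != len(edges) - 1:
            raise ValueError("need one density per bin")
        if not np.isclose(dens.sum(), 1.0, atol=1e-9):
            raise ValueError("densities must sum to 1")

    def density_at(self, length: float) -> float:
        """Per-bin probability mass at a length; 0 outside the edges."""
        edges = np.asarray(self.bin_edges, dtype=float)
        if length < edges[0] or length >= edges[-1]:
            return 0.0
        idx = int(np.searchsorted(edges, length, side="right")) - 1
        return float(np.asarray(self.densities)[idx])

    def mean(self) -> float:
        """Mean length under the histogram (bin midpoints)."""
        edges = np.asarray(self.bin_edges, dtype=float)
        mids = (edges[:-1] + edges[1:]) / 2.0
        return float(np.sum(mids * np.asarray(self.densities)))

    def mass_below(self, threshold: float) -> float:
        """Probability mass strictly below a length threshold.

        Bins straddling the threshold contribute pro rata.
        """
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        lo = np.minimum(np.maximum(threshold - edges[:-1], 0.0), np.diff(edges))
        return float(np.sum(dens * lo / np.diff(edges)))

    def to_frame(self) -> pd.DataFrame:
        edges = np.asarray(self.bin_edges)
        return pd.DataFrame(
            {
                "bin_start": edges[:-1].astype(int),
                "bin_end": edges[1:].astype(int),
                "density": np.asarray(self.densities),
            }
        )


def fit_size_distribution(
    lengths,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_edge: int = DEFAULT_MIN_EDGE,
    max_edge: int = DEFAULT_MAX_EDGE,
) -> SizeDistribution:
    """Normalized histogram of fragment lengths over fixed global edges.

    Lengths outside [min_edge, max_edge) are clipped into the terminal
    bins so every fragment contributes mass.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise InsufficientDataError("no fragment lengths")
    if bin_width < 1 or max_edge <= min_edge:
        raise ValueError("need bin_width >= 1 and max_edge > min_edge")
    edges = np.arange(min_edge, max_edge + bin_width, bin_width, dtype=float)
    clipped = np.clip(lengths, min_edge, max_edge - 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    return SizeDistribution(
        bin_edges=edges,
        densities=counts / counts.sum(),
        n_fragments=int(lengths.size),
    )


def tag_fragments(fragments: pd.DataFrame, tagging_sites: pd.DataFrame) -> pd.DataFrame:
    """Assign fetal/maternal origin tags to fragments at tagging sites.

    ``fragments`` needs columns ``chrom, start, end, site_pos, allele``
    (``site_pos``/``allele`` empty for fragments not covering a site);
    ``tagging_sites`` needs ``chrom, pos, ref, alt, maternal_copies``. At a
    site where the mother is hom-ref, an alt-carrying fragment is fetal and
    a ref-carrying one maternal(-compatible); where the mother is hom-alt
    the roles swap. Fragments at maternal heterozygous sites, or covering
    no site, stay untagged. Raises on a fragment whose interval does not
    cover its claimed site.
    """
    out = fragments.copy()
    out["allele_tag"] = UNTAGGED
    if len(tagging_sites) == 0:
        return out
    site_lookup = {
        (str(r.chrom), int(r.pos)): (str(r.ref), str(r.alt), int(r.maternal_copies))
        for r in tagging_sites.itertuples()
        if not pd.isna(r.maternal_copies)
    }
    tags = []
    for row in out.itertuples():
        site_pos = getattr(row, "site_pos", None)
        if site_pos is None or pd.isna(site_pos):
            tags.append(UNTAGGED)
            continue
        key = (str(row.chrom), int(site_pos))
        info = site_lookup.get(key)
        if info is None:
            tags.append(UNTAGGED)
            continue
        ref, alt, m = info
        # 1-based site position must fall inside the 0-based half-open fragment
        if not (row.start < int(site_pos) <= row.end):
            raise ValueError(
                f"fragment {row.chrom}:{row.start}-{row.end} does not cover "
                f"claimed site at {site_pos}"
            )
        allele = str(row.allele)
        if m == 0:
            tags.append(FETAL if allele == alt else MATERNAL if allele == ref else UNTAGGED)
        elif m == 2:
            tags.append(FETAL if allele == ref else MATERNAL if allele == alt else UNTAGGED)
        else:
            tags.append(UNTAGGED)
    out["allele_tag"] = tags
    return out


def fetal_probability_by_size(
    length: float,
    fetal_dist: SizeDistribution,
    maternal_dist: SizeDistribution,
    f: float,
) -> float:
    """Posterior probability that a fragment of a given length is fetal.

    Bayes weighting of the two size densities by the fetal fraction:
    f * d_fetal / (f * d_fetal + (1 - f) * d_maternal). Where both
    densities vanish the prior ``f`` is returned.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("fetal fraction must be in [0, 1]")
    df = fetal_dist.density_at(length)
    dm = maternal_dist.density_at(length)
    denom = f * df + (1.0 - f) * dm
    if denom == 0.0:
        return f
    return f * df / denom
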