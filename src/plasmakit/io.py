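"""Shared readers/writers and coordinate plumbing.

Conventions used throughout the package:

* VCF positions are 1-based (as in the format itself).
* BED intervals are 0-based half-open, so ``chr1  100  200`` covers
  1-based positions 101..200.
* Tabular interchange is TSV with a header row.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from intervaltree import IntervalTree


class FormatError(ValueError):
    """Raised for malformed input files (bad BED intervals, VCF records...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def contains_position(self, pos: int) -> bool:
        """Whether the interval covers 1-based position ``pos``."""
        return self.start < pos <= self.end


class GenomicIntervals:
    """An indexed set of genomic intervals with point/overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for iv in intervals:
            self.add(iv)

    def add(self, interval: GenomicInterval) -> None:
        self._trees.setdefault(interval.chrom, IntervalTree()).addi(
            interval.start, interval.end
        )
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def covers_position(self, chrom: str, pos: int) -> bool:
        """Whether any interval covers the 1-based position ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(pos - 1, pos))

    def overlaps_interval(self, chrom: str, start: int, end: int) -> bool:
        """Whether any interval overlaps the 0-based half-open [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(start, end))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, iv.begin, iv.end)
            for chrom, tree in sorted(self._trees.items())
            for iv in sorted(tree)
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenomicIntervals":
        return cls(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in frame.itertuples()
        )


def read_bed(path: str | Path) -> GenomicIntervals:
    """Read a 3+ column BED file into an indexed interval set.

    Raises :class:`FormatError` on intervals with ``end <= start``.
    """
    intervals = GenomicIntervals()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            intervals.add(iv)
    return intervals


def write_bed(intervals: GenomicIntervals | pd.DataFrame, path: str | Path) -> None:
    frame = intervals if isinstance(intervals, pd.DataFrame) else intervals.to_frame()
    frame.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TO_COPIES = {
    (0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2,
}


def _alt_copies(gt_alleles: list[int], alt_index: int) -> int | None:
    """Alt-allele copy count for one split alt; None when any allele is missing."""
    if any(a < 0 for a in gt_alleles):
        return None
    return sum(1 for a in gt_alleles if a == alt_index)


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF into a flat table, splitting multiallelic records.

    Returns one row per (record, alt) with columns ``chrom, pos, ref, alt,
    depth, allele_fraction`` plus one ``gt_<sample>`` column per sample
    holding alt-allele copies in {0, 1, 2} (NaN when the genotype is
    missing). ``depth`` comes from INFO/DP or the first sample's FORMAT/DP;
    ``allele_fraction`` from INFO/AF where present.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        genotypes = rec.genotypes if samples else []
        info_af = rec.INFO.get("AF")
        info_dp = rec.INFO.get("DP")
        fmt_dp = None
        if samples:
            try:
                fmt_dp = rec.format("DP")
            except KeyError:
                fmt_dp = None
        for alt_index, alt in enumerate(rec.ALT, start=1):
            if info_af is None:
                af = None
            elif isinstance(info_af, (tuple, list)):
                af = float(info_af[alt_index - 1])
            else:
                af = float(info_af)
            depth = info_dp
            if depth is None and fmt_dp is not None:
                depth = int(fmt_dp[0][0])
            row = {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "depth": None if depth is None else int(depth),
                "allele_fraction": af,
            }
            for si, sample in enumerate(samples):
                alleles = [a for a in genotypes[si][:-1]]
                row[f"gt_{sample.lower()}"] = _alt_copies(alleles, alt_index)
            rows.append(row)
    vcf.close()
    return pd.DataFrame(rows)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=plasmakit
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
"""

_COPIES_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(frame: pd.DataFrame, path: str | Path, samples: list[str] | None = None) -> None:
    """Write a flat variant table as a minimal VCF 4.2 file.

    ``samples`` names the ``gt_<sample>`` columns to emit as GT columns.
    ``depth`` and ``allele_fraction`` columns, when present, go to INFO.
    """
    samples = samples or []
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(frame["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"])
        if samples:
            cols += "\tFORMAT\t" + "\t".join(s.upper() for s in samples)
        fh.write(cols + "\n")
        for row in frame.itertuples():
            info = []
            depth = getattr(row, "depth", None)
            af = getattr(row, "allele_fraction", None)
            if depth is not None and not pd.isna(depth):
                info.append(f"DP={int(depth)}")
            if af is not None and not pd.isna(af):
                info.append(f"AF={af:.6g}")
            line = (
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                + (";".join(info) if info else ".")
            )
            if samples:
                gts = []
                for s in samples:
                    copies = getattr(row, f"gt_{s.lower()}", None)
                    if copies is not None and not pd.isna(copies):
                        copies = int(copies)
                    else:
                        copies = None
                    gts.append(_COPIES_TO_GT[copies])
                line += "\tGT\t" + "\t".join(gts)
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Umbrella configuration serialized to a YAML key-value file."""

    seed: int = 0
    log_level: str = "INFO"
    error_rate: float = 0.01
    fetal_fraction: float | None = None
    af_low: float = 0.20
    af_high: float = 0.80
    min_depth: int = 100
    min_bins: int = 3
    log_lr_threshold: float = 10.0
    coverage_threshold: float = 5.0
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = dict(data.get("extra") or {})
        return cls(**kwargs)
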