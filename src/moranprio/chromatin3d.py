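"""Chromatin-interaction (Hi-C) overlap of prioritized SNPs.

This module consumes interaction *calls* — fixed-width cis bin pairs with a
significance p-value, e.g. HOMER output binned at 40 kb — and never touches
raw Hi-C maps. It filters calls (Bonferroni or matched top fraction), maps
prioritized SNPs into bins ("bait" = the bin containing the SNP, "target" =
its interacting partner), and annotates targets with overlapping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicBin",
    "InteractionPair",
    "OverlapAnnotation",
    "read_interactions",
    "bonferroni_filter",
    "match_top_fraction",
    "overlap_snps",
    "annotate_targets",
    "read_gene_bed",
]

DEFAULT_BIN_SIZE = 40_000


@dataclass(frozen=True)
class GenomicBin:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"bin {self.chrom}:{self.start}-{self.end} has start >= end")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class InteractionPair:
    bin_a: GenomicBin
    bin_b: GenomicBin
    p: float
    adjusted_p: float | None = None


@dataclass(frozen=True)
class OverlapAnnotation:
    snp_id: str
    bait: GenomicBin
    target: GenomicBin
    interaction: InteractionPair
    target_genes: tuple[str, ...] = ()


def read_interactions(
    bedpe_source, bin_size: int = DEFAULT_BIN_SIZE
) -> tuple[list[InteractionPair], int]:
    """Parse BEDPE-like interaction calls (chrom1 start1 end1 chrom2 start2 end2 p).

    Bins must have width ``bin_size``; trans (inter-chromosomal) rows are
    skipped and counted. Returns (cis pairs, number of trans rows skipped).
    Malformed rows raise with the offending 1-based data row number.
    """
    df = pd.read_csv(bedpe_source, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 7:
        raise ValueError(f"expected >= 7 columns, found {df.shape[1]}")
    pairs: list[InteractionPair] = []
    n_trans = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            c1, s1, e1, c2, s2, e2, p = (
                str(row[0]),
                int(row[1]),
                int(row[2]),
                str(row[3]),
                int(row[4]),
                int(row[5]),
                float(row[6]),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed interaction row {i}: {exc}") from None
        for s, e in ((s1, e1), (s2, e2)):
            if e - s != bin_size:
                raise ValueError(
                    f"row {i}: bin width {e - s} does not match bin size {bin_size}"
                )
        if c1 != c2:
            n_trans += 1
            continue
        pairs.append(InteractionPair(GenomicBin(c1, s1, e1), GenomicBin(c2, s2, e2), p))
    if n_trans:
        logger.info("skipped %d trans interaction rows", n_trans)
    return pairs, n_trans


def bonferroni_filter(
    pairs: Sequence[InteractionPair], m: int | None = None, alpha: float = 1e-5
) -> list[InteractionPair]:
    """Retain pairs whose Bonferroni-adjusted p (min(1, p*m)) is below alpha.

    ``m`` is the number of tests and defaults to the number of pairs supplied.
    """
    if m is None:
        m = len(pairs)
    if m < len(pairs):
        raise ValueError("m must be at least the number of pairs")
    out = []
    for pr in pairs:
        adj = min(1.0, pr.p * m)
        if adj < alpha:
            out.append(replace(pr, adjusted_p=adj))
    return out


def match_top_fraction(
    reference_total: int, reference_kept: int, other_pairs: Sequence[InteractionPair]
) -> list[InteractionPair]:
    """Keep the same top fraction of a second interaction list as a reference.

    The fraction is ``reference_kept / reference_total``; the other list is
    sorted by p ascending (ties by coordinates) and the first
    floor(fraction * n) pairs are kept — possibly none, with a warning.
    """
    if not (0 < reference_kept <= reference_total):
        raise ValueError("need 0 < reference_kept <= reference_total")
    fraction = reference_kept / reference_total
    order = sorted(
        other_pairs,
        key=lambda pr: (pr.p, pr.bin_a.chrom, pr.bin_a.start, pr.bin_b.start),
    )
    k = int(fraction * len(order))
    if k == 0 and order:
        logger.warning("matched fraction %.4f keeps 0 of %d pairs", fraction, len(order))
    return order[:k]


def overlap_snps(snps: Iterable, pairs: Sequence[InteractionPair]) -> list[OverlapAnnotation]:
    """Map SNPs into interaction bins: one annotation per (SNP, pair) overlap.

    ``snps`` yields objects with ``id``, ``chrom`` and ``pos`` attributes
    (variants or summary records). A SNP overlaps a pair when its position
    falls inside either bin under the half-open [start, end) convention; the
    containing bin is the bait and the partner bin the target. A SNP landing
    in both bins of a pair is annotated once with bin_a as bait.
    """
    out: list[OverlapAnnotation] = []
    for snp in snps:
        for pr in pairs:
            if pr.bin_a.chrom != snp.chrom:
                continue
            if pr.bin_a.contains(snp.pos):
                out.append(OverlapAnnotation(snp.id, pr.bin_a, pr.bin_b, pr))
            elif pr.bin_b.contains(snp.pos):
                out.append(OverlapAnnotation(snp.id, pr.bin_b, pr.bin_a, pr))
    return out


def read_gene_bed(bed_source) -> pd.DataFrame:
    """Read a BED file of gene intervals (chrom, start, end, name)."""
    df = pd.read_csv(bed_source, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"expected >= 4 BED columns, found {df.shape[1]}")
    try:
        out = pd.DataFrame(
            {
                "chrom": df[0].astype(str),
                "start": df[1].astype(int),
                "end": df[2].astype(int),
                "name": df[3].astype(str),
            }
        )
    except ValueError as exc:
        bad = df[pd.to_numeric(df[1], errors="coerce").isna() | pd.to_numeric(df[2], errors="coerce").isna()]
        row = int(bad.index[0]) + 1 if len(bad) else "?"
        raise ValueError(f"malformed BED row {row}: {exc}") from None
    if (out["start"] >= out["end"]).any():
        row = int(out.index[(out["start"] >= out["end"])][0]) + 1
        raise ValueError(f"malformed BED row {row}: start >= end")
    return out


def annotate_targets(
    annotations: Sequence[OverlapAnnotation], gene_bed
) -> list[OverlapAnnotation]:
    """Attach to each annotation the genes overlapping its target bin.

    ``gene_bed`` is a path/buffer of a 4+-column BED or an already-parsed
    frame from :func:`read_gene_bed`. Any >= 1 bp overlap (half-open
    intervals) counts; genes are listed sorted by start coordinate.
    """
    genes = gene_bed if isinstance(gene_bed, pd.DataFrame) else read_gene_bed(gene_bed)
    out = []
    for ann in annotations:
        hit = genes[
            (genes["chrom"] == ann.target.chrom)
            & (genes["start"] < ann.target.end)
            & (genes["end"] > ann.target.start)
        ].sort_values(["start", "name"])
        out.append(replace(ann, target_genes=tuple(hit["name"])))
    return out
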