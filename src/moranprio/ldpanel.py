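"""Reference LD panel: genotype loading, allele frequencies, HWE, and windowed r².

The panel plays the role of an external haplotype reference (e.g. 1000 Genomes
CEU): it supplies the linkage-disequilibrium weights used by the Local Moran's
Index and the MAF-matched neighbor windows. Genotypes are stored as additive
dosages (0/1/2 copies of the alternate allele) with missing calls kept as NaN,
never imputed to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "LDPanel",
    "LDUndefinedError",
    "load_genotypes",
    "allele_freq",
    "maf",
    "hwe_test",
    "r2",
    "neighbors_window",
]


class LDUndefinedError(ValueError):
    """Raised when an LD value has no defined estimate.

    This happens when one of the dosage vectors is constant over the
    pairwise-complete individuals, or when fewer than two individuals have
    non-missing genotypes at both sites. Callers that use r² as a weight
    treat this as "weight absent", not as zero LD.
    """


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with 1-based genomic coordinates."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref and alt alleles are identical")


class LDPanel:
    """Reference genotype matrix over N individuals.

    Parameters
    ----------
    variants
        Biallelic SNPs; will be stored sorted by (chrom, pos). Duplicate
        (chrom, pos, ref, alt) entries are rejected.
    dosages
        Array of shape ``(len(variants), N)`` with values in {0, 1, 2} and
        NaN for missing genotypes, row-aligned with ``variants``.
    n_skipped
        Count of VCF records skipped at load time (multiallelic / non-SNP).
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        dosages: np.ndarray,
        n_skipped: int = 0,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[0] != len(variants):
            raise ValueError("dosages must be (n_variants, n_individuals)")
        order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
        self.variants: list[Variant] = [variants[i] for i in order]
        self.dosages = dosages[order]
        self.n_individuals = dosages.shape[1]
        self.n_skipped = n_skipped

        seen: set[tuple[str, int, str, str]] = set()
        self._index: dict[str, int] = {}
        for i, v in enumerate(self.variants):
            key = (v.chrom, v.pos, v.ref, v.alt)
            if key in seen:
                raise ValueError(f"duplicate variant at {v.chrom}:{v.pos} {v.ref}/{v.alt}")
            seen.add(key)
            if v.id in self._index:
                raise ValueError(f"duplicate variant id {v.id!r}")
            self._index[v.id] = i

        # per-chromosome position arrays for windowed queries
        self._by_chrom: dict[str, np.ndarray] = {}
        chroms = np.array([v.chrom for v in self.variants])
        for c in dict.fromkeys(chroms):
            self._by_chrom[c] = np.flatnonzero(chroms == c)

        self._maf_cache: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def row(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self.row(variant_id)]

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[self.row(variant_id)]

    # -- frequencies -------------------------------------------------------

    def allele_freq(self, variant_id: str) -> float:
        """Alternate-allele frequency over non-missing dosages."""
        g = self.dosage(variant_id)
        ok = np.isfinite(g)
        if not ok.any():
            raise ValueError(f"{variant_id}: all genotypes missing, frequency undefined")
        return float(g[ok].sum() / (2 * ok.sum()))

    def maf(self, variant_id: str) -> float:
        f = self.allele_freq(variant_id)
        return min(f, 1.0 - f)

    def _all_mafs(self) -> np.ndarray:
        if self._maf_cache is None:
            with np.errstate(invalid="ignore"):
                ok = np.isfinite(self.dosages)
                n = ok.sum(axis=1)
                f = np.where(n > 0, np.nansum(self.dosages, axis=1) / np.maximum(2 * n, 1), np.nan)
            self._maf_cache = np.minimum(f, 1.0 - f)
        return self._maf_cache

    # -- HWE ---------------------------------------------------------------

    def hwe_test(self, variant_id: str) -> float:
        """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg
        genotype proportions. Monomorphic variants return p = 1 by convention.
        """
        g = self.dosage(variant_id)
        g = g[np.isfinite(g)]
        if g.size == 0:
            raise ValueError(f"{variant_id}: no non-missing genotypes")
        n = g.size
        obs = np.array([(g == 0).sum(), (g == 1).sum(), (g == 2).sum()], dtype=float)
        f = (obs[1] + 2 * obs[2]) / (2 * n)
        if f == 0.0 or f == 1.0:
            return 1.0
        exp = n * np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, df=1))

    # -- LD ----------------------------------------------------------------

    def r2(self, id_a: str, id_b: str) -> float:
        """Squared Pearson correlation of dosages, pairwise-complete."""
        a = self.dosage(id_a)
        b = self.dosage(id_b)
        return _r2_vectors(a, b)

    # -- windows -----------------------------------------------------------

    def neighbors_window(
        self,
        variant_id: str,
        half_window_bp: int = 500_000,
        maf_tolerance: float = 0.05,
    ) -> list[str]:
        """MAF-matched physical-distance neighbors of a focal SNP.

        Returns ids of all *other* panel variants on the same chromosome with
        ``|pos_j - pos_i| <= half_window_bp`` (boundary inclusive) and
        ``|MAF_j - MAF_i| <= maf_tolerance``, ordered by position.
        """
        if half_window_bp <= 0:
            raise ValueError("half_window_bp must be positive")
        i = self.row(variant_id)
        v = self.variants[i]
        rows = self._by_chrom[v.chrom]
        pos = np.array([self.variants[j].pos for j in rows])
        mafs = self._all_mafs()[rows]
        focal_maf = self._all_mafs()[i]
        keep = (np.abs(pos - v.pos) <= half_window_bp) & (
            np.abs(mafs - focal_maf) <= maf_tolerance
        )
        out = [self.variants[j].id for j, k in zip(rows, keep) if k]
        return [x for x in out if x != variant_id]


def _r2_vectors(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise LDUndefinedError("fewer than 2 pairwise-complete individuals")
    x = a[ok]
    y = b[ok]
    xc = x - x.mean()
    yc = y - y.mean()
    sx = (xc**2).sum()
    sy = (yc**2).sum()
    if sx == 0.0 or sy == 0.0:
        raise LDUndefinedError("zero dosage variance over pairwise-complete individuals")
    r = (xc * yc).sum() / np.sqrt(sx * sy)
    return float(min(r * r, 1.0))


# ---------------------------------------------------------------------------
# module-level functional surface


def load_genotypes(vcf_source: str) -> LDPanel:
    """Load biallelic SNPs from a VCF into an :class:`LDPanel`.

    Multiallelic records and non-SNP records (indels, symbolic alleles) are
    skipped; the skip count is logged and kept on ``panel.n_skipped``.
    Missing genotypes (``./.``) are stored as NaN.
    """
    from cyvcf2 import VCF

    bases = {"A", "C", "G", "T"}
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    vcf = VCF(str(vcf_source), gts012=True)
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or rec.REF not in bases or alts[0] not in bases:
            n_skipped += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alts[0]}"
        # with gts012=True: 0/1/2 = alt dosage, 3 = unknown
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        variants.append(Variant(vid, rec.CHROM, rec.POS, rec.REF, alts[0]))
        rows.append(g)
    vcf.close()
    if not variants:
        raise ValueError(f"no biallelic SNP records retained from {vcf_source}")
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)
    return LDPanel(variants, np.vstack(rows), n_skipped=n_skipped)


def allele_freq(panel: LDPanel, variant_id: str) -> float:
    return panel.allele_freq(variant_id)


def maf(panel: LDPanel, variant_id: str) -> float:
    return panel.maf(variant_id)


def hwe_test(panel: LDPanel, variant_id: str) -> float:
    return panel.hwe_test(variant_id)


def r2(panel: LDPanel, id_a: str, id_b: str) -> float:
    return panel.r2(id_a, id_b)


def neighbors_window(
    panel: LDPanel,
    variant_id: str,
    half_window_bp: int = 500_000,
    maf_tolerance: float = 0.05,
) -> list[str]:
    return panel.neighbors_window(variant_id, half_window_bp, maf_tolerance)
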