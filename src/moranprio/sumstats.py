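"""GWAS summary statistics: reading, validation, and risk-allele harmonization.

The internal effect scale is beta = log(OR); the odds ratio is a derived view.
Harmonization refers every record to the risk-increasing allele (OR >= 1) by
swapping alleles and negating beta where needed, so that downstream rank
transforms see a consistent effect direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryRecord",
    "StudySet",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize_to_risk_allele",
    "qc_filter",
]

#: canonical column names used on read and write
COLUMNS = [
    "id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "or",
    "beta",
    "se",
    "p",
    "maf",
    "info",
    "flipped",
]


@dataclass
class SummaryRecord:
    """One SNP's association summary on the log-odds scale."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    maf: float
    info: float | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.id}: se must be positive")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.id}: p must be in (0, 1]")
        if not (0 < self.maf <= 0.5):
            raise ValueError(f"{self.id}: maf must be in (0, 0.5]")

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)


class StudySet:
    """An ordered, id-unique collection of summary records."""

    def __init__(self, records: Iterable[SummaryRecord], provenance: str = "") -> None:
        recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.id))
        index: dict[str, SummaryRecord] = {}
        for r in recs:
            if r.id in index:
                raise ValueError(f"duplicate SNP id {r.id!r}")
            index[r.id] = r
        self.records: list[SummaryRecord] = recs
        self.provenance = provenance
        self._index = index
        #: row-numbered (1-based data row, reason) diagnostics from parsing
        self.rejected: list[tuple[int, str]] = []

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __getitem__(self, snp_id: str) -> SummaryRecord:
        return self._index[snp_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": r.id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "or": r.or_value,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "maf": r.maf,
                "info": r.info if r.info is not None else np.nan,
                "flipped": r.flipped,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=COLUMNS)


def read_summary_stats(
    tsv_source,
    column_map: Mapping[str, str] | None = None,
    provenance: str = "",
) -> StudySet:
    """Parse a TSV of GWAS summary statistics into a :class:`StudySet`.

    ``column_map`` maps canonical field names (id, chrom, pos, effect_allele,
    other_allele, or, beta, se, p, maf, info) to the file's column names;
    omitted entries default to the canonical name itself. Exactly one of
    ``or`` / ``beta`` must resolve per row (the other is derived). Malformed
    rows are rejected with row-numbered diagnostics kept on ``.rejected``;
    a duplicated id is a hard error.
    """
    cmap = {k: k for k in COLUMNS}
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(tsv_source, sep="\t", dtype=str)
    required = ["id", "chrom", "pos", "effect_allele", "other_allele", "se", "p", "maf"]
    for key in required:
        if cmap[key] not in df.columns:
            raise ValueError(f"required column {cmap[key]!r} (field {key!r}) missing")
    has_or = cmap["or"] in df.columns
    has_beta = cmap["beta"] in df.columns
    if not (has_or or has_beta):
        raise ValueError("need an effect column: either 'or' or 'beta'")

    records: list[SummaryRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))

        def get(key: str) -> str | None:
            v = row.get(cmap[key])
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v

        try:
            beta = _effect_beta(get("or") if has_or else None, get("beta") if has_beta else None)
            info_raw = get("info")
            rec = SummaryRecord(
                id=str(get("id")),
                chrom=str(get("chrom")),
                pos=int(get("pos")),
                effect_allele=str(get("effect_allele")),
                other_allele=str(get("other_allele")),
                beta=beta,
                se=float(get("se")),
                p=float(get("p")),
                maf=float(get("maf")),
                info=float(info_raw) if info_raw is not None else None,
            )
        except (TypeError, ValueError) as exc:
            rejected.append((i, str(exc)))
            continue
        records.append(rec)

    study = StudySet(records, provenance=provenance)
    study.rejected = rejected
    for i, reason in rejected:
        logger.warning("row %d rejected: %s", i, reason)
    return study


def _effect_beta(or_str: str | None, beta_str: str | None) -> float:
    if or_str is not None:
        orv = float(or_str)
        if orv <= 0 or not math.isfinite(orv):
            raise ValueError(f"odds ratio must be positive and finite, got {orv}")
        beta = math.log(orv)
        if beta_str is not None:
            b = float(beta_str)
            if abs(b - beta) > 1e-9:
                raise ValueError(f"inconsistent or/beta: ln({orv}) != {b}")
        return beta
    if beta_str is None:
        raise ValueError("neither or nor beta present")
    b = float(beta_str)
    if not math.isfinite(b):
        raise ValueError("beta must be finite")
    return b


def write_summary_stats(study: StudySet, path) -> None:
    study.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")


def harmonize_to_risk_allele(study: StudySet) -> StudySet:
    """Refer every record to its risk-increasing allele (OR >= 1).

    Records with OR < 1 have alleles swapped and beta negated (OR inverted);
    p, se and MAF are untouched. OR exactly 1 is kept unflipped. Idempotent.
    """
    out = []
    for r in study.records:
        if r.beta < 0:
            out.append(
                replace(
                    r,
                    effect_allele=r.other_allele,
                    other_allele=r.effect_allele,
                    beta=-r.beta,
                    flipped=True,
                )
            )
        else:
            out.append(replace(r))
    return StudySet(out, provenance=study.provenance)


def qc_filter(
    study: StudySet, min_maf: float = 0.05, min_info: float = 0.91
) -> tuple[StudySet, dict[str, int]]:
    """Retain records with MAF strictly above ``min_maf`` and, when an info
    score is present, info >= ``min_info``.

    Returns the filtered set and a per-criterion removal report (a record
    failing both criteria counts once under each).
    """
    if not (0 <= min_maf <= 1 and 0 <= min_info <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    kept, n_maf, n_info = [], 0, 0
    for r in study.records:
        fail_maf = not (r.maf > min_maf)
        fail_info = r.info is not None and r.info < min_info
        n_maf += fail_maf
        n_info += fail_info
        if not (fail_maf or fail_info):
            kept.append(r)
    return StudySet(kept, provenance=study.provenance), {"maf": n_maf, "info": n_info}
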