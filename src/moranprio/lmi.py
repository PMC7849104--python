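"""Genomic Local Moran's Index: LD-weighted local autocorrelation of effect sizes.

The statistic transfers a classic geospatial "hot spot" detector to the genome.
Each SNP's odds ratio is rank-transformed to a normal score z; linkage
disequilibrium (r²) with physically close, MAF-matched neighbors plays the
role of inverse geographic distance; and the index

    LMI_i = z_i * sum_j(z_j * r²_ij) / sum_j(r²_ij)

is large and positive where a SNP with a high standardized effect sits inside
an LD cluster of similarly high effects. Because the score pools evidence over
an LD neighborhood instead of relying on a single per-SNP test, it can surface
low-frequency clusters that individually underpowered association p-values
miss.

Selection follows three rules: discard negative-LMI SNPs (discordant or
unlinked neighborhoods), discard positive-LMI SNPs whose own transformed
effect falls in the bottom half of the z distribution, then keep the top
fraction (default 0.5%) of the survivors by LMI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ldpanel import LDPanel, LDUndefinedError
from .sumstats import StudySet

__all__ = [
    "LMIRecord",
    "standardize_or",
    "compute_lmi",
    "filter_lmi",
    "select_top_fraction",
]


@dataclass
class LMIRecord:
    """Per-SNP Local Moran's Index bookkeeping.

    ``estimable`` is False when the SNP is absent from the LD panel, too rare
    in it (panel MAF below 1%), or has no weighted neighbors; such records
    carry no LMI value and no exclusion flags.
    """

    id: str
    z: float
    neighbor_ids: list[str] = field(default_factory=list)
    weight_sum: float = 0.0
    local_mean: float = math.nan
    lmi: float = math.nan
    estimable: bool = False
    excluded_negative: bool = False
    excluded_bottom_tail: bool = False
    rank: int | None = None
    p: float | None = None


def standardize_or(study: StudySet | Mapping[str, float]) -> dict[str, float]:
    """Rank-based inverse-normal transform of the (harmonized) odds ratios.

    Each SNP gets z = Phi^-1((rank - 0.5)/n) with mid-ranks for ties, ranking
    the ORs ascending; the transform is strictly monotone between distinct OR
    values and assigns z = 0 to a single SNP or to the middle of a tie block.
    """
    if isinstance(study, StudySet):
        ids = study.ids()
        vals = np.array([study[i].beta for i in ids])  # monotone in OR
    else:
        ids = list(study.keys())
        vals = np.array([study[i] for i in ids], dtype=float)
    n = len(ids)
    if n == 0:
        return {}
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - 0.5) / n)
    return dict(zip(ids, map(float, z)))


def compute_lmi(
    zmap: Mapping[str, float],
    panel: LDPanel,
    half_window_bp: int = 500_000,
    maf_tolerance: float = 0.05,
    min_panel_maf: float = 0.01,
    p_values: Mapping[str, float] | None = None,
) -> list[LMIRecord]:
    """Compute the Local Moran's Index for every scored SNP.

    Neighbors are panel variants on the same chromosome within
    ``half_window_bp`` of the focal SNP, MAF-matched within
    ``maf_tolerance``, and restricted to SNPs that themselves carry a z score.
    Weights are pairwise r² from the panel; neighbors with undefined LD
    contribute nothing. A SNP missing from the panel, with panel MAF below
    ``min_panel_maf``, or with zero total weight is marked not estimable.
    Windows never span chromosomes.
    """
    mafs = {vid: panel.maf(vid) for vid in zmap if vid in panel}
    records: list[LMIRecord] = []
    for vid, z in zmap.items():
        rec = LMIRecord(id=vid, z=float(z), p=p_values.get(vid) if p_values else None)
        records.append(rec)
        if vid not in panel or mafs[vid] < min_panel_maf:
            continue
        neigh = [j for j in panel.neighbors_window(vid, half_window_bp, maf_tolerance) if j in zmap]
        if not neigh:
            continue
        focal = panel.dosage(vid)
        wsum = 0.0
        acc = 0.0
        kept: list[str] = []
        for j in neigh:
            try:
                w = _pair_r2(focal, panel.dosage(j))
            except LDUndefinedError:
                continue
            kept.append(j)
            wsum += w
            acc += zmap[j] * w
        rec.neighbor_ids = kept
        rec.weight_sum = wsum
        if wsum <= 0.0:
            continue
        rec.local_mean = acc / wsum
        rec.lmi = rec.z * rec.local_mean
        rec.estimable = True
    return records


def _pair_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise LDUndefinedError("fewer than 2 pairwise-complete individuals")
    x, y = a[ok], b[ok]
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise LDUndefinedError("zero variance")
    r = float(xc @ yc) / math.sqrt(sx * sy)
    return min(r * r, 1.0)


def filter_lmi(records: Sequence[LMIRecord]) -> list[LMIRecord]:
    """Apply the two exclusion rules; returns the retained records.

    Rule 1 discards SNPs with negative LMI. Rule 2 discards positive-LMI SNPs
    whose z lies strictly below the median z of *all* scored SNPs (the bottom
    half of the ordered transformed OR distribution); the median itself is
    retained. Flags are set in place on the discarded records; the two flags
    are mutually exclusive and non-estimable records carry neither.
    """
    zs = np.array([r.z for r in records], dtype=float)
    if zs.size == 0:
        return []
    med = float(np.median(zs))
    kept: list[LMIRecord] = []
    for r in records:
        r.excluded_negative = False
        r.excluded_bottom_tail = False
        if not r.estimable:
            continue
        if r.lmi < 0:
            r.excluded_negative = True
        elif r.z < med:
            r.excluded_bottom_tail = True
        else:
            kept.append(r)
    return kept


def select_top_fraction(
    records: Sequence[LMIRecord], fraction: float = 0.005
) -> tuple[list[LMIRecord], float]:
    """Select the top ``fraction`` of retained records by LMI, descending.

    k = floor(fraction * n). Ties at equal LMI break by smaller association
    p-value (when present), then lexicographic id. Selected records get ranks
    1..k; the implied LMI threshold (the k-th record's LMI) is returned with
    them. k = 0 yields an empty selection.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    order = sorted(
        records,
        key=lambda r: (-r.lmi, r.p if r.p is not None else math.inf, r.id),
    )
    k = math.floor(fraction * len(order))
    selected = order[:k]
    for i, r in enumerate(selected, start=1):
        r.rank = i
    threshold = selected[-1].lmi if selected else math.nan
    return selected, threshold
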