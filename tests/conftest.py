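"""Shared fixtures: tiny hand-built panels and the batched cluster scenario."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from moranprio import lmi, simulate
from moranprio.ldpanel import LDPanel, LDUndefinedError, Variant

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_lmi(zmap, panel, half_window_bp=500_000, maf_tolerance=0.05, min_panel_maf=0.01):
    """Independent LMI oracle: all-pairs double loop with the same predicates.

    Returns id -> LMI (None when not estimable). Deliberately shares no code
    with lmi.compute_lmi beyond the panel's primitive r² accessor.
    """
    out = {}
    for vid, z in zmap.items():
        if vid not in panel or panel.maf(vid) < min_panel_maf:
            out[vid] = None
            continue
        vi = panel.variant(vid)
        num = den = 0.0
        for other in zmap:
            if other == vid or other not in panel:
                continue
            vj = panel.variant(other)
            if vj.chrom != vi.chrom or abs(vj.pos - vi.pos) > half_window_bp:
                continue
            if abs(panel.maf(other) - panel.maf(vid)) > maf_tolerance:
                continue
            try:
                w = panel.r2(vid, other)
            except LDUndefinedError:
                continue
            num += zmap[other] * w
            den += w
        out[vid] = z * num / den if den > 0 else None
    return out


@pytest.fixture
def small_panel() -> LDPanel:
    """Six SNPs on two chromosomes with hand-set dosages over 8 individuals.

    Positions on chr1 are 1.0, 1.2, 1.5 Mb (all within one +/-500 kb window);
    chr2 has 2.0, 2.3, 3.1 Mb (the last outside the window of the first).
    """
    variants = [
        Variant("rs1", "1", 1_000_000, "A", "G"),
        Variant("rs2", "1", 1_200_000, "C", "T"),
        Variant("rs3", "1", 1_500_000, "A", "C"),
        Variant("rs4", "2", 2_000_000, "G", "T"),
        Variant("rs5", "2", 2_300_000, "A", "G"),
        Variant("rs6", "2", 3_100_000, "C", "G"),
    ]
    dosages = np.array(
        [
            [0, 1, 1, 2, 0, 1, 2, 1],  # rs1: f = 8/16 = 0.5
            [0, 1, 1, 2, 0, 1, 2, 1],  # rs2: identical to rs1 -> r2 = 1
            [2, 1, 1, 0, 2, 1, 0, 1],  # rs3: flipped rs1 -> r2 = 1
            [0, 0, 1, 1, 0, 0, 1, 1],  # rs4
            [0, 1, 0, 1, 0, 1, 0, 1],  # rs5: orthogonal to rs4
            [0, 0, 0, 1, np.nan, 0, 0, 0],  # rs6: one missing call
        ],
        dtype=float,
    )
    return LDPanel(variants, dosages)


def _rank_map(ids_sorted):
    return {v: i + 1 for i, v in enumerate(ids_sorted)}


@dataclass
class ScenarioStats:
    """Summary of one low-MAF cluster scenario run."""

    median_lmi_rank: float
    median_p_rank: float
    selection_ids: list[str]
    cluster_ids: list[str]
    common_hit_id: str
    n_scored: int


def summarize_scenario(seed: int) -> ScenarioStats:
    sc = simulate.scenario_low_maf_cluster(seed=seed)
    zmap = lmi.standardize_or(sc.study)
    pmap = {r.id: r.p for r in sc.study.records}
    records = lmi.compute_lmi(zmap, sc.panel, p_values=pmap)
    by_lmi = sorted(
        records,
        key=lambda r: (-(r.lmi if r.estimable and math.isfinite(r.lmi) else -math.inf), r.id),
    )
    rank_lmi = _rank_map([r.id for r in by_lmi])
    rank_p = _rank_map([r.id for r in sorted(sc.study.records, key=lambda r: (r.p, r.id))])
    cluster = [c for c in sc.cluster_ids if c in sc.study]
    retained = lmi.filter_lmi(records)
    selected, _ = lmi.select_top_fraction(retained, 0.005)
    return ScenarioStats(
        median_lmi_rank=float(np.median([rank_lmi[c] for c in cluster])),
        median_p_rank=float(np.median([rank_p[c] for c in cluster])),
        selection_ids=[s.id for s in selected],
        cluster_ids=sc.cluster_ids,
        common_hit_id=sc.common_hit_id,
        n_scored=len(sc.study),
    )


@pytest.fixture(scope="session")
def scenario_batch() -> list[ScenarioStats]:
    """Fifty seeded low-MAF cluster scenarios, shared across test modules."""
    return [summarize_scenario(seed) for seed in range(50)]
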