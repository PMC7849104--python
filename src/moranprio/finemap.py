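"""Approximate-Bayes-factor credible sets around prioritized SNPs.

For a region anchored on a lead SNP, each member's evidence for association is
the Wakefield asymptotic Bayes factor computed from its log-OR estimate and
standard error under a normal effect prior N(0, W). Normalizing the Bayes
factors over the region gives per-SNP posterior probabilities of being the
causal variant (single-causal-variant assumption); the credible set is the
smallest posterior-descending prefix whose cumulative mass reaches the target
(0.99 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ldpanel import LDPanel, LDUndefinedError
from .sumstats import StudySet

__all__ = ["CredibleSet", "wakefield_bf", "credible_set"]

#: default prior variance of the log-OR effect (prior SD 0.2)
DEFAULT_PRIOR_W = 0.04


@dataclass(frozen=True)
class CredibleSetMember:
    id: str
    bf: float
    posterior: float
    cumulative: float
    in_set: bool


@dataclass(frozen=True)
class CredibleSet:
    """A fine-mapping region and its credible set.

    ``members`` covers the whole region sorted by posterior descending;
    ``in_set`` marks the smallest prefix reaching ``mass``. ``contains_min_p``
    records whether the region's smallest-p SNP made it into the set.
    """

    lead_id: str
    chrom: str
    start: int
    end: int
    members: tuple[CredibleSetMember, ...]
    mass: float
    contains_min_p: bool

    @property
    def set_ids(self) -> list[str]:
        return [m.id for m in self.members if m.in_set]

    @property
    def size(self) -> int:
        return sum(m.in_set for m in self.members)


def wakefield_bf(beta: float, se: float, prior_w: float = DEFAULT_PRIOR_W) -> float:
    """Asymptotic Bayes factor for association vs. no effect.

    With V = se² and z = beta/se:

        BF = sqrt(V / (V + W)) * exp(z² W / (2 (V + W)))

    W = 0 (point-mass prior at zero) gives BF = 1 for any z.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if prior_w < 0:
        raise ValueError("prior variance must be non-negative")
    v = se * se
    z = beta / se
    return math.sqrt(v / (v + prior_w)) * math.exp(z * z * prior_w / (2 * (v + prior_w)))


def credible_set(
    lead_id: str,
    study: StudySet,
    panel: LDPanel,
    r2_min: float = 0.1,
    half_window_bp: int = 500_000,
    mass: float = 0.99,
    prior_w: float = DEFAULT_PRIOR_W,
) -> CredibleSet:
    """Build the credible set for one lead SNP.

    Region members are the lead plus every scored SNP on the same chromosome
    within ``half_window_bp`` whose LD with the lead exceeds ``r2_min``
    (strict; undefined LD excludes the SNP). Posteriors are the Wakefield
    Bayes factors normalized over the region. Nearby leads produce separate,
    possibly overlapping sets; no merging is attempted.
    """
    if lead_id not in study:
        raise KeyError(f"lead {lead_id!r} not in study")
    if lead_id not in panel:
        raise KeyError(f"lead {lead_id!r} not in LD panel")
    lead = study[lead_id]
    lead_dosage = panel.dosage(lead_id)
    if np.nanstd(lead_dosage) == 0:
        raise ValueError(f"lead {lead_id!r} has no dosage variance in the panel; LD undefined")

    member_ids = [lead_id]
    for rec in study.records:
        if rec.id == lead_id or rec.chrom != lead.chrom:
            continue
        if abs(rec.pos - lead.pos) > half_window_bp:
            continue
        if rec.id not in panel:
            continue
        try:
            ld = panel.r2(lead_id, rec.id)
        except LDUndefinedError:
            continue
        if ld > r2_min:
            member_ids.append(rec.id)

    bfs = np.array([wakefield_bf(study[i].beta, study[i].se, prior_w) for i in member_ids])
    post = bfs / bfs.sum()
    # deterministic order: posterior desc, then p asc, then id
    order = sorted(
        range(len(member_ids)),
        key=lambda k: (-post[k], study[member_ids[k]].p, member_ids[k]),
    )
    cum = 0.0
    members: list[CredibleSetMember] = []
    reached = False
    for k in order:
        cum += post[k]
        members.append(
            CredibleSetMember(member_ids[k], float(bfs[k]), float(post[k]), float(cum), not reached)
        )
        if not reached and cum >= mass - 1e-12:
            reached = True

    min_p_id = min(member_ids, key=lambda i: (study[i].p, i))
    in_set_ids = {m.id for m in members if m.in_set}
    return CredibleSet(
        lead_id=lead_id,
        chrom=lead.chrom,
        start=max(1, lead.pos - half_window_bp),
        end=lead.pos + half_window_bp,
        members=tuple(members),
        mass=mass,
        contains_min_p=min_p_id in in_set_ids,
    )
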