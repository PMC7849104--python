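"""Per-SNP case-control association and random-effects meta-analysis.

Association is a logistic regression of case status on additive allele dosage
(0/1/2), optionally adjusted for covariates (age, sex, region indicators,
principal components supplied by the caller). Effect pooling across studies
uses the DerSimonian-Laird random-effects estimator. A genomic inflation
factor is provided as a confounding diagnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ldpanel import LDPanel
from .sumstats import StudySet, SummaryRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "MetaResult",
    "logistic_assoc",
    "association_scan",
    "genomic_lambda",
    "meta_random_effects",
]

#: |log-OR| beyond which a fit is treated as (quasi-)separated
SEPARATION_BETA = 20.0


@dataclass(frozen=True)
class AssocResult:
    """Dosage-term estimate from one logistic fit.

    ``converged`` is False when the fit separated or failed to converge; the
    statistics are then NaN rather than an exception, so genome scans can
    continue past degenerate SNPs.
    """

    snp_id: str
    beta: float
    se: float
    p: float
    n: int
    converged: bool
    separated: bool = False


def logistic_assoc(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    snp_id: str = "",
) -> AssocResult:
    """Fit case status ~ dosage (+ covariates) by maximum likelihood.

    Newton-Raphson with log-likelihood tolerance 1e-8 and at most 100
    iterations. Complete or quasi-complete separation is reported as a
    flagged NA result. A rank-deficient covariate matrix is a configuration
    error and raises.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; cannot fit")
    cols = [np.ones_like(g), g]
    if covariates is not None:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols.extend(X.T)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design[:, [0] + list(range(2, design.shape[1]))]) < design.shape[1] - 1:
        raise ValueError("covariate matrix is rank deficient")

    na = AssocResult(snp_id, np.nan, np.nan, np.nan, len(y), converged=False, separated=True)
    if g.min() == g.max():
        # monomorphic dosage: no estimable effect
        return AssocResult(snp_id, np.nan, np.nan, np.nan, len(y), converged=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        return na
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > SEPARATION_BETA:
        return na
    if not fit.mle_retvals.get("converged", False):
        return AssocResult(snp_id, np.nan, np.nan, np.nan, len(y), converged=False)
    return AssocResult(snp_id, beta, se, float(fit.pvalues[1]), len(y), converged=True)


def association_scan(
    panel: LDPanel,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    provenance: str = "scan",
) -> tuple[StudySet, list[AssocResult]]:
    """Run :func:`logistic_assoc` for every panel SNP.

    Returns a :class:`StudySet` of the converged fits (MAF taken from the
    panel; effect allele = alt) plus the full per-SNP result list including
    flagged failures. SNPs that are monomorphic in the panel are flagged,
    not scored.
    """
    results: list[AssocResult] = []
    records: list[SummaryRecord] = []
    for v in panel.variants:
        g = panel.dosage(v.id)
        res = logistic_assoc(y, np.nan_to_num(g, nan=np.nanmean(g)), covariates, snp_id=v.id)
        results.append(res)
        if not res.converged:
            continue
        f = panel.allele_freq(v.id)
        m = min(f, 1 - f)
        if m <= 0:
            continue
        records.append(
            SummaryRecord(
                id=v.id,
                chrom=v.chrom,
                pos=v.pos,
                effect_allele=v.alt,
                other_allele=v.ref,
                beta=res.beta,
                se=res.se,
                p=max(res.p, np.nextafter(0, 1)),
                maf=m,
            )
        )
    return StudySet(records, provenance=provenance), results


def genomic_lambda(
    p_values: Sequence[float] | None = None,
    chisq: Sequence[float] | None = None,
) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over the
    null chi-square(1) median (~0.4549).

    Supply either two-sided p-values (converted through the inverse
    chi-square survival function) or the chi-square statistics directly.
    """
    if (p_values is None) == (chisq is None):
        raise ValueError("supply exactly one of p_values or chisq")
    if chisq is None:
        p = np.asarray(p_values, dtype=float)
        x = stats.chi2.isf(p, df=1)
    else:
        x = np.asarray(chisq, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(x) / stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    tau2: float
    q: float
    p: float
    k: int


def meta_random_effects(
    betas: Sequence[float], ses: Sequence[float], labels: Sequence[str] | None = None
) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-study log-ORs.

    Fixed-effect weights w = 1/se²; Cochran's Q about the fixed-effect mean;
    tau² = max(0, (Q - df) / (Σw - Σw²/Σw)); random-effect weights
    w* = 1/(se² + tau²). A single study passes through with tau² = 0.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one study")
    if b.shape != s.shape or not (np.isfinite(b).all() and np.isfinite(s).all()):
        raise ValueError("betas and ses must be finite and same length")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    k = b.size
    if k == 1:
        z = b[0] / s[0]
        return MetaResult(float(b[0]), float(s[0]), 0.0, 0.0, float(2 * stats.norm.sf(abs(z))), 1)
    w = 1.0 / s**2
    b_fe = float((w * b).sum() / w.sum())
    q = float((w * (b - b_fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (s**2 + tau2)
    pooled = float((w_re * b).sum() / w_re.sum())
    se = float(np.sqrt(1.0 / w_re.sum()))
    z = pooled / se
    return MetaResult(pooled, se, float(tau2), q, float(2 * stats.norm.sf(abs(z))), k)
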