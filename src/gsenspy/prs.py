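"""Polygenic risk scores and their trait associations.

A PRS is the weighted sum of effect-allele dosages over the variants a
weight table shares with the genotype matrix, z-standardized across
individuals.  Standardization uses the population SD convention (divide
by n); tiny hand-worked examples are sensitive to this choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from gsenspy.simulate import GenotypeMatrix, SumStats

logger = logging.getLogger(__name__)

__all__ = ["PRSVector", "AssociationResult", "score_prs", "prs_trait_association"]


@dataclass
class PRSVector:
    """Standardized per-individual scores for one discovery trait."""

    scores: np.ndarray
    trait_label: str
    n_variants_used: int = 0
    r2_with: dict = field(default_factory=dict)


@dataclass
class AssociationResult:
    """Standardized OLS coefficient of a phenotype on a PRS."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    r2: float


def score_prs(G: GenotypeMatrix, w: SumStats) -> PRSVector:
    """Score and z-standardize: score_i = sum_j weight_j * dosage_ij.

    Only variants present in both the genotype matrix and the weight table
    contribute; the intersection size is logged.  Raises if the
    intersection is empty or the raw scores have zero variance (e.g. all
    weights zero).
    """
    pos = {vid: j for j, vid in enumerate(G.variant_ids)}
    g_idx, w_idx = [], []
    for k, vid in enumerate(w.variant_ids):
        j = pos.get(vid)
        if j is not None:
            g_idx.append(j)
            w_idx.append(k)
    if not g_idx:
        raise ValueError("no variants shared between genotypes and weights")
    logger.info("score_prs: %d/%d weight variants matched", len(g_idx), len(w.variant_ids))

    raw = G.dosages[:, g_idx].astype(float) @ np.asarray(w.weight, dtype=float)[w_idx]
    sd = raw.std()  # population convention, ddof=0
    if sd == 0.0:
        raise ValueError("raw polygenic scores have zero variance")
    return PRSVector(
        scores=(raw - raw.mean()) / sd,
        trait_label=w.trait,
        n_variants_used=len(g_idx),
    )


def prs_trait_association(
    prs: PRSVector | np.ndarray,
    pheno: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """OLS of the standardized phenotype on the standardized PRS (+ covariates).

    Both variables are z-scored, so without covariates the coefficient is
    the Pearson correlation.  `r2` is the incremental variance explained
    by the PRS beyond the covariates.
    """
    s = prs.scores if isinstance(prs, PRSVector) else np.asarray(prs, dtype=float)
    y = np.asarray(pheno, dtype=float)
    if s.shape[0] != y.shape[0]:
        raise ValueError("PRS and phenotype lengths differ")
    z = lambda v: (v - v.mean()) / v.std()
    s, y = z(s), z(y)

    if covariates is None:
        X = sm.add_constant(s)
        base_r2 = 0.0
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != y.shape[0]:
            C = C.T
        X = sm.add_constant(np.column_stack([s, C]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear covariates")
        base_r2 = sm.OLS(y, sm.add_constant(C)).fit().rsquared

    fit = sm.OLS(y, X).fit()
    lo, hi = fit.conf_int()[1]
    return AssociationResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        ci_low=float(lo),
        ci_high=float(hi),
        r2=float(fit.rsquared - base_r2),
    )
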