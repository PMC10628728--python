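"""Genetic relationship matrix from additive dosages.

A_jk = (1/m) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),
i.e. the average cross-product of dosages standardized under
Hardy-Weinberg.  Off-diagonal entries estimate genome-wide relatedness;
diagonal entries have expectation ~1 in an outbred sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gsenspy.simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["GRM", "compute_grm"]


@dataclass
class GRM:
    """n x n genetic relationship matrix plus bookkeeping."""

    values: np.ndarray
    n_variants_used: int
    individual_ids: list[str]

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_grm(G: GenotypeMatrix, allele_freqs: np.ndarray | None = None) -> GRM:
    """GRM with per-variant standardization by allele frequency.

    Frequencies default to the sample frequencies of the analyzed
    genotypes (pass `allele_freqs` to override, e.g. with the generating
    truth).  Monomorphic variants carry no relatedness information and are
    excluded; the count is logged.
    """
    X = G.dosages.astype(float)
    n, m = X.shape
    if m < 1:
        raise ValueError("need at least 1 variant")
    if allele_freqs is None:
        p = X.mean(axis=0) / 2.0
    else:
        p = np.asarray(allele_freqs, dtype=float)
        if p.shape[0] != m:
            raise ValueError("allele_freqs length must equal n_variants")

    het = 2.0 * p * (1.0 - p)
    poly = (het > 0.0) & (X.var(axis=0) > 0.0)
    n_dropped = int(m - poly.sum())
    if n_dropped:
        logger.info("compute_grm: excluded %d monomorphic variant(s)", n_dropped)
    if not poly.any():
        raise ValueError("all variants are monomorphic; GRM undefined")

    Z = (X[:, poly] - 2.0 * p[poly]) / np.sqrt(het[poly])
    m_used = int(poly.sum())
    A = (Z @ Z.T) / m_used
    A = 0.5 * (A + A.T)  # enforce exact symmetry
    return GRM(values=A, n_variants_used=m_used, individual_ids=list(G.individual_ids))
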