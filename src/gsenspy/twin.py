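"""Twin-based heritability from MZ/DZ pair correlations.

Monozygotic pairs share all additive genetic variance, dizygotic pairs
half of it; both share the common-environment component.  The Falconer
decomposition turns the two intraclass correlations into variance shares:

    a2 = 2 (r_MZ - r_DZ)    additive genetic
    c2 = 2 r_DZ - r_MZ      shared environment
    e2 = 1 - r_MZ           unique environment

Intraclass correlations use double-entry Pearson (each pair entered in
both orders), which is exchangeable in twin order by construction.  The
point-estimate route (rather than a maximum-likelihood ACE fit) is chosen
because only the a2 point estimate and its standard error feed the
downstream sensitivity models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gsenspy.simulate import TwinSample

__all__ = ["TwinCorrelations", "ACEEstimate", "twin_correlations", "falconer_ace"]


@dataclass
class TwinCorrelations:
    r_mz: float
    r_dz: float
    n_mz: int
    n_dz: int


@dataclass
class ACEEstimate:
    """Variance shares; a2 + c2 + e2 == 1 exactly after normalization."""

    a2: float
    c2: float
    e2: float
    se_a2: float
    clamped: bool = False


def _double_entry_r(p1: np.ndarray, p2: np.ndarray) -> float:
    a = np.concatenate([p1, p2])
    b = np.concatenate([p2, p1])
    if np.std(a) == 0.0:
        raise ValueError("zero phenotypic variance within zygosity group")
    return float(np.corrcoef(a, b)[0, 1])


def twin_correlations(tw: TwinSample | pd.DataFrame) -> TwinCorrelations:
    """Intraclass correlations by zygosity via double-entry Pearson."""
    pairs = tw.pairs if isinstance(tw, TwinSample) else tw
    out = {}
    counts = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs["zygosity"] == zyg]
        if len(sub) < 2:
            raise ValueError(f"need at least 2 {zyg} pairs, got {len(sub)}")
        out[zyg] = _double_entry_r(sub["pheno1"].to_numpy(float), sub["pheno2"].to_numpy(float))
        counts[zyg] = len(sub)
    return TwinCorrelations(r_mz=out["MZ"], r_dz=out["DZ"], n_mz=counts["MZ"], n_dz=counts["DZ"])


def _fisher_se_r(r: float, n_pairs: int) -> float:
    """Approximate SE of a correlation from n pairs (Fisher-z delta method)."""
    if n_pairs <= 3:
        return float("nan")
    return (1.0 - r**2) / np.sqrt(n_pairs - 3)


def falconer_ace(tc: TwinCorrelations) -> ACEEstimate:
    """Falconer decomposition with clamping to the admissible region.

    Raw shares outside [0, 1] (possible when r_DZ > r_MZ or r_DZ <
    r_MZ / 2 by sampling noise) are clamped to [0, 1] and the triple is
    renormalized to sum to exactly 1; `clamped` records that this
    happened.  SE of a2 by the delta method from the Fisher-z SEs of the
    two correlations, using the pair counts.
    """
    a2 = 2.0 * (tc.r_mz - tc.r_dz)
    c2 = 2.0 * tc.r_dz - tc.r_mz
    e2 = 1.0 - tc.r_mz
    raw = np.array([a2, c2, e2])
    clipped = np.clip(raw, 0.0, 1.0)
    clamped = bool(np.any(clipped != raw))
    total = float(clipped.sum())
    if total == 0.0:
        norm = np.array([0.0, 0.0, 1.0])  # degenerate: r_mz = 1, r_dz = 1
        clamped = True
    else:
        norm = clipped / total
    se_a2 = 2.0 * np.sqrt(
        _fisher_se_r(tc.r_mz, tc.n_mz) ** 2 + _fisher_se_r(tc.r_dz, tc.n_dz) ** 2
    )
    return ACEEstimate(
        a2=float(norm[0]), c2=float(norm[1]), e2=float(norm[2]),
        se_a2=float(se_a2), clamped=clamped,
    )
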