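"""Synthetic cohorts with a known genetic architecture.

Every downstream stage (GRM/REML, twin decomposition, polygenic scoring,
SEM decomposition) is exercised against cohorts generated here, where the
true heritabilities, the genetic correlation between exposure and outcome
(the pleiotropy knob), the causal exposure->outcome path, and hence the
true genetic-confounding proportion are all known in closed form.

Generative model
----------------
Unlinked biallelic variants: dosage_ij ~ Binomial(2, p_j).  Per-variant
effects (beta_x_j, beta_y_j) are drawn from a bivariate normal with
correlation rg (infinitesimal model: every variant causal) and rescaled so
the population variance of the centred genetic value
G = sum_j beta_j (x_j - 2 p_j) equals the target heritability exactly.

Phenotypes (before covariates):

    X = G_x + e_x,                 Var(e_x) = 1 - h2x   (so Var(X) = 1)
    Y_raw = b_xy * X + G_y + e_y,  Var(e_y) = 1 - h2y

Y_raw is rescaled to unit variance; the exposure-outcome correlation then
decomposes into a causal part b_xy and a genetic-confounding part
rg * sqrt(h2x * h2y), both divided by sd(Y_raw).

Discovery GWAS weights are the true effects plus sampling noise with
variance 1 / (n_gwas * 2 p_j (1 - p_j)), the standard large-sample variance
of a per-variant marginal regression coefficient.

Twins are simulated at the phenotype level: pairs drawn from a bivariate
normal with correlation h2 + c2 (MZ) or h2/2 + c2 (DZ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gsenspy._rng import substream

__all__ = [
    "GenotypeMatrix",
    "EffectSizes",
    "CohortTable",
    "SumStats",
    "TwinSample",
    "simulate_genotypes",
    "simulate_effect_sizes",
    "simulate_phenotypes",
    "simulate_gwas_sumstats",
    "simulate_twin_sample",
    "simulate_covariates",
    "true_confounding_proportion",
    "standardized_outcome_h2",
    "expected_exposure_outcome_correlation",
]


@dataclass
class GenotypeMatrix:
    """Additive dosages (n individuals x m variants) with allele frequencies.

    Dosages count effect alleles, so each entry is 0, 1 or 2; no
    missingness in the simulated case.
    """

    dosages: np.ndarray
    allele_freqs: np.ndarray
    variant_ids: list[str]
    individual_ids: list[str]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.allele_freqs.shape[0] != self.dosages.shape[1]:
            raise ValueError("allele_freqs length must equal n_variants")
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")


@dataclass
class EffectSizes:
    """True per-variant additive effects for an exposure/outcome pair.

    beta_x and beta_y are scaled so the population genetic variance of the
    centred genetic value hits target_h2x / target_h2y exactly for the
    realised draw; their per-variant correlation is target_rg.
    """

    beta_x: np.ndarray
    beta_y: np.ndarray
    target_h2x: float
    target_h2y: float
    target_rg: float
    # standardized draw behind beta_x; lets a second outcome share the same
    # exposure architecture (same beta_x, fresh correlated beta_y)
    raw_x: np.ndarray = field(repr=False, default=None)


@dataclass
class CohortTable:
    """Simulated cohort: one row per individual.

    Columns: exposure, outcome_att, outcome_int, covariates (age, sex,
    site), true genetic values (kept for oracle checks), family_id and
    zygosity (``none`` outside twin subsets).
    """

    data: pd.DataFrame
    params: dict = field(default_factory=dict)


@dataclass
class SumStats:
    """Estimated per-variant weights from a (simulated) discovery GWAS."""

    variant_ids: list[str]
    weight: np.ndarray
    n_gwas: int
    trait: str = "x"


@dataclass
class TwinSample:
    """Phenotype pairs for MZ and DZ twins (long format, one row per pair)."""

    pairs: pd.DataFrame  # columns: family_id, zygosity, pheno1, pheno2
    n_mz: int
    n_dz: int


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw unlinked genotypes: p_j ~ Uniform(maf_range), dosage ~ Binom(2, p_j).

    maf_range must be a subset of (0, 0.5]; identical seeds reproduce
    identical matrices.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if n_variants < 1:
        raise ValueError("need at least 1 variant")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = substream(seed, "genotypes")
    p = rng.uniform(lo, hi, size=n_variants)
    dosages = rng.binomial(2, p, size=(n_individuals, n_variants)).astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages,
        allele_freqs=p,
        variant_ids=[f"snp{j}" for j in range(n_variants)],
        individual_ids=[f"ind{i}" for i in range(n_individuals)],
    )


def simulate_effect_sizes(
    n_variants: int,
    target_h2x: float,
    target_h2y: float,
    target_rg: float,
    allele_freqs: np.ndarray,
    seed: int = 0,
    shared_x_from: EffectSizes | None = None,
) -> EffectSizes:
    """Draw correlated per-variant effects under the infinitesimal model.

    (u_j, v_j) are standard bivariate normal with correlation target_rg;
    beta = scale * draw with the scale chosen so that
    sum_j beta_j^2 * 2 p_j (1 - p_j) equals the target h2 exactly.
    Pass `shared_x_from` to reuse an existing exposure draw (same beta_x)
    when simulating a second outcome against the same exposure.
    """
    if not (0.0 <= target_h2x <= 1.0 and 0.0 <= target_h2y <= 1.0):
        raise ValueError("heritabilities must lie in [0, 1]")
    if abs(target_rg) > 1.0:
        raise ValueError(f"|target_rg| must be <= 1, got {target_rg}")
    p = np.asarray(allele_freqs, dtype=float)
    if p.shape[0] != n_variants:
        raise ValueError("allele_freqs length must equal n_variants")
    het = 2.0 * p * (1.0 - p)

    rng = substream(seed, "effects")
    if shared_x_from is not None:
        u = np.asarray(shared_x_from.raw_x, dtype=float)
        if u.shape[0] != n_variants:
            raise ValueError("shared_x_from has mismatched n_variants")
        rng.standard_normal(n_variants)  # keep stream position independent of branch
    else:
        u = rng.standard_normal(n_variants)
    w = rng.standard_normal(n_variants)
    v = target_rg * u + np.sqrt(max(0.0, 1.0 - target_rg**2)) * w

    def _scale(draw: np.ndarray, h2: float) -> np.ndarray:
        if h2 == 0.0:
            return np.zeros(n_variants)
        var = float(np.sum(draw**2 * het))
        return draw * np.sqrt(h2 / var)

    beta_x = _scale(u, target_h2x) if shared_x_from is None else shared_x_from.beta_x
    return EffectSizes(
        beta_x=beta_x,
        beta_y=_scale(v, target_h2y),
        target_h2x=target_h2x if shared_x_from is None else shared_x_from.target_h2x,
        target_h2y=target_h2y,
        target_rg=target_rg,
        raw_x=u,
    )


def genetic_values(G: GenotypeMatrix, beta: np.ndarray) -> np.ndarray:
    """Centred additive genetic value sum_j beta_j (x_ij - 2 p_j)."""
    centred = G.dosages.astype(float) - 2.0 * G.allele_freqs
    return centred @ np.asarray(beta, dtype=float)


DEFAULT_COVARIATE_EFFECTS = {"age": 0.05, "sex": 0.10, "site": 0.05}


def simulate_covariates(n: int, rng: np.random.Generator, n_sites: int = 5) -> pd.DataFrame:
    """Age ~ Normal(9.9, 0.6), sex ~ Bernoulli(0.5), site ~ Categorical(k)."""
    return pd.DataFrame(
        {
            "age": rng.normal(9.9, 0.6, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "site": rng.integers(0, n_sites, size=n).astype(float),
        }
    )


def simulate_phenotypes(
    G: GenotypeMatrix,
    eff: EffectSizes,
    b_xy: float = 0.0,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
    eff_second: EffectSizes | None = None,
    b_xy_second: float | None = None,
) -> CohortTable:
    """Build a cohort with exposure, outcomes, covariates and true genetic values.

    exposure = G_x + noise (unit population variance before covariates);
    outcome = b_xy * exposure + G_y + noise, then rescaled to unit
    population variance.  The attention-problems analogue `outcome_att`
    comes from `eff`; the internalizing analogue `outcome_int` from
    `eff_second` when given (typically drawn with shared_x_from=eff), else
    it reuses `eff` with independent environmental noise.

    Covariate columns are appended and their stated linear effects added to
    exposure and outcomes (so residualisation downstream is non-trivial).
    """
    if not np.isfinite(b_xy):
        raise ValueError("b_xy must be finite")
    if eff.beta_x.shape[0] != G.n_variants:
        raise ValueError("effect sizes and genotypes have mismatched n_variants")
    if eff_second is not None and eff_second.beta_y.shape[0] != G.n_variants:
        raise ValueError("second effect sizes have mismatched n_variants")
    rng = substream(seed, "phenotypes")
    n = G.n_individuals

    gx = genetic_values(G, eff.beta_x)
    ex = rng.normal(0.0, np.sqrt(max(0.0, 1.0 - eff.target_h2x)), size=n)
    exposure = gx + ex

    def _outcome(e: EffectSizes, b: float) -> tuple[np.ndarray, np.ndarray]:
        gy = genetic_values(G, e.beta_y)
        ey = rng.normal(0.0, np.sqrt(max(0.0, 1.0 - e.target_h2y)), size=n)
        raw = b * exposure + gy + ey
        sd = np.sqrt(
            _raw_outcome_variance(e.target_h2x, e.target_h2y, e.target_rg, b)
        )
        return raw / sd, gy / sd

    out_att, gy_att = _outcome(eff, b_xy)
    if eff_second is not None:
        out_int, gy_int = _outcome(
            eff_second, b_xy if b_xy_second is None else b_xy_second
        )
    else:
        out_int, gy_int = _outcome(eff, b_xy if b_xy_second is None else b_xy_second)

    cov = simulate_covariates(n, rng)
    effects = DEFAULT_COVARIATE_EFFECTS if covariate_effects is None else covariate_effects
    shift = np.zeros(n)
    for name, beta in effects.items():
        col = cov[name].to_numpy()
        shift = shift + beta * (col - col.mean())

    data = pd.DataFrame(
        {
            "exposure": exposure + shift,
            "outcome_att": out_att + shift,
            "outcome_int": out_int + shift,
            "genetic_value_x": gx,
            "genetic_value_y": gy_att,
            "genetic_value_y_int": gy_int,
            "family_id": ["none"] * n,
            "zygosity": ["none"] * n,
        }
    )
    data = pd.concat([data, cov], axis=1)
    data.index = pd.Index(G.individual_ids, name="individual_id")
    params = {
        "b_xy": b_xy,
        "h2x": eff.target_h2x,
        "h2y": eff.target_h2y,
        "rg": eff.target_rg,
        "covariate_effects": dict(effects),
    }
    return CohortTable(data=data, params=params)


def simulate_gwas_sumstats(
    eff: EffectSizes,
    allele_freqs: np.ndarray,
    n_gwas: int,
    which_trait: str = "x",
    seed: int = 0,
    variant_ids: list[str] | None = None,
) -> SumStats:
    """Noisy discovery-GWAS weights: beta_j + N(0, 1/(n_gwas * 2 p_j (1-p_j))).

    Larger discovery samples give weights closer to the true effects and
    hence higher polygenic-score r2 downstream.
    """
    if n_gwas < 1:
        raise ValueError("n_gwas must be >= 1")
    if which_trait not in ("x", "y"):
        raise ValueError("which_trait must be 'x' or 'y'")
    beta = eff.beta_x if which_trait == "x" else eff.beta_y
    p = np.asarray(allele_freqs, dtype=float)
    het = 2.0 * p * (1.0 - p)
    rng = substream(seed, f"sumstats_{which_trait}")
    noise = rng.normal(0.0, 1.0, size=beta.shape[0]) / np.sqrt(n_gwas * het)
    ids = variant_ids if variant_ids is not None else [f"snp{j}" for j in range(len(beta))]
    return SumStats(variant_ids=list(ids), weight=beta + noise, n_gwas=int(n_gwas), trait=which_trait)


def simulate_twin_sample(
    n_mz: int, n_dz: int, h2: float, c2: float, seed: int = 0
) -> TwinSample:
    """Twin pairs from the ACE model at the phenotype level.

    MZ pairs share all additive-genetic and shared-environment variance
    (pair correlation h2 + c2); DZ pairs share half the additive variance
    (h2/2 + c2).  Marginal variances are 1.
    """
    if h2 < 0 or c2 < 0 or h2 + c2 > 1.0 + 1e-12:
        raise ValueError(f"need h2, c2 >= 0 and h2 + c2 <= 1, got h2={h2}, c2={c2}")
    rng = substream(seed, "twins")

    def _pairs(n: int, r: float, zyg: str, start: int) -> pd.DataFrame:
        cov = np.array([[1.0, r], [r, 1.0]])
        draws = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        return pd.DataFrame(
            {
                "family_id": [f"fam{start + i}" for i in range(n)],
                "zygosity": zyg,
                "pheno1": draws[:, 0],
                "pheno2": draws[:, 1],
            }
        )

    mz = _pairs(n_mz, h2 + c2, "MZ", 0)
    dz = _pairs(n_dz, 0.5 * h2 + c2, "DZ", n_mz)
    return TwinSample(pairs=pd.concat([mz, dz], ignore_index=True), n_mz=n_mz, n_dz=n_dz)


def _raw_outcome_variance(h2x: float, h2y: float, rg: float, b_xy: float) -> float:
    """Var(b*X + G_y + e_y) with Var(X)=1, Var(G_y)=h2y, Cov(X,G_y)=rg*sqrt(h2x*h2y)."""
    return 1.0 + b_xy**2 + 2.0 * b_xy * rg * np.sqrt(h2x * h2y)


def true_confounding_proportion(
    h2x: float, v_gy: float, rg: float, b_xy: float
) -> float:
    """Share of the exposure-outcome covariance flowing through the genetic path.

    Under the generative model the standardized covariance splits into a
    causal part b_xy and a genetic part rg * sqrt(h2x * v_gy); the
    proportion is genetic / (causal + genetic).  v_gy is the genetic
    variance of the (unit-exposure-scale) outcome.
    """
    g = rg * np.sqrt(h2x * v_gy)
    denom = b_xy + g
    if abs(denom) < 1e-12:
        raise ZeroDivisionError(
            "exposure-outcome association is zero; confounding proportion undefined"
        )
    return float(g / denom)


def standardized_outcome_h2(h2x: float, h2y: float, rg: float, b_xy: float) -> float:
    """Total genetic variance of the unit-variance outcome.

    The outcome inherits genetic variance through its own polygenic
    component and through the causal path from the (heritable) exposure:
    (b^2 h2x + h2y + 2 b rg sqrt(h2x h2y)) / Var(Y_raw).  This is the h2
    a variance-component estimator targets and the value the SEM's
    outcome-heritability constraint refers to.
    """
    genetic = b_xy**2 * h2x + h2y + 2.0 * b_xy * rg * np.sqrt(h2x * h2y)
    return float(genetic / _raw_outcome_variance(h2x, h2y, rg, b_xy))


def expected_exposure_outcome_correlation(
    h2x: float, h2y: float, rg: float, b_xy: float
) -> float:
    """Population corr(exposure, outcome) under the generative model."""
    return float(
        (b_xy + rg * np.sqrt(h2x * h2y))
        / np.sqrt(_raw_outcome_variance(h2x, h2y, rg, b_xy))
    )
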