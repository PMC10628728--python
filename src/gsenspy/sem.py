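"""Latent-variable structural models for genetic-confounding decomposition.

The observed variables are two polygenic scores and the two phenotypes,
all covariate-residualized and standardized:

    Sx  exposure PRS        X  exposure
    Sy  outcome PRS         Y  outcome

Each PRS is treated as an error-prone indicator of a latent genetic
factor: Sx = lambda_x * G*x + noise, Sy = lambda_y * G*y + noise, with
corr(G*x, G*y) = rho_g.  The latent factor's contribution to its trait is
pinned to a heritability estimate: the path G*x -> X is a = sqrt(h2x),
and the path c from G*y -> Y is solved so the total modeled genetic
variance of Y (the direct path, the path through X, and their covariance)
equals h2y:

    c^2 + 2 a b rho_g c + (a^2 b^2 - h2y) = 0,   c >= 0.

The residual exposure->outcome path b is the association left after
removing genetic confounding; the model-implied total correlation is
b + c * a * rho_g, so the genetic-confounding share is
c * a * rho_g / (b + c * a * rho_g).

Supplying a larger h2 (e.g. twin-based instead of SNV-based) attributes
more of the PRS-tagged covariance to latent genetics, so the decomposition
with SNV-based h2 is read as a lower bound on genetic confounding and the
twin-based one as an upper bound.

Fitting minimizes the maximum-likelihood discrepancy
F = log|Sigma| + tr(S Sigma^-1) - log|S| - p over (lambda_x, lambda_y,
rho_g, b) with box constraints, from several deterministic starting
points (the objective can be multimodal near constraint boundaries).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gsenspy._rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "InfeasibleModelError",
    "ObservedCorrelations",
    "GsensModelSpec",
    "GsensParameters",
    "GsensResult",
    "observed_correlations",
    "implied_correlations",
    "solve_outcome_constraint",
    "prs_only_adjustment",
    "fit_gsens_xy",
    "fit_gsens_y",
    "bootstrap_ci",
    "heritability_sweep",
    "SweepResult",
    "BootstrapCI",
]

LABELS_XY = ("Sx", "Sy", "X", "Y")
LABELS_Y = ("Sy", "X", "Y")


class InfeasibleModelError(ValueError):
    """The heritability constraint cannot be satisfied at these parameters."""


@dataclass
class ObservedCorrelations:
    """Correlation matrix among the analysis variables, with sample size.

    The sufficient statistic for all model fits: labels order the rows
    and columns, `n` carries the information for resampling-based CIs.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray
    n: int

    def subset(self, labels: tuple[str, ...]) -> "ObservedCorrelations":
        idx = [self.labels.index(l) for l in labels]
        return ObservedCorrelations(
            labels=tuple(labels), matrix=self.matrix[np.ix_(idx, idx)], n=self.n
        )


@dataclass
class GsensModelSpec:
    """Which heritability inputs to combine with the PRSs.

    mode tags the provenance of the h2 values (prs_only | snv_h2 |
    twin_h2) for reporting; h2x/h2y are the values actually plugged in.
    `nonneg_residual` constrains the residual exposure->outcome path to be
    nonnegative (the adjusted association is floored at null rather than
    allowed to flip sign).  `outcome_constraint` chooses how h2y pins the
    outcome's genetic variance: "total" (default; direct path plus the
    path through the heritable exposure) or "direct" (c^2 = h2y).
    """

    mode: str = "snv_h2"
    h2x: float = 0.5
    h2y: float = 0.5
    use_exposure_prs: bool = True
    nonneg_residual: bool = True
    outcome_constraint: str = "total"

    def __post_init__(self) -> None:
        for name, v in (("h2x", self.h2x), ("h2y", self.h2y)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.outcome_constraint not in ("total", "direct"):
            raise ValueError("outcome_constraint must be 'total' or 'direct'")


@dataclass
class GsensParameters:
    """Fitted path coefficients of the four-variable latent model."""

    lambda_x: float
    lambda_y: float
    rho_g: float
    b: float
    a: float
    c: float
    h2y: float = float("nan")


@dataclass
class GsensResult:
    """Decomposition of the exposure-outcome association.

    total_effect is the model-implied correlation b + c*a*rho_g;
    adjusted_effect is the residual path b; confounding_abs their
    difference, and confounding_pct its share of the total.  CI fields are
    filled by `bootstrap_ci` (percentile intervals).
    """

    mode: str
    total_effect: float
    adjusted_effect: float
    confounding_abs: float
    confounding_pct: float
    fit_discrepancy: float = float("nan")
    parameters: GsensParameters | None = None
    adjusted_ci: tuple[float, float] | None = None
    confounding_pct_ci: tuple[float, float] | None = None
    ci_method: str | None = None
    n_infeasible_reps: int = 0
    ci_unstable: bool = False


def observed_correlations(
    data: pd.DataFrame | np.ndarray,
    labels: tuple[str, ...] | None = None,
    n: int | None = None,
    repair_tol: float = 0.05,
) -> ObservedCorrelations:
    """Pearson correlation matrix of residualized columns.

    Accepts a DataFrame/array of columns (n inferred from rows) or an
    already-computed square matrix (pass `n` explicitly).  Near-PSD
    matrices (smallest eigenvalue > -repair_tol) are repaired by clipping
    negative eigenvalues and rescaling to unit diagonal, with a warning;
    anything worse raises.
    """
    if isinstance(data, pd.DataFrame):
        labels = labels or tuple(data.columns)
        arr = data.to_numpy(float)
    else:
        arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array")
    if arr.shape[0] == arr.shape[1] and n is not None:
        R = arr.copy()
    else:
        if arr.shape[1] < 3:
            raise ValueError("need at least 3 columns")
        if arr.shape[0] <= arr.shape[1]:
            raise ValueError("need more rows than columns")
        n = arr.shape[0]
        R = np.corrcoef(arr, rowvar=False)
    if labels is None:
        labels = tuple(f"v{i}" for i in range(R.shape[0]))

    R = 0.5 * (R + R.T)
    eig = np.linalg.eigvalsh(R)
    if eig[0] < -repair_tol:
        raise ValueError(f"correlation matrix is not PSD (min eigenvalue {eig[0]:.3g})")
    if eig[0] < 1e-10:
        warnings.warn("near-singular correlation matrix; clipping eigenvalues", stacklevel=2)
        w, V = np.linalg.eigh(R)
        w = np.clip(w, 1e-10, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return ObservedCorrelations(labels=tuple(labels), matrix=R, n=int(n))


def solve_outcome_constraint(b: float, rho_g: float, a: float, h2y: float) -> float:
    """Nonnegative root of c^2 + 2 a b rho_g c + (a^2 b^2 - h2y) = 0.

    This pins the total modeled genetic variance of the outcome (direct
    latent path plus the path through the heritable exposure) to h2y.
    Raises InfeasibleModelError when no nonnegative real root exists.
    """
    if not (0.0 < h2y <= 1.0):
        raise ValueError(f"h2y must lie in (0, 1], got {h2y}")
    disc = h2y - a**2 * b**2 * (1.0 - rho_g**2)
    if disc < 0.0:
        raise InfeasibleModelError(
            f"outcome heritability constraint infeasible (discriminant {disc:.3g})"
        )
    c = -a * b * rho_g + np.sqrt(disc)
    if c < 0.0:
        raise InfeasibleModelError("no nonnegative root for the outcome genetic path")
    return float(c)


def implied_correlations(par: GsensParameters) -> np.ndarray:
    """Model-implied 4x4 correlation matrix in (Sx, Sy, X, Y) order."""
    lx, ly, rg, b, a, c = par.lambda_x, par.lambda_y, par.rho_g, par.b, par.a, par.c
    R = np.eye(4)
    pairs = {
        (0, 1): lx * ly * rg,
        (0, 2): lx * a,
        (0, 3): lx * (b * a + c * rg),
        (1, 2): ly * rg * a,
        (1, 3): ly * (c + b * a * rg),
        (2, 3): b + c * a * rg,
    }
    for (i, j), v in pairs.items():
        R[i, j] = R[j, i] = v
    return R


def _check_order(corr: ObservedCorrelations, labels: tuple[str, ...]) -> ObservedCorrelations:
    if corr.labels == labels:
        return corr
    if set(labels).issubset(corr.labels):
        return corr.subset(labels)
    if len(corr.labels) == len(labels):
        # unlabeled input: assume canonical order
        return ObservedCorrelations(labels=labels, matrix=corr.matrix, n=corr.n)
    raise ValueError(f"expected variables {labels}, got {corr.labels}")


def prs_only_adjustment(corr: ObservedCorrelations | pd.DataFrame) -> GsensResult:
    """Regression adjustment for both PRSs (no measurement-error correction).

    total = standardized simple-regression coefficient of Y on X (their
    correlation); adjusted = coefficient of X in the regression of Y on
    {X, Sx, Sy}, computed from the correlation matrix via the normal
    equations so summary-level input suffices.
    """
    if isinstance(corr, pd.DataFrame):
        corr = observed_correlations(corr)
    corr = _check_order(corr, LABELS_XY)
    R = corr.matrix
    iSx, iSy, iX, iY = 0, 1, 2, 3
    total = R[iX, iY]
    pred = [iX, iSx, iSy]
    Rpp = R[np.ix_(pred, pred)]
    rpy = R[pred, iY]
    if abs(np.linalg.det(Rpp)) < 1e-12:
        raise ValueError("singular predictor correlation matrix")
    beta = np.linalg.solve(Rpp, rpy)
    adjusted = float(beta[0])
    conf = total - adjusted
    return GsensResult(
        mode="prs_only",
        total_effect=float(total),
        adjusted_effect=adjusted,
        confounding_abs=float(conf),
        confounding_pct=float(100.0 * conf / total) if total != 0 else float("nan"),
    )


def _ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    sign, logdet_Sig = np.linalg.slogdet(Sigma)
    if sign <= 0:
        # implied matrix not PD: finite penalty keeps numerical gradients usable
        return 10.0 * _PENALTY
    _, logdet_S = np.linalg.slogdet(S)
    p = S.shape[0]
    return float(logdet_Sig + np.trace(np.linalg.solve(Sigma, S)) - logdet_S - p)


_PENALTY = 1e6


def _xy_objective(theta: np.ndarray, S: np.ndarray, spec: GsensModelSpec) -> float:
    lx, ly, rg, b = theta
    a = np.sqrt(spec.h2x)
    try:
        if spec.outcome_constraint == "direct":
            c = np.sqrt(spec.h2y)
        else:
            c = solve_outcome_constraint(b, rg, a, spec.h2y)
    except InfeasibleModelError:
        disc = spec.h2y - a**2 * b**2 * (1.0 - rg**2)
        return _PENALTY * (1.0 + disc**2)
    # residual variance of Y must be nonnegative for a proper model
    e_y = 1.0 - (b**2 + c**2 + 2.0 * a * b * c * rg)
    if e_y < -1e-10:
        return _PENALTY * (1.0 + e_y**2)
    Sigma = implied_correlations(
        GsensParameters(lambda_x=lx, lambda_y=ly, rho_g=rg, b=b, a=a, c=c)
    )
    return _ml_discrepancy(S, Sigma)


def _xy_starts(corr: ObservedCorrelations, spec: GsensModelSpec) -> list[np.ndarray]:
    R = corr.matrix
    a = np.sqrt(spec.h2x)
    try:
        b0 = max(prs_only_adjustment(corr).adjusted_effect, 0.0)
    except ValueError:
        b0 = max(R[2, 3] / 2.0, 0.0)
    lx0 = float(np.clip(abs(R[0, 2]) / a, 0.05, 1.0))
    ly0 = float(np.clip(abs(R[1, 3]) / np.sqrt(spec.h2y), 0.05, 1.0))
    rg0 = float(np.clip(R[0, 1] / max(lx0 * ly0, 1e-6), -0.95, 0.95))
    starts = [
        np.array([lx0, ly0, rg0, b0]),
        np.array([0.5, 0.5, 0.0, b0]),
        np.array([0.9, 0.9, 0.0, b0]),
        np.array([0.5, 0.5, 0.5, b0]),
        np.array([0.9, 0.9, 0.5, b0]),
        np.array([0.7, 0.7, 0.25, max(R[2, 3], 0.0)]),
    ]
    return starts


def fit_gsens_xy(corr: ObservedCorrelations, spec: GsensModelSpec) -> GsensResult:
    """Fit the four-variable model (PRSs for exposure and outcome).

    The exposure latent path is fixed at a = sqrt(h2x); c is solved from
    the outcome-heritability constraint at every objective evaluation; the
    free parameters (lambda_x, lambda_y, rho_g, b) minimize the ML
    discrepancy under box constraints, from >= 6 deterministic starts.
    Requires h2x >= r(Sx,X)^2 and h2y >= r(Sy,Y)^2, i.e. the supplied
    heritability must be at least the variance its PRS already explains.
    """
    corr = _check_order(corr, LABELS_XY)
    R = corr.matrix
    if spec.h2x < R[0, 2] ** 2 - 1e-10:
        raise InfeasibleModelError(
            f"h2x={spec.h2x:.4f} below exposure PRS r2={R[0, 2] ** 2:.4f}"
        )
    if spec.h2y < R[1, 3] ** 2 - 1e-10:
        raise InfeasibleModelError(
            f"h2y={spec.h2y:.4f} below outcome PRS r2={R[1, 3] ** 2:.4f}"
        )
    a = np.sqrt(spec.h2x)
    b_hi = np.sqrt(max(1.0 - spec.h2y, 0.0) / max(1.0 - spec.h2x, 1e-9)) if spec.h2x < 1 else 1.5
    b_lo = 0.0 if spec.nonneg_residual else -b_hi
    bounds = [(0.0, 1.0), (0.0, 1.0), (-1.0, 1.0), (b_lo, max(b_hi, 1e-6))]

    best = None
    for x0 in _xy_starts(corr, spec):
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _xy_objective, x0, args=(R, spec), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY:
        raise InfeasibleModelError("no feasible solution found from any start")
    # polish with a derivative-free pass; helps reach the 1e-8 discrepancy scale
    polish = optimize.minimize(
        _xy_objective, best.x, args=(R, spec), method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    if polish.fun < best.fun:
        best = polish
    lx, ly, rg, b = np.clip(best.x, [bd[0] for bd in bounds], [bd[1] for bd in bounds])
    if spec.outcome_constraint == "direct":
        c = float(np.sqrt(spec.h2y))
    else:
        c = solve_outcome_constraint(b, rg, a, spec.h2y)
    par = GsensParameters(
        lambda_x=float(lx), lambda_y=float(ly), rho_g=float(rg), b=float(b),
        a=float(a), c=float(c), h2y=spec.h2y,
    )
    conf = c * a * rg
    total = b + conf
    return GsensResult(
        mode=spec.mode,
        total_effect=float(total),
        adjusted_effect=float(b),
        confounding_abs=float(conf),
        confounding_pct=float(100.0 * conf / total) if total != 0 else float("nan"),
        fit_discrepancy=float(best.fun),
        parameters=par,
    )


def _y_implied(ly: float, rxg: float, b: float, c: float) -> np.ndarray:
    R = np.eye(3)
    R[0, 1] = R[1, 0] = ly * rxg
    R[0, 2] = R[2, 0] = ly * (c + b * rxg)
    R[1, 2] = R[2, 1] = b + c * rxg
    return R


def _y_objective(theta: np.ndarray, S: np.ndarray, c: float) -> float:
    ly, rxg, b = theta
    e_y = 1.0 - (b**2 + c**2 + 2.0 * b * c * rxg)
    if e_y < -1e-10:
        return _PENALTY * (1.0 + e_y**2)
    return _ml_discrepancy(S, _y_implied(ly, rxg, b, c))


def fit_gsens_y(corr: ObservedCorrelations, spec: GsensModelSpec) -> GsensResult:
    """Outcome-PRS-only model on the 3x3 (Sy, X, Y) correlations.

    Just identified: c is fixed at sqrt(h2y); lambda_y solves
    c lambda^2 - (r_SyY - r_SyX r_XY) lambda - c r_SyX^2 = 0 (positive
    root), then rho_xg = r(Sy,X)/lambda_y and b = r(X,Y) - c rho_xg.
    Falls back to constrained numerical minimization when the closed form
    violates a constraint (e.g. b < 0 under the nonnegativity flag).
    Genetic confounding is c * rho_xg: the exposure correlates with the
    outcome's latent genetic factor directly (no exposure PRS is used).
    """
    corr = _check_order(corr, LABELS_Y)
    R = corr.matrix
    r_syx, r_syy, r_xy = R[0, 1], R[0, 2], R[1, 2]
    # note: r(Sy,Y) may legitimately exceed sqrt(h2y) when the causal path
    # b * rho_xg contributes, so no r2-based feasibility precheck here;
    # admissibility is decided by the lambda_y root itself
    c = float(np.sqrt(spec.h2y))
    d = r_syy - r_syx * r_xy
    ly = (d + np.sqrt(d**2 + 4.0 * c**2 * r_syx**2)) / (2.0 * c)
    closed_ok = ly > 1e-9
    if closed_ok:
        rxg = r_syx / ly
        b = r_xy - c * rxg
        closed_ok = ly <= 1.0 + 1e-9 and abs(rxg) <= 1.0 + 1e-9 and (
            b >= -1e-9 or not spec.nonneg_residual
        )
    if closed_ok:
        ly = min(float(ly), 1.0)
        rxg = float(np.clip(rxg, -1.0, 1.0))
        b = float(max(b, 0.0)) if spec.nonneg_residual else float(b)
        F = _ml_discrepancy(R, _y_implied(ly, rxg, b, c))
    else:
        bounds = [(1e-6, 1.0), (-1.0, 1.0), (0.0 if spec.nonneg_residual else -1.5, 1.5)]
        best = None
        for x0 in ([0.5, 0.0, max(r_xy, 0.0)], [0.9, 0.5, 0.1], [0.7, -0.5, 0.1]):
            res = optimize.minimize(
                _y_objective, np.clip(x0, [b_[0] for b_ in bounds], [b_[1] for b_ in bounds]),
                args=(R, c), method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or best.fun >= _PENALTY:
            raise InfeasibleModelError("outcome-only model infeasible")
        ly, rxg, b = (float(v) for v in best.x)
        F = float(best.fun)
    par = GsensParameters(
        lambda_x=float("nan"), lambda_y=ly, rho_g=rxg, b=b, a=1.0, c=c, h2y=spec.h2y
    )
    conf = c * rxg
    total = b + conf
    return GsensResult(
        mode=spec.mode + "_outcome_only",
        total_effect=float(total),
        adjusted_effect=float(b),
        confounding_abs=float(conf),
        confounding_pct=float(100.0 * conf / total) if total != 0 else float("nan"),
        fit_discrepancy=F,
        parameters=par,
    )


def _fit_for(corr: ObservedCorrelations, spec: GsensModelSpec) -> GsensResult:
    if spec.mode == "prs_only":
        return prs_only_adjustment(corr)
    if spec.use_exposure_prs:
        return fit_gsens_xy(corr, spec)
    return fit_gsens_y(corr.subset(LABELS_Y) if set(LABELS_Y) < set(corr.labels) else corr, spec)


@dataclass
class BootstrapCI:
    adjusted_ci: tuple[float, float]
    confounding_pct_ci: tuple[float, float]
    n_infeasible: int
    method: str
    estimates: pd.DataFrame = field(repr=False, default=None)
    unstable: bool = False


def bootstrap_ci(
    data: pd.DataFrame,
    spec: GsensModelSpec,
    B: int = 200,
    seed: int = 0,
) -> BootstrapCI:
    """Nonparametric bootstrap CIs over individuals.

    `data` holds the residualized analysis columns (Sx, Sy, X, Y, or the
    3-variable subset).  Each replicate resamples rows with replacement,
    recomputes the correlation matrix and refits.  Replicates where the
    model is infeasible are dropped and counted; more than 20% infeasible
    flags the interval as unstable.  Percentile 95% intervals.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = substream(seed, "bootstrap")
    n = len(data)
    arr = data.to_numpy(float)
    labels = tuple(data.columns)
    rows = []
    n_bad = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            corr = observed_correlations(arr[idx], labels=labels)
            res = _fit_for(corr, spec)
            rows.append((res.adjusted_effect, res.confounding_pct))
        except (InfeasibleModelError, ValueError):
            n_bad += 1
    if not rows:
        raise InfeasibleModelError("all bootstrap replicates infeasible")
    est = pd.DataFrame(rows, columns=["adjusted_effect", "confounding_pct"])
    unstable = n_bad > 0.2 * B
    if unstable:
        logger.warning("bootstrap: %d/%d replicates infeasible", n_bad, B)
    q = lambda col: tuple(np.percentile(est[col].dropna(), [2.5, 97.5]))
    return BootstrapCI(
        adjusted_ci=q("adjusted_effect"),
        confounding_pct_ci=q("confounding_pct"),
        n_infeasible=n_bad,
        method="nonparametric_bootstrap",
        estimates=est,
        unstable=unstable,
    )


def wishart_ci(
    corr: ObservedCorrelations,
    spec: GsensModelSpec,
    B: int = 200,
    seed: int = 0,
) -> BootstrapCI:
    """Normal-theory Monte-Carlo CIs when only a correlation matrix is known.

    Samples covariance matrices from Wishart(n-1, S/(n-1)), converts each
    to a correlation matrix, and refits; percentile 95% intervals.
    """
    if B < 100:
        raise ValueError("need at least 100 replicates")
    rng = substream(seed, "wishart")
    df = corr.n - 1
    scale = corr.matrix / df
    rows = []
    n_bad = 0
    for _ in range(B):
        W = stats.wishart.rvs(df=df, scale=scale, random_state=rng)
        d = np.sqrt(np.diag(W))
        Rb = W / np.outer(d, d)
        try:
            cb = observed_correlations(Rb, labels=corr.labels, n=corr.n)
            res = _fit_for(cb, spec)
            rows.append((res.adjusted_effect, res.confounding_pct))
        except (InfeasibleModelError, ValueError):
            n_bad += 1
    if not rows:
        raise InfeasibleModelError("all Monte-Carlo replicates infeasible")
    est = pd.DataFrame(rows, columns=["adjusted_effect", "confounding_pct"])
    q = lambda col: tuple(np.percentile(est[col].dropna(), [2.5, 97.5]))
    return BootstrapCI(
        adjusted_ci=q("adjusted_effect"),
        confounding_pct_ci=q("confounding_pct"),
        n_infeasible=n_bad,
        method="wishart_monte_carlo",
        estimates=est,
        unstable=n_bad > 0.2 * B,
    )


@dataclass
class SweepResult:
    """Decomposition along a grid of supplied outcome heritabilities."""

    h2_grid: np.ndarray
    adjusted_effect: np.ndarray
    confounding_pct: np.ndarray
    feasible: np.ndarray
    h2_fully_explained: float  # smallest h2y at which the residual path is ~0
    table: pd.DataFrame = field(repr=False, default=None)


def heritability_sweep(
    corr: ObservedCorrelations,
    h2_grid: np.ndarray,
    spec: GsensModelSpec,
    tol: float = 1e-4,
    refine: bool = True,
) -> SweepResult:
    """Refit across a grid of outcome heritabilities.

    Reports the smallest grid h2y at which the adjusted (residual) effect
    drops to <= tol — the heritability at which genetic confounding would
    fully explain the observed association — refined by bisection between
    the bracketing grid points.  Grid values below the outcome PRS r2 are
    infeasible and marked, not fatal.
    """
    grid = np.sort(np.asarray(h2_grid, dtype=float))
    if np.any((grid <= 0) | (grid > 1)):
        raise ValueError("h2 grid must lie within (0, 1]")

    def _adjusted(h2y: float) -> float:
        return _fit_for(corr, replace(spec, h2y=float(h2y))).adjusted_effect

    adj = np.full(grid.shape, np.nan)
    pct = np.full(grid.shape, np.nan)
    feas = np.zeros(grid.shape, dtype=bool)
    for i, h in enumerate(grid):
        try:
            res = _fit_for(corr, replace(spec, h2y=float(h)))
        except (InfeasibleModelError, ValueError):
            continue
        adj[i], pct[i], feas[i] = res.adjusted_effect, res.confounding_pct, True

    thresh = float("nan")
    hit = np.where(feas & (adj <= tol))[0]
    if hit.size:
        i = hit[0]
        thresh = float(grid[i])
        if refine and i > 0 and feas[i - 1] and adj[i - 1] > tol:
            lo, hi = float(grid[i - 1]), float(grid[i])
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                try:
                    if _adjusted(mid) <= tol:
                        hi = mid
                    else:
                        lo = mid
                except (InfeasibleModelError, ValueError):
                    lo = mid
                if hi - lo < 1e-6:
                    break
            thresh = hi
    table = pd.DataFrame(
        {"h2y": grid, "adjusted_effect": adj, "confounding_pct": pct, "feasible": feas}
    )
    return SweepResult(
        h2_grid=grid, adjusted_effect=adj, confounding_pct=pct, feasible=feas,
        h2_fully_explained=thresh, table=table,
    )
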