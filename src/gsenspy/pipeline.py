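"""End-to-end orchestration of the genetic-confounding analysis.

One configuration drives: cohort simulation (or loading), phenotype
preprocessing, GRM + REML heritability per trait, twin heritability,
polygenic scoring, covariate residualization, correlation assembly, the
three model sets (PRS-only regression adjustment; SEM with SNV-based h2;
SEM with twin-based h2), optional outcome-PRS-only sensitivity fits, and
bootstrap confidence intervals.  Every stage appends a JSON-lines log
record with its seed and output shapes, and re-running the same
configuration reproduces the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gsenspy import io as gio
from gsenspy.grm import compute_grm
from gsenspy.greml import greml_fit
from gsenspy.preprocess import (
    log_transform_scores,
    rank_inverse_normal,
    residualize_and_standardize,
)
from gsenspy.prs import score_prs
from gsenspy.sem import (
    GsensModelSpec,
    bootstrap_ci,
    fit_gsens_xy,
    fit_gsens_y,
    observed_correlations,
    prs_only_adjustment,
)
from gsenspy.simulate import (
    simulate_effect_sizes,
    simulate_genotypes,
    simulate_gwas_sumstats,
    simulate_phenotypes,
    simulate_twin_sample,
    standardized_outcome_h2,
)
from gsenspy.twin import falconer_ace, twin_correlations

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportTable", "run_pipeline", "compare_models"]


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    Simulation defaults mirror the study conditions the pipeline emulates:
    SNV-based heritabilities of 0.08 (exposure), 0.18 (attention-problems
    analogue) and 0.07 (internalizing analogue); twin-based values 0.58,
    0.88 and 0.48 with 216 MZ and 333 DZ twin pairs; residual causal paths
    sized so the total exposure-outcome correlations land near 0.10 and
    0.05.  The discovery-GWAS size is scaled to the simulated variant
    panel so each PRS explains a realistic fraction (well below all) of
    the SNV heritability.
    """

    seed: int = 0
    out_dir: str = "gsens_run"

    # simulation (ignored when a cohort CSV is supplied)
    n_individuals: int = 2000
    n_variants: int = 1000
    maf_range: tuple = (0.05, 0.5)
    h2x: float = 0.08
    h2y_att: float = 0.18
    h2y_int: float = 0.07
    rg_att: float = 0.5
    rg_int: float = 0.5
    b_xy_att: float = 0.04
    b_xy_int: float = 0.01
    n_gwas: int = 5000
    n_mz: int = 216
    n_dz: int = 333
    twin_h2: dict = field(
        default_factory=lambda: {"exposure": 0.58, "att": 0.88, "int": 0.48}
    )
    twin_c2: float = 0.0

    # input files (optional; cohort CSV must already contain PRS columns
    # Sx, Sy_att, Sy_int, and SNV h2 then comes from the h2 fields above)
    cohort_csv: str | None = None
    twin_csvs: dict = field(default_factory=dict)  # trait -> path

    # preprocessing
    covariates: list = field(default_factory=lambda: ["age", "sex", "site"])
    rank_int_exposure: bool = True
    log_outcomes: bool = False

    # models
    models: dict = field(
        default_factory=lambda: {
            "prs_only": True, "snv_h2": True, "twin_h2": True, "outcome_only": False
        }
    )
    heritability_source: str = "estimated"  # "estimated" | "true"
    nonneg_residual: bool = True
    bootstrap_B: int = 0  # 0 disables CIs; else >= 100

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class ReportTable:
    """One row per (outcome, model) with the decomposition and the h2 used."""

    rows: pd.DataFrame


class _StageLog:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.write_text("")

    def record(self, stage: str, **info) -> None:
        logger.info("stage %s: %s", stage, info)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps({"stage": stage, **info}, default=str) + "\n")


def _preprocess(cfg: PipelineConfig, data: pd.DataFrame) -> pd.DataFrame:
    out = data.copy()
    if cfg.rank_int_exposure:
        out["exposure"] = rank_inverse_normal(out["exposure"].to_numpy())
    if cfg.log_outcomes:
        for col in ("outcome_att", "outcome_int"):
            out[col] = log_transform_scores(out[col].to_numpy())
    return out


def _covariate_matrix(data: pd.DataFrame, covariates: list) -> np.ndarray | None:
    cols = []
    for name in covariates:
        if name == "site":
            cols.append(pd.get_dummies(data[name], drop_first=True).to_numpy(float))
        else:
            cols.append(data[name].to_numpy(float).reshape(-1, 1))
    return np.column_stack(cols) if cols else None


def _clip_h2(value: float, prs_r: float, floor: float = 0.01) -> float:
    """Keep a supplied h2 admissible: within (0,1] and >= the PRS's own r2."""
    lo = max(floor, prs_r**2 + 1e-6)
    return float(min(max(value, lo), 1.0))


def _simulate_stage(cfg: PipelineConfig, out: Path, log: _StageLog):
    G = simulate_genotypes(cfg.n_individuals, cfg.n_variants, cfg.maf_range, cfg.seed)
    eff_att = simulate_effect_sizes(
        cfg.n_variants, cfg.h2x, cfg.h2y_att, cfg.rg_att, G.allele_freqs, cfg.seed
    )
    eff_int = simulate_effect_sizes(
        cfg.n_variants, cfg.h2x, cfg.h2y_int, cfg.rg_int, G.allele_freqs,
        cfg.seed + 1, shared_x_from=eff_att,
    )
    cohort = simulate_phenotypes(
        G, eff_att, cfg.b_xy_att, seed=cfg.seed,
        eff_second=eff_int, b_xy_second=cfg.b_xy_int,
    )
    gio.write_cohort_csv(cohort, out / "cohort.csv")
    log.record("simulate", seed=cfg.seed, n=G.n_individuals, m=G.n_variants)

    ss_x = simulate_gwas_sumstats(eff_att, G.allele_freqs, cfg.n_gwas, "x", cfg.seed)
    ss_att = simulate_gwas_sumstats(eff_att, G.allele_freqs, cfg.n_gwas, "y", cfg.seed + 1)
    ss_int = simulate_gwas_sumstats(eff_int, G.allele_freqs, cfg.n_gwas, "y", cfg.seed + 2)
    data = cohort.data.copy()
    data["Sx"] = score_prs(G, ss_x).scores
    data["Sy_att"] = score_prs(G, ss_att).scores
    data["Sy_int"] = score_prs(G, ss_int).scores
    log.record("sumstats_prs", n_gwas=cfg.n_gwas, m=cfg.n_variants)
    return G, data


def _twin_stage(cfg: PipelineConfig, out: Path, log: _StageLog) -> dict:
    twins = {}
    for k, trait in enumerate(("exposure", "att", "int")):
        if trait in cfg.twin_csvs:
            twins[trait] = gio.read_twin_csv(cfg.twin_csvs[trait])
        else:
            twins[trait] = simulate_twin_sample(
                cfg.n_mz, cfg.n_dz, cfg.twin_h2[trait], cfg.twin_c2,
                seed=cfg.seed + 10 + k,
            )
            gio.write_twin_csv(twins[trait], out / f"twins_{trait}.csv")
    log.record("twins", n_mz=twins["exposure"].n_mz, n_dz=twins["exposure"].n_dz)
    return twins


def run_pipeline(cfg: PipelineConfig) -> ReportTable:
    """Execute the full analysis; artifacts land in cfg.out_dir.

    Writes: resolved_config.yaml, stages.jsonl, cohort.csv, twin tables,
    per-outcome correlation summary JSON, and report.csv.  Errors from any
    stage are re-raised with the stage name prefixed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog(out / "stages.jsonl")
    gio.dump_config_yaml(cfg.to_dict(), out / "resolved_config.yaml")

    stage = "simulate"
    try:
        if cfg.cohort_csv is None:
            G, data = _simulate_stage(cfg, out, log)
        else:
            G = None
            data = gio.read_cohort_csv(cfg.cohort_csv).data
            missing = {"Sx", "Sy_att", "Sy_int"} - set(data.columns)
            if missing:
                raise ValueError(f"cohort CSV lacks PRS columns {sorted(missing)}")
            log.record("load", path=cfg.cohort_csv, n=len(data))

        stage = "twins"
        twins = _twin_stage(cfg, out, log)

        stage = "preprocess"
        data = _preprocess(cfg, data)
        log.record(stage, rank_int=cfg.rank_int_exposure, log_outcomes=cfg.log_outcomes)

        stage = "heritability"
        h2: dict = {"snv": {}, "twin": {}}
        if cfg.heritability_source == "estimated" and G is not None:
            grm = compute_grm(G)
            covs = _covariate_matrix(data, cfg.covariates)
            for trait, col in (
                ("exposure", "exposure"), ("att", "outcome_att"), ("int", "outcome_int")
            ):
                h2["snv"][trait] = greml_fit(grm, data[col].to_numpy(), covs).h2
        else:
            # supplied values: the generative truths on the standardized scale
            h2["snv"] = {
                "exposure": cfg.h2x,
                "att": standardized_outcome_h2(cfg.h2x, cfg.h2y_att, cfg.rg_att, cfg.b_xy_att),
                "int": standardized_outcome_h2(cfg.h2x, cfg.h2y_int, cfg.rg_int, cfg.b_xy_int),
            }
        for trait in ("exposure", "att", "int"):
            h2["twin"][trait] = falconer_ace(twin_correlations(twins[trait])).a2
        log.record(
            stage, source=cfg.heritability_source,
            **{f"snv_{k}": round(v, 4) for k, v in h2["snv"].items()},
            **{f"twin_{k}": round(v, 4) for k, v in h2["twin"].items()},
        )

        stage = "correlations"
        corrs, resid_cols = {}, {}
        for outcome, sy_col, y_col in (
            ("att", "Sy_att", "outcome_att"), ("int", "Sy_int", "outcome_int")
        ):
            resid = residualize_and_standardize(
                data, ["Sx", sy_col, "exposure", y_col], cfg.covariates
            )
            resid.columns = ["Sx", "Sy", "X", "Y"]
            resid_cols[outcome] = resid
            corrs[outcome] = observed_correlations(resid)
            gio.write_summary_json(
                corrs[outcome], out / f"correlations_{outcome}.json",
                h2={"snv": h2["snv"][outcome], "twin": h2["twin"][outcome],
                    "snv_exposure": h2["snv"]["exposure"],
                    "twin_exposure": h2["twin"]["exposure"]},
            )
        log.record(stage, n=corrs["att"].n)

        stage = "model_fits"
        rows = []
        for outcome in ("att", "int"):
            corr = corrs[outcome]
            fits: list[tuple[str, object, GsensModelSpec | None]] = []
            if cfg.models.get("prs_only"):
                fits.append(("prs_only", prs_only_adjustment(corr), None))
            for model, src in (("snv_h2", "snv"), ("twin_h2", "twin")):
                if not cfg.models.get(model):
                    continue
                spec = GsensModelSpec(
                    mode=model,
                    h2x=_clip_h2(h2[src]["exposure"], corr.matrix[0, 2]),
                    h2y=_clip_h2(h2[src][outcome], corr.matrix[1, 3]),
                    nonneg_residual=cfg.nonneg_residual,
                )
                fits.append((model, fit_gsens_xy(corr, spec), spec))
                if cfg.models.get("outcome_only"):
                    spec_y = dataclasses.replace(spec, use_exposure_prs=False)
                    fits.append(
                        (model + "_outcome_only",
                         fit_gsens_y(corr.subset(("Sy", "X", "Y")), spec_y), spec_y)
                    )
            for model, res, spec in fits:
                if cfg.bootstrap_B >= 100:
                    bspec = spec if spec is not None else GsensModelSpec(
                        mode="prs_only", h2x=0.5, h2y=0.5
                    )
                    ci = bootstrap_ci(
                        resid_cols[outcome], bspec, B=cfg.bootstrap_B, seed=cfg.seed
                    )
                    res.adjusted_ci = ci.adjusted_ci
                    res.confounding_pct_ci = ci.confounding_pct_ci
                    res.ci_method = ci.method
                    res.n_infeasible_reps = ci.n_infeasible
                    res.ci_unstable = ci.unstable
                rows.append(
                    {
                        "outcome": outcome,
                        "model": model,
                        "total_effect": res.total_effect,
                        "adjusted_effect": res.adjusted_effect,
                        "adjusted_ci_low": res.adjusted_ci[0] if res.adjusted_ci else np.nan,
                        "adjusted_ci_high": res.adjusted_ci[1] if res.adjusted_ci else np.nan,
                        "confounding_abs": res.confounding_abs,
                        "confounding_pct": res.confounding_pct,
                        "confounding_pct_ci_low": res.confounding_pct_ci[0]
                        if res.confounding_pct_ci else np.nan,
                        "confounding_pct_ci_high": res.confounding_pct_ci[1]
                        if res.confounding_pct_ci else np.nan,
                        "h2x_used": spec.h2x if spec else np.nan,
                        "h2y_used": spec.h2y if spec else np.nan,
                        "fit_discrepancy": res.fit_discrepancy,
                        "ci_unstable": res.ci_unstable,
                    }
                )
        report = pd.DataFrame(rows)
        float_cols = report.select_dtypes(float).columns
        report[float_cols] = report[float_cols].round(10)
        report.to_csv(out / "report.csv", index=False)
        log.record(stage, n_rows=len(report))
        return ReportTable(rows=report)
    except Exception as exc:
        raise RuntimeError(
            f"[stage: {stage}] {exc} (check the stage's inputs in resolved_config.yaml)"
        ) from exc


def compare_models(report: ReportTable | pd.DataFrame) -> pd.DataFrame:
    """Per-outcome ordering of confounding percentages across model sets.

    Flags violations of the expected prs_only <= snv_h2 <= twin_h2
    pattern, which should hold whenever the twin h2 supplied is at least
    the SNV h2: correcting the PRS for more measurement error attributes
    more of the association to latent genetics.
    """
    df = report.rows if isinstance(report, ReportTable) else report
    out = []
    order = ["prs_only", "snv_h2", "twin_h2"]
    for outcome, sub in df.groupby("outcome"):
        sub = sub.set_index("model")
        present = [m for m in order if m in sub.index]
        if len(present) < 2:
            continue
        pcts = {m: float(sub.loc[m, "confounding_pct"]) for m in present}
        ranking = sorted(present, key=lambda m: pcts[m])
        out.append(
            {
                "outcome": outcome,
                "expected": " <= ".join(present),
                "observed": " <= ".join(ranking),
                "violated": ranking != present,
                **{f"pct_{m}": pcts[m] for m in present},
            }
        )
    return pd.DataFrame(out)
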