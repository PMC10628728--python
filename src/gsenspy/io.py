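"""Readers and writers for the field's text and binary exchange formats.

- Genotypes: PLINK ``.raw``-style whitespace-delimited text (header
  FID IID PAT MAT SEX PHENOTYPE then one additive-coded column per
  variant, named ``<id>_<allele>``).
- GRM: the GCTA binary triple — ``.grm.bin`` (float32 lower triangle
  including the diagonal, row-major), ``.grm.N.bin`` (float32 number of
  variants per pair), ``.grm.id`` (two-column FID IID text).
- Weight tables: TSV with columns variant_id, effect_allele, weight.
- Cohort and twin-pair tables: CSV with header.
- Model summaries: JSON (labels, correlation matrix, n, h2 values).
- Pipeline configuration: YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gsenspy.grm import GRM
from gsenspy.simulate import CohortTable, GenotypeMatrix, SumStats, TwinSample
from gsenspy.sem import ObservedCorrelations

logger = logging.getLogger(__name__)

__all__ = [
    "write_plink_raw",
    "read_plink_raw",
    "write_grm_gcta",
    "read_grm_gcta",
    "write_weights_tsv",
    "read_weights_tsv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_twin_csv",
    "read_twin_csv",
    "write_summary_json",
    "read_summary_json",
    "load_config_yaml",
    "dump_config_yaml",
]


def write_plink_raw(G: GenotypeMatrix, path: str | Path) -> None:
    cols = {
        "FID": G.individual_ids,
        "IID": G.individual_ids,
        "PAT": 0,
        "MAT": 0,
        "SEX": 0,
        "PHENOTYPE": -9,
    }
    df = pd.DataFrame(cols)
    geno = pd.DataFrame(
        G.dosages, columns=[f"{vid}_A" for vid in G.variant_ids]
    ).reset_index(drop=True)
    pd.concat([df, geno], axis=1).to_csv(path, sep=" ", index=False)


def read_plink_raw(path: str | Path) -> GenotypeMatrix:
    """Read additive-coded text genotypes; allele frequencies from the sample."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    var_cols = [c for c in df.columns if c not in meta]
    dosages = df[var_cols].to_numpy()
    if not np.isin(dosages, (0, 1, 2)).all():
        raise ValueError("dosages outside {0,1,2} (missing values unsupported)")
    p = dosages.mean(axis=0) / 2.0
    p = np.clip(p, 1e-6, 1 - 1e-6)
    variant_ids = [c.rsplit("_", 1)[0] for c in var_cols]
    return GenotypeMatrix(
        dosages=dosages.astype(np.int8),
        allele_freqs=p,
        variant_ids=variant_ids,
        individual_ids=[str(i) for i in df["IID"]],
    )


def write_grm_gcta(grm: GRM, prefix: str | Path) -> None:
    """Write the GCTA triple (.grm.bin, .grm.N.bin, .grm.id)."""
    prefix = str(prefix)
    n = grm.n
    tri = grm.values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    np.full(tri.shape, grm.n_variants_used, dtype="<f4").tofile(prefix + ".grm.N.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for iid in grm.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm_gcta(prefix: str | Path) -> GRM:
    prefix = str(prefix)
    ids = [line.split()[1] for line in open(prefix + ".grm.id")]
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(float)
    if tri.shape[0] != n * (n + 1) // 2:
        raise ValueError("GRM binary length inconsistent with .grm.id")
    A = np.zeros((n, n))
    A[np.tril_indices(n)] = tri
    A = A + np.tril(A, -1).T
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    m = int(counts[0]) if counts.size else 0
    return GRM(values=A, n_variants_used=m, individual_ids=ids)


def write_weights_tsv(w: SumStats, path: str | Path, effect_allele: str = "A") -> None:
    pd.DataFrame(
        {
            "variant_id": w.variant_ids,
            "effect_allele": effect_allele,
            "weight": w.weight,
        }
    ).to_csv(path, sep="\t", index=False)


def read_weights_tsv(
    path: str | Path, trait: str = "x", expected_allele: str = "A"
) -> SumStats:
    """Read a weight table; rows with a mismatched effect allele are dropped."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "effect_allele", "weight"):
        if col not in df.columns:
            raise ValueError(f"weight table missing column {col!r}")
    ok = df["effect_allele"].astype(str) == expected_allele
    if (~ok).any():
        logger.warning("read_weights_tsv: dropped %d allele-mismatched rows", int((~ok).sum()))
    df = df[ok]
    return SumStats(
        variant_ids=[str(v) for v in df["variant_id"]],
        weight=df["weight"].to_numpy(float),
        n_gwas=0,
        trait=trait,
    )


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort.data.to_csv(path, index=True)


def read_cohort_csv(path: str | Path) -> CohortTable:
    return CohortTable(data=pd.read_csv(path, index_col=0), params={})


def write_twin_csv(tw: TwinSample, path: str | Path) -> None:
    tw.pairs.to_csv(path, index=False)


def read_twin_csv(path: str | Path) -> TwinSample:
    df = pd.read_csv(path)
    for col in ("family_id", "zygosity", "pheno1", "pheno2"):
        if col not in df.columns:
            raise ValueError(f"twin table missing column {col!r}")
    return TwinSample(
        pairs=df,
        n_mz=int((df["zygosity"] == "MZ").sum()),
        n_dz=int((df["zygosity"] == "DZ").sum()),
    )


def write_summary_json(
    corr: ObservedCorrelations, path: str | Path, h2: dict | None = None
) -> None:
    payload = {
        "labels": list(corr.labels),
        "matrix": corr.matrix.tolist(),
        "n": corr.n,
        "h2": h2 or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_summary_json(path: str | Path) -> tuple[ObservedCorrelations, dict]:
    payload = json.loads(Path(path).read_text())
    corr = ObservedCorrelations(
        labels=tuple(payload["labels"]),
        matrix=np.asarray(payload["matrix"], dtype=float),
        n=int(payload["n"]),
    )
    return corr, payload.get("h2", {})


def load_config_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_config_yaml(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
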