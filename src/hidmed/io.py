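"""File I/O: dosage matrices (plain TSV or PLINK ``--recode A`` dialect),
phenotype tables, effect-vector TSVs and run manifests.

All artifacts are plain TSV/JSON so every intermediate of a run can be
inspected and diffed.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError
from .regression import EffectVector, RegressionResult
from .simulate import GenotypeMatrix

PLINK_PEDIGREE_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_dosage_matrix(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read an additive dosage matrix.

    ``tsv``: header row of SNP ids, one row per individual.
    ``plink_raw``: the PLINK ``--recode A`` export; pedigree columns are
    dropped and the ``_ALLELE`` suffix is stripped from SNP names.
    Rows containing missing genotypes are rejected with their indices
    reported; entries outside {0, 1, 2} raise a ParseError naming the
    position.
    """
    path = Path(path)
    if dialect not in ("tsv", "plink_raw"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse header/table: {exc}") from exc
    if dialect == "plink_raw":
        drop = [c for c in df.columns if c.upper() in PLINK_PEDIGREE_COLS]
        df = df.drop(columns=drop)
        df.columns = [c.rsplit("_", 1)[0] if "_" in c else c
                      for c in df.columns]
    if df.isna().any(axis=None):
        bad = df.index[df.isna().any(axis=1)].tolist()
        logging.getLogger(__name__).warning(
            "%s: removed %d rows with missing genotypes (indices %s)",
            path, len(bad), bad[:20])
        df = df.dropna()
    values = df.to_numpy()
    invalid = ~np.isin(values, [0, 1, 2])
    if invalid.any():
        i, j = np.argwhere(invalid)[0]
        raise ParseError(
            f"{path}: invalid dosage {values[i, j]!r} at line {i + 2}, "
            f"column {df.columns[j]!r}")
    return GenotypeMatrix(values.astype(np.int8), list(df.columns))


def read_phenotypes(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.isna().any(axis=None):
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing phenotype values in rows {bad}")
    return df


def write_effects(result: RegressionResult, path) -> None:
    """Effects TSV: snp_id, role, estimate, se."""
    result.effects_frame().to_csv(path, sep="\t", index=False)


def read_effect_vector(path, role: str) -> EffectVector:
    df = pd.read_csv(path, sep="\t")
    sub = df[df["role"] == role] if "role" in df.columns else df
    if sub.empty:
        raise ParseError(f"{path}: no rows with role {role!r}")
    se = sub["se"].to_numpy() if "se" in sub.columns else None
    return EffectVector(sub["estimate"].to_numpy(),
                        list(sub["snp_id"]), role, se)


def write_snp_list(result: RegressionResult, snp_ids: list[str], path) -> None:
    """Kept/removed SNP list; removed SNPs carry reason code "O" (outlier)."""
    kept = set(result.kept_snps.tolist())
    rows = [(sid, "kept" if j in kept else "removed",
             "" if j in kept else "O")
            for j, sid in enumerate(snp_ids)]
    pd.DataFrame(rows, columns=["snp_id", "status", "reason"]).to_csv(
        path, sep="\t", index=False)


def write_manifest(path, *, seed, options: dict) -> None:
    import hidmed

    manifest = {
        "package": "hidmed",
        "version": hidmed.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "options": options,
    }
    Path(path).write_text(json.dumps(manifest, indent=1))
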