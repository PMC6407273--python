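"""Readers and writers for every on-disk format the pipeline touches.

Genotypes: PLINK text (.ped/.map) and binary (.bed/.bim/.fam, SNP-major with
the standard magic bytes).  Genotype matrices are additive allele-1 counts
(int8) with −1 for missing — the sentinel is never conflated with homozygous
reference.  Coordinates are 1-based inclusive throughout (PLINK/VCF
convention).

Tabular formats are tab-separated with a header: covariate/phenotype tables,
obstruction labels, per-scan summary statistics, QC reports, LMS coefficient
tables ({sex, age, M, S, L}, one row per age grid point per sex), expression
matrices (probes × subjects) and probe annotation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import MISSING, Cohort
from .reference import LmsReference, SEXES

__all__ = [
    "PlinkFormatError",
    "write_plink_text", "read_plink_text",
    "write_plink_bed", "read_plink_bed",
    "write_covariates", "read_covariates",
    "write_labels", "read_labels",
    "write_summary_stats", "read_summary_stats",
    "write_lms_table", "read_lms_table",
    "write_expression", "read_expression",
    "load_config",
]

BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major

# 2-bit PLINK .bed codes, indexed by allele-1 count (0, 1, 2); missing = 0b01
_BED_CODE_BY_COUNT = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}
_COUNT_BY_BED_CODE = np.full(4, MISSING, dtype=np.int8)
for _cnt, _code in _BED_CODE_BY_COUNT.items():
    _COUNT_BY_BED_CODE[_code] = _cnt


class PlinkFormatError(ValueError):
    pass


def _sex_code(sex: np.ndarray) -> np.ndarray:
    return np.where(sex == "male", 1, 2)


def _fam_frame(cohort: Cohort) -> pd.DataFrame:
    subj = cohort.subjects
    return pd.DataFrame(
        {
            "fid": subj["id"],
            "iid": subj["id"],
            "father": 0,
            "mother": 0,
            "sex": _sex_code(subj["sex"].to_numpy()),
            "phenotype": -9,
        }
    )


def _map_frame(cohort: Cohort) -> pd.DataFrame:
    info = cohort.snp_info
    return pd.DataFrame(
        {
            "chromosome": info["chromosome"],
            "snp_id": info["snp_id"],
            "cm": 0,
            "position": info["position"],
        }
    )


def write_plink_text(cohort: Cohort, prefix) -> None:
    """Write .ped/.map.  Each genotype is an allele pair; missing is '0 0'."""
    prefix = Path(prefix)
    _map_frame(cohort).to_csv(prefix.with_suffix(".map"), sep="\t",
                              header=False, index=False)
    a1 = cohort.snp_info["allele1"].to_numpy()
    a2 = cohort.snp_info["allele2"].to_numpy()
    fam = _fam_frame(cohort)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(cohort.n_subjects):
            fields = [str(fam.iloc[i][c]) for c in fam.columns]
            g = cohort.genotypes[i]
            for j in range(cohort.n_snps):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 2:
                    fields += [a1[j], a1[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write("\t".join(fields) + "\n")


def read_plink_text(prefix) -> Cohort:
    """Read a .ped/.map pair back into a genotype-only cohort.

    Allele-1 (the counted allele) is taken as the first allele seen at each
    SNP; covariates beyond sex are not carried by the format and come back as
    NaN/defaults.
    """
    prefix = Path(prefix)
    map_df = pd.read_csv(
        prefix.with_suffix(".map"), sep="\t", header=None,
        names=["chromosome", "snp_id", "cm", "position"],
    )
    m = len(map_df)
    ids, sexes, rows = [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{prefix.with_suffix('.ped')}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            ids.append(parts[1])
            sexes.append("male" if parts[4] == "1" else "female")
            rows.append(parts[6:])
    alleles1 = [None] * m
    alleles2 = [None] * m
    geno = np.full((len(rows), m), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        for j in range(m):
            x, y = row[2 * j], row[2 * j + 1]
            if x == "0" or y == "0":
                continue
            for al in (x, y):
                if alleles1[j] is None:
                    alleles1[j] = al
                elif al != alleles1[j] and alleles2[j] is None:
                    alleles2[j] = al
            geno[i, j] = (x == alleles1[j]) + (y == alleles1[j])
    snp_info = map_df[["snp_id", "chromosome", "position"]].copy()
    snp_info["allele1"] = [a if a is not None else "0" for a in alleles1]
    snp_info["allele2"] = [a if a is not None else "0" for a in alleles2]
    subjects = _stub_subjects(ids, sexes)
    return Cohort(subjects=subjects, genotypes=geno, snp_info=snp_info)


def _stub_subjects(ids, sexes) -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame(
        {
            "id": ids,
            "sex": sexes,
            "age": np.nan,
            "height": np.nan,
            "smoking_status": "excluded",
            "pack_years": np.nan,
            "current_smoker": False,
            "fev1": np.nan,
            "fvc": np.nan,
        }
    )


def write_plink_bed(cohort: Cohort, prefix) -> None:
    """Write .bed/.bim/.fam (SNP-major binary)."""
    prefix = Path(prefix)
    info = cohort.snp_info
    bim = pd.DataFrame(
        {
            "chromosome": info["chromosome"],
            "snp_id": info["snp_id"],
            "cm": 0,
            "position": info["position"],
            "allele1": info["allele1"],
            "allele2": info["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    _fam_frame(cohort).to_csv(prefix.with_suffix(".fam"), sep="\t",
                              header=False, index=False)

    n = cohort.n_subjects
    n_pad = (-n) % 4
    codes = np.empty((cohort.n_snps, n + n_pad), dtype=np.uint8)
    g = cohort.genotypes.T  # SNP-major
    codes[:, :n] = np.select(
        [g == 2, g == 1, g == 0], [0b00, 0b10, 0b11], default=0b01
    )
    codes[:, n:] = 0b00  # padding bits
    quads = codes.reshape(cohort.n_snps, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink_bed(prefix) -> Cohort:
    """Read a .bed/.bim/.fam triple; validates magic bytes and file length."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep="\t", header=None,
        names=["chromosome", "snp_id", "cm", "position", "allele1", "allele2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep="\t", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3]!r}"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: expected {expected} bytes, got {len(raw)}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    two_bit = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    two_bit[:, 0::4] = body & 0b11
    two_bit[:, 1::4] = (body >> 2) & 0b11
    two_bit[:, 2::4] = (body >> 4) & 0b11
    two_bit[:, 3::4] = (body >> 6) & 0b11
    geno = _COUNT_BY_BED_CODE[two_bit[:, :n]].T.copy()
    subjects = _stub_subjects(
        fam["iid"].astype(str).tolist(),
        ["male" if s == 1 else "female" for s in fam["sex"]],
    )
    snp_info = bim[["snp_id", "chromosome", "position", "allele1", "allele2"]].copy()
    return Cohort(subjects=subjects, genotypes=geno, snp_info=snp_info)


# ---------------------------------------------------------------------------
# tabular formats


def write_covariates(cohort: Cohort, path) -> None:
    cohort.subjects.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_stats(summary, path) -> None:
    """Per-scan summary statistics with scan metadata in '#'-comment header."""
    with open(path, "w") as fh:
        fh.write(f"# definition={summary.spec.definition}\n")
        fh.write(f"# stratum={summary.spec.stratum}\n")
        fh.write(f"# covariates={','.join(summary.spec.resolved_covariates())}\n")
        fh.write(f"# n_cases={summary.n_cases}\n")
        fh.write(f"# n_controls={summary.n_controls}\n")
        fh.write(f"# lambda_gc={summary.lambda_gc:.6f}\n")
        summary.results.to_csv(fh, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_lms_table(reference: LmsReference, path) -> None:
    parts = []
    for sex in SEXES:
        tab = reference.tables[sex].copy()
        tab.insert(0, "sex", sex)
        parts.append(tab)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_lms_table(path, **kwargs) -> LmsReference:
    df = pd.read_csv(path, sep="\t")
    tables = {
        sex: grp[["age", "M", "S", "L"]].sort_values("age").reset_index(drop=True)
        for sex, grp in df.groupby("sex")
    }
    return LmsReference(tables=tables, **kwargs)


def write_expression(expression: pd.DataFrame, annotation: pd.DataFrame,
                     expr_path, annot_path) -> None:
    expression.to_csv(expr_path, sep="\t", index_label="probe_id")
    annotation.to_csv(annot_path, sep="\t", index=False)


def read_expression(expr_path, annot_path):
    expression = pd.read_csv(expr_path, sep="\t", index_col="probe_id")
    annotation = pd.read_csv(annot_path, sep="\t")
    return expression, annotation


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline/simulation configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
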