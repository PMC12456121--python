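"""Readers and writers for genotypes, phenotypes, covariates and kernels.

Genotypes come in as VCF (via cyvcf2) or as a dosage TSV (lines x markers
with a header row of marker IDs); tables travel as CSV/TSV; kernels as
square labelled CSV.  All writers round-trip exactly with their readers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from menvgp.kernels import (
    BLUETable,
    EnvCovariateTable,
    EnvKernel,
    GenotypeMatrix,
    GRM,
    QCReport,
)

logger = logging.getLogger(__name__)

PLOT_COLUMNS = ("env", "rep", "row", "col", "genotype")


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a line x marker dosage matrix from VCF or dosage TSV.

    VCF genotype calls are mapped 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, missing ->
    NaN; multi-allelic records are skipped with a logged count.
    """
    path = Path(path)
    if fmt is None:
        name = path.name.lower()
        fmt = "vcf" if (".vcf" in name or name.endswith(".bcf")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = np.array(vcf.samples)
    marker_ids, columns = [], []
    n_multiallelic = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        dos = np.full(len(line_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            dos[i] = float(a1 + a2)
        vid = variant.ID if variant.ID not in (None, ".") else \
            f"{variant.CHROM}_{variant.POS}"
        marker_ids.append(vid)
        columns.append(dos)
    if n_multiallelic:
        logger.info("skipped %d multi-allelic VCF records", n_multiallelic)
    if not columns:
        raise ValueError(f"no usable biallelic records in {path}")
    G = GenotypeMatrix(
        line_ids=line_ids,
        marker_ids=np.array(marker_ids),
        dosages=np.column_stack(columns),
    )
    G.n_multiallelic_skipped = n_multiallelic
    return G


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        line_ids=df.index.to_numpy(dtype=str),
        marker_ids=df.columns.to_numpy(dtype=str),
        dosages=df.to_numpy(dtype=float),
    )


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    G.to_frame().to_csv(path, sep="\t", index_label="line")


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal single-chromosome VCF for a dosage matrix (inbred-friendly)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.line_ids)) + "\n")
        for j, mid in enumerate(G.marker_ids):
            calls = [gt_map.get(v, "./.") if not np.isnan(v) else "./."
                     for v in G.dosages[:, j]]
            fh.write(f"1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_phenotypes(path, trait: str | None = None) -> pd.DataFrame:
    """Validated plot-level phenotype table.

    Requires columns env, rep, row, col, genotype plus at least one trait
    column; rejects duplicate (env, row, col) plot coordinates and
    non-numeric trait entries, naming the offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    trait_cols = [trait] if trait else [c for c in df.columns
                                        if c not in PLOT_COLUMNS]
    if not trait_cols or any(c not in df.columns for c in trait_cols):
        raise ValueError("no trait column found")
    dup = df.duplicated(subset=["env", "row", "col"], keep=False)
    if dup.any():
        bad = df.index[dup][:5].tolist()
        raise ValueError(f"duplicate (env, row, col) plot coordinates at "
                         f"rows {bad} (0-based, excluding header)")
    for c in trait_cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[numeric.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value in trait column {c!r} at "
                             f"row {bad[0]} (0-based, excluding header)")
        df[c] = numeric
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    return df


def write_phenotypes(plots: pd.DataFrame, path) -> None:
    plots.to_csv(path, index=False)


def read_ecs(path) -> EnvCovariateTable:
    """Environment x covariate CSV with environment row labels."""
    df = pd.read_csv(path, index_col=0)
    return EnvCovariateTable(
        env_ids=df.index.to_numpy(dtype=str),
        covariate_names=df.columns.to_numpy(dtype=str),
        values=df.to_numpy(dtype=float),
    )


def write_ecs(ec: EnvCovariateTable, path) -> None:
    ec.to_frame().to_csv(path, index_label="environment")


def write_kernel(kernel: GRM | EnvKernel, path) -> None:
    kernel.to_frame().to_csv(path)


def read_kernel(path, kind: str = "grm"):
    df = pd.read_csv(path, index_col=0)
    if kind == "grm":
        return GRM(line_ids=df.index.to_numpy(dtype=str), K=df.to_numpy(float))
    return EnvKernel(env_ids=df.index.to_numpy(dtype=str), Omega=df.to_numpy(float))


def write_qc_report(report: QCReport, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


def write_blues(blues: BLUETable, path) -> None:
    blues.values.to_csv(path, index_label="genotype")


def read_blues(path) -> BLUETable:
    df = pd.read_csv(path, index_col=0)
    return BLUETable(values=df)
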