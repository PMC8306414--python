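"""File formats: VCF v4.2, PLINK-style text dosage tables, phenotype TSVs.

Positions are 1-based inclusive (VCF convention) everywhere.  Dosages count
ALT-allele copies; missing calls are ``./.`` in VCF and ``NA`` in text
tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BLOOD_TYPES, GenotypeMatrix

logger = logging.getLogger(__name__)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}

PHENOTYPE_COLUMNS = ["sample_id", "sex", "age", "abo", "sbp", "dbp", "outcome"]


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCF v4.2 with GT calls from ALT dosages."""
    path = Path(path)
    order = np.lexsort(
        (genotypes.snps["pos"].to_numpy(),
         genotypes.snps["chrom"].astype(str).to_numpy())
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=abokit\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids) + "\n"
        )
        for j in order:
            row = genotypes.snps.iloc[j]
            calls = [
                "./." if np.isnan(d) else _GT_STRINGS[int(d)]
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    n_header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosage_rows, meta_rows = [], []
    for i, variant in enumerate(vcf):
        line_no = n_header + i + 1
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}:{line_no}: multi-allelic record "
                f"{variant.ID or variant.POS} (ALT={variant.ALT})"
            )
        # genotypes: [allele_a, allele_b, phased]; -1 codes a missing allele
        row = np.empty(len(sample_ids))
        for s, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            row[s] = np.nan if (a < 0 or b < 0) else float(a + b)
        dosage_rows.append(row)
        meta_rows.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "ref": variant.REF,
                "alt": variant.ALT[0],
            }
        )
    dosages = (
        np.array(dosage_rows).T if dosage_rows
        else np.empty((len(sample_ids), 0))
    )
    return GenotypeMatrix(dosages, sample_ids, pd.DataFrame(
        meta_rows, columns=["snp_id", "chrom", "pos", "ref", "alt"]
    ))


def write_plink_text(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """PLINK-style text dosage table: one SNP per row, one sample per column."""
    df = genotypes.snps[["snp_id", "chrom", "pos", "ref", "alt"]].copy()
    dosage = pd.DataFrame(
        genotypes.dosages.T, columns=genotypes.sample_ids
    )
    pd.concat([df.reset_index(drop=True), dosage], axis=1).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def _read_plink_text(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, sample_ids, df[meta_cols])


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read VCF or PLINK-text genotypes into a dosage matrix.

    Phased (``|``) and unphased (``/``) separators are both accepted;
    ``./.`` becomes a missing dosage; multi-allelic records raise, citing
    the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "plink_text"
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_plink_text(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_phenotypes(samples: pd.DataFrame, path: str | Path) -> None:
    df = samples.rename(columns={"serotype": "abo"})
    cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV with at least sample_id and abo columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "abo"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    bad = df[~df["abo"].isin(BLOOD_TYPES)]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"{path}: invalid abo value {first['abo']!r} for sample "
            f"{first['sample_id']!r} (row {bad.index[0] + 2})"
        )
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def reconcile_samples(
    genotypes: GenotypeMatrix, phenotypes: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame, dict[str, list[str]]]:
    """Align genotype and phenotype tables on sample_id.

    Returns the intersected, genotype-ordered pair plus a report of ids
    present in only one source.
    """
    geno_ids = list(genotypes.sample_ids)
    pheno_ids = list(phenotypes["sample_id"])
    shared = [s for s in geno_ids if s in set(pheno_ids)]
    report = {
        "genotypes_only": sorted(set(geno_ids) - set(pheno_ids)),
        "phenotypes_only": sorted(set(pheno_ids) - set(geno_ids)),
    }
    if report["genotypes_only"] or report["phenotypes_only"]:
        logger.warning(
            "sample reconciliation: %d genotype-only, %d phenotype-only ids",
            len(report["genotypes_only"]), len(report["phenotypes_only"]),
        )
    if not shared:
        raise ValueError("no samples shared between genotypes and phenotypes")
    gm = genotypes.subset_samples(shared)
    ph = (
        phenotypes.set_index("sample_id").loc[shared].reset_index()
    )
    return gm, ph, report


def write_truth_table(cohort, path: str | Path) -> None:
    """Ground-truth TSV: diplotypes plus injected relative pairs."""
    df = pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "diplotype": cohort.diplotypes(),
        }
    )
    pair_of = {}
    for a, b, kind in cohort.relative_pairs:
        pair_of[a] = (b, kind)
        pair_of[b] = (a, kind)
    df["relative_of"] = [
        pair_of.get(s, ("", ""))[0] for s in df["sample_id"]
    ]
    df["relation"] = [pair_of.get(s, ("", ""))[1] for s in df["sample_id"]]
    df.to_csv(path, sep="\t", index=False)


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [
        c for c in ("snp_id", "effect_allele", "other_allele", "beta", "se")
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"{path}: summary table missing columns {missing}")
    return df
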