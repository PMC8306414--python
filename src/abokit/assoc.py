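"""Per-SNP association scans for ABO blood types.

Two parallel formulations over minor-allele (additive) dosages:

* binomial — four dichotomizations of the serotype (O vs. non-O, A vs.
  non-A, B vs. non-B, AB vs. non-AB), each a logistic regression;
* multinomial — one quaternary log-linear model per SNP with type O as the
  reference level, yielding A-vs-O, B-vs-O and AB-vs-O contrasts.

Covariates (sex, age, top principal components) enter both models.  Wald
two-sided p-values; genome-wide screening at a Bonferroni-style alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import fit_logistic, fit_multinomial, wald_p
from .data import BLOOD_TYPES, GenotypeMatrix

logger = logging.getLogger(__name__)

BINARY_CONTRASTS = ["O-vs-nonO", "A-vs-nonA", "B-vs-nonB", "AB-vs-nonAB"]
MULTINOMIAL_CONTRASTS = ["A-vs-O", "B-vs-O", "AB-vs-O"]

RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
    "contrast", "beta", "se", "OR", "p", "neg_log10_p", "n_used", "converged",
]


@dataclass
class AssocResult:
    """One GWAS summary row: a SNP x contrast effect estimate."""

    snp_id: str
    contrast: str
    beta: float
    se: float
    p: float
    n_used: int
    converged: bool
    effect_allele: str = ""
    other_allele: str = ""
    eaf: float = np.nan
    chrom: str = ""
    pos: int = 0

    @property
    def OR(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.beta))

    def as_row(self) -> dict:
        return {
            "snp_id": self.snp_id, "chrom": self.chrom, "pos": self.pos,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele, "eaf": self.eaf,
            "contrast": self.contrast, "beta": self.beta, "se": self.se,
            "OR": self.OR, "p": self.p,
            "neg_log10_p": -math.log10(self.p) if self.p > 0 else np.inf,
            "n_used": self.n_used, "converged": self.converged,
        }


@dataclass
class ScanConfig:
    """Scan-wide settings; alpha is the genome-wide screening threshold."""

    alpha_genomewide: float = 5e-8
    covariates: list[str] = field(default_factory=lambda: ["sex", "age"])
    n_pcs: int = 10
    additive: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_genomewide < 1:
            raise ValueError("alpha_genomewide must be in (0,1)")


def code_additive(
    genotypes: GenotypeMatrix,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Recode dosages as copies of the in-sample minor (effect) allele.

    The major allele is the reference; when ALT frequency exceeds 0.5 the
    dosage is flipped to count REF copies.  An exact 50/50 tie makes the
    lexicographically smaller allele string the effect allele.
    """
    for _, row in genotypes.snps.iterrows():
        if "," in str(row["alt"]):
            raise ValueError(
                f"multi-allelic site {row['snp_id']} (alt={row['alt']!r}) "
                "not supported"
            )
    with np.errstate(invalid="ignore"):
        aaf = np.nanmean(genotypes.dosages, axis=0) / 2.0
    dosages = genotypes.dosages.copy()
    records = []
    for j, (_, row) in enumerate(genotypes.snps.iterrows()):
        ref, alt = str(row["ref"]), str(row["alt"])
        flip = aaf[j] > 0.5 or (aaf[j] == 0.5 and not alt < ref)
        if flip:
            dosages[:, j] = 2.0 - dosages[:, j]
            effect, other, eaf = ref, alt, 1.0 - aaf[j]
        else:
            effect, other, eaf = alt, ref, aaf[j]
        records.append(
            {"snp_id": row["snp_id"], "effect_allele": effect,
             "other_allele": other, "eaf": eaf}
        )
    return dosages, pd.DataFrame(records)


def _design(
    dosage: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-case design matrix [1, dosage, covariates] and its row mask."""
    keep = ~np.isnan(dosage)
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    cols = [np.ones(keep.sum()), dosage[keep]]
    if covariates is not None:
        cols.append(covariates[keep])
    return np.column_stack(cols), keep


def fit_logistic_snp(
    dosage: np.ndarray,
    binary_outcome: np.ndarray,
    covariate_matrix: np.ndarray | None = None,
    snp_id: str = "",
    contrast: str = "",
) -> AssocResult:
    """Logistic association of one SNP with a dichotomized serotype."""
    X, keep = _design(np.asarray(dosage, float), covariate_matrix)
    y = np.asarray(binary_outcome, float)[keep]
    d = X[:, 1]
    if np.nanstd(d) == 0:
        raise ValueError(f"monomorphic dosage for SNP {snp_id or '<unnamed>'}")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    fit = fit_logistic(X, y)
    se = float(np.sqrt(max(fit.cov[1, 1], 0.0)))
    beta = float(fit.beta[1])
    return AssocResult(
        snp_id=snp_id, contrast=contrast, beta=beta, se=se,
        p=wald_p(beta, se), n_used=int(keep.sum()), converged=fit.converged,
    )


def fit_multinomial_snp(
    dosage: np.ndarray,
    serotypes: np.ndarray,
    covariate_matrix: np.ndarray | None = None,
    snp_id: str = "",
) -> list[AssocResult]:
    """Quaternary log-linear association: A-vs-O, B-vs-O, AB-vs-O.

    One joint model per SNP (not three separate logistic fits), with type O
    as the reference level.
    """
    sero = np.asarray(serotypes, dtype=object)
    X, keep = _design(np.asarray(dosage, float), covariate_matrix)
    sero = sero[keep]
    if "O" not in set(sero):
        raise ValueError("reference type O absent from the data")
    if np.nanstd(X[:, 1]) == 0:
        raise ValueError(f"monomorphic dosage for SNP {snp_id or '<unnamed>'}")
    if len(set(sero)) < 2:
        raise ValueError("need at least two serotype levels")
    y_index = np.array([BLOOD_TYPES.index(s) for s in sero])
    fit = fit_multinomial(X, y_index, n_classes=4)
    p_cols = X.shape[1]
    results = []
    for k, contrast in enumerate(MULTINOMIAL_CONTRASTS):
        beta = float(fit.beta[k, 1])
        var = fit.cov[k * p_cols + 1, k * p_cols + 1]
        se = float(np.sqrt(max(var, 0.0)))
        results.append(
            AssocResult(
                snp_id=snp_id, contrast=contrast, beta=beta, se=se,
                p=wald_p(beta, se), n_used=int(keep.sum()),
                converged=fit.converged,
            )
        )
    return results


def _covariate_matrix(
    phenotypes: pd.DataFrame, config: ScanConfig, pcs: np.ndarray | None
) -> np.ndarray | None:
    cols = []
    if "sex" in config.covariates and "sex" in phenotypes.columns:
        cols.append((phenotypes["sex"] == "male").to_numpy(float))
    if "age" in config.covariates and "age" in phenotypes.columns:
        cols.append(phenotypes["age"].to_numpy(float))
    if pcs is not None and config.n_pcs > 0:
        cols.append(pcs[:, : config.n_pcs])
    if not cols:
        return None
    return np.column_stack(cols)


def run_scan(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    mode: str = "binomial",
    config: ScanConfig | None = None,
    pcs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Genome-wide association table over all SNPs.

    Binomial mode fits all four dichotomizations per SNP; multinomial mode
    fits one quaternary model per SNP.  Monomorphic or failing SNPs are
    logged and skipped, never fatal.  Rows are Manhattan-plot ready
    (chrom, pos, -log10 p).
    """
    if mode not in ("binomial", "multinomial"):
        raise ValueError(f"unknown scan mode {mode!r}")
    config = config or ScanConfig()
    if list(phenotypes["sample_id"]) != list(genotypes.sample_ids):
        phenotypes = (
            phenotypes.set_index("sample_id")
            .loc[genotypes.sample_ids]
            .reset_index()
        )
    dosages, alleles = code_additive(genotypes)
    covs = _covariate_matrix(phenotypes, config, pcs)
    sero = phenotypes["abo"] if "abo" in phenotypes.columns else \
        phenotypes["serotype"]
    sero = sero.to_numpy(dtype=object)

    rows = []
    for j in range(genotypes.n_snps):
        meta = genotypes.snps.iloc[j]
        d = dosages[:, j]
        try:
            if mode == "binomial":
                snp_results = []
                for btype, contrast in zip(BLOOD_TYPES, BINARY_CONTRASTS):
                    y = (sero == btype).astype(float)
                    snp_results.append(
                        fit_logistic_snp(
                            d, y, covs, snp_id=meta["snp_id"],
                            contrast=contrast,
                        )
                    )
            else:
                snp_results = fit_multinomial_snp(
                    d, sero, covs, snp_id=meta["snp_id"]
                )
        except ValueError as exc:
            logger.warning("skipping SNP %s: %s", meta["snp_id"], exc)
            continue
        arow = alleles.iloc[j]
        for res in snp_results:
            res.chrom = str(meta["chrom"])
            res.pos = int(meta["pos"])
            res.effect_allele = arow["effect_allele"]
            res.other_allele = arow["other_allele"]
            res.eaf = float(arow["eaf"])
            rows.append(res.as_row())
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def screen_hits(results: pd.DataFrame, alpha: float = 5e-8) -> pd.DataFrame:
    """Rows with p below alpha, sorted ascending by p.

    Ties break by larger |beta|, then by (chrom, pos).
    """
    if len(results) == 0:
        return results.copy()
    hits = results[results["p"] < alpha].copy()
    hits["_absbeta"] = -hits["beta"].abs()
    hits = hits.sort_values(
        ["p", "_absbeta", "chrom", "pos"], kind="mergesort"
    ).drop(columns="_absbeta")
    return hits.reset_index(drop=True)
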