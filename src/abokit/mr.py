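"""Mendelian randomization with ABO tag SNPs as instruments.

Implements the Wald ratio per instrument, the fixed-effect
inverse-variance-weighted (IVW) pooled estimate, and the weighted-median
estimator (consistent when instruments carrying at least half the weight
are valid).  One-sample MR builds the instrument table within a cohort
(logistic SNP -> blood-type-contrast effects, linear or logistic
SNP -> outcome effects); two-sample MR joins and harmonizes two external
summary-statistics tables.

Binary-exposure estimates stay on the log-odds-of-exposure scale; no
rescaling is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import fit_logistic_snp
from .data import BLOOD_TYPES, GenotypeMatrix

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n",
]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class InstrumentRow:
    """Harmonized per-SNP exposure and outcome effects."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str = ""

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(
                f"{self.snp_id}: standard errors must be positive"
            )


@dataclass
class MRResult:
    """A causal estimate from one MR method."""

    method: str
    estimate: float
    se: float
    p: float
    n_instruments: int
    wald_ratios: pd.DataFrame = field(default_factory=pd.DataFrame)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.estimate - z * self.se, self.estimate + z * self.se


def wald_ratio(row: InstrumentRow) -> tuple[float, float]:
    """Per-instrument causal estimate with first-order delta-method SE."""
    if row.beta_exposure == 0:
        raise ValueError(
            f"{row.snp_id}: weak instrument (beta_exposure = 0)"
        )
    ratio = row.beta_outcome / row.beta_exposure
    se = row.se_outcome / abs(row.beta_exposure)
    return ratio, se


def _ratio_table(rows: list[InstrumentRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        ratio, se = wald_ratio(r)
        recs.append({"snp_id": r.snp_id, "ratio": ratio, "se": se})
    return pd.DataFrame(recs)


def ivw(rows: list[InstrumentRow]) -> MRResult:
    """Fixed-effect inverse-variance-weighted pooled Wald ratio."""
    if len(rows) < 1:
        raise ValueError("IVW needs at least one instrument")
    tab = _ratio_table(rows)
    w = 1.0 / tab["se"] ** 2
    estimate = float(np.sum(w * tab["ratio"]) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = estimate / se
    return MRResult(
        method="IVW",
        estimate=estimate,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        n_instruments=len(rows),
        wald_ratios=tab,
    )


def weighted_median(
    rows: list[InstrumentRow],
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratios are ordered ascending; with inverse-variance weights w_j
    standardized to sum 1, the estimate interpolates the ratios at
    cumulative weight 0.5 using the midpoint convention s_j - w_j/2.
    """
    if len(rows) < 2:
        raise ValueError("weighted median needs at least two instruments")
    if len(rows) < 3:
        warnings.warn(
            "weighted median with fewer than 3 instruments is fragile",
            stacklevel=2,
        )
    tab = _ratio_table(rows)
    w = (1.0 / tab["se"] ** 2).to_numpy()
    ratios = tab["ratio"].to_numpy()

    def wm(r: np.ndarray) -> float:
        order = np.argsort(r)
        r_s, w_s = r[order], w[order]
        w_n = w_s / w_s.sum()
        mid = np.cumsum(w_n) - w_n / 2
        return float(np.interp(0.5, mid, r_s))

    estimate = wm(ratios)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    ses = tab["se"].to_numpy()
    for b in range(n_boot):
        draws[b] = wm(rng.normal(ratios, ses))
    se = float(draws.std(ddof=1))
    z = estimate / se if se > 0 else np.inf
    return MRResult(
        method="weighted_median",
        estimate=estimate,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        n_instruments=len(rows),
        wald_ratios=tab,
    )


def _linear_snp_effect(
    dosage: np.ndarray, trait: np.ndarray, covariates: np.ndarray | None
) -> tuple[float, float]:
    keep = ~np.isnan(dosage) & ~np.isnan(trait)
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    cols = [dosage[keep]]
    if covariates is not None:
        cols.append(covariates[keep])
    X = sm.add_constant(np.column_stack(cols))
    res = sm.OLS(trait[keep], X).fit()
    return float(res.params[1]), float(res.bse[1])


def one_sample_mr(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    exposure_contrast: str,
    outcome_trait: str,
    iv_snps: list[str],
    covariates: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MRResult]:
    """One-sample MR of a blood-type contrast on a measured trait.

    ``exposure_contrast`` is a blood type (e.g. ``"B"`` for B vs. non-B).
    Instrument exposure effects come from logistic regression of the
    contrast indicator on each SNP dosage; outcome effects from linear
    regression (continuous trait) or logistic regression (binary trait) on
    the same dosage.  Monomorphic instruments are dropped with a warning.
    """
    if exposure_contrast not in BLOOD_TYPES:
        raise ValueError(f"unknown blood-type contrast {exposure_contrast!r}")
    sero = (
        phenotypes["abo"] if "abo" in phenotypes.columns
        else phenotypes["serotype"]
    ).to_numpy(dtype=object)
    y_exp = (sero == exposure_contrast).astype(float)
    trait = phenotypes[outcome_trait].to_numpy(dtype=float)
    binary_outcome = set(np.unique(trait[~np.isnan(trait)])) <= {0.0, 1.0}

    rows: list[InstrumentRow] = []
    for snp in iv_snps:
        dosage = genotypes.dosage_of(snp)
        if np.nanstd(dosage) == 0:
            warnings.warn(f"instrument {snp} monomorphic; dropped",
                          stacklevel=2)
            continue
        res_exp = fit_logistic_snp(dosage, y_exp, covariates, snp_id=snp,
                                   contrast=exposure_contrast)
        if binary_outcome:
            res_out = fit_logistic_snp(dosage, trait, covariates, snp_id=snp)
            b_out, se_out = res_out.beta, res_out.se
        else:
            b_out, se_out = _linear_snp_effect(dosage, trait, covariates)
        rows.append(
            InstrumentRow(
                snp_id=snp,
                beta_exposure=res_exp.beta,
                se_exposure=res_exp.se,
                beta_outcome=b_out,
                se_outcome=se_out,
            )
        )
    if not rows:
        raise ValueError("no usable instruments")
    out = {"IVW": ivw(rows)}
    if len(rows) >= 2:
        out["weighted_median"] = weighted_median(rows, n_boot=n_boot,
                                                 seed=seed)
    else:
        logger.info("single instrument: weighted median not computed")
    return out


def harmonize(
    exposure: pd.DataFrame, outcome: pd.DataFrame
) -> list[InstrumentRow]:
    """Inner-join two summary tables on snp_id and align effect alleles.

    Outcome rows whose effect/other alleles are swapped relative to the
    exposure get their beta sign flipped; strand-ambiguous (A/T, C/G) SNPs
    and allele-incompatible rows are dropped with a warning.
    """
    merged = exposure.merge(
        outcome, on="snp_id", suffixes=("_exp", "_out"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("no shared SNPs between exposure and outcome tables")
    rows = []
    for _, r in merged.iterrows():
        ea_e, oa_e = str(r["effect_allele_exp"]), str(r["other_allele_exp"])
        ea_o, oa_o = str(r["effect_allele_out"]), str(r["other_allele_out"])
        if frozenset((ea_e, oa_e)) in _PALINDROMIC:
            warnings.warn(
                f"{r['snp_id']}: strand-ambiguous alleles {ea_e}/{oa_e}; "
                "dropped", stacklevel=2,
            )
            continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            b_out = float(r["beta_out"])
        elif (ea_o, oa_o) == (oa_e, ea_e):
            b_out = -float(r["beta_out"])
        else:
            warnings.warn(
                f"{r['snp_id']}: incompatible alleles "
                f"({ea_e}/{oa_e} vs {ea_o}/{oa_o}); dropped", stacklevel=2,
            )
            continue
        rows.append(
            InstrumentRow(
                snp_id=str(r["snp_id"]),
                beta_exposure=float(r["beta_exp"]),
                se_exposure=float(r["se_exp"]),
                beta_outcome=b_out,
                se_outcome=float(r["se_out"]),
                effect_allele=ea_e,
            )
        )
    if not rows:
        raise ValueError("no instruments survive harmonization")
    return rows


def two_sample_mr(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MRResult]:
    """Two-sample MR from external summary statistics."""
    rows = harmonize(exposure_stats, outcome_stats)
    out = {"IVW": ivw(rows)}
    if len(rows) >= 2:
        out["weighted_median"] = weighted_median(rows, n_boot=n_boot,
                                                 seed=seed)
    return out


def results_table(
    results: dict[str, MRResult], contrast: str = ""
) -> pd.DataFrame:
    """Flat output table: contrast, method, estimate, se, p, n_instruments."""
    return pd.DataFrame(
        [
            {
                "contrast": contrast,
                "method": r.method,
                "estimate": r.estimate,
                "se": r.se,
                "p": r.p,
                "n_instruments": r.n_instruments,
            }
            for r in results.values()
        ]
    )
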