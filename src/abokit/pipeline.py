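"""End-to-end orchestration: simulate -> QC -> GWAS -> select -> evaluate -> MR.

Every intermediate table is written as TSV under the output directory, the
resolved value of every parameter is logged, and reruns with the same
configuration are byte-identical on all numeric tables (all randomness
flows from the single root seed via fixed per-stage offsets).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .assoc import ScanConfig, run_scan, screen_hits
from .classify import (
    binary_metrics,
    fit_abo_classifier,
    multiclass_metrics,
    predict_probabilities,
    probability_pattern_table,
    roc_auc,
)
from .config import PipelineConfig
from .data import BLOOD_TYPES
from .ld import find_common_tag, iterative_select, ld_matrix
from .mr import one_sample_mr, results_table
from .qc import compute_pcs, estimate_ibd, filter_call_rate, filter_snps, \
    prune_related
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)

# fixed per-stage offsets from the pipeline root seed
_MR_SEED_OFFSET = 7001


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages, writing artifacts under ``out_dir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulation.rng_seed = config.seed
    logger.info("pipeline parameters: %s", json.dumps(config.to_dict(),
                                                      default=str))
    summary: dict = {"stages": []}

    stage = "simulate"
    try:
        if config.run_simulate:
            cohort = simulate_cohort(config.simulation)
            gm = cohort.genotypes()
            phenotypes = cohort.samples.rename(columns={"serotype": "abo"})
            aio.write_vcf(gm, out / "genotypes.vcf")
            aio.write_phenotypes(cohort.samples, out / "phenotypes.tsv")
            aio.write_truth_table(cohort, out / "truth.tsv")
            summary["n_simulated"] = gm.n_samples
        else:
            gm = aio.read_genotypes(config.genotype_path,
                                    config.genotype_format)
            phenotypes = aio.read_phenotypes(config.phenotype_path)
            gm, phenotypes, recon = aio.reconcile_samples(gm, phenotypes)
            summary["sample_reconciliation"] = recon
        summary["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        raise StageError(stage, exc) from exc

    pcs = None
    stage = "qc"
    try:
        if config.run_qc:
            gm, cr_report = filter_call_rate(
                gm, config.sample_call_rate, config.snp_call_rate
            )
            gm, snp_report = filter_snps(
                gm, config.maf_min, config.hwe_p_threshold
            )
            null_ids = [s for s in gm.snp_ids if s.startswith("null")]
            ibd_gm = gm.subset_snps(null_ids) if len(null_ids) >= 100 else gm
            pihat = estimate_ibd(ibd_gm)
            missingness = {
                sid: 1.0 - cr
                for sid, cr in zip(gm.sample_ids, gm.call_rate_samples())
            }
            retained, rel_report = prune_related(
                pihat, config.pihat_threshold, missingness
            )
            gm = gm.subset_samples(retained)
            phenotypes = (
                phenotypes.set_index("sample_id").loc[retained].reset_index()
            )
            qc_rows = cr_report.as_frame()
            qc_rows.loc[len(qc_rows)] = [
                "n_dropped_relatedness", rel_report.n_dropped_relatedness
            ]
            qc_rows.loc[len(qc_rows)] = ["n_final", gm.n_samples]
            qc_rows.to_csv(out / "qc_report.tsv", sep="\t", index=False)
            if config.k_pcs > 0:
                pcset = compute_pcs(gm, config.k_pcs, config.pca_ld_prune_r2)
                pcs = pcset.scores
                pd.DataFrame(
                    pcs,
                    index=gm.sample_ids,
                    columns=[f"PC{i + 1}" for i in range(config.k_pcs)],
                ).to_csv(out / "pcs.tsv", sep="\t")
            summary["n_retained"] = gm.n_samples
            summary["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    scan_cfg = ScanConfig(
        alpha_genomewide=config.alpha_genomewide,
        covariates=list(config.covariates),
        n_pcs=config.k_pcs,
    )
    hits = None
    stage = "gwas"
    try:
        if config.run_gwas:
            if config.gwas_mode in ("binomial", "both"):
                results_bin = run_scan(gm, phenotypes, "binomial", scan_cfg,
                                       pcs)
                results_bin.to_csv(out / "gwas_binomial.tsv", sep="\t",
                                   index=False, float_format="%.6g")
                hits = screen_hits(results_bin, config.alpha_genomewide)
                hits.to_csv(out / "hits_binomial.tsv", sep="\t", index=False,
                            float_format="%.6g")
                summary["n_hits_binomial"] = int(hits["snp_id"].nunique())
            if config.gwas_mode in ("multinomial", "both"):
                results_multi = run_scan(gm, phenotypes, "multinomial",
                                         scan_cfg, pcs)
                results_multi.to_csv(out / "gwas_multinomial.tsv", sep="\t",
                                     index=False, float_format="%.6g")
                if hits is None:
                    hits = screen_hits(results_multi,
                                       config.alpha_genomewide)
                    hits.to_csv(out / "hits_multinomial.tsv", sep="\t",
                                index=False, float_format="%.6g")
            summary["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    selected: list[str] = []
    stage = "select"
    try:
        if config.run_select and hits is not None and len(hits):
            hit_snps = list(pd.unique(hits["snp_id"]))
            dosage_cols = np.column_stack(
                [gm.dosage_of(s) for s in hit_snps]
            )
            ld = ld_matrix(dosage_cols, hit_snps)
            ld.pairs_table().to_csv(out / "ld_pairs.tsv", sep="\t",
                                    index=False, float_format="%.4f")
            selected = iterative_select(hits, ld, config.r2_threshold)
            pvals = hits.groupby("snp_id")["p"].min().to_dict()
            selected = find_common_tag(
                selected, hit_snps, ld,
                config.common_tag_high_r2, config.common_tag_low_r2, pvals,
            )
            (out / "selected_snps.txt").write_text(
                "\n".join(selected) + "\n"
            )
            summary["selected_snps"] = selected
            summary["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "evaluate"
    try:
        eval_set = list(config.eval_snp_set) or selected
        if config.run_evaluate and eval_set:
            X = np.column_stack([gm.dosage_of(s) for s in eval_set])
            keep = ~np.isnan(X).any(axis=1)
            X = X[keep]
            sero = phenotypes.loc[keep, "abo"].to_numpy(dtype=object)
            model = fit_abo_classifier(X, sero, ridge=config.ridge,
                                       snp_ids=eval_set)
            proba = predict_probabilities(model, X)
            report = multiclass_metrics(
                proba[["pO", "pA", "pB", "pAB"]].to_numpy(), sero,
                model.prevalences_,
            )
            report.confusion.to_csv(out / "confusion.tsv", sep="\t")
            rows = []
            for i, t in enumerate(BLOOD_TYPES):
                truth = sero == t
                bm = binary_metrics(
                    proba.iloc[:, i].to_numpy(), truth,
                    model.prevalences_[t],
                )
                auc, curve = roc_auc(proba.iloc[:, i].to_numpy(), truth)
                curve.to_csv(out / f"roc_{t}.tsv", sep="\t", index=False,
                             float_format="%.6g")
                rows.append(
                    {"set": "+".join(eval_set), "type": t,
                     "accuracy": bm["accuracy"],
                     "sensitivity": bm["sensitivity"],
                     "specificity": bm["specificity"], "ppv": bm["ppv"],
                     "npv": bm["npv"], "f1": bm["f1"], "auc": auc}
                )
            pd.DataFrame(rows).to_csv(out / "binary_metrics.tsv", sep="\t",
                                      index=False, float_format="%.4f")
            probability_pattern_table(model, X).to_csv(
                out / "probability_patterns.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            summary["accuracy"] = report.accuracy
            summary["f1_micro"] = report.f1_micro
            summary["f1_macro"] = report.f1_macro
            summary["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "mr"
    try:
        iv_snps = list(config.mr_iv_snps) or selected
        if config.run_mr and iv_snps:
            tables = []
            for trait in config.mr_outcome_traits:
                res = one_sample_mr(
                    gm, phenotypes, config.mr_exposure_contrast, trait,
                    iv_snps, n_boot=config.mr_bootstrap_draws,
                    seed=(config.seed + _MR_SEED_OFFSET) % 2**31,
                )
                tab = results_table(
                    res, contrast=f"{config.mr_exposure_contrast}-vs-non"
                             f"{config.mr_exposure_contrast}",
                )
                tab.insert(0, "outcome", trait)
                tables.append(tab)
            mr_out = pd.concat(tables, ignore_index=True)
            mr_out.to_csv(out / "mr_results.tsv", sep="\t", index=False,
                          float_format="%.6g")
            summary["mr"] = mr_out.to_dict(orient="records")
            summary["stages"].append(stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
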