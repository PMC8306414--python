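"""Pipeline configuration with lossless YAML round-trips.

Every parameter has a default equal to the corresponding module-level
default; the resolved values of all parameters are logged when a pipeline
runs, so no default is ever silent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import AlleleSystem, SimulationConfig, TagSNPSpec


@dataclass
class PipelineConfig:
    """Stage toggles plus every per-module parameter."""

    seed: int = 2021
    # stage toggles
    run_simulate: bool = True
    run_qc: bool = True
    run_gwas: bool = True
    run_select: bool = True
    run_evaluate: bool = True
    run_mr: bool = True
    # inputs (used when run_simulate is off)
    genotype_path: str = ""
    genotype_format: str = "vcf"
    phenotype_path: str = ""
    # simulation
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # qc
    sample_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_p_threshold: float = 1e-6
    pihat_threshold: float = 0.1875
    k_pcs: int = 10
    pca_ld_prune_r2: float = 0.2
    # association scan
    alpha_genomewide: float = 5e-8
    covariates: list[str] = field(default_factory=lambda: ["sex", "age"])
    gwas_mode: str = "both"  # binomial | multinomial | both
    # selection
    r2_threshold: float = 0.8
    common_tag_high_r2: float = 0.9
    common_tag_low_r2: float = 0.8
    # prediction
    ridge: float = 1e-4
    eval_snp_set: list[str] = field(default_factory=list)  # empty: selected
    # MR
    mr_exposure_contrast: str = "B"
    mr_outcome_traits: list[str] = field(
        default_factory=lambda: ["sbp", "dbp"]
    )
    mr_iv_snps: list[str] = field(default_factory=list)
    mr_bootstrap_draws: int = 1000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        sim["allele_system"] = list(
            self.simulation.allele_system.as_tuple()
        )
        sim["tag_specs"] = [
            dataclasses.asdict(s) for s in self.simulation.tag_specs
        ]
        sim["null_maf_range"] = list(self.simulation.null_maf_range)
        sim["age_range"] = list(self.simulation.age_range)
        sim["causal_effects"] = {
            k: list(v) for k, v in self.simulation.causal_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "allele_system" in sim:
            sim["allele_system"] = AlleleSystem(*sim["allele_system"])
        if "tag_specs" in sim and sim["tag_specs"] is not None:
            sim["tag_specs"] = [TagSNPSpec(**s) for s in sim["tag_specs"]]
        if "null_maf_range" in sim:
            sim["null_maf_range"] = tuple(sim["null_maf_range"])
        if "age_range" in sim:
            sim["age_range"] = tuple(sim["age_range"])
        if "causal_effects" in sim:
            sim["causal_effects"] = {
                k: (v[0], float(v[1]))
                for k, v in (sim["causal_effects"] or {}).items()
            }
        return cls(simulation=SimulationConfig(**sim), **d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
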