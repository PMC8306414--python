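"""Synthetic ABO cohort generator.

Simulates the genetic architecture of the ABO blood-group system at the
haplotype level: each haplotype carries one of the three classical
functional alleles (O, A, B), plus allele bits for "tag" SNPs held at a
target linkage disequilibrium (r-squared) with a chosen functional-allele
indicator.  Serological blood type follows Mendelian dominance (O recessive,
A and B codominant), optionally corrupted by a typing-error rate.  A
genome-wide background of null SNPs, sex/age covariates, blood-pressure
traits with configurable causal effects, and deliberate QC contaminants
(duplicate pairs, sib pairs, low-call-rate samples) complete the cohort.

LD is induced by the D-parameterization: for anchor-indicator frequency p
and tag-allele frequency q, the haplotype-level covariance is set to
``D = sign * sqrt(r2 * p(1-p) q(1-q))``, i.e. ``P(tag=1 | anchor=1) = q + D/p``,
so the target r-squared is exact in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BLOOD_TYPES, Cohort

FUNCTIONAL_ALLELES = ("O", "A", "B")

# fixed per-stage offsets from the root seed, so stages are independently
# reproducible
_SEED_OFFSETS = {
    "haplotypes": 11,
    "tags": 23,
    "null": 37,
    "relatives": 41,
    "serotype": 53,
    "covariates": 61,
    "traits": 71,
    "missing": 83,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng((int(seed) + _SEED_OFFSETS[stage]) % 2**31)


@dataclass(frozen=True)
class AlleleSystem:
    """Population frequencies of the three classical ABO haplotype alleles."""

    freq_O: float = 0.55
    freq_A: float = 0.22
    freq_B: float = 0.23

    def __post_init__(self) -> None:
        freqs = (self.freq_O, self.freq_A, self.freq_B)
        if any(f < 0 or f > 1 for f in freqs):
            raise ValueError(f"allele frequencies must be in [0,1]: {freqs}")
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise ValueError(
                f"allele frequencies must sum to 1 (got {sum(freqs)!r})"
            )

    def freq_of(self, allele: str) -> float:
        return {"O": self.freq_O, "A": self.freq_A, "B": self.freq_B}[allele]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.freq_O, self.freq_A, self.freq_B)


def max_r2(p: float, q: float, sign: int = 1) -> float:
    """Largest attainable r-squared between indicators of frequency p and q."""
    if sign >= 0:
        d_max = min(p * (1 - q), q * (1 - p))
    else:
        d_max = min(p * q, (1 - p) * (1 - q))
    return d_max**2 / (p * (1 - p) * q * (1 - q))


@dataclass(frozen=True)
class TagSNPSpec:
    """A tag SNP held at a target haplotype r-squared with an anchor allele.

    ``anchor`` names the functional allele whose indicator the tag tracks
    (``None`` for an unlinked SNP); ``tag_allele_freq`` is the population
    frequency of the tag (ALT) allele; ``sign`` orients D.
    """

    snp_id: str
    anchor: str | None
    tag_allele_freq: float
    target_r2: float
    sign: int = 1
    chrom: str = "9"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if self.anchor is not None and self.anchor not in FUNCTIONAL_ALLELES:
            raise ValueError(f"unknown anchor allele {self.anchor!r}")
        if not 0 < self.tag_allele_freq < 1:
            raise ValueError("tag_allele_freq must be in (0,1)")
        if not 0 <= self.target_r2 <= 1:
            raise ValueError("target_r2 must be in [0,1]")

    def check_feasible(self, anchor_freq: float) -> None:
        """Raise if the target r-squared is unattainable at these frequencies."""
        if self.anchor is None:
            return
        p, q = anchor_freq, self.tag_allele_freq
        r2_cap = max_r2(p, q, self.sign)
        if self.target_r2 > r2_cap + 1e-12:
            d_max = math.sqrt(r2_cap * p * (1 - p) * q * (1 - q))
            raise ValueError(
                f"{self.snp_id}: target r2={self.target_r2} infeasible for "
                f"anchor freq p={p}, tag freq q={q}; D_max={d_max:.6g} "
                f"caps r2 at {r2_cap:.6g}"
            )


@dataclass
class HaplotypeSet:
    """Per-haplotype functional alleles and tag-SNP allele bits."""

    functional: np.ndarray                 # (n_haplotypes,) of "O"/"A"/"B"
    allele_system: AlleleSystem
    tag_bits: dict[str, np.ndarray] = field(default_factory=dict)
    tag_specs: list[TagSNPSpec] = field(default_factory=list)

    @property
    def n_haplotypes(self) -> int:
        return len(self.functional)


def sample_abo_haplotypes(
    n_haplotypes: int, allele_system: AlleleSystem, seed: int
) -> HaplotypeSet:
    """Draw i.i.d. functional ABO alleles for an even number of haplotypes."""
    if n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even (haplotypes pair into "
                         "individuals)")
    rng = np.random.default_rng(seed)
    functional = rng.choice(
        np.array(FUNCTIONAL_ALLELES),
        size=n_haplotypes,
        p=list(allele_system.as_tuple()),
    )
    return HaplotypeSet(functional=functional, allele_system=allele_system)


def _conditional_tag_probs(
    p: float, q: float, target_r2: float, sign: int
) -> tuple[float, float]:
    """P(tag=1 | anchor=1) and P(tag=1 | anchor=0) under the D-model."""
    d = sign * math.sqrt(target_r2 * p * (1 - p) * q * (1 - q))
    p1 = q + d / p
    p0 = q - d / (1 - p)
    # guard float round-off at the feasibility boundary
    return min(max(p1, 0.0), 1.0), min(max(p0, 0.0), 1.0)


def attach_tag_snp(
    haplotypes: HaplotypeSet, spec: TagSNPSpec, seed: int
) -> HaplotypeSet:
    """Return a copy of ``haplotypes`` with allele bits for one tag SNP."""
    n = haplotypes.n_haplotypes
    rng = np.random.default_rng(seed)
    if spec.anchor is None:
        bits = (rng.random(n) < spec.tag_allele_freq).astype(np.uint8)
    else:
        p = haplotypes.allele_system.freq_of(spec.anchor)
        spec.check_feasible(p)
        p1, p0 = _conditional_tag_probs(
            p, spec.tag_allele_freq, spec.target_r2, spec.sign
        )
        anchor_ind = haplotypes.functional == spec.anchor
        u = rng.random(n)
        bits = np.where(anchor_ind, u < p1, u < p0).astype(np.uint8)
    new_bits = dict(haplotypes.tag_bits)
    new_bits[spec.snp_id] = bits
    return HaplotypeSet(
        functional=haplotypes.functional.copy(),
        allele_system=haplotypes.allele_system,
        tag_bits=new_bits,
        tag_specs=list(haplotypes.tag_specs) + [spec],
    )


def serotype(
    diplotype: tuple[str, str],
    typing_error_rate: float = 0.0,
    seed: int | None = None,
) -> str:
    """Serological blood type of a functional-allele pair.

    O is recessive; A and B are codominant.  With probability
    ``typing_error_rate`` the recorded type is a uniform draw from the other
    three types (an error model for serological misclassification).
    """
    a1, a2 = diplotype
    if a1 not in FUNCTIONAL_ALLELES or a2 not in FUNCTIONAL_ALLELES:
        raise ValueError(f"unknown functional alleles {diplotype!r}")
    alleles = {a1, a2}
    if alleles == {"O"}:
        true_type = "O"
    elif alleles == {"A", "B"}:
        true_type = "AB"
    elif "A" in alleles:
        true_type = "A"
    else:
        true_type = "B"
    if typing_error_rate > 0:
        rng = np.random.default_rng(seed)
        if rng.random() < typing_error_rate:
            others = [t for t in BLOOD_TYPES if t != true_type]
            return others[rng.integers(3)]
    return true_type


def _serotype_vector(
    functional: np.ndarray, typing_error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized serotyping of an (n, 2) functional-allele array."""
    has_a = np.any(functional == "A", axis=1)
    has_b = np.any(functional == "B", axis=1)
    types = np.full(functional.shape[0], "O", dtype=object)
    types[has_a & ~has_b] = "A"
    types[has_b & ~has_a] = "B"
    types[has_a & has_b] = "AB"
    if typing_error_rate > 0:
        flip = rng.random(len(types)) < typing_error_rate
        for i in np.flatnonzero(flip):
            others = [t for t in BLOOD_TYPES if t != types[i]]
            types[i] = others[rng.integers(3)]
    return types


def simulate_null_haplotypes(
    n_samples: int,
    n_null_snps: int,
    maf_range: tuple[float, float],
    seed: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Haplotype bits and metadata for independent genome-wide null SNPs."""
    lo, hi = maf_range
    if n_null_snps and not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5]: {maf_range}")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_null_snps)
    haps = (
        rng.random((n_samples, n_null_snps, 2)) < mafs[None, :, None]
    ).astype(np.uint8)
    chroms = [str(1 + (i % 22)) for i in range(n_null_snps)]
    allele_pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    meta = pd.DataFrame(
        {
            "snp_id": [f"null{i:06d}" for i in range(n_null_snps)],
            "chrom": chroms,
            "pos": [1_000_000 + 1_000 * (i // 22) for i in range(n_null_snps)],
            "ref": [allele_pairs[i % 4][0] for i in range(n_null_snps)],
            "alt": [allele_pairs[i % 4][1] for i in range(n_null_snps)],
            "maf": mafs,
        }
    )
    return haps, meta


def simulate_null_genome(
    n_samples: int,
    n_null_snps: int,
    maf_range: tuple[float, float],
    seed: int,
):
    """Genotype dosages for null SNPs independent of serotype."""
    from .data import GenotypeMatrix

    haps, meta = simulate_null_haplotypes(
        n_samples, n_null_snps, maf_range, seed
    )
    dosages = haps.sum(axis=2).astype(float)
    sample_ids = [f"S{i + 1:05d}" for i in range(n_samples)]
    return GenotypeMatrix(dosages, sample_ids, meta)


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator, with study-like defaults.

    The default allele frequencies give a type distribution qualitatively
    similar to East-Asian cohorts; they are configuration, not estimates.
    The default tag panel mirrors a functional O-determining indel tagged
    redundantly by two intronic SNPs, plus one A-tag and one B-tag.
    """

    n_samples: int = 1008
    allele_system: AlleleSystem = field(default_factory=AlleleSystem)
    tag_specs: list[TagSNPSpec] | None = None
    n_null_snps: int = 2000
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    # ~2% serology/genotype discordance, the order observed when serological
    # types are checked against genetic predictions; also keeps the perfect
    # tags from completely separating the association fits
    typing_error_rate: float = 0.02
    n_duplicate_pairs: int = 5
    n_sib_pairs: int = 10
    causal_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    genotype_missing_rate: float = 0.001
    n_low_callrate_samples: int = 1
    low_callrate_missing_rate: float = 0.10
    # trait model parameters (mmHg scales; age centred at 50 years)
    sbp_mean: float = 125.0
    sbp_sd: float = 12.0
    sbp_age_coef: float = 0.5
    sbp_male_shift: float = 4.0
    dbp_mean: float = 78.0
    dbp_sd: float = 8.0
    dbp_age_coef: float = 0.25
    dbp_male_shift: float = 3.0
    outcome_logit_intercept: float = -2.0
    age_range: tuple[float, float] = (30.0, 70.0)
    rng_seed: int = 2021

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 <= self.typing_error_rate < 1:
            raise ValueError("typing_error_rate must be in [0,1)")
        if self.tag_specs is None:
            self.tag_specs = default_tag_specs(self.allele_system)


def default_tag_specs(allele_system: AlleleSystem) -> list[TagSNPSpec]:
    """The default ABO-locus panel: three perfect anchor tags plus two
    redundant O-tags in high (but imperfect) LD with the functional indel."""
    fo, fa, fb = allele_system.as_tuple()
    return [
        TagSNPSpec("rs8176719", "O", fo, 1.00, chrom="9",
                   pos=133_257_521, ref="TC", alt="T"),
        TagSNPSpec("rs529565", "O", fo, 0.95, chrom="9",
                   pos=133_271_182, ref="T", alt="C"),
        TagSNPSpec("rs687289", "O", fo, 0.98, chrom="9",
                   pos=133_266_456, ref="G", alt="A"),
        TagSNPSpec("rs635634", "A", fa, 1.00, chrom="9",
                   pos=133_279_427, ref="C", alt="T"),
        TagSNPSpec("rs7030248", "B", fb, 1.00, chrom="9",
                   pos=133_271_798, ref="T", alt="G"),
    ]


def noiseless_three_tag_config(
    n_samples: int = 921,
    rng_seed: int = 2021,
    allele_system: AlleleSystem | None = None,
) -> SimulationConfig:
    """Idealized cohort: three perfect anchor tags, zero typing error.

    Serotype is then a deterministic Mendelian function of the three tag
    dosages, so classification performance bounds are exact.  No relatives,
    no missingness, no null background.
    """
    allele_system = allele_system or AlleleSystem()
    fo, fa, fb = allele_system.as_tuple()
    specs = [
        TagSNPSpec("rs8176719", "O", fo, 1.0, chrom="9",
                   pos=133_257_521, ref="TC", alt="T"),
        TagSNPSpec("rs635634", "A", fa, 1.0, chrom="9",
                   pos=133_279_427, ref="C", alt="T"),
        TagSNPSpec("rs7030248", "B", fb, 1.0, chrom="9",
                   pos=133_271_798, ref="T", alt="G"),
    ]
    return SimulationConfig(
        n_samples=n_samples,
        allele_system=allele_system,
        tag_specs=specs,
        n_null_snps=0,
        typing_error_rate=0.0,
        n_duplicate_pairs=0,
        n_sib_pairs=0,
        genotype_missing_rate=0.0,
        n_low_callrate_samples=0,
        rng_seed=rng_seed,
    )


def _tag_meta(specs: list[TagSNPSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in specs],
            "chrom": [s.chrom for s in specs],
            "pos": [s.pos for s in specs],
            "ref": [s.ref for s in specs],
            "alt": [s.alt for s in specs],
            "anchor": [s.anchor for s in specs],
            "target_r2": [s.target_r2 for s in specs],
        }
    )


def _simulate_parent_haplotypes(
    allele_system: AlleleSystem,
    tag_specs: list[TagSNPSpec],
    null_mafs: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Two fresh population haplotypes (one parent)."""
    functional = rng.choice(
        np.array(FUNCTIONAL_ALLELES), size=2, p=list(allele_system.as_tuple())
    )
    tag = {}
    for spec in tag_specs:
        if spec.anchor is None:
            tag[spec.snp_id] = (rng.random(2) < spec.tag_allele_freq).astype(
                np.uint8
            )
        else:
            p = allele_system.freq_of(spec.anchor)
            p1, p0 = _conditional_tag_probs(
                p, spec.tag_allele_freq, spec.target_r2, spec.sign
            )
            u = rng.random(2)
            tag[spec.snp_id] = np.where(
                functional == spec.anchor, u < p1, u < p0
            ).astype(np.uint8)
    null = (rng.random((len(null_mafs), 2)) < null_mafs[:, None]).astype(
        np.uint8
    )
    return functional, tag, null


def inject_relatives(
    cohort: Cohort,
    n_duplicate_pairs: int,
    n_sib_pairs: int,
    seed: int,
) -> Cohort:
    """Append duplicate and full-sib pairs with recorded ground truth.

    Duplicates copy both haplotypes of a random existing sample.  Sibs are
    generated by Mendelian transmission from two fresh simulated parents:
    the ABO locus (functional allele + tag SNPs) is transmitted as one
    block, null SNPs independently (free recombination genome-wide).
    """
    if n_duplicate_pairs == 0 and n_sib_pairs == 0:
        return cohort
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    if n_duplicate_pairs > n:
        raise ValueError("not enough samples to duplicate")

    functional = [cohort.functional]
    tag_haps = {k: [v] for k, v in cohort.tag_haps.items()}
    null_haps = [cohort.null_haps]
    new_ids: list[str] = []
    pairs = list(cohort.relative_pairs)
    tag_ids = list(cohort.tag_snps["snp_id"])
    n_null = cohort.null_haps.shape[1]

    donor_idx = rng.choice(n, size=n_duplicate_pairs, replace=False)
    for j, di in enumerate(donor_idx):
        dup_id = f"DUP{j + 1:04d}"
        functional.append(cohort.functional[[di]])
        for t in tag_ids:
            tag_haps[t].append(cohort.tag_haps[t][[di]])
        null_haps.append(cohort.null_haps[[di]])
        new_ids.append(dup_id)
        pairs.append((cohort.sample_ids[di], dup_id, "duplicate"))

    allele_system = getattr(cohort, "allele_system", None)
    if allele_system is None:
        allele_system = AlleleSystem()
    null_mafs = cohort.null_snps["maf"].to_numpy() if "maf" in cohort.null_snps \
        else np.full(n_null, 0.25)
    tag_specs = getattr(cohort, "tag_specs", None) or []

    for j in range(n_sib_pairs):
        parents = [
            _simulate_parent_haplotypes(
                allele_system, tag_specs, null_mafs, rng
            )
            for _ in range(2)
        ]
        sib_ids = (f"SIB{j + 1:04d}A", f"SIB{j + 1:04d}B")
        for sid in sib_ids:
            # one whole-block choice per parent at the ABO locus
            locus_pick = rng.integers(2, size=2)
            func = np.array(
                [parents[k][0][locus_pick[k]] for k in range(2)], dtype=object
            )
            functional.append(func[None, :])
            for t in tag_ids:
                bits = np.array(
                    [parents[k][1][t][locus_pick[k]] for k in range(2)],
                    dtype=np.uint8,
                )
                tag_haps[t].append(bits[None, :])
            # independent transmission per null SNP
            null_pick = rng.integers(2, size=(n_null, 2))
            child_null = np.stack(
                [
                    parents[0][2][np.arange(n_null), null_pick[:, 0]],
                    parents[1][2][np.arange(n_null), null_pick[:, 1]],
                ],
                axis=1,
            ).astype(np.uint8)
            null_haps.append(child_null[None, :, :])
            new_ids.append(sid)
        pairs.append((sib_ids[0], sib_ids[1], "sib"))

    samples = pd.concat(
        [
            cohort.samples,
            pd.DataFrame({"sample_id": new_ids}),
        ],
        ignore_index=True,
    )
    out = Cohort(
        functional=np.concatenate(functional, axis=0),
        tag_haps={k: np.concatenate(v, axis=0) for k, v in tag_haps.items()},
        tag_snps=cohort.tag_snps,
        null_haps=np.concatenate(null_haps, axis=0),
        null_snps=cohort.null_snps,
        samples=samples,
        relative_pairs=pairs,
    )
    out.allele_system = allele_system  # type: ignore[attr-defined]
    out.tag_specs = tag_specs  # type: ignore[attr-defined]
    return out


def simulate_traits(
    cohort: Cohort,
    causal_effects: dict[str, tuple[str, float]],
    seed: int,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Sex, age, blood pressures and an optional binary outcome.

    ``causal_effects`` maps a trait name (``sbp``, ``dbp``, ``outcome``) to
    a ``(blood_type, effect)`` pair: an additive shift (mmHg) for carriers
    of that serotype for the pressure traits, a log-odds shift for the
    binary outcome.  Zero effects give traits independent of serotype.
    """
    cfg = config or SimulationConfig(n_samples=cohort.n_samples)
    if "serotype" not in cohort.samples.columns:
        raise ValueError("cohort has no serotypes; serotype it first")
    for trait, (contrast, _) in causal_effects.items():
        if trait not in ("sbp", "dbp", "outcome"):
            raise ValueError(f"unknown trait {trait!r}")
        if contrast not in BLOOD_TYPES:
            raise ValueError(f"unknown blood-type contrast {contrast!r}")
    rng = np.random.default_rng(seed)
    n = cohort.n_samples
    df = cohort.samples.copy()
    sero = df["serotype"].to_numpy()
    male = (df["sex"] == "male").to_numpy()
    age_c = df["age"].to_numpy() - 50.0

    def shift(trait: str) -> np.ndarray:
        if trait in causal_effects:
            ctype, eff = causal_effects[trait]
            return np.where(sero == ctype, eff, 0.0)
        return np.zeros(n)

    df["sbp"] = (
        cfg.sbp_mean
        + cfg.sbp_age_coef * age_c
        + cfg.sbp_male_shift * male
        + shift("sbp")
        + rng.normal(0, cfg.sbp_sd, n)
    )
    df["dbp"] = (
        cfg.dbp_mean
        + cfg.dbp_age_coef * age_c
        + cfg.dbp_male_shift * male
        + shift("dbp")
        + rng.normal(0, cfg.dbp_sd, n)
    )
    logit = cfg.outcome_logit_intercept + shift("outcome")
    df["outcome"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    return df


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """End-to-end cohort generation under one root seed."""
    seed = config.rng_seed
    n = config.n_samples
    haps = sample_abo_haplotypes(
        2 * n, config.allele_system, (seed + _SEED_OFFSETS["haplotypes"]) % 2**31
    )
    for i, spec in enumerate(config.tag_specs):
        haps = attach_tag_snp(
            haps, spec, (seed + _SEED_OFFSETS["tags"] + 101 * i) % 2**31
        )
    functional = haps.functional.reshape(n, 2).astype(object)
    tag_haps = {
        sid: bits.reshape(n, 2) for sid, bits in haps.tag_bits.items()
    }
    null_haps, null_meta = simulate_null_haplotypes(
        n, config.n_null_snps, config.null_maf_range,
        (seed + _SEED_OFFSETS["null"]) % 2**31,
    )
    samples = pd.DataFrame(
        {"sample_id": [f"S{i + 1:05d}" for i in range(n)]}
    )
    cohort = Cohort(
        functional=functional,
        tag_haps=tag_haps,
        tag_snps=_tag_meta(config.tag_specs),
        null_haps=null_haps,
        null_snps=null_meta,
        samples=samples,
        relative_pairs=[],
    )
    cohort.allele_system = config.allele_system  # type: ignore[attr-defined]
    cohort.tag_specs = config.tag_specs  # type: ignore[attr-defined]

    cohort = inject_relatives(
        cohort,
        config.n_duplicate_pairs,
        config.n_sib_pairs,
        (seed + _SEED_OFFSETS["relatives"]) % 2**31,
    )
    n_total = cohort.n_samples

    rng_cov = _stage_rng(seed, "covariates")
    cohort.samples["sex"] = np.where(
        rng_cov.random(n_total) < 0.5, "male", "female"
    )
    cohort.samples["age"] = rng_cov.uniform(*config.age_range, n_total)
    rng_sero = _stage_rng(seed, "serotype")
    cohort.samples["serotype"] = _serotype_vector(
        cohort.functional, config.typing_error_rate, rng_sero
    )
    cohort.samples = simulate_traits(
        cohort,
        config.causal_effects,
        (seed + _SEED_OFFSETS["traits"]) % 2**31,
        config,
    )

    # genotype missingness: background rate everywhere, plus designated
    # low-call-rate samples for the QC stage to catch
    n_snps_total = len(cohort.tag_snps) + len(cohort.null_snps)
    rng_miss = _stage_rng(seed, "missing")
    if config.genotype_missing_rate > 0 or config.n_low_callrate_samples > 0:
        mask = rng_miss.random((n_total, n_snps_total)) < \
            config.genotype_missing_rate
        lowcall = rng_miss.choice(
            config.n_samples,
            size=min(config.n_low_callrate_samples, config.n_samples),
            replace=False,
        )
        for si in lowcall:
            mask[si] |= rng_miss.random(n_snps_total) < \
                config.low_callrate_missing_rate
        cohort.missing_mask = mask
        cohort.low_callrate_samples = [  # type: ignore[attr-defined]
            cohort.sample_ids[i] for i in lowcall
        ]
    return cohort
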