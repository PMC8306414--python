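"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of the per-SNP metadata table.
SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]

#: The four serological blood types, in domain order with O (the recessive
#: reference type) first.
BLOOD_TYPES = ["O", "A", "B", "AB"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with SNP metadata.

    Dosages count copies of the ALT allele (0/1/2) as ``float64``; missing
    calls are ``NaN``.  Positions are 1-based (VCF convention).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{self.dosages.shape[0]} dosage rows but "
                f"{len(self.sample_ids)} sample ids"
            )
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.snps)} SNP metadata rows"
            )
        missing = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP metadata lacks columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def call_rate_samples(self) -> np.ndarray:
        """Per-sample fraction of non-missing genotype calls."""
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def call_rate_snps(self) -> np.ndarray:
        """Per-SNP fraction of non-missing genotype calls."""
        if self.n_samples == 0:
            return np.ones(self.n_snps)
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency estimated from the dosages."""
        with np.errstate(invalid="ignore"):
            aaf = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(aaf, 1.0 - aaf)

    def subset_samples(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep_idx = self._sample_indices(keep)
        return GenotypeMatrix(
            self.dosages[keep_idx, :],
            [self.sample_ids[i] for i in keep_idx],
            self.snps.copy(),
        )

    def subset_snps(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        if len(keep) and isinstance(next(iter(keep)), str):
            order = {s: i for i, s in enumerate(self.snps["snp_id"])}
            keep_idx = np.array([order[s] for s in keep], dtype=int)
        else:
            keep_idx = np.asarray(keep)
            if keep_idx.dtype == bool:
                keep_idx = np.flatnonzero(keep_idx)
        return GenotypeMatrix(
            self.dosages[:, keep_idx],
            list(self.sample_ids),
            self.snps.iloc[keep_idx].reset_index(drop=True),
        )

    def dosage_of(self, snp_id: str) -> np.ndarray:
        idx = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return self.dosages[:, idx[0]]

    def _sample_indices(self, keep) -> np.ndarray:
        keep = list(keep)
        if keep and isinstance(keep[0], str):
            order = {s: i for i, s in enumerate(self.sample_ids)}
            return np.array([order[s] for s in keep], dtype=int)
        arr = np.asarray(keep)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        return arr.astype(int)


@dataclass
class Cohort:
    """A simulated cohort carrying its haplotype-level ground truth.

    ``functional`` holds the two ABO functional alleles per individual
    (strings ``O``/``A``/``B``); ``tag_haps`` and ``null_haps`` hold the two
    haplotype allele bits per individual for locus tag SNPs and genome-wide
    null SNPs.  ``genotypes()`` collapses haplotypes into an analysis-ready
    :class:`GenotypeMatrix`.
    """

    functional: np.ndarray                      # (n, 2) of "O"/"A"/"B"
    tag_haps: dict[str, np.ndarray]             # snp_id -> (n, 2) uint8
    tag_snps: pd.DataFrame                      # metadata incl. anchor
    null_haps: np.ndarray                       # (n, n_null, 2) uint8
    null_snps: pd.DataFrame
    samples: pd.DataFrame                       # sample_id, sex, age, ...
    relative_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    missing_mask: np.ndarray | None = None      # (n, n_snps) True=missing

    @property
    def n_samples(self) -> int:
        return self.functional.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def genotypes(self) -> GenotypeMatrix:
        """Dosage matrix over tag SNPs followed by null SNPs."""
        cols = [self.tag_haps[s].sum(axis=1) for s in self.tag_snps["snp_id"]]
        tag_block = (
            np.column_stack(cols) if cols else np.empty((self.n_samples, 0))
        )
        null_block = self.null_haps.sum(axis=2)
        dosages = np.concatenate(
            [tag_block.astype(float), null_block.astype(float)], axis=1
        )
        if self.missing_mask is not None:
            dosages = dosages.copy()
            dosages[self.missing_mask] = np.nan
        snps = pd.concat(
            [self.tag_snps[SNP_COLUMNS], self.null_snps[SNP_COLUMNS]],
            ignore_index=True,
        )
        return GenotypeMatrix(dosages, self.sample_ids, snps)

    def diplotypes(self) -> list[str]:
        """Sorted functional-allele pair per individual, e.g. ``"AO"``."""
        return ["".join(sorted(pair)) for pair in self.functional]
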