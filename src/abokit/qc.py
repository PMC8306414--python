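"""Cohort preprocessing: call-rate filters, IBD relatedness pruning, PCA.

Relatedness uses Purcell-style method-of-moments estimation: observed
identity-by-state (IBS) counts are mapped to probabilities of sharing 0, 1
or 2 alleles identical-by-descent via allele-frequency expectations, and
pi-hat = P(IBD=2) + P(IBD=1)/2.  Principal components are computed on an
LD-pruned, mean-imputed, column-standardized dosage matrix; missing dosages
are imputed for PCA only, never for association fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Sample bookkeeping for one QC pass; counts always reconcile."""

    n_input: int
    n_dropped_callrate: int = 0
    n_dropped_relatedness: int = 0
    n_retained: int = 0
    n_snps_input: int = 0
    n_snps_dropped: int = 0
    sample_call_rate: dict[str, float] = field(default_factory=dict)
    dropped_samples: dict[str, str] = field(default_factory=dict)  # id -> why

    def validate(self) -> None:
        total = (
            self.n_dropped_callrate + self.n_dropped_relatedness
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(
                f"QC counts do not reconcile: {self.n_input} in, "
                f"{total} accounted for"
            )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("n_input", self.n_input),
                ("n_dropped_callrate", self.n_dropped_callrate),
                ("n_dropped_relatedness", self.n_dropped_relatedness),
                ("n_retained", self.n_retained),
                ("n_snps_input", self.n_snps_input),
                ("n_snps_dropped", self.n_snps_dropped),
            ],
            columns=["field", "value"],
        )


@dataclass
class PCSet:
    """Top-K principal components of the genotype matrix."""

    scores: np.ndarray             # (n_samples, k)
    loadings: np.ndarray           # (n_snps_used, k)
    explained_variance_ratio: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]


def filter_call_rate(
    genotypes: GenotypeMatrix,
    sample_threshold: float = 0.95,
    snp_threshold: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-call-rate samples first, then low-call-rate SNPs."""
    for t in (sample_threshold, snp_threshold):
        if not 0 < t <= 1:
            raise ValueError("call-rate thresholds must be in (0,1]")
    report = QCReport(
        n_input=genotypes.n_samples, n_snps_input=genotypes.n_snps
    )
    cr = genotypes.call_rate_samples()
    report.sample_call_rate = dict(zip(genotypes.sample_ids, cr))
    keep_samples = cr >= sample_threshold
    if not keep_samples.any():
        raise ValueError("call-rate filter removed every sample")
    for sid, ok in zip(genotypes.sample_ids, keep_samples):
        if not ok:
            report.dropped_samples[sid] = "call_rate"
    report.n_dropped_callrate = int((~keep_samples).sum())
    gm = genotypes.subset_samples(keep_samples)
    keep_snps = gm.call_rate_snps() >= snp_threshold
    report.n_snps_dropped = int((~keep_snps).sum())
    gm = gm.subset_snps(keep_snps)
    report.n_retained = gm.n_samples
    report.validate()
    return gm, report


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities of
    heterozygote counts no more likely than the observed one)."""
    n = n_het + n_hom_minor + n_hom_major
    n_rare = 2 * n_hom_minor + n_het
    if n == 0:
        return 1.0
    # enumerate all heterozygote counts with the observed allele parity
    het_min = n_rare % 2
    hets = np.arange(het_min, min(n_rare, 2 * n - n_rare) + 1, 2)
    from scipy.special import gammaln

    logp = (
        hets * np.log(2)
        + gammaln(n + 1)
        - gammaln((n_rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (n_rare + hets) / 2 + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_snps(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_threshold: float = 1e-6,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs by minor-allele frequency and Hardy-Weinberg exact test."""
    keep = np.ones(genotypes.n_snps, dtype=bool)
    maf = genotypes.maf()
    keep &= maf >= maf_min
    reasons = pd.DataFrame(
        {"snp_id": genotypes.snp_ids, "maf": maf, "hwe_p": np.nan}
    )
    for j in np.flatnonzero(keep):
        g = genotypes.dosages[:, j]
        g = g[~np.isnan(g)]
        aaf = g.mean() / 2
        het = int(np.sum(g == 1))
        if aaf <= 0.5:
            hom_minor, hom_major = int(np.sum(g == 2)), int(np.sum(g == 0))
        else:
            hom_minor, hom_major = int(np.sum(g == 0)), int(np.sum(g == 2))
        p = hwe_exact_p(het, hom_minor, hom_major)
        reasons.loc[j, "hwe_p"] = p
        if p < hwe_p_threshold:
            keep[j] = False
    reasons["retained"] = keep
    return genotypes.subset_snps(keep), reasons


def estimate_ibd(
    genotypes: GenotypeMatrix, maf: np.ndarray | None = None
) -> pd.DataFrame:
    """Pairwise pi-hat matrix by method-of-moments IBS -> IBD estimation.

    For each pair, counts of IBS 0/1/2 over jointly non-missing SNPs are
    equated to their allele-frequency expectations under IBD states
    (P(IBS0|IBD0)=2p^2q^2, P(IBS1|IBD0)=4p^3q+4pq^3, P(IBS1|IBD1)=2pq,
    P(IBS2|IBD2)=1); the solved state probabilities are clamped to [0,1]
    and pi-hat = P2 + P1/2.
    """
    g = genotypes.dosages
    n, m = g.shape
    if m < 100:
        warnings.warn(
            f"only {m} SNPs for IBD estimation; at least 100 approximately "
            "independent SNPs recommended",
            stacklevel=2,
        )
    if maf is None:
        maf = genotypes.maf()
    poly = maf > 0
    if not poly.any():
        raise ValueError("all SNPs monomorphic; IBD undefined")
    g = g[:, poly]
    m = g.shape[1]

    valid = ~np.isnan(g)
    gz = np.nan_to_num(g)
    ind = [((gz == k) & valid).astype(float) for k in (0.0, 1.0, 2.0)]

    # pairwise IBS counts via indicator cross-products
    n0 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    n1 = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    )
    v = valid.astype(float)

    # per-SNP expectations from unbiased factorial-moment estimators of
    # p^2 q^2, p^3 q + p q^3 and pq (plug-in sample frequencies bias pi-hat
    # upward), summed over jointly valid SNPs per pair
    x = np.nansum(g, axis=0)                 # ALT allele count
    t = 2.0 * valid.sum(axis=0)              # total alleles observed
    y = t - x
    with np.errstate(divide="ignore", invalid="ignore"):
        denom4 = t * (t - 1) * (t - 2) * (t - 3)
        p2q2 = x * (x - 1) * y * (y - 1) / denom4
        p3q_pq3 = (x * (x - 1) * (x - 2) * y + x * y * (y - 1) * (y - 2)) \
            / denom4
        pq = x * y / (t * (t - 1))
    e0_ibd0 = 2.0 * np.nan_to_num(p2q2)
    e1_ibd0 = 4.0 * np.nan_to_num(p3q_pq3)
    e1_ibd1 = 2.0 * np.nan_to_num(pq)

    s_e0 = (v * e0_ibd0) @ v.T
    s_e1_0 = (v * e1_ibd0) @ v.T
    s_e1_1 = (v * e1_ibd1) @ v.T

    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = n0 / s_e0
        p1 = (n1 - p0 * s_e1_0) / s_e1_1
    # pi-hat = P2 + P1/2 with P2 = 1 - P0 - P1; only the final value is
    # clamped — clamping the state probabilities censors noise one-sidedly
    # and biases pi-hat upward at modest SNP counts
    pihat = np.clip(
        np.nan_to_num(1.0 - p0 - 0.5 * p1), 0.0, 1.0
    )
    np.fill_diagonal(pihat, 1.0)
    ids = genotypes.sample_ids
    return pd.DataFrame(pihat, index=ids, columns=ids)


def prune_related(
    pihat: pd.DataFrame,
    threshold: float = 0.1875,
    missingness: dict[str, float] | None = None,
) -> tuple[list[str], QCReport]:
    """Greedy relatedness pruning.

    While any pair exceeds the pi-hat threshold, drop the member with the
    greater genotype missingness (ties: the lexicographically larger sample
    id).  Pairs are visited worst-first for determinism.
    """
    if not 0 < threshold < 1:
        raise ValueError("pi-hat threshold must be in (0,1)")
    ids = list(pihat.index)
    miss = missingness or {}
    mat = pihat.to_numpy().copy()
    np.fill_diagonal(mat, 0.0)
    active = {i: True for i in range(len(ids))}
    dropped: dict[str, str] = {}
    while True:
        live = [i for i, on in active.items() if on]
        sub = mat[np.ix_(live, live)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        ia, ib = live[a], live[b]
        ma = miss.get(ids[ia], 0.0)
        mb = miss.get(ids[ib], 0.0)
        if ma > mb:
            victim = ia
        elif mb > ma:
            victim = ib
        else:
            victim = ia if ids[ia] > ids[ib] else ib
        active[victim] = False
        dropped[ids[victim]] = "relatedness"
    retained = [ids[i] for i, on in active.items() if on]
    report = QCReport(
        n_input=len(ids),
        n_dropped_relatedness=len(dropped),
        n_retained=len(retained),
        dropped_samples=dropped,
    )
    report.validate()
    return retained, report


def _greedy_ld_prune(
    dosages: np.ndarray, maf: np.ndarray, r2_threshold: float
) -> np.ndarray:
    """Window-free greedy pruning: visit SNPs by descending MAF, keep a SNP
    iff its dosage r^2 with every kept SNP stays below the threshold."""
    n, m = dosages.shape
    x = dosages - np.nanmean(dosages, axis=0)
    x = np.nan_to_num(x)
    norms = np.sqrt((x**2).sum(axis=0))
    order = np.lexsort((np.arange(m), -maf))
    kept: list[int] = []
    for j in order:
        if norms[j] == 0:
            continue
        if kept:
            r = (x[:, kept].T @ x[:, j]) / (norms[kept] * norms[j])
            if np.max(r**2) >= r2_threshold:
                continue
        kept.append(j)
    return np.array(sorted(kept), dtype=int)


def compute_pcs(
    genotypes: GenotypeMatrix,
    k: int = 10,
    ld_prune_r2: float = 0.2,
) -> PCSet:
    """Top-K principal components for population-structure adjustment.

    LD-prunes, mean-imputes missing dosages, column-standardizes and takes
    the SVD.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    keep = _greedy_ld_prune(genotypes.dosages, genotypes.maf(), ld_prune_r2)
    if k > min(genotypes.n_samples, len(keep)):
        raise ValueError(
            f"k={k} exceeds min(samples={genotypes.n_samples}, "
            f"pruned SNPs={len(keep)})"
        )
    x = genotypes.dosages[:, keep].copy()
    col_mean = np.nanmean(x, axis=0)
    nan_r, nan_c = np.where(np.isnan(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    x -= col_mean
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    evr = (s**2) / np.sum(s**2)
    return PCSet(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=evr[:k],
        snp_ids=[genotypes.snp_ids[i] for i in keep],
        sample_ids=list(genotypes.sample_ids),
    )
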