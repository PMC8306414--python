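"""Pairwise linkage disequilibrium and LD-aware instrument selection.

LD is the composite (genotype-dosage correlation) r-squared, the natural
estimator on unphased data; it equals the haplotype-level r-squared in
expectation under Hardy-Weinberg equilibrium.  Selection follows the
iterative rule: walk the association hits in ascending p-order and accept a
SNP only if it is below the r-squared threshold against everything already
selected.  A post-pass can replace a high-LD selected pair by one common
tag SNP correlated with both but independent of the rest of the set.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    a = np.asarray(dosage_a, float)
    b = np.asarray(dosage_b, float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for a constant (or empty) dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LDMatrix:
    """Symmetric r-squared matrix over a SNP panel."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, equal_nan=True):
            raise ValueError("r2 matrix must be symmetric")
        if np.nanmin(self.r2) < -1e-12 or np.nanmax(self.r2) > 1 + 1e-9:
            raise ValueError("r2 values must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def value(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} missing from LD matrix")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.snp_ids,
                            columns=self.snp_ids)

    def pairs_table(self) -> pd.DataFrame:
        rows = [
            {"snp_a": a, "snp_b": b, "r2": self.value(a, b)}
            for a, b in itertools.combinations(self.snp_ids, 2)
        ]
        return pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])


def ld_matrix(dosages: np.ndarray, snp_ids: list[str]) -> LDMatrix:
    """All-pairs composite r-squared for a dosage matrix (samples x SNPs)."""
    m = len(snp_ids)
    r2 = np.eye(m)
    for i, j in itertools.combinations(range(m), 2):
        r2[i, j] = r2[j, i] = ld_r2(dosages[:, i], dosages[:, j])
    return LDMatrix(snp_ids=snp_ids, r2=r2)


def iterative_select(
    hits: pd.DataFrame, ld: LDMatrix, r2_threshold: float = 0.8
) -> list[str]:
    """Greedy LD-aware selection of independent hits.

    ``hits`` must already be in screening order (ascending p, ties
    resolved).  Each SNP is accepted iff its r-squared with every
    already-selected SNP is below the threshold.  A SNP appearing in
    several contrast rows is considered once, at its best rank.
    """
    selected: list[str] = []
    seen: set[str] = set()
    for snp in hits["snp_id"]:
        if snp in seen:
            continue
        seen.add(snp)
        if all(ld.value(snp, s) < r2_threshold for s in selected):
            selected.append(snp)
    return selected


def find_common_tag(
    selected: list[str],
    candidates: list[str],
    ld: LDMatrix,
    high_r2: float = 0.9,
    low_r2: float = 0.8,
    pvalues: dict[str, float] | None = None,
) -> list[str]:
    """Replace a high-LD selected pair by one common tag SNP.

    For every selected pair (X, Y) with r2(X,Y) >= high_r2, search the
    candidates for a Z with r2(X,Z) >= high_r2, r2(Y,Z) >= high_r2 and
    r2(Z,W) < low_r2 for every other selected W; the best Z (largest
    min(r2(X,Z), r2(Y,Z)), ties by smaller p) replaces {X, Y}.  With no
    eligible pair or candidate the set is returned unchanged.
    """
    if high_r2 < low_r2:
        raise ValueError("high_r2 must be >= low_r2")
    pvalues = pvalues or {}
    selected = list(selected)
    changed = True
    while changed:
        changed = False
        for x, y in itertools.combinations(selected, 2):
            if ld.value(x, y) < high_r2:
                continue
            others = [w for w in selected if w not in (x, y)]
            best = None
            for z in candidates:
                if z in selected:
                    continue
                rxz, ryz = ld.value(x, z), ld.value(y, z)
                if rxz < high_r2 or ryz < high_r2:
                    continue
                if any(ld.value(z, w) >= low_r2 for w in others):
                    continue
                key = (min(rxz, ryz), -pvalues.get(z, np.inf))
                if best is None or key > best[0]:
                    best = (key, z)
            if best is not None:
                z = best[1]
                logger.info("replacing high-LD pair (%s, %s) by common tag %s",
                            x, y, z)
                selected = [s for s in selected if s not in (x, y)] + [z]
                changed = True
                break
            logger.info("high-LD pair (%s, %s) kept: no eligible common tag",
                        x, y)
    return selected
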