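"""LD estimation from a reference panel and greedy r²-threshold pruning.

The LD matrix is the Pearson correlation of allele counts (genotypic r,
not haplotype r — reference panels here are unphased).  Missing genotypes
are mean-imputed per SNP before correlation.  Pruning removes the
smallest number of SNPs the greedy max-degree heuristic can find so that
no remaining pair exceeds the r² threshold; the true minimum vertex
cover is NP-hard, so this is a heuristic, matching common practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GenotypePanel

__all__ = ["LdMatrix", "compute_ld", "prune_by_ld", "DEFAULT_PRUNE_R2"]

# Recommended pruning threshold regardless of SNP panel.
DEFAULT_PRUNE_R2 = 0.9


@dataclass
class LdMatrix:
    """Symmetric SNP x SNP Pearson-correlation matrix."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValueError(f"r is {self.r.shape}, expected ({m}, {m})")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix is not symmetric")
        if np.any(np.abs(self.r) > 1.0 + 1e-10):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = np.array([pos[s] for s in snp_ids], dtype=int)
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


def compute_ld(panel: GenotypePanel, snp_ids: Sequence[str]) -> LdMatrix:
    """Estimate the LD correlation matrix for ``snp_ids`` from a panel.

    Missing genotypes are mean-imputed per SNP; the result is
    symmetrized as (r + rᵀ)/2 and the diagonal forced to exactly 1.

    Raises ``ValueError`` naming the SNP if any requested SNP is
    monomorphic (zero genotype variance) in the panel.
    """
    idx = panel.snp_index(snp_ids)
    g = panel.genotypes[:, idx].copy()
    col_mean = np.nanmean(g, axis=0)
    nan_mask = np.isnan(g)
    if nan_mask.any():
        g[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = g.std(axis=0)
    if np.any(sd == 0):
        bad = snp_ids[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"SNP {bad} is monomorphic in the reference panel")
    z = (g - g.mean(axis=0)) / sd
    r = (z.T @ z) / g.shape[0]
    r = (r + r.T) / 2.0
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(list(snp_ids), r)


def prune_by_ld(
    ld: LdMatrix, r2_threshold: float = DEFAULT_PRUNE_R2
) -> tuple[list[str], list[str]]:
    """Greedily remove SNPs until all remaining pairwise r² ≤ threshold.

    Builds the graph whose edges are SNP pairs with r² above the
    threshold, then repeatedly deletes the vertex with the highest
    current degree (recomputing degrees after each deletion) until no
    edge remains.  Ties on degree are broken by removing the SNP that
    occurs *latest* in the set's positional order — deterministic and
    independent of association statistics, so pruning cannot bias the
    test toward significant SNPs.

    Returns ``(kept_snp_ids, removed_snp_ids)`` preserving input order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    m = ld.m
    adj = ld.r ** 2 > r2_threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(m, dtype=bool)
    removed: list[int] = []
    degree = adj.sum(axis=1)
    while True:
        deg_alive = np.where(alive, degree, -1)
        top = int(deg_alive.max())
        if top <= 0:
            break
        # argmax of reversed array -> latest index among ties
        j = m - 1 - int(np.argmax(deg_alive[::-1]))
        alive[j] = False
        removed.append(j)
        degree -= adj[:, j]
        degree[j] = 0
    kept = [ld.snp_ids[i] for i in range(m) if alive[i]]
    return kept, [ld.snp_ids[i] for i in sorted(removed)]
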