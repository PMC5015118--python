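"""Resampling reference tests: the methods the analytic test replaces.

Two independent oracles for the set statistic T = Σ zᵢ²:

* a phenotype-permutation test on individual-level data (PLINK-style);
* a multivariate-normal simulation test from the LD matrix alone
  (VEGAS-style), including the staged 1000 → n_sims escalation design.

Both return empirical p-values with the (r + 1)/(s + 1) convention, so
they never return 0 but are floored at 1/(s + 1) — exactly the
resampling limitation the analytic quadratic-form tail is free of.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ld import LdMatrix
from .settest import SnpSet
from .simulate import SyntheticCohort, stream

__all__ = ["EmpiricalPValue", "permutation_set_test", "mvn_simulation_set_test"]

# VEGAS staging: initial draws, and the interim p below which to escalate
STAGE1_DRAWS = 1000
STAGE1_ESCALATE_P = 0.001


@dataclass(frozen=True)
class EmpiricalPValue:
    """Empirical tail estimate: p = (exceedances + 1) / (draws + 1)."""

    exceedances: int
    draws: int

    @property
    def p(self) -> float:
        return (self.exceedances + 1) / (self.draws + 1)

    @property
    def floor(self) -> float:
        """Smallest p this many draws can ever report."""
        return 1.0 / (self.draws + 1)


def _set_statistics(genotypes: np.ndarray, phenos: np.ndarray) -> np.ndarray:
    """T = Σ t² over SNPs for each phenotype column, via the identity
    t² = r²(n − 2)/(1 − r²) for the simple-regression t statistic."""
    n = genotypes.shape[0]
    gc = genotypes - genotypes.mean(axis=0)
    gn = gc / np.linalg.norm(gc, axis=0)
    yc = phenos - phenos.mean(axis=0)
    yn = yc / np.linalg.norm(yc, axis=0)
    r = gn.T @ yn  # m x n_pheno correlations
    r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-15)
    t2 = r2 * (n - 2) / (1.0 - r2)
    return t2.sum(axis=0)


def permutation_set_test(
    cohort: SyntheticCohort, snp_set: SnpSet, n_perm: int, seed: int
) -> EmpiricalPValue:
    """PLINK-style permutation test of one SNP set.

    The observed statistic is Σ t² from regressing the true phenotype on
    each set SNP; the null distribution comes from ``n_perm``
    permutations of the phenotype vector.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    idx = cohort.panel.snp_index(snp_set.snp_ids)
    g = cohort.panel.genotypes[:, idx].copy()
    nan_mask = np.isnan(g)
    if nan_mask.any():
        col_mean = np.nanmean(g, axis=0)
        g[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    if np.any(g.std(axis=0) == 0):
        raise ValueError("monomorphic SNP in set")
    y = np.asarray(cohort.phenotype, dtype=float)
    t_obs = float(_set_statistics(g, y[:, None])[0])

    rng = stream(seed, "permutation")
    n = y.size
    exceed = 0
    chunk = max(1, min(n_perm, 64_000_000 // (8 * n)))  # bound scratch memory
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(y[:, None], (1, b)), axis=0)
        t_perm = _set_statistics(g, perms)
        exceed += int((t_perm >= t_obs).sum())
        done += b
    return EmpiricalPValue(exceedances=exceed, draws=n_perm)


def mvn_simulation_set_test(
    ld: LdMatrix,
    t_obs: float,
    n_sims: int,
    seed: int,
    staged: bool = False,
) -> EmpiricalPValue:
    """VEGAS-style simulation test from the LD matrix alone.

    Draws z ~ MVN(0, R) through a symmetric square root of R (eigen
    form with negative eigenvalues clamped — tolerant of the rank
    deficiency that duplicated SNPs cause, where Cholesky fails) and
    compares T = Σ zᵢ² with ``t_obs``.

    With ``staged=True`` the VEGAS two-stage design is used: 1000
    initial draws, escalating to ``n_sims`` only when the interim
    (+1-corrected) p-value is below 0.001.
    """
    if t_obs < 0:
        raise ValueError("t_obs must be nonnegative")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    lam, vec = np.linalg.eigh(ld.r)
    lam = np.clip(lam, 0.0, None)
    root = vec * np.sqrt(lam)  # A with A Aᵀ = R
    rng = stream(seed, "mvn-simulation")

    def count_exceed(draws: int) -> int:
        exceed = 0
        chunk = max(1, min(draws, 32_000_000 // max(1, ld.m)))
        done = 0
        while done < draws:
            b = min(chunk, draws - done)
            u = rng.standard_normal((ld.m, b))
            z = root @ u
            t = (z ** 2).sum(axis=0)
            exceed += int((t >= t_obs).sum())
            done += b
        return exceed

    if staged and n_sims > STAGE1_DRAWS:
        interim = EmpiricalPValue(count_exceed(STAGE1_DRAWS), STAGE1_DRAWS)
        if interim.p >= STAGE1_ESCALATE_P:
            return interim
    return EmpiricalPValue(count_exceed(n_sims), n_sims)
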