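"""Synthetic cohorts for validating the set-based test.

Generates genotype panels (unlinked SNPs, or block-structured LD via a
thresholded latent Gaussian), quantitative phenotypes with a controlled
per-causal-variant fraction of variance explained, perfect-LD
augmentations, clustered causal configurations, and single-SNP marginal
association scans that turn a cohort into GWAS summary statistics.

Defaults mirror the validation conditions the method was designed
around: 10,000 individuals, allele frequencies U(0.01, 0.99), genotypes
Binomial(2, p), causal effects drawn N(0, 1) and rescaled so each causal
variant explains 0.4% of phenotypic variance (0.2% in the LD-pruning
scenarios), sets of at least 10 SNPs, and clustered causal placement via
a Binomial(50, 0.1) cluster-size draw within random 200 kb regions.

All randomness flows from a single integer seed through named streams
(genotypes / effects / residuals / placement / scan), so every
sub-experiment is independently reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GenotypePanel, SummaryRecord
from .settest import SnpSet

__all__ = [
    "SyntheticCohort",
    "ScenarioConfig",
    "stream",
    "simulate_unlinked_genotypes",
    "simulate_block_genotypes",
    "simulate_phenotype",
    "place_clustered_causals",
    "add_perfect_ld_snp",
    "marginal_scan",
    "power_metric",
    "simulate_scenario",
    "simulate_lowld_causal_sets",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_PER_VARIANT_H2",
    "DEFAULT_PER_VARIANT_H2_PRUNING",
    "MIN_SET_SIZE",
]

logger = logging.getLogger("fastbat")

# study-condition defaults for the unlinked validation scenarios
DEFAULT_N_SAMPLES = 10_000
DEFAULT_PER_VARIANT_H2 = 0.004      # unlinked power scenarios
DEFAULT_PER_VARIANT_H2_PRUNING = 0.002  # block-LD pruning scenarios
MIN_SET_SIZE = 10  # genes with fewer SNPs are excluded from power studies

_FREQ_LOW, _FREQ_HIGH = 0.01, 0.99


def stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG: independent, reproducible stream per purpose."""
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SyntheticCohort:
    """Simulated genotypes + phenotype with known causal configuration."""

    panel: GenotypePanel
    phenotype: np.ndarray
    causal_snp_ids: list[str]
    per_variant_h2: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.phenotype) != self.panel.n_samples:
            raise ValueError("phenotype length != sample count")
        missing = set(self.causal_snp_ids) - set(self.panel.snp_ids)
        if missing:
            raise ValueError(f"causal ids not in panel: {sorted(missing)[:5]}")


@dataclass
class ScenarioConfig:
    """Full description of one simulation scenario."""

    n_samples: int = DEFAULT_N_SAMPLES
    set_sizes: Sequence[int] = field(default_factory=lambda: [20] * 50)
    n_causal_per_set: int = 1
    per_variant_h2: float = DEFAULT_PER_VARIANT_H2
    ld_structure: str = "unlinked"  # or "blockwise"
    block_size: int = 5
    within_block_rho: float = 0.9
    causal_placement: str = "random"  # or "clustered"
    cluster_region_bp: int = 200_000
    cluster_size_n: int = 50
    cluster_size_p: float = 0.1
    n_causal_total: int = 50  # used only for clustered placement
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.set_sizes) or self.n_samples < 1:
            raise ValueError("all counts must be positive")
        if self.causal_placement == "random":
            total = self.n_causal_per_set * len(self.set_sizes)
        else:
            total = self.n_causal_total
        if self.per_variant_h2 * total >= 1:
            raise ValueError("total heritability must be < 1")
        if self.ld_structure not in ("unlinked", "blockwise"):
            raise ValueError(f"unknown ld_structure {self.ld_structure!r}")


def _make_panel(
    genotypes: np.ndarray,
    positions: np.ndarray,
    chrom: str = "1",
    prefix: str = "snp",
) -> GenotypePanel:
    n, m = genotypes.shape
    return GenotypePanel(
        sample_ids=[f"sim_{i + 1}" for i in range(n)],
        snp_ids=[f"{prefix}{j + 1}" for j in range(m)],
        chromosomes=np.array([chrom] * m, dtype=object),
        positions=np.asarray(positions, dtype=int),
        allele1=np.array(["A"] * m, dtype=object),
        allele2=np.array(["G"] * m, dtype=object),
        genotypes=genotypes.astype(float),
    )


def simulate_unlinked_genotypes(
    n: int, m: int, seed: int, positions: np.ndarray | None = None
) -> GenotypePanel:
    """Unlinked SNPs: per-SNP frequency p ~ U(0.01, 0.99), genotypes
    i.i.d. Binomial(2, p), no missingness, positions on a 1-bp grid."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    rng = stream(seed, "genotypes")
    freqs = rng.uniform(_FREQ_LOW, _FREQ_HIGH, size=m)
    g = rng.binomial(2, freqs, size=(n, m))
    if positions is None:
        positions = np.arange(1, m + 1)
    return _make_panel(g, positions)


def simulate_block_genotypes(
    n: int,
    m: int,
    block_size: int,
    within_block_rho: float,
    seed: int,
    spacing_bp: int = 1000,
) -> GenotypePanel:
    """Block-LD genotypes via a thresholded latent Gaussian copula.

    Two latent haplotype draws per individual; within a block the latent
    vectors follow an AR(1) with parameter ``within_block_rho``, blocks
    are independent.  Each latent value is thresholded at the normal
    quantile of the SNP's frequency so the marginal genotype is
    Binomial(2, p); realized within-block LD increases monotonically
    with rho.  Positions are a ``spacing_bp``-spaced grid so the panel
    spans a realistic genomic length.
    """
    if not (0.0 <= within_block_rho < 1.0):
        raise ValueError("within_block_rho must be in [0, 1)")
    rng = stream(seed, "genotypes")
    freqs = rng.uniform(_FREQ_LOW, _FREQ_HIGH, size=m)
    thresholds = stats.norm.ppf(freqs)
    rho = within_block_rho
    innov_scale = np.sqrt(1.0 - rho ** 2)
    z = np.empty((n, 2, m))
    for j in range(m):
        eps = rng.standard_normal((n, 2))
        if j % block_size == 0:  # block start: fresh draw
            z[:, :, j] = eps
        else:
            z[:, :, j] = rho * z[:, :, j - 1] + innov_scale * eps
    g = (z < thresholds).sum(axis=1)
    positions = np.arange(1, m + 1) * spacing_bp
    return _make_panel(g, positions)


def simulate_phenotype(
    panel: GenotypePanel,
    causal_snp_ids: Sequence[str],
    per_variant_h2: float,
    seed: int,
) -> SyntheticCohort:
    """Quantitative phenotype y = Σⱼ wⱼβⱼ + e.

    wⱼ is the causal genotype standardized to mean 0, variance 1.
    Effects are drawn bⱼ ~ N(0, 1) and rescaled to |βⱼ| = √h² (sign
    from bⱼ), so each causal variant contributes exactly
    ``per_variant_h2`` of phenotypic variance; the residual is drawn
    with variance 1 − k·h² analytically (no post-hoc scaling), making
    var(y) ≈ 1.
    """
    k = len(causal_snp_ids)
    if per_variant_h2 * k >= 1:
        raise ValueError("total heritability >= 1")
    n = panel.n_samples
    genetic = np.zeros(n)
    if k:
        idx = panel.snp_index(causal_snp_ids)
        w = panel.genotypes[:, idx].copy()
        col_mean = np.nanmean(w, axis=0)
        nan_mask = np.isnan(w)
        if nan_mask.any():
            w[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
        sd = w.std(axis=0)
        if np.any(sd == 0):
            bad = causal_snp_ids[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"causal SNP {bad} is monomorphic")
        w = (w - w.mean(axis=0)) / sd
        b = stream(seed, "effects").standard_normal(k)
        beta = np.sign(b) * np.sqrt(per_variant_h2)
        beta[beta == 0] = np.sqrt(per_variant_h2)
        genetic = w @ beta
    resid_sd = np.sqrt(1.0 - per_variant_h2 * k)
    e = stream(seed, "residuals").normal(0.0, resid_sd, size=n)
    return SyntheticCohort(
        panel=panel,
        phenotype=genetic + e,
        causal_snp_ids=list(causal_snp_ids),
        per_variant_h2=per_variant_h2,
        seed=seed,
    )


def place_clustered_causals(
    panel: GenotypePanel,
    seed: int,
    n_causal_total: int = 50,
    region_bp: int = 200_000,
    cluster_size_n: int = 50,
    cluster_size_p: float = 0.1,
    maf_min: float = 0.01,
) -> list[str]:
    """Cluster causal variants in random genomic regions.

    Repeat {pick a uniform-random ``region_bp`` window; draw cluster
    size k ~ Binomial(cluster_size_n, cluster_size_p); sample
    min(k, remaining budget) common SNPs in the window} until
    ``n_causal_total`` causals are placed.
    """
    rng = stream(seed, "placement")
    pos = panel.positions
    lo, hi = int(pos.min()), int(pos.max())
    if hi - lo < 3 * region_bp:
        raise ValueError("panel spans too little sequence for clustered placement")
    common = panel.maf() >= maf_min
    chosen: list[int] = []
    chosen_mask = np.zeros(panel.n_snps, dtype=bool)
    attempts = 0
    while len(chosen) < n_causal_total:
        attempts += 1
        if attempts > 10_000:
            raise ValueError("panel too sparse to place all clustered causals")
        start = rng.integers(lo, max(lo + 1, hi - region_bp + 1))
        k = int(rng.binomial(cluster_size_n, cluster_size_p))
        if k == 0:
            continue
        in_window = (pos >= start) & (pos < start + region_bp) & common & ~chosen_mask
        candidates = np.flatnonzero(in_window)
        if candidates.size == 0:
            continue
        take = min(k, n_causal_total - len(chosen), candidates.size)
        picked = rng.choice(candidates, size=take, replace=False)
        chosen.extend(int(j) for j in picked)
        chosen_mask[picked] = True
    return [panel.snp_ids[j] for j in sorted(chosen)]


def add_perfect_ld_snp(
    panel: GenotypePanel, target_snp_id: str, new_snp_id: str
) -> GenotypePanel:
    """Append an exact copy of ``target_snp_id``'s genotype column, so
    r(new, target) = 1.  The copy sits adjacent to the target."""
    j = int(panel.snp_index([target_snp_id])[0])
    if new_snp_id in panel.snp_ids:
        raise ValueError(f"SNP id {new_snp_id} already in panel")
    return GenotypePanel(
        sample_ids=panel.sample_ids,
        snp_ids=panel.snp_ids + [new_snp_id],
        chromosomes=np.append(panel.chromosomes, panel.chromosomes[j]),
        positions=np.append(panel.positions, panel.positions[j]),
        allele1=np.append(panel.allele1, panel.allele1[j]),
        allele2=np.append(panel.allele2, panel.allele2[j]),
        genotypes=np.hstack([panel.genotypes, panel.genotypes[:, j:j + 1]]),
    )


def marginal_scan(cohort: SyntheticCohort) -> list[SummaryRecord]:
    """Single-SNP association scan: simple linear regression of the
    phenotype on each SNP's (mean-imputed) allele count.

    Returns one summary record per polymorphic SNP with beta, se,
    two-sided p from the t statistic, allele frequency and n.
    Monomorphic SNPs are dropped with a log entry.
    """
    panel, y = cohort.panel, np.asarray(cohort.phenotype, dtype=float)
    n = panel.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for a regression scan")
    sy = y.std()
    if sy == 0:
        raise ValueError("phenotype has zero variance")
    g = panel.genotypes.copy()
    col_mean = np.nanmean(g, axis=0)
    nan_mask = np.isnan(g)
    if nan_mask.any():
        g[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    syy = float((yc ** 2).sum())
    poly = sxx > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("marginal scan: dropped %d monomorphic SNP(s)", n_mono)
    sxy = gc.T @ yc
    beta = np.zeros_like(sxx)
    beta[poly] = sxy[poly] / sxx[poly]
    resid_ss = syy - beta * sxy
    resid_ss = np.maximum(resid_ss, 0.0)
    se = np.sqrt(resid_ss / (n - 2) / np.where(poly, sxx, 1.0))
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    freq = g.mean(axis=0) / 2.0

    records = []
    for j in np.flatnonzero(poly):
        records.append(
            SummaryRecord(
                snp_id=panel.snp_ids[j],
                allele1=str(panel.allele1[j]),
                allele2=str(panel.allele2[j]),
                freq=float(np.clip(freq[j], 1e-12, 1 - 1e-12)),
                beta=float(beta[j]),
                se=float(se[j]) if se[j] > 0 else None,
                pvalue=float(pvals[j]),
                n=float(n),
            )
        )
    return records


def power_metric(pvalues: Sequence[float]) -> float:
    """Mean 1-df chi-squared: each p is transformed to the χ²₁ quantile
    at survival probability p, and the mean over sets is returned.
    Under the null this tends to E[χ²₁] = 1; larger means more power."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return float(stats.chi2.isf(p, df=1).mean())


# gap between consecutive sets, in bp — keeps ±50 kb gene windows disjoint
_SET_GAP_BP = 200_001


def simulate_scenario(
    config: ScenarioConfig,
) -> tuple[SyntheticCohort, list[SnpSet]]:
    """Build a full scenario: panel, phenotype and the set structure.

    Sets are laid out consecutively on one synthetic chromosome with a
    gap large enough that ±50 kb gene windows never overlap.  Causal
    variants are placed uniformly within each set (``random``) or
    clustered across the panel in 200 kb regions (``clustered``).
    """
    sizes = list(config.set_sizes)
    m_total = sum(sizes)
    # per-set position blocks separated by a large gap
    positions = np.empty(m_total, dtype=int)
    bounds = []
    cursor, offset = 0, 1
    spacing = 1 if config.ld_structure == "unlinked" else 1000
    for sz in sizes:
        positions[cursor:cursor + sz] = offset + np.arange(sz) * spacing
        bounds.append((cursor, cursor + sz))
        cursor += sz
        offset += sz * spacing + _SET_GAP_BP

    if config.ld_structure == "unlinked":
        panel = simulate_unlinked_genotypes(
            config.n_samples, m_total, config.seed, positions=positions
        )
    else:
        panel = simulate_block_genotypes(
            config.n_samples, m_total, config.block_size,
            config.within_block_rho, config.seed,
        )
        panel.positions = positions  # layout with inter-set gaps

    sets = []
    for i, (lo, hi) in enumerate(bounds):
        sets.append(
            SnpSet(
                set_id=f"GENE{i + 1}",
                snp_ids=tuple(panel.snp_ids[lo:hi]),
                chromosome="1",
                span_start=int(positions[lo]),
                span_end=int(positions[hi - 1]),
            )
        )

    if config.causal_placement == "clustered":
        causals = place_clustered_causals(
            panel,
            seed=config.seed,
            n_causal_total=config.n_causal_total,
            region_bp=config.cluster_region_bp,
            cluster_size_n=config.cluster_size_n,
            cluster_size_p=config.cluster_size_p,
        )
    else:
        rng = stream(config.seed, "placement")
        causals = []
        for lo, hi in bounds:
            picked = rng.choice(
                np.arange(lo, hi),
                size=min(config.n_causal_per_set, hi - lo),
                replace=False,
            )
            causals.extend(panel.snp_ids[j] for j in sorted(picked))

    cohort = simulate_phenotype(panel, causals, config.per_variant_h2, config.seed)
    return cohort, sets


def simulate_lowld_causal_sets(
    n_samples: int,
    n_sets: int,
    seed: int,
    n_null_blocks: int = 3,
    block_size: int = 6,
    within_block_rho: float = 0.999,
    per_variant_h2: float = DEFAULT_PER_VARIANT_H2_PRUNING,
) -> tuple[SyntheticCohort, list[SnpSet]]:
    """Sets whose causal variant sits in a low-LD position.

    Each set holds one causal SNP that is unlinked to everything, plus
    ``n_null_blocks`` blocks of ``block_size`` null SNPs in very high
    within-block LD (latent AR(1) parameter ``within_block_rho``; the
    default 0.999 yields realized genotypic r² ≈ 0.93–0.95 between
    adjacent SNPs after the thresholding attenuation).
    This is the regime where LD pruning helps: the redundant high-LD
    null SNPs inflate the null part of the set statistic without adding
    signal, and pruning removes them while the causal SNP, having no
    close LD partner, always survives.
    """
    rng = stream(seed, "genotypes")
    per_set = 1 + n_null_blocks * block_size
    m_total = n_sets * per_set
    innov = np.sqrt(1.0 - within_block_rho ** 2)
    g = np.empty((n_samples, m_total))
    causal_cols = []
    col = 0
    for _ in range(n_sets):
        causal_cols.append(col)
        g[:, col] = rng.binomial(2, rng.uniform(_FREQ_LOW, _FREQ_HIGH),
                                 size=n_samples)
        col += 1
        for _ in range(n_null_blocks):
            # one shared moderate frequency per block: SNPs in
            # near-perfect LD necessarily have near-equal frequencies,
            # and quantile thresholding attenuates the latent
            # correlation badly when thresholds differ
            t = stats.norm.ppf(rng.uniform(0.15, 0.85))
            z = rng.standard_normal((n_samples, 2))
            for j in range(block_size):
                if j > 0:
                    z = within_block_rho * z + innov * rng.standard_normal(
                        (n_samples, 2)
                    )
                g[:, col] = (z < t).sum(axis=1)
                col += 1
    positions = np.arange(1, m_total + 1) * 1000
    panel = _make_panel(g, positions)
    sets = [
        SnpSet(
            set_id=f"GENE{i + 1}",
            snp_ids=tuple(panel.snp_ids[i * per_set:(i + 1) * per_set]),
            chromosome="1",
            span_start=int(positions[i * per_set]),
            span_end=int(positions[(i + 1) * per_set - 1]),
        )
        for i in range(n_sets)
    ]
    causals = [panel.snp_ids[c] for c in causal_cols]
    cohort = simulate_phenotype(panel, causals, per_variant_h2, seed)
    return cohort, sets
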