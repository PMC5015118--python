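"""Readers and writers for the file formats the tool touches.

Supported formats:

* GCTA ``.ma`` summary statistics (whitespace-delimited, header
  ``SNP A1 A2 freq b se p N``) and a minimal two-column ``SNP p`` layout;
* PLINK 1 binary genotypes (``.bed``/``.bim``/``.fam``, SNP-major), with
  the usual reference-panel QC filters (MAF, HWE, missingness);
* gene annotation lists (``chr start end gene`` per line);
* GCTA-style SNP-set lists (set name followed by its SNP ids);
* the results TSV written after a set-based run.

Coordinates are 1-based inclusive throughout (the PLINK ``.bim``
convention).  Missing genotypes are kept in the panel (as NaN) and
handled downstream by mean imputation in LD estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryRecord",
    "GeneAnnotation",
    "GenotypePanel",
    "read_ma_summary",
    "write_ma_summary",
    "read_plink_panel",
    "write_plink_panel",
    "hwe_pvalue",
    "read_gene_list",
    "write_gene_list",
    "read_set_list",
    "write_set_list",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

# Default reference-panel QC thresholds.
DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_P_MIN = 1e-6
DEFAULT_MISSING_MAX = 0.02

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = 0x01


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's GWAS association result.

    Either the (beta, se) pair or the p-value must be usable so that a
    per-SNP chi-squared statistic can be formed downstream.
    """

    snp_id: str
    allele1: str
    allele2: str
    freq: float | None
    beta: float | None
    se: float | None
    pvalue: float | None
    n: float | None

    def __post_init__(self) -> None:
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError(
                f"SNP {self.snp_id}: p-value {self.pvalue} outside (0, 1]; "
                "p = 0 must be handled upstream by supplying b/se instead"
            )
        if self.se is not None and not self.se > 0:
            raise ValueError(f"SNP {self.snp_id}: se must be > 0, got {self.se}")
        if self.freq is not None and not (0.0 < self.freq < 1.0):
            raise ValueError(f"SNP {self.snp_id}: freq {self.freq} outside (0, 1)")
        has_beta_se = self.beta is not None and self.se is not None
        if not has_beta_se and self.pvalue is None:
            raise ValueError(
                f"SNP {self.snp_id}: need (b, se) or p to form a chi-squared statistic"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's genomic span; coordinates 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )


@dataclass
class GenotypePanel:
    """Reference genotypes: counted-allele dosages per sample x SNP.

    ``genotypes`` is an n_samples x n_snps float array of {0, 1, 2} counts
    of ``allele1`` (the PLINK A1 allele), with NaN marking missing calls.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chromosomes: np.ndarray  # object/str, per SNP
    positions: np.ndarray  # int, per SNP, 1-based
    allele1: np.ndarray  # counted allele, per SNP
    allele2: np.ndarray
    genotypes: np.ndarray  # float, n x m, NaN = missing

    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids in panel")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} not in panel") from None

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, ignoring missing calls."""
        f = np.nanmean(self.genotypes, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypePanel(
            sample_ids=self.sample_ids,
            snp_ids=[self.snp_ids[j] for j in keep],
            chromosomes=self.chromosomes[keep],
            positions=self.positions[keep],
            allele1=self.allele1[keep],
            allele2=self.allele2[keep],
            genotypes=self.genotypes[:, keep],
        )


# ---------------------------------------------------------------------------
# GCTA .ma summary statistics
# ---------------------------------------------------------------------------

_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def _opt_float(value) -> float | None:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if np.isnan(v) else v


def read_ma_summary(path: str | Path) -> list[SummaryRecord]:
    """Read GCTA ``.ma`` summary statistics (``SNP A1 A2 freq b se p N``).

    Also accepts the minimal two-column ``SNP p`` layout.  Malformed
    numeric fields become missing where the field is optional; a record
    with neither (b, se) nor p raises.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.upper(): c for c in df.columns}
    if "SNP" not in cols or ("P" not in cols and not ("B" in cols and "SE" in cols)):
        raise ValueError(
            f"{path}: need columns SNP plus p or b/se "
            f"(got {list(df.columns)}; expected GCTA layout {_MA_COLUMNS})"
        )
    dup = df[cols["SNP"]].duplicated()
    if dup.any():
        first = df[cols["SNP"]][dup].iloc[0]
        raise ValueError(f"{path}: duplicate SNP id {first!r}")

    def col(name: str):
        c = cols.get(name)
        return df[c] if c is not None else pd.Series([None] * len(df))

    records = []
    for snp, a1, a2, freq, b, se, p, n in zip(
        df[cols["SNP"]], col("A1"), col("A2"), col("FREQ"),
        col("B"), col("SE"), col("P"), col("N"),
    ):
        records.append(
            SummaryRecord(
                snp_id=str(snp),
                allele1="" if a1 is None or pd.isna(a1) else str(a1),
                allele2="" if a2 is None or pd.isna(a2) else str(a2),
                freq=_opt_float(freq),
                beta=_opt_float(b),
                se=_opt_float(se),
                pvalue=_opt_float(p),
                n=_opt_float(n),
            )
        )
    return records


def write_ma_summary(records: Sequence[SummaryRecord], path: str | Path) -> None:
    def fmt(v) -> str:
        return "NA" if v is None else repr(v)

    with open(path, "w") as fh:
        fh.write("\t".join(_MA_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [r.snp_id, r.allele1 or "NA", r.allele2 or "NA",
                     fmt(r.freq), fmt(r.beta), fmt(r.se), fmt(r.pvalue), fmt(r.n)]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK 1 binary genotypes
# ---------------------------------------------------------------------------

# PLINK 1 .bed two-bit codes (per sample, SNP-major), value = count of A1:
#   00 -> 2 copies of A1,  01 -> missing,  10 -> 1 copy,  11 -> 0 copies
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def hwe_pvalue(genotype_column: np.ndarray) -> float:
    """Hardy-Weinberg goodness-of-fit p-value for one SNP.

    1-df chi-squared test of observed vs expected genotype counts at the
    sample allele frequency.  Missing calls are ignored; monomorphic
    SNPs return p = 1 (no evidence against HWE).
    """
    x = genotype_column[~np.isnan(genotype_column)]
    n = x.size
    if n == 0:
        return 1.0
    counts = np.array([(x == 0).sum(), (x == 1).sum(), (x == 2).sum()], dtype=float)
    p = (2 * counts[2] + counts[1]) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    chisq = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chisq, df=1))


def read_plink_panel(
    prefix: str | Path,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
    missing_max: float = DEFAULT_MISSING_MAX,
) -> GenotypePanel:
    """Read a PLINK 1 ``.bed``/``.bim``/``.fam`` triplet and apply QC.

    SNPs with MAF < ``maf_min``, HWE p-value < ``hwe_p_min`` or missing
    rate > ``missing_max`` are removed.  Pass 0 / 0 / 1 to disable the
    filters.  Only SNP-major v1 files are supported.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None, dtype=str,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    n, m = len(fam), len(bim)
    sample_ids = (fam[0].astype(str) + "_" + fam[1].astype(str)).tolist()

    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not a PLINK 1 .bed file)")
    if raw[2] != _BED_SNP_MAJOR:
        raise ValueError(
            f"{prefix}.bed: individual-major mode (0x{raw[2]:02x}) is unsupported"
        )
    bytes_per_snp = (n + 3) // 4
    payload = raw[3:]
    if payload.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed: payload {payload.size} bytes inconsistent with "
            f"{n} samples x {m} SNPs ({bytes_per_snp * m} expected)"
        )
    # unpack two-bit fields: byte >> (2k) & 3 for sample k within the byte
    mat = payload.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0x03
    genotypes = _BED_DECODE[codes[:, :n]].T  # n x m

    panel = GenotypePanel(
        sample_ids=sample_ids,
        snp_ids=bim["snp"].tolist(),
        chromosomes=bim["chrom"].to_numpy(dtype=object),
        positions=bim["pos"].astype(int).to_numpy(),
        allele1=bim["a1"].to_numpy(dtype=object),
        allele2=bim["a2"].to_numpy(dtype=object),
        genotypes=genotypes,
    )
    keep = (panel.maf() >= maf_min) & (panel.missing_rate() <= missing_max)
    if hwe_p_min > 0:
        hwe = np.array([hwe_pvalue(genotypes[:, j]) for j in range(m)])
        keep &= hwe >= hwe_p_min
    return panel.subset_snps(keep)


def write_plink_panel(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK 1 ``.bed``/``.bim``/``.fam`` (SNP-major)."""
    prefix = Path(prefix)
    n, m = panel.genotypes.shape
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in panel.sample_ids:
            fid, _, iid = s.partition("_")
            fh.write(f"{fid} {iid or fid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(m):
            fh.write(
                f"{panel.chromosomes[j]} {panel.snp_ids[j]} 0 "
                f"{panel.positions[j]} {panel.allele1[j]} {panel.allele2[j]}\n"
            )
    # invert the decode table: dosage 2 -> 00, 1 -> 10, 0 -> 11, NaN -> 01
    g = panel.genotypes
    codes = np.full(g.shape, 1, dtype=np.uint8)
    codes[g == 2.0] = 0
    codes[g == 1.0] = 2
    codes[g == 0.0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# gene lists, set lists, results tables
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene list: ``chr start end gene`` per line, no header."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{line_no}: expected 4 columns, got {len(parts)}")
            chrom, start, end, gene = parts
            if gene in seen:
                raise ValueError(f"{path}:{line_no}: duplicate gene id {gene!r}")
            seen.add(gene)
            genes.append(GeneAnnotation(gene, chrom, int(start), int(end)))
    return genes


def write_gene_list(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome} {g.start} {g.end} {g.gene_id}\n")


def read_set_list(path: str | Path) -> dict[str, list[str]]:
    """Read a GCTA-style set list: set name on one line, then one SNP id
    per line, terminated by ``END``.  Returns {set_id: snp_ids}."""
    sets: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if not token:
                continue
            if current is None:
                current = token
                sets[current] = []
            elif token.upper() == "END":
                if not sets[current]:
                    raise ValueError(f"{path}: set {current!r} has no SNPs")
                current = None
            else:
                sets[current].append(token)
    if current is not None:
        raise ValueError(f"{path}: set {current!r} not terminated by END")
    return sets


def write_set_list(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, snps in sets.items():
            fh.write(name + "\n")
            for s in snps:
                fh.write(s + "\n")
            fh.write("END\n")


RESULT_COLUMNS = [
    "Gene", "Chr", "Start", "End", "nSNPs_raw", "nSNPs_pruned",
    "Chisq_obs", "P_fastBAT", "TopSNP", "TopSNP_P",
]


def write_results(results, path: str | Path, header_comment: str | None = None) -> None:
    """Write per-set results as a TSV (one row per SnpSet tested)."""
    rows = []
    for r in results:
        rows.append({
            "Gene": r.set_id,
            "Chr": r.chromosome if r.chromosome is not None else "NA",
            "Start": r.span_start if r.span_start is not None else -1,
            "End": r.span_end if r.span_end is not None else -1,
            "nSNPs_raw": r.n_snps_raw,
            "nSNPs_pruned": r.n_snps_pruned,
            "Chisq_obs": repr(r.chisq_obs),
            "P_fastBAT": repr(r.p_fastbat),
            "TopSNP": r.top_snp_id,
            "TopSNP_P": repr(r.top_snp_p),
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chr": str},
                     float_precision="round_trip")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing result columns {sorted(missing)}")
    return df
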