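"""Genotype/phenotype input-output and cohort-level quality control.

Genotypes are held as minor-allele counts (0/1/2, with -1 marking a missing
call) in a samples x SNPs matrix together with per-SNP metadata and a binary
case/control phenotype.  Two dialects are supported: a plain-text TSV trio
(matrix + SNP table + phenotype table) and PLINK 1 bed/bim/fam.

QC utilities implement the usual case/control cohort checks: a Cochran-
Armitage trend statistic per SNP, the genomic inflation factor computed from
those statistics, and random control subsampling to a balanced design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: Median of the chi-square distribution with one degree of freedom,
#: the null reference for the genomic inflation factor.
CHI2_1_MEDIAN = 0.4549364


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one genotyped SNP.

    ``maf`` is the minor-allele frequency within the loaded cohort; ``alleles``
    is (minor, major) after recoding.  Positions are 1-based.
    """

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, str] = ("A", "B")
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.pos}")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"SNP {self.id}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class GenotypeData:
    """A case/control genotype cohort.

    ``matrix`` holds minor-allele counts in {0, 1, 2} with ``MISSING`` (-1)
    as the missing sentinel; shape is (n_samples, n_snps).  ``phenotype`` is
    0 (control) / 1 (case); it may be None for genotype-only intermediates,
    but any phenotyped cohort must contain at least one case and one control.
    SNPs are sorted by (chromosome, position).
    """

    samples: list[str]
    snps: list[SnpMeta]
    matrix: np.ndarray
    phenotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.matrix, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid allele count {int(self.matrix[i, j])} for sample "
                f"{self.samples[i]!r}, SNP {self.snps[j].id!r}"
            )
        keys = [(s.chrom, s.pos) for s in self.snps]
        if keys != sorted(keys):
            raise ValueError("SNPs must be sorted by (chromosome, position)")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape != (len(self.samples),):
                raise ValueError("phenotype length does not match samples")
            if not set(np.unique(self.phenotype)) <= {0, 1}:
                raise ValueError("phenotype must be coded 0 (control) / 1 (case)")
            if not (self.phenotype == 1).any() or not (self.phenotype == 0).any():
                raise ValueError("phenotype needs at least one case and one control")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def chromosomes(self) -> dict[str, np.ndarray]:
        """SNP index array per chromosome, in position order."""
        out: dict[str, np.ndarray] = {}
        for j, s in enumerate(self.snps):
            out.setdefault(s.chrom, []).append(j)  # type: ignore[arg-type]
        return {c: np.asarray(v, dtype=int) for c, v in out.items()}

    def imputed_matrix(self) -> np.ndarray:
        """Matrix with missing calls imputed to the SNP's rounded mean count.

        Files keep the sentinel; models see complete data.
        """
        m = self.matrix.astype(np.float64)
        miss = m == MISSING
        if miss.any():
            m[miss] = np.nan
            col_mean = np.nanmean(m, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            fill = np.rint(col_mean).astype(np.float64)
            m = np.where(np.isnan(m), fill[None, :], m)
        return m

    def subset_samples(self, idx: np.ndarray) -> "GenotypeData":
        idx = np.asarray(idx, dtype=int)
        return GenotypeData(
            samples=[self.samples[i] for i in idx],
            snps=list(self.snps),
            matrix=self.matrix[idx],
            phenotype=None if self.phenotype is None else self.phenotype[idx],
        )

    def recode_minor(self) -> "GenotypeData":
        """Flip SNPs so counts are minor-allele counts in this cohort.

        Recomputes every SNP's MAF; alleles are swapped for flipped SNPs.
        """
        m = self.matrix.astype(np.float64)
        m[m == MISSING] = np.nan
        freq = np.nanmean(m, axis=0) / 2.0
        freq = np.where(np.isnan(freq), 0.0, freq)
        out = self.matrix.copy()
        snps = []
        for j, s in enumerate(self.snps):
            f = freq[j]
            if f > 0.5:
                obs = out[:, j] != MISSING
                out[obs, j] = 2 - out[obs, j]
                f = 1.0 - f
                alleles = (s.alleles[1], s.alleles[0])
            else:
                alleles = s.alleles
            snps.append(replace(s, alleles=alleles, maf=float(f)))
        return GenotypeData(self.samples, snps, out, self.phenotype)


def _ext(base: str | Path, ext: str) -> Path:
    return Path(str(base) + ext)


def _sorted_order(snps: list[SnpMeta]) -> list[int]:
    return sorted(range(len(snps)), key=lambda j: (snps[j].chrom, snps[j].pos))


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
#
# <base>.geno.tsv   header: sample_id <tab> snp ids...; one row per sample
# <base>.snps.tsv   columns: snp, chrom, pos, a1, a2
# <base>.pheno.tsv  columns: sample, status (0/1)


def _read_tsv(base: str | Path) -> GenotypeData:
    base = Path(base)
    geno = pd.read_csv(_ext(base, ".geno.tsv"), sep="\t", index_col=0)
    meta = pd.read_csv(_ext(base, ".snps.tsv"), sep="\t", dtype={"chrom": str})
    pheno_path = _ext(base, ".pheno.tsv")
    if not pheno_path.exists():
        raise FileNotFoundError(f"phenotype file missing: {pheno_path}")
    pheno = pd.read_csv(pheno_path, sep="\t", index_col=0)

    if list(geno.columns) != list(meta["snp"]):
        raise ValueError(f"{base}: SNP metadata order does not match genotype header")
    vals = geno.to_numpy()
    bad = ~np.isin(vals, (0, 1, 2, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{_ext(base, '.geno.tsv')}: invalid allele count "
            f"{vals[i, j]!r} at row {i + 2} (sample {geno.index[i]!r}), "
            f"column {geno.columns[j]!r}"
        )
    samples = [str(s) for s in geno.index]
    missing_pheno = [s for s in samples if s not in pheno.index]
    if missing_pheno:
        raise ValueError(f"phenotype missing for samples: {missing_pheno[:5]}")
    status = pheno.loc[samples, "status"].to_numpy()

    snps = [
        SnpMeta(
            id=str(r.snp),
            chrom=str(r.chrom),
            pos=int(r.pos),
            alleles=(str(r.a1), str(r.a2)),
        )
        for r in meta.itertuples()
    ]
    order = _sorted_order(snps)
    gd = GenotypeData(
        samples=samples,
        snps=[snps[j] for j in order],
        matrix=vals[:, order].astype(np.int8),
        phenotype=status,
    )
    return gd.recode_minor()


def _write_tsv(gd: GenotypeData, base: str | Path) -> None:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(gd.matrix, index=pd.Index(gd.samples, name="sample_id"),
                 columns=gd.snp_ids).to_csv(_ext(base, ".geno.tsv"), sep="\t")
    pd.DataFrame(
        {
            "snp": gd.snp_ids,
            "chrom": [s.chrom for s in gd.snps],
            "pos": [s.pos for s in gd.snps],
            "a1": [s.alleles[0] for s in gd.snps],
            "a2": [s.alleles[1] for s in gd.snps],
        }
    ).to_csv(_ext(base, ".snps.tsv"), sep="\t", index=False)
    if gd.phenotype is not None:
        pd.DataFrame(
            {"sample": gd.samples, "status": gd.phenotype.astype(int)}
        ).to_csv(_ext(base, ".pheno.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK 1 bed/bim/fam (variant-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit codes, low bits first within each byte:
#   00 hom A1, 01 missing, 10 het, 11 hom A2.  A1 counts are stored.
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink(prefix: str | Path) -> GenotypeData:
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, ".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, p = len(fam), len(bim)
    pheno_raw = fam["pheno"].to_numpy()
    if not np.isin(pheno_raw, (1, 2)).all():
        raise ValueError(
            "fam phenotype column must be 1 (control) / 2 (case); "
            f"got values {sorted(set(pheno_raw))}"
        )
    phenotype = (pheno_raw == 2).astype(np.int8)

    raw = np.fromfile(_ext(prefix, ".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a variant-major PLINK bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != bpv * p:
        raise ValueError(f"{prefix}.bed: expected {bpv * p} data bytes, got {body.size}")
    blocks = body.reshape(p, bpv)
    shifts = np.arange(4) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    counts = _CODE_TO_COUNT[codes.reshape(p, -1)[:, :n]]  # (p, n) A1 counts

    snps = [
        SnpMeta(id=str(r.snp), chrom=str(r.chrom), pos=int(r.pos),
                alleles=(str(r.a1), str(r.a2)))
        for r in bim.itertuples()
    ]
    order = _sorted_order(snps)
    gd = GenotypeData(
        samples=[str(i) for i in fam["iid"]],
        snps=[snps[j] for j in order],
        matrix=counts.T[:, order],
        phenotype=phenotype,
    )
    return gd.recode_minor()


def _write_plink(gd: GenotypeData, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if gd.phenotype is None:
        raise ValueError("PLINK fam requires a phenotype")
    with open(_ext(prefix, ".fam"), "w") as fh:
        for s, y in zip(gd.samples, gd.phenotype):
            fh.write(f"{s} {s} 0 0 0 {2 if y == 1 else 1}\n")
    with open(_ext(prefix, ".bim"), "w") as fh:
        for s in gd.snps:
            fh.write(f"{s.chrom} {s.id} 0 {s.pos} {s.alleles[0]} {s.alleles[1]}\n")
    n = gd.n_samples
    bpv = (n + 3) // 4
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(bpv, dtype=np.uint8)
        for j in range(gd.n_snps):
            buf[:] = 0
            col = gd.matrix[:, j]
            for i in range(n):
                buf[i // 4] |= _COUNT_TO_CODE[int(col[i])] << ((i % 4) * 2)
            fh.write(buf.tobytes())


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeData:
    """Read a cohort in the given dialect ("tsv" or "plink").

    For "tsv", ``path`` is the common basename of ``.geno.tsv``, ``.snps.tsv``
    and ``.pheno.tsv``; for "plink" it is the bed/bim/fam prefix.  Counts are
    recoded to minor-allele counts within the cohort on read.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gd: GenotypeData, path: str | Path, format: str = "tsv") -> None:
    """Write a cohort in the given dialect (inverse of :func:`read_genotypes`)."""
    if format == "tsv":
        _write_tsv(gd, path)
    elif format == "plink":
        _write_plink(gd, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Cohort QC
# ---------------------------------------------------------------------------


def trend_chi2(gd: GenotypeData) -> np.ndarray:
    """Cochran-Armitage trend statistic (additive scores 0/1/2) per SNP.

    Missing calls are excluded SNP-wise.  Monomorphic SNPs get statistic 0;
    all-missing SNPs get NaN (flagged and omitted downstream).
    """
    if gd.phenotype is None:
        raise ValueError("trend test requires a phenotype")
    y = gd.phenotype.astype(np.float64)
    stats = np.zeros(gd.n_snps)
    w = np.array([0.0, 1.0, 2.0])
    for j in range(gd.n_snps):
        col = gd.matrix[:, j]
        obs = col != MISSING
        if not obs.any():
            stats[j] = np.nan
            logger.warning("SNP %s: all calls missing, trend statistic omitted",
                           gd.snps[j].id)
            continue
        g = col[obs]
        yy = y[obs]
        n_g = np.array([(g == k).sum() for k in range(3)], dtype=np.float64)
        r_g = np.array([yy[g == k].sum() for k in range(3)])
        n_tot = n_g.sum()
        r_tot = r_g.sum()
        if (n_g > 0).sum() < 2 or r_tot == 0 or r_tot == n_tot:
            stats[j] = 0.0
            continue
        num = n_tot * (w * r_g).sum() - r_tot * (w * n_g).sum()
        var = (
            r_tot * (n_tot - r_tot)
            * (n_tot * (w**2 * n_g).sum() - ((w * n_g).sum()) ** 2)
        )
        stats[j] = 0.0 if var == 0 else n_tot * num**2 / var
    return stats


def genomic_inflation(chi2_stats: np.ndarray) -> float:
    """Genomic inflation factor: median statistic over the chi-square(1) median.

    NaN entries (all-missing SNPs) are dropped.  A homogeneous cohort gives a
    value near 1; population structure inflates it.
    """
    stats = np.asarray(chi2_stats, dtype=float)
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise ValueError("no finite association statistics")
    return float(np.median(stats) / CHI2_1_MEDIAN)


def balance_controls(phenotype: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a case/control-balanced subcohort.

    Keeps every case and a uniform random subset of controls of equal size.
    Deterministic for a fixed seed; raises if controls are fewer than cases
    (no upsampling).
    """
    phenotype = np.asarray(phenotype)
    cases = np.flatnonzero(phenotype == 1)
    controls = np.flatnonzero(phenotype == 0)
    if controls.size < cases.size:
        raise ValueError(
            f"cannot balance: {controls.size} controls < {cases.size} cases"
        )
    rng = np.random.default_rng(seed)
    kept = rng.choice(controls, size=cases.size, replace=False)
    return np.sort(np.concatenate([cases, kept]))
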