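"""SNP-to-gene mapping for disease-map genes.

Two mappings are supported: *physical* (the SNP lies within the gene's
genomic interval, closed and 1-based) and *eQTL* (a significant cis
expression-QTL links the SNP to the gene, within the conventional 1 Mb
window).  eQTL Z-scores are converted to linear-model effect sizes from the
Z-score, the minor-allele frequency q and the eQTL cohort size m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import SnpMeta

logger = logging.getLogger(__name__)

CIS_WINDOW = 1_000_000  # bp; conventional cis-eQTL distance


@dataclass(frozen=True)
class GeneRecord:
    """A gene's genomic interval (1-based, closed)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class EqtlRecord:
    """One significant cis-eQTL summary record.

    ``zscore`` is the association Z-score of the SNP with the gene's
    expression, ``maf`` the minor-allele frequency q of the SNP in the eQTL
    cohort, ``n`` the cohort size m.  The linear effect size beta is derived,
    not stored; the expression-model intercept is never needed numerically.
    """

    snp_id: str
    gene_id: str
    zscore: float
    maf: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValueError(f"eQTL {self.snp_id}->{self.gene_id}: MAF must be in (0,1)")
        if self.n < 1:
            raise ValueError(f"eQTL {self.snp_id}->{self.gene_id}: cohort size < 1")

    @property
    def beta(self) -> float:
        return float(beta_from_z(self.zscore, self.maf, self.n))


@dataclass
class SnpGeneMap:
    """Gene -> set of SNP (column) indices, for one mapping type."""

    mapping_type: str  # "physical" | "eqtl"
    genes: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        if self.mapping_type not in ("physical", "eqtl"):
            raise ValueError(f"unknown mapping type {self.mapping_type!r}")
        self.genes = {g: frozenset(v) for g, v in self.genes.items() if v}

    @property
    def mapped_snps(self) -> np.ndarray:
        """Sorted union of all mapped SNP indices."""
        out: set[int] = set()
        for v in self.genes.values():
            out |= v
        return np.asarray(sorted(out), dtype=int)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def map_physical(snps: list[SnpMeta], genes: list[GeneRecord]) -> SnpGeneMap:
    """Map each SNP to every gene whose closed interval contains it.

    A SNP may map to several overlapping genes; genes without SNPs are
    dropped.
    """
    out: dict[str, set[int]] = {}
    for g in genes:
        hits = {
            j
            for j, s in enumerate(snps)
            if s.chrom == g.chrom and g.start <= s.pos <= g.end
        }
        if hits:
            out[g.gene_id] = hits
    if not out:
        logger.warning("physical mapping produced no SNP-gene links")
    return SnpGeneMap("physical", out)  # type: ignore[arg-type]


def map_eqtl(
    snps: list[SnpMeta],
    eqtl_table: list[EqtlRecord],
    genes: list[GeneRecord],
    enforce_cis: bool = True,
) -> SnpGeneMap:
    """Map each SNP to the disease-map genes it is a significant cis-eQTL for.

    Records for genes outside the disease map or for unknown SNPs are
    skipped; records violating the cis window (when both positions are known)
    are rejected with a warning.  The supplied table is taken as already
    restricted to significant associations.
    """
    snp_index = {s.id: j for j, s in enumerate(snps)}
    gene_by_id = {g.gene_id: g for g in genes}
    out: dict[str, set[int]] = {}
    for rec in eqtl_table:
        if rec.gene_id not in gene_by_id:
            continue
        j = snp_index.get(rec.snp_id)
        if j is None:
            logger.info("eQTL record for unknown SNP %s skipped", rec.snp_id)
            continue
        g = gene_by_id[rec.gene_id]
        s = snps[j]
        if enforce_cis:
            if s.chrom != g.chrom or _gene_distance(s.pos, g) > CIS_WINDOW:
                logger.warning(
                    "eQTL record %s->%s violates the 1 Mb cis window; rejected",
                    rec.snp_id, rec.gene_id,
                )
                continue
        out.setdefault(rec.gene_id, set()).add(j)
    return SnpGeneMap("eqtl", out)  # type: ignore[arg-type]


def _gene_distance(pos: int, gene: GeneRecord) -> int:
    if gene.start <= pos <= gene.end:
        return 0
    return min(abs(pos - gene.start), abs(pos - gene.end))


def beta_from_z(z, q, m):
    """Effect size of a SNP on expression from its eQTL Z-score.

    beta = Z / sqrt(2 q (1-q) (m + Z^2)) with q the MAF and m the cohort
    size; odd in Z and increasing in |Z| at fixed (q, m).  Vectorized.
    """
    z = np.asarray(z, dtype=float)
    q = np.asarray(q, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("MAF q must lie strictly inside (0, 1)")
    if np.any(m < 1):
        raise ValueError("cohort size m must be >= 1")
    return z / np.sqrt(2.0 * q * (1.0 - q) * (m + z**2))


def filter_missense(gene_pairs, snp_ids: list[str],
                    consequences: dict[str, set[str]]):
    """Keep gene pairs whose top-scoring SNP pair carries a missense variant.

    ``gene_pairs`` are scored pairs exposing ``best_snp_a``/``best_snp_b``
    column indices into ``snp_ids``.  SNPs absent from the consequence table
    count as non-missense.
    """
    kept = []
    for pair in gene_pairs:
        terms: set[str] = set()
        for j in (pair.best_snp_a, pair.best_snp_b):
            sid = snp_ids[j]
            if sid not in consequences:
                logger.info("SNP %s absent from consequence table; treated as "
                            "non-missense", sid)
                continue
            terms |= consequences[sid]
        if "missense" in terms:
            kept.append(pair)
    return kept


# ---------------------------------------------------------------------------
# Table readers (BED-like gene TSV, eQTL TSV, consequence TSV, disease map)
# ---------------------------------------------------------------------------


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Gene annotation TSV with columns gene, chrom, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneRecord(str(r.gene), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def read_eqtl_table(path: str | Path) -> list[EqtlRecord]:
    """cis-eQTL summary TSV with columns snp, gene, zscore, maf, n."""
    df = pd.read_csv(path, sep="\t")
    return [
        EqtlRecord(str(r.snp), str(r.gene), float(r.zscore), float(r.maf), int(r.n))
        for r in df.itertuples()
    ]


def read_consequence_table(path: str | Path) -> dict[str, set[str]]:
    """Variant-consequence TSV (snp, consequence) -> snp id to term set."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.snp), set()).add(str(r.consequence))
    return out
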