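"""Self-contained synthetic cohorts with the structure the pipeline assumes.

The generator emulates the statistical shape of the real inputs — a
case/control GWAS cohort with linkage disequilibrium, a curated disease map
(gene list plus known biological edges), a cis-eQTL summary table and a
variant-consequence table — without reproducing any real data.  Genotypes
come from the same haplotype-cluster mosaic model the pipeline fits, so LD
decays with distance; phenotypes follow a logistic model with planted
marginal and interaction (epistatic) coefficients on chosen SNP pairs, and
the planted pairs' SNPs are guaranteed to be mapped to their genes both
physically and through planted eQTL rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gwas_io import GenotypeData, SnpMeta, write_genotypes
from .hmm import HaplotypeClusterModel, THETA_FLOOR
from .mapping import EqtlRecord, GeneRecord

logger = logging.getLogger(__name__)

#: eQTL reference cohort size used for synthetic Z-score records; matches the
#: scale of large whole-blood eQTL meta-analyses.
EQTL_COHORT_SIZE = 31_684


@dataclass
class PlantedPair:
    """One planted epistatic gene pair with its logistic coefficients.

    The interaction acts between one SNP of each gene (the middle SNP of the
    gene's block).  ``z1``/``z2`` are the planted eQTL Z-scores of those two
    SNPs on their genes; their signs, with the sign of ``alpha12``, determine
    whether the pair survives the same-sign filter.
    """

    gene_a: int
    gene_b: int
    alpha1: float = 0.0
    alpha2: float = 0.0
    alpha12: float = 1.0
    z1: float = 8.0
    z2: float = 8.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("planted pair must link two distinct genes")


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    Defaults describe a balanced case/control cohort of 2000 samples over
    100 LD-structured SNPs on 2 chromosomes, organized into 20 genes of
    heterogeneous size, with one strongly epistatic planted gene pair whose
    coefficients are all positive (so it should survive the same-sign
    filter with direction +1).
    """

    n_samples: int = 2000
    p_snps: int = 100
    n_chromosomes: int = 2
    K_true: int = 4
    jump_rate: float = 0.05
    maf_bounds: tuple[float, float] = (0.1, 0.5)
    n_genes: int = 20
    min_gene_snps: int = 2
    max_gene_snps: int = 8
    planted_pairs: list[PlantedPair] = field(
        default_factory=lambda: [PlantedPair(gene_a=0, gene_b=10, alpha12=1.0)]
    )
    alpha0: float = 0.0
    background_z: float = 6.0
    missense_fraction: float = 0.1
    #: jump probability at gene-block starts.  Disease-map genes are
    #: scattered across the genome, so between-gene LD is negligible while
    #: within-gene LD is strong; a near-free recombination at each gene
    #: boundary emulates that without simulating intergenic SNPs.
    inter_gene_jump: float = 0.95
    ld_model: str = "hmm"  # "hmm" | "independent" (misspecification switch)
    map_id: str = "SYN1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_bounds
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.jump_rate <= 1.0):
            raise ValueError("jump rate must be a probability")
        for pp in self.planted_pairs:
            if not (0 <= pp.gene_a < self.n_genes and 0 <= pp.gene_b < self.n_genes):
                raise ValueError("planted pair references a gene outside the map")
        if self.n_genes * self.min_gene_snps > self.p_snps:
            raise ValueError("not enough SNPs for the requested genes")


def _true_models(config: SyntheticConfig, rng: np.random.Generator,
                 chrom_sizes: list[int]) -> list[HaplotypeClusterModel]:
    lo, hi = config.maf_bounds
    models = []
    for c, p in enumerate(chrom_sizes):
        K = config.K_true
        alpha = np.full((p, K), 1.0 / K)
        rho = np.full(p, config.jump_rate)
        rho[0] = 1.0  # unused
        # haplotype-like clusters: per-site allele frequency inside the MAF
        # bounds, clusters split into an equal number of minor-allele-rich
        # (+d) and -poor (-d) groups.  With uniform cluster weights the
        # mixture mean equals the site frequency exactly, while cluster runs
        # carry allele correlations -- LD that decays with the jump rate and
        # is cut at gene boundaries by recombination hotspots.
        freq = rng.uniform(lo, hi, size=p)
        diff = rng.uniform(0.75, 1.0, size=p) * np.minimum(freq, 1.0 - freq)
        signs = rng.permutation(
            np.where(np.arange(K) < K // 2, 1.0,
                     np.where(np.arange(K) >= K - K // 2, -1.0, 0.0))
        )
        theta = freq[:, None] + signs[None, :] * diff[:, None]
        theta = np.clip(theta, THETA_FLOOR, 1 - THETA_FLOOR)
        models.append(HaplotypeClusterModel(
            chrom=str(c + 1), snp_ids=[], alpha=alpha, rho=rho, theta=theta))
    return models


def simulate_genotypes(config: SyntheticConfig) -> tuple[GenotypeData, list[HaplotypeClusterModel]]:
    """Draw an LD-structured genotype cohort (no phenotype yet).

    Returns the cohort (phenotype None) and the generating per-chromosome
    models.  With ``ld_model="independent"`` sites are drawn independently
    (binomial at a random MAF in bounds), a deliberate misspecification
    switch for robustness checks.
    """
    rng = np.random.default_rng(config.seed)
    sizes = [config.p_snps // config.n_chromosomes] * config.n_chromosomes
    sizes[-1] += config.p_snps - sum(sizes)
    models = _true_models(config, rng, sizes)
    # recombination hotspots at gene starts: map genes are far apart
    offsets = np.cumsum([0] + sizes)
    for block in gene_blocks(config):
        j = block[0]
        c = int(np.searchsorted(offsets, j, side="right") - 1)
        local = j - offsets[c]
        if local > 0:
            models[c].rho[local] = config.inter_gene_jump

    blocks = []
    snps: list[SnpMeta] = []
    j0 = 0
    for c, (model, p) in enumerate(zip(models, sizes)):
        if config.ld_model == "hmm":
            blocks.append(model.sample_genotypes(config.n_samples, rng))
        elif config.ld_model == "independent":
            lo, hi = config.maf_bounds
            freqs = rng.uniform(lo, hi, size=p)
            blocks.append(rng.binomial(2, freqs, size=(config.n_samples, p))
                          .astype(np.int8))
        else:
            raise ValueError(f"unknown ld_model {config.ld_model!r}")
        ids = [f"rs{j0 + j + 1}" for j in range(p)]
        model.snp_ids = ids
        snps.extend(
            SnpMeta(id=ids[j], chrom=str(c + 1), pos=1000 * (j + 1),
                    alleles=("A", "G"))
            for j in range(p)
        )
        j0 += p
    matrix = np.concatenate(blocks, axis=1)
    gd = GenotypeData(
        samples=[f"ind{i + 1}" for i in range(config.n_samples)],
        snps=snps, matrix=matrix, phenotype=None,
    ).recode_minor()
    return gd, models


def gene_blocks(config: SyntheticConfig) -> list[list[int]]:
    """Deterministic partition of SNP columns into gene blocks.

    Gene sizes are drawn (seeded) between the configured bounds, mimicking
    the heterogeneous SNP-per-gene counts of real disease maps, so the
    size-normalization of the gene score is exercised.
    """
    rng = np.random.default_rng(config.seed + 1)
    sizes = rng.integers(config.min_gene_snps, config.max_gene_snps + 1,
                         size=config.n_genes)
    total = config.p_snps
    # reserve worst-case waste from chromosome-boundary skips
    budget = total - config.n_chromosomes * (config.max_gene_snps - 1)
    while sizes.sum() > budget:
        sizes[np.argmax(sizes)] -= 1
        if sizes.min() < config.min_gene_snps:
            raise ValueError("gene layout does not fit; increase p_snps")
    chrom_sizes = [total // config.n_chromosomes] * config.n_chromosomes
    chrom_sizes[-1] += total - sum(chrom_sizes)
    boundaries = np.cumsum(chrom_sizes)
    blocks, start = [], 0
    for g in range(config.n_genes):
        end = start + int(sizes[g])
        # keep each gene on a single chromosome
        for b in boundaries:
            if start < b < end:
                start = int(b)
                end = start + int(sizes[g])
                break
        blocks.append(list(range(start, end)))
        start = end
    return blocks


def planted_snps(config: SyntheticConfig, blocks: list[list[int]]
                 ) -> list[tuple[int, int]]:
    """The (snp_a, snp_b) column pair carrying each planted interaction."""
    out = []
    for pp in config.planted_pairs:
        a = blocks[pp.gene_a][len(blocks[pp.gene_a]) // 2]
        b = blocks[pp.gene_b][len(blocks[pp.gene_b]) // 2]
        out.append((a, b))
    return out


def simulate_phenotype(matrix: np.ndarray, config: SyntheticConfig,
                       seed: int | None = None) -> np.ndarray:
    """Bernoulli phenotype from the planted logistic model.

    The linear predictor sums the planted marginal and interaction terms
    over all planted pairs (allele-count coding), is centered to its sample
    mean so that alpha0 = 0 yields a roughly balanced cohort, and feeds a
    logistic link.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    blocks = gene_blocks(config)
    eta = np.zeros(matrix.shape[0])
    for pp, (a, b) in zip(config.planted_pairs, planted_snps(config, blocks)):
        x1 = matrix[:, a].astype(float)
        x2 = matrix[:, b].astype(float)
        eta += pp.alpha1 * x1 + pp.alpha2 * x2 + pp.alpha12 * x1 * x2
    if eta.std() > 0:
        eta = eta - eta.mean()
    prob = 1.0 / (1.0 + np.exp(-(config.alpha0 + eta)))
    return (rng.random(matrix.shape[0]) < prob).astype(np.int8)


@dataclass
class FixtureBundle:
    """Everything the pipeline needs, mutually consistent."""

    genotypes: GenotypeData
    genes: list[GeneRecord]
    eqtls: list[EqtlRecord]
    consequences: dict[str, set[str]]
    disease_map: dict
    true_models: list[HaplotypeClusterModel]
    config: SyntheticConfig
    gene_ids: list[str]
    planted: list[tuple[str, str]]  # planted gene-id pairs


def make_fixture(config: SyntheticConfig, outdir: str | Path | None = None
                 ) -> FixtureBundle:
    """Generate a full, mutually consistent input bundle.

    Every planted pair's SNPs map to their genes both physically (the SNP
    lies in the gene interval) and through a planted eQTL row, and carry a
    missense consequence so that both selection filters can recover the
    pair.  If ``outdir`` is given, all dialects are written there.
    """
    gd, models = simulate_genotypes(config)
    pheno = simulate_phenotype(gd.matrix, config)
    if pheno.min() == pheno.max():  # pathological planted model
        pheno[0] = 1 - pheno[0]
    gd = GenotypeData(gd.samples, gd.snps, gd.matrix, pheno)

    blocks = gene_blocks(config)
    gene_ids = [f"G{g + 1:02d}" for g in range(config.n_genes)]
    genes = []
    for g, block in enumerate(blocks):
        chroms = {gd.snps[j].chrom for j in block}
        if len(chroms) > 1:  # keep genes on one chromosome: trim the block
            first = gd.snps[block[0]].chrom
            block = [j for j in block if gd.snps[j].chrom == first]
            blocks[g] = block
        lo = min(gd.snps[j].pos for j in block)
        hi = max(gd.snps[j].pos for j in block)
        genes.append(GeneRecord(gene_ids[g], gd.snps[block[0]].chrom, lo, hi))

    rng = np.random.default_rng(config.seed + 3)
    eqtls: list[EqtlRecord] = []
    pair_snps = planted_snps(config, blocks)
    planted_cols = {a for a, _ in pair_snps} | {b for _, b in pair_snps}
    for g, block in enumerate(blocks):
        for j in block:
            maf = gd.snps[j].maf
            maf = float(np.clip(maf, 0.01, 0.49)) if np.isfinite(maf) else 0.25
            z = float(rng.normal(0, 1)) + np.sign(rng.normal()) * config.background_z
            eqtls.append(EqtlRecord(gd.snps[j].id, gene_ids[g], z, maf,
                                    EQTL_COHORT_SIZE))
    # planted pairs get controlled Z signs on their interaction SNPs
    for pp, (a, b) in zip(config.planted_pairs, pair_snps):
        for col, gene, z in ((a, pp.gene_a, pp.z1), (b, pp.gene_b, pp.z2)):
            for k, rec in enumerate(eqtls):
                if rec.snp_id == gd.snps[col].id and rec.gene_id == gene_ids[gene]:
                    eqtls[k] = EqtlRecord(rec.snp_id, rec.gene_id, z,
                                          rec.maf, rec.n)

    consequences: dict[str, set[str]] = {}
    for j, s in enumerate(gd.snps):
        if j in planted_cols or rng.random() < config.missense_fraction:
            consequences[s.id] = {"missense"}
        else:
            consequences[s.id] = {"intron_variant"}

    known_edges = []
    for _ in range(config.n_genes):
        a, b = rng.choice(config.n_genes, size=2, replace=False)
        known_edges.append(sorted((gene_ids[a], gene_ids[b])))
    disease_map = {
        "map_id": config.map_id,
        "genes": gene_ids,
        "edges": sorted(map(list, {tuple(e) for e in known_edges})),
    }

    planted_gene_pairs = [
        tuple(sorted((gene_ids[pp.gene_a], gene_ids[pp.gene_b])))
        for pp in config.planted_pairs
    ]
    bundle = FixtureBundle(gd, genes, eqtls, consequences, disease_map,
                           models, config, gene_ids, planted_gene_pairs)
    if outdir is not None:
        write_fixture(bundle, outdir)
    return bundle


def write_fixture(bundle: FixtureBundle, outdir: str | Path,
                  plink: bool = False) -> None:
    """Write every input file of the bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(bundle.genotypes, outdir / "cohort", format="tsv")
    if plink:
        write_genotypes(bundle.genotypes, outdir / "cohort", format="plink")
    pd.DataFrame(
        [{"gene": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
         for g in bundle.genes]
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"snp": e.snp_id, "gene": e.gene_id, "zscore": e.zscore,
          "maf": e.maf, "n": e.n} for e in bundle.eqtls]
    ).to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"snp": s, "consequence": t} for s, terms in
         sorted(bundle.consequences.items()) for t in sorted(terms)]
    ).to_csv(outdir / "consequences.tsv", sep="\t", index=False)
    with open(outdir / "disease_map.yaml", "w") as fh:
        yaml.safe_dump(bundle.disease_map, fh, sort_keys=False)


def read_disease_map(path: str | Path) -> dict:
    """Disease-map YAML: map_id, gene list and known biological edges."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("map_id", "genes"):
        if key not in doc:
            raise ValueError(f"disease map missing {key!r}")
    doc.setdefault("edges", [])
    return doc


def preset(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study conditions: "small" (fast smoke) or "paper-shaped"
    (map-scale gene counts)."""
    if name == "small":
        return SyntheticConfig(
            n_samples=400, p_snps=40, n_chromosomes=2, K_true=2, n_genes=8,
            min_gene_snps=2, max_gene_snps=6,
            planted_pairs=[PlantedPair(gene_a=0, gene_b=4, alpha12=1.5)],
            seed=seed,
        )
    if name == "paper-shaped":
        return SyntheticConfig(
            n_samples=2000, p_snps=150, n_chromosomes=3, K_true=4, n_genes=25,
            min_gene_snps=2, max_gene_snps=10,
            planted_pairs=[PlantedPair(gene_a=0, gene_b=12, alpha12=1.0),
                           PlantedPair(gene_a=3, gene_b=20, alpha12=-1.0,
                                       z1=8.0, z2=-8.0)],
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")
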