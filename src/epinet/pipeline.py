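"""End-to-end orchestration of the per-map epistasis workflow.

For each disease map: map SNPs to genes (physically and via cis-eQTLs), fit
the haplotype-cluster model per chromosome, score every mapped SNP as a
target, aggregate ranks into gene-pair scores, keep the top 2% as epistatic
edges, apply the missense filter (physical mapping) and the same-sign
direction filter (eQTL mapping), and report network topology with
permutation p-values.  A manifest records seeds and parameters so a run can
be reproduced bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregation import (GenePairScore, gene_pair_scores, rank_matrix,
                          select_top_pairs)
from .direction import evaluate_directions, same_sign_filter
from .epistasis import ScoringConfig, score_all_targets
from .gwas_io import GenotypeData, balance_controls, genomic_inflation, \
    read_genotypes, trend_chi2
from .hmm import HaplotypeClusterModel, fit_hmm
from .mapping import (SnpGeneMap, filter_missense, map_eqtl, map_physical,
                      read_consequence_table, read_eqtl_table, read_gene_table)
from .network import EpistaticNetwork, build_network, topology_report
from .synthetic import read_disease_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    genotypes: str
    genotype_format: str = "tsv"
    genes: str = "genes.tsv"
    eqtl: str = "eqtl.tsv"
    consequences: str = "consequences.tsv"
    disease_maps: list[str] = field(default_factory=list)
    mappings: list[str] = field(default_factory=lambda: ["physical", "eqtl"])
    balance: bool = True
    hmm_K: int = 4
    hmm_iters: int = 20
    hmm_restarts: int = 2
    l1_ratio: float = 0.5
    n_folds: int = 5
    outcome_variant: str = "robust"
    encoding: str = "dominant"
    selection_fraction: float = 0.02
    permutation_S: int = 1000
    clip_eps: float = 0.01
    seed: int = 0
    outdir: str = "epinet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class MapResult:
    """Artifacts of one disease map's analysis."""

    map_id: str
    gene_scores: dict[str, list[GenePairScore]]
    edges: dict[str, list[GenePairScore]]
    missense_pairs: list[GenePairScore]
    direction_table: pd.DataFrame
    topology: pd.DataFrame
    networks: dict[str, EpistaticNetwork]


def fit_chromosome_models(gd: GenotypeData, K: int, n_iter: int, seed: int,
                          n_restarts: int = 2) -> dict[str, HaplotypeClusterModel]:
    """Fit the mosaic model for every chromosome of the cohort."""
    M = gd.imputed_matrix().astype(int)
    models = {}
    for k, (chrom, idx) in enumerate(sorted(gd.chromosomes().items())):
        models[chrom] = fit_hmm(
            M[:, idx], K=K, n_iter=n_iter, seed=seed + 1000 * k, chrom=chrom,
            snp_ids=[gd.snps[j].id for j in idx], n_restarts=n_restarts,
        )
        logger.info("chromosome %s: HMM fitted, loglik %.2f", chrom,
                    models[chrom].loglik_history[-1])
    return models


def prepare_cohort(config: RunConfig) -> GenotypeData:
    """Load the cohort, QC-log the inflation factor, balance controls."""
    gd = read_genotypes(config.genotypes, config.genotype_format)
    gif = genomic_inflation(trend_chi2(gd))
    logger.info("genomic inflation factor: %.3f over %d SNPs", gif, gd.n_snps)
    if config.balance:
        assert gd.phenotype is not None
        n_cases = int((gd.phenotype == 1).sum())
        n_controls = int((gd.phenotype == 0).sum())
        if n_controls > n_cases:
            keep = balance_controls(gd.phenotype, seed=config.seed)
            gd = gd.subset_samples(keep).recode_minor()
            logger.info("controls subsampled: %d cases / %d controls retained",
                        n_cases, n_cases)
    return gd


def run_map(config: RunConfig, gd: GenotypeData,
            models: dict[str, HaplotypeClusterModel],
            disease_map: dict) -> MapResult:
    """Run the full workflow for one disease map."""
    map_id = str(disease_map["map_id"])
    genes_all = read_gene_table(config.genes)
    map_gene_ids = set(map(str, disease_map["genes"]))
    genes = [g for g in genes_all if g.gene_id in map_gene_ids]
    eqtl_table = read_eqtl_table(config.eqtl)
    consequences = read_consequence_table(config.consequences)

    maps: dict[str, SnpGeneMap] = {}
    if "physical" in config.mappings:
        maps["physical"] = map_physical(gd.snps, genes)
    if "eqtl" in config.mappings:
        maps["eqtl"] = map_eqtl(gd.snps, eqtl_table, genes)

    scoring = ScoringConfig(
        l1_ratio=config.l1_ratio, n_folds=config.n_folds,
        variant=config.outcome_variant, encoding=config.encoding,
        eps=config.clip_eps, seed=config.seed,
    )

    gene_scores: dict[str, list[GenePairScore]] = {}
    edges: dict[str, list[GenePairScore]] = {}
    networks: dict[str, EpistaticNetwork] = {}
    for mtype, smap in maps.items():
        if smap.n_genes < 2:
            logger.warning("map %s / %s: fewer than 2 genes with mapped SNPs; "
                           "skipped", map_id, mtype)
            continue
        sm = score_all_targets(gd, smap, models, scoring)
        rm = rank_matrix(sm)
        scores = gene_pair_scores(rm, smap)
        gene_scores[mtype] = scores
        edges[mtype] = select_top_pairs(scores, config.selection_fraction)
        networks[mtype] = build_network(
            [e.genes for e in edges[mtype]],
            set(smap.genes), map_id=map_id, provenance=mtype,
        )

    if not networks:
        raise ValueError(f"map {map_id}: no mapping produced >= 2 mapped genes")
    if {"physical", "eqtl"} <= set(networks):
        networks["joint"] = networks["physical"].union(networks["eqtl"])

    missense_pairs: list[GenePairScore] = []
    if "physical" in edges:
        missense_pairs = filter_missense(edges["physical"], gd.snp_ids,
                                         consequences)

    direction_table = pd.DataFrame()
    if "eqtl" in edges:
        beta_lookup = {(r.snp_id, r.gene_id): r.beta for r in eqtl_table}
        y01 = gd.phenotype.astype(float)
        results = evaluate_directions(edges["eqtl"], gd.imputed_matrix(),
                                      gd.snp_ids, beta_lookup, y01)
        kept = same_sign_filter(results)
        kept_ids = {(r.gene_a, r.gene_b) for r in kept}
        rows = []
        for r in results:
            rows.append({
                "gene_a": r.gene_a, "gene_b": r.gene_b,
                "snp_a": r.snp_a, "snp_b": r.snp_b,
                "alpha12": r.alpha12, "beta1": r.beta1, "beta2": r.beta2,
                "direction": r.direction if r.direction is not None else 0,
                "converged": r.converged,
                "same_sign": (r.gene_a, r.gene_b) in kept_ids,
                "reading": r.reading or "",
            })
        direction_table = pd.DataFrame(rows)

    topo = topology_report(list(networks.values()), S=config.permutation_S,
                           seed=config.seed)
    return MapResult(map_id, gene_scores, edges, missense_pairs,
                     direction_table, topo, networks)


def _write_map_result(res: MapResult, outdir: Path) -> None:
    d = outdir / res.map_id
    d.mkdir(parents=True, exist_ok=True)
    for mtype, scores in res.gene_scores.items():
        pd.DataFrame(
            [{"gene_a": g.gene_a, "gene_b": g.gene_b, "score": g.score,
              "best_snp_a": g.best_snp_a, "best_snp_b": g.best_snp_b,
              "best_snp_score": g.best_pair_score} for g in scores]
        ).to_csv(d / f"gene_scores_{mtype}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_a": g.gene_a, "gene_b": g.gene_b, "score": g.score}
             for g in res.edges[mtype]]
        ).to_csv(d / f"edges_{mtype}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene_a": g.gene_a, "gene_b": g.gene_b, "score": g.score}
         for g in res.missense_pairs]
    ).to_csv(d / "missense_pairs.tsv", sep="\t", index=False)
    res.direction_table.to_csv(d / "direction.tsv", sep="\t", index=False)
    res.topology.to_csv(d / "topology.tsv", sep="\t", index=False)


def run(config: RunConfig) -> list[MapResult]:
    """Run every disease map; failures abort the map, not the run."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gd = prepare_cohort(config)
    models = fit_chromosome_models(gd, config.hmm_K, config.hmm_iters,
                                   config.seed, config.hmm_restarts)
    results = []
    for path in config.disease_maps:
        dmap = read_disease_map(path)
        try:
            res = run_map(config, gd, models, dmap)
        except Exception:
            logger.exception("map %s failed; continuing with remaining maps",
                             dmap.get("map_id"))
            continue
        _write_map_result(res, outdir)
        results.append(res)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "maps_completed": [r.map_id for r in results],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
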