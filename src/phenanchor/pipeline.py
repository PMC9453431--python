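"""End-to-end pipeline driver.

Stage order mirrors the analysis: differential expression -> trend-gated
BMC modeling -> co-expression network with modules -> leave-one-concentration-
out perturbation -> phenotype fit and anchoring report.  Every stage draws
its own seed from the global seed and the stage name, so adding a stage
never perturbs another stage's stream, and a rerun with the same config is
bit-identical for the deterministic stages.  A manifest records the output
files, their SHA-256 hashes, the config hash and any stage failures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as pio
from .bmc import BmcConfig, gene_bmc_table, geneset_bmc
from .datatypes import CountMatrix, ExperimentDesign, PhenotypeTable
from .dge import DgeConfig, deg_partition, filter_low_counts, nb_wald, normalize_counts, size_factors
from .anchoring import anchor_report, hypergeometric_enrichment, ward_cluster
from .loco import classify_edges, edge_weight_ratios, loco_networks, loco_summary, module_weight_matrix
from .network import (
    CoexpressionNetwork,
    NetworkConfig,
    centralities,
    detect_modules,
    fold_change_matrix,
    infer_network,
    select_top_cv,
    threshold_network,
)
from .phenotype import fit_loglogistic, phenotype_bmc

logger = logging.getLogger("phenanchor")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


@dataclass
class PipelineConfig:
    counts: Optional[str] = None
    design: Optional[str] = None
    phenotype: Optional[str] = None
    gmt: Optional[str] = None
    outdir: str = "phenanchor_run"
    seed: int = 0
    teratogenic_concs: tuple[float, ...] = (20.0, 50.0)
    anchor_module: Optional[int] = None  # default: module with most trend-passing genes
    bmr_added_risk: float = 0.10
    dge: DgeConfig = field(default_factory=DgeConfig)
    bmc: BmcConfig = field(default_factory=BmcConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    n_bmc_bootstrap: int = 0  # per-gene BMDL/BMDU bootstrap draws in the run
    loco_tau_threshold: float = 1.0

    def config_hash(self) -> str:
        """Hash of the analysis parameters only: input/output paths do not
        affect the computation, so identical analyses hash identically."""
        payload = dataclasses.asdict(self)
        for key in ("counts", "design", "phenotype", "gmt", "outdir"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    counts: Optional[CountMatrix] = None,
    design: Optional[ExperimentDesign] = None,
    phenotype: Optional[PhenotypeTable] = None,
    gene_sets: Optional[dict[str, set[str]]] = None,
) -> dict:
    """Run every stage, writing outputs and a manifest under ``cfg.outdir``.

    Inputs may be passed in memory or read from the paths in the config.
    A stage failure is recorded in the manifest and later stages that
    depend on it are skipped; the manifest's ``complete`` flag reports
    whether everything ran.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
        "errors": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)

    def fail(stage: str, exc: Exception) -> None:
        logger.error("stage %s failed: %s", stage, exc)
        manifest["stages"][stage] = "failed"
        manifest["errors"][stage] = "".join(
            traceback.format_exception_only(type(exc), exc)
        ).strip()

    if counts is None and cfg.counts:
        counts = pio.read_counts(cfg.counts)
    if design is None and cfg.design:
        design = pio.read_design(cfg.design)
    if phenotype is None and cfg.phenotype:
        try:
            phenotype = pio.read_phenotype(cfg.phenotype)
        except FileNotFoundError as exc:
            logger.warning("phenotype input missing, anchoring will be skipped: %s", exc)
    if gene_sets is None and cfg.gmt:
        gene_sets = pio.read_gmt(cfg.gmt)
    if counts is None or design is None:
        raise ValueError("counts and design are required inputs")

    # ---- dge ------------------------------------------------------------
    results = None
    norm = None
    try:
        filtered = filter_low_counts(counts, cfg.dge)
        sf = size_factors(filtered)
        norm = normalize_counts(filtered, sf)
        results = nb_wald(filtered, design, cfg.dge)
        partition = deg_partition(results, set(cfg.teratogenic_concs))
        p_dge = outdir / "dge_results.tsv"
        with open(p_dge, "w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
            results.to_csv(fh, sep="\t", index=False)
        p_part = outdir / "deg_partition.json"
        pio.write_json({k: sorted(v) for k, v in partition.items()}, p_part)
        record("dge", p_dge, p_part)
    except Exception as exc:
        fail("dge", exc)

    # ---- trend_bmc ------------------------------------------------------
    bmc_records = None
    bmc_table = None
    if norm is not None:
        try:
            log_expr = np.log2(norm + cfg.dge.pseudocount)
            bmc_table, bmc_records = gene_bmc_table(
                log_expr,
                design,
                cfg.bmc,
                seed=stage_seed(cfg.seed, "trend_bmc"),
                n_boot=cfg.n_bmc_bootstrap,
            )
            p_bmc = outdir / "gene_bmc.tsv"
            with open(p_bmc, "w") as fh:
                for key, value in meta.items():
                    fh.write(f"# {key}={value}\n")
                fh.write("# bmr_sd=pooled_model_residual_sd\n")
                bmc_table.to_csv(fh, sep="\t", index=False)
            record("trend_bmc", p_bmc)
        except Exception as exc:
            fail("trend_bmc", exc)

    # ---- coexpr_network -------------------------------------------------
    net: Optional[CoexpressionNetwork] = None
    fc = None
    edges = None
    module_of = None
    if norm is not None:
        try:
            net_cfg = dataclasses.replace(
                cfg.network, seed=stage_seed(cfg.seed, "coexpr_network")
            )
            fc = fold_change_matrix(norm, design, cfg.dge.pseudocount)
            n_top = min(net_cfg.n_top_cv, fc.shape[0])
            fc = select_top_cv(fc, n_top)
            edges = infer_network(fc, net_cfg)
            net = threshold_network(edges, net_cfg)
            if len(net.edges):
                module_of = detect_modules(net)
                cent = centralities(net)
            else:
                module_of, cent = {}, pd.DataFrame()
            p_edges = outdir / "network_edges.tsv"
            pio.write_edges(net.edges, p_edges, metadata=meta)
            p_mod = outdir / "network_modules.tsv"
            pd.Series(module_of, name="module_id").rename_axis("gene_id").to_csv(
                p_mod, sep="\t"
            )
            p_cent = outdir / "network_centralities.tsv"
            cent.to_csv(p_cent, sep="\t", index=False)
            p_gml = outdir / "network.graphml"
            pio.write_graphml(net.edges, p_gml)
            p_sif = outdir / "network.sif"
            pio.write_sif(net.edges, p_sif)
            record("coexpr_network", p_edges, p_mod, p_cent, p_sif)
        except Exception as exc:
            fail("coexpr_network", exc)

    # ---- loco_perturbation ----------------------------------------------
    module_genes: Optional[set[str]] = None
    if fc is not None and edges is not None and module_of:
        try:
            if cfg.anchor_module is not None:
                module_id = cfg.anchor_module
            elif bmc_table is not None:
                # default: the module richest in trend-responsive genes
                passing = set(bmc_table.loc[bmc_table["trend_passes"], "gene_id"])
                score = pd.Series(module_of).groupby(pd.Series(module_of)).size() * 0.0
                for g, m in module_of.items():
                    if g in passing:
                        score[m] = score.get(m, 0) + 1
                module_id = int(score.idxmax()) if score.max() > 0 else int(
                    pd.Series(module_of).value_counts().index[0]
                )
            else:
                module_id = int(pd.Series(module_of).value_counts().index[0])
            module_genes = {g for g, m in module_of.items() if m == module_id}
            if len(module_genes) >= 2:
                net_cfg = dataclasses.replace(
                    cfg.network, seed=stage_seed(cfg.seed, "coexpr_network")
                )
                full_w = module_weight_matrix(edges, module_genes)
                reduced = loco_networks(fc, design, module_genes, net_cfg)
                ratios = edge_weight_ratios(full_w, reduced)
                classes = classify_edges(ratios, tau_threshold=cfg.loco_tau_threshold)
                p_ratio = outdir / "loco_ratios.tsv"
                with open(p_ratio, "w") as fh:
                    for key, value in meta.items():
                        fh.write(f"# {key}={value}\n")
                    ratios.to_csv(fh, sep="\t")
                p_cls = outdir / "loco_classification.tsv"
                classes.to_csv(p_cls, sep="\t")
                p_sum = outdir / "loco_summary.json"
                pio.write_json(
                    {"module_id": module_id, **loco_summary(classes)}, p_sum
                )
                record("loco_perturbation", p_ratio, p_cls, p_sum)
            else:
                manifest["stages"]["loco_perturbation"] = "skipped (module too small)"
        except Exception as exc:
            fail("loco_perturbation", exc)

    # ---- phenotype ------------------------------------------------------
    pheno_fit = None
    if phenotype is not None:
        try:
            pheno_fit = fit_loglogistic(phenotype)
            pheno_fit = phenotype_bmc(pheno_fit, cfg.bmr_added_risk)
            p_fit = outdir / "phenotype_fit.json"
            pio.write_json(pheno_fit.to_dict(), p_fit)
            record("phenotype", p_fit)
        except Exception as exc:
            fail("phenotype", exc)
    else:
        manifest["stages"]["phenotype"] = "skipped (no phenotype input)"

    # ---- anchoring_enrichment -------------------------------------------
    try:
        wrote = []
        if results is not None:
            partition = deg_partition(results, set(cfg.teratogenic_concs))
            overlap = partition["overlap"]
            if len(overlap) >= 2:
                profiles = (
                    results[results["gene_id"].isin(overlap)]
                    .pivot_table(index="gene_id", columns="concentration", values="log2fc")
                    .fillna(0.0)
                )
                k = min(6, profiles.shape[0])
                clusters = ward_cluster(profiles, k_clusters=k)
                p_clu = outdir / "overlap_clusters.tsv"
                clusters.rename_axis("gene_id").to_csv(p_clu, sep="\t")
                wrote.append(p_clu)
            if gene_sets:
                background = set(counts.gene_ids)
                for name, genes in partition.items():
                    if not genes:
                        continue
                    enr = hypergeometric_enrichment(genes, gene_sets, background)
                    p_enr = outdir / f"enrichment_{name}.tsv"
                    enr.to_csv(p_enr, sep="\t", index=False)
                    wrote.append(p_enr)
        if (
            bmc_records is not None
            and pheno_fit is not None
            and module_genes is not None
        ):
            summary = geneset_bmc(bmc_records, module_genes)
            report = anchor_report(summary, pheno_fit, module_id=module_id)
            p_anchor = outdir / "anchor_report.json"
            pio.write_json(report.to_dict(), p_anchor)
            wrote.append(p_anchor)
        if wrote:
            record("anchoring_enrichment", *wrote)
        else:
            manifest["stages"]["anchoring_enrichment"] = "skipped (missing upstream outputs)"
    except Exception as exc:
        fail("anchoring_enrichment", exc)

    manifest["complete"] = all(v == "ok" for v in manifest["stages"].values())
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest
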