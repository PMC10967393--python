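"""End-to-end orchestration: simulate -> threshold/TPM -> DE -> network ->
modules -> preservation -> genetics -> hubs -> screen, with one seed, a YAML
config, and a provenance manifest of parameter and artifact checksums."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann_io
from . import diffexpr, genetics, hub_pca, module_analysis, network, preservation
from . import screen as screen_mod
from . import synthetic
from .expression import log_transform, threshold_genes, tpm_normalize

log = logging.getLogger("lncnet")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "lncnet_run"
    # simulation (used when no input paths are given)
    cohort: dict = field(default_factory=dict)
    n_snps: int = 250
    snp_enriched_modules: tuple = ("M1",)
    snp_enrichment_excess: float = 0.35
    screen_n_genes: int = 200
    screen_regulators: dict = field(default_factory=lambda: {
        "T0000": 1.5, "T0001": -1.5})
    # analysis parameters
    min_reads: int = 10
    min_frac: float = 0.40
    covariates: tuple = ("batch",)
    soft_power: int | None = 6
    min_module_size: int = 30
    merge_cut_height: float = 0.20
    de_location: str = "rectum"
    de_contrast: str = "UC-inf"
    frac_train: float = 0.70
    n_permutations: int = 50
    n_boot: int = 2000
    snp_window: int = 50_000
    hub_threshold: float = 0.05
    screen_n_perm: int = 200
    screen_bin: str = "TNF_hi"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def demo_config(seed: int = 0, outdir: str = "lncnet_demo") -> PipelineConfig:
    """A small cohort exercising every stage in a few CPU-minutes."""
    return PipelineConfig(
        seed=seed, outdir=outdir,
        cohort=dict(n_patients=60, n_genes=800, n_modules=4,
                    module_sizes=(120, 90, 70, 50)),
    )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the provenance manifest (also written).

    All randomness is routed through per-stage seeds derived from
    ``config.seed``, so two runs with the same config are byte-identical.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(s.generate_state(1)[0] % (2 ** 31))
                  for name, s in zip(
            ["cohort", "snps", "screen", "split", "zsummary", "stars"],
            ss.spawn(6))}

    # --- simulate ----------------------------------------------------------
    log.info("stage: simulate")
    cohort_cfg = synthetic.CohortConfig(**{**config.cohort,
                                           "seed": stage_seed["cohort"]})
    annotation, meta, counts, truth = synthetic.generate_cohort(cohort_cfg)
    sim_dir = out / "simulate"
    synthetic.write_cohort(sim_dir, annotation, meta, counts, truth)
    snps = synthetic.generate_snp_catalog(
        annotation, list(config.snp_enriched_modules), truth,
        n_snps=config.n_snps, enrichment_excess=config.snp_enrichment_excess,
        seed=stage_seed["snps"])
    synthetic.write_snps(snps, sim_dir / "snps.bed")
    screen_table = synthetic.generate_screen(
        n_genes=config.screen_n_genes, regulators=config.screen_regulators,
        seed=stage_seed["screen"])
    screen_table.to_csv(sim_dir / "screen.tsv", sep="\t", index=False)

    # --- expression --------------------------------------------------------
    log.info("stage: expression")
    retained, retention = threshold_genes(
        counts, min_reads=config.min_reads, min_frac=config.min_frac,
        annotation=annotation)
    lengths = annotation.set_index("gene_id")["length"]
    tpm = tpm_normalize(counts, lengths, retained)
    logtpm = log_transform(tpm)
    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    retention.to_csv(expr_dir / "retention.tsv", sep="\t")
    pd.Series(retained).to_csv(expr_dir / "retained_genes.tsv", sep="\t",
                               index=False, header=["gene_id"])

    # --- differential expression ------------------------------------------
    log.info("stage: differential expression")
    de_spec = diffexpr.DeModelSpec(contrast=config.de_contrast)
    de = diffexpr.run_de(logtpm, annotation, de_spec, config.de_location)
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    de.to_csv(de_dir / f"{config.de_location}_{config.de_contrast}.tsv", sep="\t")
    de_sets = diffexpr.call_de(de)

    # --- network -----------------------------------------------------------
    log.info("stage: network")
    resid = network.regress_covariates(logtpm, list(config.covariates))
    beta = config.soft_power
    _, sft_table = network.pick_soft_threshold(resid)
    if beta is None:
        beta, _ = network.pick_soft_threshold(resid)
    net = network.adjacency(resid, beta)
    network.tom(net)
    assignment = network.detect_modules(net.dissimilarity, net.genes,
                                        min_module_size=config.min_module_size)
    net_dir = out / "network"
    net_dir.mkdir(exist_ok=True)
    sft_table.to_csv(net_dir / "soft_threshold.tsv", sep="\t", index=False)
    assignment.labels.to_csv(net_dir / "modules_unmerged.tsv", sep="\t")

    # --- module analysis ---------------------------------------------------
    log.info("stage: modules")
    mes = module_analysis.eigengenes(resid, assignment)
    merged, mes, lineage = module_analysis.merge_modules(
        mes, assignment, resid, cut_height=config.merge_cut_height)
    kme_tab = module_analysis.kme(resid, mes)
    kim = module_analysis.intramodular_connectivity(net, merged)
    traits = synthetic.trait_design(meta)
    r, p, stars = module_analysis.module_trait_correlation(mes, traits)
    composition = module_analysis.module_composition(merged, annotation)
    mod_dir = out / "modules"
    mod_dir.mkdir(exist_ok=True)
    merged.labels.to_csv(mod_dir / "modules.tsv", sep="\t")
    mes.scores.to_csv(mod_dir / "eigengenes.tsv", sep="\t")
    kme_tab.to_csv(mod_dir / "kme.tsv", sep="\t")
    trait_tab = r.round(6).astype(str) + stars
    trait_tab.to_csv(mod_dir / "module_trait.tsv", sep="\t")
    composition.to_csv(mod_dir / "composition.tsv", sep="\t")
    json.dump(lineage, open(mod_dir / "merge_lineage.json", "w"), indent=1)

    # --- preservation ------------------------------------------------------
    log.info("stage: preservation")
    train_ids, test_ids = preservation.stratified_split(
        meta, frac_train=config.frac_train, seed=stage_seed["split"])
    train_expr = resid.subset_samples(train_ids)
    test_expr = resid.subset_samples(test_ids)
    train_net = network.adjacency(train_expr.subset_genes(net.genes), beta)
    report = preservation.zsummary(
        train_net, merged, train_expr, test_expr,
        n_permutations=config.n_permutations, seed=stage_seed["zsummary"])
    pres_dir = out / "preservation"
    pres_dir.mkdir(exist_ok=True)
    report.table.to_csv(pres_dir / "zsummary.tsv", sep="\t")

    # --- genetics ----------------------------------------------------------
    log.info("stage: genetics")
    net_ann = annotation[annotation["gene_id"].isin(net.genes)]
    adjacency_map = genetics.snp_adjacent_genes(net_ann, snps,
                                                window=config.snp_window)
    enrich_rows = []
    for mod in merged.modules:
        res = genetics.bootstrap_enrichment(
            merged.genes_of(mod), net.genes, adjacency_map, annotation,
            n_boot=config.n_boot, seed=stage_seed["snps"], module_label=mod)
        enrich_rows.append({
            "module": mod,
            "lnc_observed": res.observed["lncRNA"],
            "lnc_p": res.p_value["lncRNA"],
            "pc_observed": res.observed["protein_coding"],
            "pc_p": res.p_value["protein_coding"]})
    gen_dir = out / "genetics"
    gen_dir.mkdir(exist_ok=True)
    pd.DataFrame(enrich_rows).to_csv(gen_dir / "snp_enrichment.tsv", sep="\t",
                                     index=False)
    bt = annotation.set_index("gene_id")["biotype"]
    lnc_map = {m: [g for g in merged.genes_of(m) if bt.get(g) == "lncRNA"]
               for m in merged.modules}
    dsp = genetics.disease_specific_proportions(lnc_map, adjacency_map, snps)
    dsp.to_csv(gen_dir / "disease_specific.tsv", sep="\t")
    de_all = de_sets["up"].union(de_sets["down"])
    overlap_rows = []
    for mod in merged.modules:
        ov, p_ov = genetics.module_de_overlap(
            merged.genes_of(mod), [g for g in de_all if g in set(net.genes)],
            universe_size=len(net.genes))
        overlap_rows.append({"module": mod, "overlap": ov, "p": p_ov})
    pd.DataFrame(overlap_rows).to_csv(gen_dir / "de_overlap.tsv", sep="\t",
                                      index=False)

    # --- hubs --------------------------------------------------------------
    log.info("stage: hubs")
    hub_dir = out / "hubs"
    hub_dir.mkdir(exist_ok=True)
    focus = max(merged.modules, key=lambda m: abs(r.loc[m].fillna(0)).max())
    export = hub_pca.hub_network(net, merged, focus, config.hub_threshold,
                                 annotation)
    export.write_graphml(hub_dir / f"{focus}.graphml")
    export.write_edge_tsv(hub_dir / f"{focus}_edges.tsv")
    contrib, scores = hub_pca.pca_contributions(resid, merged.genes_of(focus))
    contrib.to_csv(hub_dir / f"{focus}_pca.tsv", sep="\t")
    top = hub_pca.top_contributors(contrib, annotation, k=10)
    top.to_csv(hub_dir / f"{focus}_top_lncRNAs.tsv", sep="\t")

    # --- screen ------------------------------------------------------------
    log.info("stage: screen")
    guide_gene = screen_table.set_index("sgRNA")["gene"]
    lfc = screen_mod.sgRNA_log2fc(screen_table, config.screen_bin, "pooled")
    results = [
        screen_mod.stars_fdr(lfc, guide_gene, direction,
                             comparison=(config.screen_bin, "pooled"),
                             n_perm=config.screen_n_perm,
                             seed=stage_seed["stars"])
        for direction in ("enriched", "depleted")]
    hits = screen_mod.call_hits(results)
    screen_dir = out / "screen"
    screen_dir.mkdir(exist_ok=True)
    for res in results:
        res.table.to_csv(screen_dir / f"stars_{res.direction}.tsv", sep="\t")
    hits.to_csv(screen_dir / "hits.tsv", sep="\t", index=False)

    # --- manifest ----------------------------------------------------------
    artifacts = sorted(p for p in out.rglob("*") if p.is_file()
                       and p.name != "manifest.json")
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else
                       str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "stage_seeds": stage_seed,
        "modules": {"n_unmerged": len(assignment.modules),
                    "n_merged": len(merged.modules)},
        "artifacts": {str(p.relative_to(out)): _checksum(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
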