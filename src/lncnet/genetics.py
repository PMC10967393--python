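"""Linking coexpression modules to disease genetics: SNP-adjacency windows,
composition-matched bootstrap enrichment, disease-specific SNP proportions,
and hypergeometric overlap of module and differential-expression gene sets.

A gene is SNP-adjacent when a catalog SNP falls inside the gene body
extended by a window (default 50 kb) on each side; coordinates are 0-based
half-open, the extended window clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


def snp_adjacent_genes(annotation: pd.DataFrame, snps: pd.DataFrame,
                       window: int = 50_000) -> dict[str, list[str]]:
    """Map gene_id -> list of SNP ids within the gene's extended window.

    A SNP at position p is adjacent to a gene (start, end) iff
    max(0, start - window) <= p < end + window on the same chromosome.
    Genes with no adjacent SNP are present with an empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for rec in annotation.itertuples():
        lo = max(0, rec.start - window)
        hi = rec.end + window
        trees.setdefault(rec.chrom, IntervalTree()).addi(lo, hi, rec.gene_id)

    out: dict[str, list[str]] = {g: [] for g in annotation["gene_id"]}
    for snp in snps.itertuples():
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for hit in tree.at(snp.position):
            out[hit.data].append(snp.snp_id)
    return out


@dataclass
class EnrichmentResult:
    module: str
    observed: dict          # biotype -> observed SNP-adjacent proportion
    background: dict        # biotype -> universe SNP-adjacent proportion
    p_value: dict           # biotype -> one-sided bootstrap p (NaN if absent)
    n_boot: int


def bootstrap_enrichment(
    module_genes,
    universe,
    adjacency_map: dict,
    annotation: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    module_label: str = "",
) -> EnrichmentResult:
    """Composition-matched bootstrap test of SNP-adjacency enrichment.

    Null draws sample, without replacement, gene sets of the module's size
    with the module's lncRNA / protein-coding composition from the
    universe; the one-sided p per biotype is
    (1 + #{draws with proportion >= observed}) / (1 + n_boot).
    """
    module_genes = pd.Index(module_genes)
    universe = pd.Index(universe)
    if not module_genes.isin(universe).all():
        raise ValueError("module genes must be a subset of the universe")

    bt = annotation.set_index("gene_id")["biotype"]
    adj = pd.Series({g: len(adjacency_map.get(g, [])) > 0 for g in universe})

    rng = np.random.default_rng(seed)
    observed, background, pvals = {}, {}, {}
    for biotype in ("lncRNA", "protein_coding"):
        uni_b = universe[bt.reindex(universe).values == biotype]
        mod_b = module_genes[bt.reindex(module_genes).values == biotype]
        background[biotype] = float(adj[uni_b].mean()) if len(uni_b) else np.nan
        if len(mod_b) == 0:
            observed[biotype] = np.nan
            pvals[biotype] = np.nan
            continue
        obs = float(adj[mod_b].mean())
        observed[biotype] = obs
        pool = adj[uni_b].values.astype(bool)
        m = len(mod_b)
        # a without-replacement draw of m genes enters the statistic only
        # through its adjacency count, so the count is drawn directly
        # (hypergeometric), which is distributionally identical to sampling
        # the gene sets themselves
        k_pool = int(pool.sum())
        counts = rng.hypergeometric(k_pool, len(pool) - k_pool, m, size=n_boot)
        hits = int((counts / m >= obs - 1e-12).sum())
        pvals[biotype] = (1 + hits) / (1 + n_boot)
    return EnrichmentResult(module_label, observed, background, pvals, n_boot)


def disease_specific_proportions(
    module_lnc_map: dict[str, list[str]],
    adjacency_map: dict,
    snps: pd.DataFrame,
    min_count: int = 3,
) -> pd.DataFrame:
    """UC vs CD fractions among each module's disease-specific SNP-adjacent lncRNAs.

    ``module_lnc_map`` maps module label -> its lncRNA gene ids.  A lncRNA
    counts as UC (CD) if any adjacent SNP is UC-specific (CD-specific);
    shared-only lncRNAs are excluded.  Modules with fewer than ``min_count``
    disease-specific SNP-adjacent lncRNAs are omitted.
    """
    label_of = snps.set_index("snp_id")["disease"]
    rows = []
    for module, lncs in module_lnc_map.items():
        n_uc = n_cd = 0
        for g in lncs:
            labels = {label_of[s] for s in adjacency_map.get(g, [])}
            uc = "UC-specific" in labels
            cd = "CD-specific" in labels
            n_uc += uc
            n_cd += cd
        total = n_uc + n_cd
        if total < min_count:
            continue
        rows.append({"module": module, "n_uc": n_uc, "n_cd": n_cd,
                     "uc_fraction": n_uc / total, "cd_fraction": n_cd / total})
    return pd.DataFrame(rows, columns=["module", "n_uc", "n_cd", "uc_fraction",
                                       "cd_fraction"]).set_index("module")


def module_de_overlap(module_genes, de_genes, universe_size: int) -> tuple[int, float]:
    """One-sided hypergeometric over-representation of a DE set in a module.

    P(X >= overlap) with X ~ Hypergeometric(N=universe, K=|module|, n=|de|).
    """
    module_genes, de_genes = set(module_genes), set(de_genes)
    overlap = len(module_genes & de_genes)
    K, n = len(module_genes), len(de_genes)
    if K > universe_size or n > universe_size:
        raise ValueError("sets larger than the universe")
    if overlap > min(K, n):
        raise ValueError("overlap exceeds the smaller set")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, K, n))
    return overlap, p
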