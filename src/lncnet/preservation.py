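"""Train/test network reproducibility: stratified splitting, cross-set
module membership, permutation Zsummary module preservation, and
betweenness-centrality overlap of high-influence nodes.

The Zsummary composite per module combines a density Z (mean within-module
adjacency in the test data) with a connectivity Z (median of the Z-scores
of cor(kIM_ref, kIM_test), cor(kME_ref, kME_test), and cor(a_ref, a_test)
over module genes/pairs), each standardized against a permutation null in
which module labels are reassigned to random same-size gene sets.
Zsummary > 10 is read as high preservation, 5-10 moderate, < 5 low.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .module_analysis import ModuleEigengenes, eigengenes, kme, project_eigengenes
from .network import GREY, CoexpressionNetwork, ModuleAssignment, adjacency


def stratified_split(sample_meta: pd.DataFrame, frac_train: float = 0.70,
                     strata: str = "severity", seed: int = 0):
    """Split samples into train/test, stratified on a metadata column.

    Per stratum, floor(frac_train * n) samples go to train (largest-remainder
    rounding of the overall target count); singleton strata go to train with
    a warning.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, idx in sample_meta.groupby(strata, observed=True).groups.items():
        ids = np.array(sorted(idx))
        if len(ids) == 1:
            import warnings
            warnings.warn(f"stratum of size 1 assigned to train")
            train.extend(ids)
            continue
        rng.shuffle(ids)
        n_train = int(np.floor(frac_train * len(ids)))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return pd.Index(sorted(train)), pd.Index(sorted(test))


def split_report(expr: ExpressionMatrix, train_ids, test_ids,
                 keys=("severity", "disease", "inflamed", "tissue")) -> dict:
    """Distribution tables per stratum and the per-gene mean-expression
    train-vs-test correlation with fitted slope."""
    tables = {}
    for key in keys:
        if key not in expr.sample_meta.columns:
            continue
        tab = pd.DataFrame({
            "train": expr.sample_meta.loc[train_ids, key].value_counts(normalize=True),
            "test": expr.sample_meta.loc[test_ids, key].value_counts(normalize=True),
        }).fillna(0.0)
        tables[key] = tab
    m_train = expr.values.loc[train_ids].mean(axis=0)
    m_test = expr.values.loc[test_ids].mean(axis=0)
    r = float(np.corrcoef(m_train, m_test)[0, 1])
    slope = float(np.polyfit(m_train, m_test, 1)[0])
    return {"tables": tables, "mean_expression_r": r, "mean_expression_slope": slope}


def cross_kme(test_expr: ExpressionMatrix, train_mes: ModuleEigengenes) -> pd.DataFrame:
    """kME of test-set genes against train-defined eigengenes.

    Test samples are projected onto the stored train eigengene weight
    vectors; test genes are then correlated against the projected scores.
    """
    projected = project_eigengenes(test_expr, train_mes)
    proxy = ModuleEigengenes(scores=projected,
                             variance_explained=train_mes.variance_explained)
    return kme(test_expr, proxy)


@dataclass
class PreservationReport:
    table: pd.DataFrame  # per module: Zdensity, Zconnectivity, Zsummary, class

    @staticmethod
    def classify(z: float) -> str:
        if z > 10:
            return "high"
        if z >= 5:
            return "moderate"
        return "low"


def _set_kme(Z: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """kME of a gene set against its own first principal component.

    ``Z`` is the gene-standardized sample x gene matrix (unit variance per
    column), so correlations reduce to dot products with the normalized
    eigengene.
    """
    X = Z[:, idx]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    me = U[:, 0]
    # columns of X are standardized, me is unit-norm and zero-mean, so the
    # correlation is me @ X / sqrt(n)
    return (me @ X) / np.sqrt(X.shape[0])


def _module_stats(a_test: np.ndarray, a_ref: np.ndarray,
                  z_test: np.ndarray, z_ref: np.ndarray,
                  idx: np.ndarray) -> np.ndarray:
    """(density, cor_kIM, cor_kME, cor_adj) for one gene set."""
    sub_t = a_test[np.ix_(idx, idx)]
    s = len(idx)
    density = (sub_t.sum() - np.trace(sub_t)) / (s * (s - 1))
    kim_t = sub_t.sum(axis=1) - np.diag(sub_t)
    sub_r = a_ref[np.ix_(idx, idx)]
    kim_r = sub_r.sum(axis=1) - np.diag(sub_r)
    triu = np.triu_indices(s, 1)

    def safe_cor(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    cor_kim = safe_cor(kim_r, kim_t)
    cor_kme = abs(safe_cor(_set_kme(z_ref, idx), _set_kme(z_test, idx)))
    cor_adj = safe_cor(sub_r[triu], sub_t[triu])
    return np.array([density, cor_kim, cor_kme, cor_adj])


def zsummary(
    ref_net: CoexpressionNetwork,
    assignment: ModuleAssignment,
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    n_permutations: int = 200,
    seed: int = 0,
) -> PreservationReport:
    """Permutation module-preservation Z statistics in a test data set.

    Observed per-module statistics compare the reference network against an
    adjacency built from the test expression at the same soft power:
    density (mean within-module test adjacency) and three connectivity
    correlations (kIM, kME, adjacency) between reference and test.  The
    null reassigns module labels to random same-size gene sets; every
    statistic is recomputed on both data sets per draw.  Modules smaller
    than 3 genes are skipped; grey is excluded.
    """
    genes = ref_net.genes
    test_net = adjacency(test_expr.subset_genes(genes), ref_net.beta)
    if not test_net.genes.equals(genes):
        raise ValueError("test expression lost genes (constant in test set)")
    a_test, a_ref = test_net.adjacency, ref_net.adjacency

    def standardized(e):
        X = e.values[list(genes)].values
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return (X - X.mean(axis=0)) / sd

    z_ref, z_test = standardized(ref_expr), standardized(test_expr)

    labels = assignment.labels.reindex(genes)
    rng = np.random.default_rng(seed)
    sizes = sorted({len(np.where(labels.values == m)[0]) for m in assignment.modules})
    # one shared null per distinct module size
    null_by_size = {}
    for s in sizes:
        if s < 3:
            continue
        null = np.empty((n_permutations, 4))
        for b in range(n_permutations):
            perm = rng.choice(len(genes), size=s, replace=False)
            null[b] = _module_stats(a_test, a_ref, z_test, z_ref, perm)
        null_by_size[s] = null

    rows = []
    for mod in assignment.modules:
        idx = np.where(labels.values == mod)[0]
        if len(idx) < 3:
            continue
        obs = _module_stats(a_test, a_ref, z_test, z_ref, idx)
        null = null_by_size[len(idx)]
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        sd[sd == 0] = np.nan
        z = (obs - mu) / sd
        z_density = z[0]
        z_connectivity = np.nanmedian(z[1:])
        z_summary = (z_density + z_connectivity) / 2
        rows.append({"module": mod, "n_genes": len(idx),
                     "Zdensity": z_density, "Zconnectivity": z_connectivity,
                     "Zsummary": z_summary,
                     "preservation": PreservationReport.classify(z_summary)})
    return PreservationReport(pd.DataFrame(rows).set_index("module"))


def betweenness(tom_matrix: np.ndarray, genes: pd.Index,
                edge_threshold: float) -> pd.Series:
    """Betweenness centrality on the binarized graph TOM >= threshold.

    Unweighted shortest paths; isolated nodes get 0.
    """
    t = np.asarray(tom_matrix)
    mask = np.triu(t >= edge_threshold, k=1)
    g = nx.Graph()
    g.add_nodes_from(range(len(genes)))
    g.add_edges_from(zip(*np.where(mask)))
    bc = nx.betweenness_centrality(g, normalized=False)
    return pd.Series([bc[i] for i in range(len(genes))], index=genes, name="bc")


def bc_overlap(
    tom_a: np.ndarray, tom_b: np.ndarray, genes: pd.Index,
    biotypes: pd.Series, edge_threshold: float, quantile: float = 0.75,
) -> pd.Series:
    """Overlap of high-influence nodes between two networks, per biotype.

    High-influence = betweenness centrality in the top (1 - quantile) tail
    of each network; overlap = |top_a & top_b| / |top_a| within biotype.
    """
    bc_a = betweenness(tom_a, genes, edge_threshold)
    bc_b = betweenness(tom_b, genes, edge_threshold)
    bt = biotypes.reindex(genes)
    out = {}
    for biotype in bt.dropna().unique():
        sel = bt == biotype
        a, b = bc_a[sel], bc_b[sel]
        top_a = set(a[a >= a.quantile(quantile)].index)
        top_b = set(b[b >= b.quantile(quantile)].index)
        out[biotype] = len(top_a & top_b) / len(top_a) if top_a else np.nan
    return pd.Series(out, name="bc_overlap")
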