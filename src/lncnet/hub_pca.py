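"""Hub-gene network export and PCA-loading prioritization of lncRNAs.

Modules of interest are exported as thresholded graphs centered on lncRNAs
and their directly connected neighbors (for rendering in external tools),
and lncRNAs are ranked by the Euclidean magnitude ("hypotenuse") of their
loadings on the first two principal components of the module expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import CoexpressionNetwork, ModuleAssignment


@dataclass
class ModuleGraphExport:
    module: str
    threshold: float
    graph: nx.Graph  # node attrs: biotype, degree, kIM; edge attr: weight

    @property
    def nodes(self) -> pd.DataFrame:
        recs = [{"gene_id": n, **d} for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(recs).set_index("gene_id") if recs else pd.DataFrame()

    @property
    def edges(self) -> pd.DataFrame:
        recs = [{"gene_a": u, "gene_b": v, "weight": d["weight"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(recs, columns=["gene_a", "gene_b", "weight"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edge_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def hub_network(
    net: CoexpressionNetwork,
    assignment: ModuleAssignment,
    module: str,
    threshold: float,
    annotation: pd.DataFrame,
    lncRNA_neighborhood: bool = True,
) -> ModuleGraphExport:
    """Thresholded intra-module graph restricted to lncRNA neighborhoods.

    Keeps intra-module edges with TOM >= ``threshold``; with
    ``lncRNA_neighborhood`` the node set is every lncRNA of the module plus
    each lncRNA's directly connected neighbors.  Node degree (on the
    retained subgraph) doubles as the display size attribute.
    """
    if module not in assignment.modules:
        raise KeyError(f"unknown module {module!r}")
    if net.tom is None:
        raise ValueError("TOM not computed on this network")
    genes = assignment.genes_of(module)
    genes = genes[genes.isin(net.genes)]
    pos = {g: i for i, g in enumerate(net.genes)}
    idx = np.array([pos[g] for g in genes])
    bt = annotation.set_index("gene_id")["biotype"]

    sub = net.tom[np.ix_(idx, idx)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    ii, jj = np.where(np.triu(sub >= threshold, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(genes[i], genes[j], weight=float(sub[i, j]))
    if g.number_of_edges() == 0:
        warnings.warn(f"threshold {threshold} removes all edges of {module}")

    if lncRNA_neighborhood:
        lncs = [n for n in g.nodes if bt.get(n) == "lncRNA"]
        keep = set(lncs)
        for n in lncs:
            keep.update(g.neighbors(n))
        g = g.subgraph(keep).copy()

    kim = pd.Series(net.connectivity, index=net.genes)
    for n in g.nodes:
        g.nodes[n]["biotype"] = bt.get(n, "unknown")
        g.nodes[n]["degree"] = g.degree[n]
        g.nodes[n]["kIM"] = float(kim[n])
    return ModuleGraphExport(module, threshold, g)


def pca_contributions(expr: ExpressionMatrix, genes=None):
    """Per-gene loadings on PC1/PC2 with hypotenuse magnitude, plus scores.

    PCA of the standardized module expression (samples as observations);
    loadings are correlation-scale (axis weights times singular value over
    sqrt(n - 1)), so the hypotenuse sqrt(l1^2 + l2^2) is comparable across
    modules.  PC1 is oriented positively with mean module expression; PC2's
    sign is fixed by its largest-magnitude loading.  Constant genes are
    dropped with a warning.
    """
    vals = expr.values if genes is None else expr.values[list(genes)]
    if vals.shape[1] < 3 or vals.shape[0] < 3:
        raise ValueError("need at least 3 genes and 3 samples")
    sd = vals.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {(sd == 0).sum()} constant genes from PCA")
        vals = vals.loc[:, sd > 0]
    X = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X.values, full_matrices=False)
    avg = X.values.mean(axis=1)
    if avg.std() > 0 and np.corrcoef(U[:, 0], avg)[0, 1] < 0:
        U[:, 0] *= -1
        Vt[0] *= -1
    lead = np.argmax(np.abs(Vt[1]))
    if Vt[1, lead] < 0:
        U[:, 1] *= -1
        Vt[1] *= -1

    loadings = Vt[:2].T * S[:2] / np.sqrt(n - 1)
    contrib = pd.DataFrame({
        "loading1": loadings[:, 0],
        "loading2": loadings[:, 1],
        "magnitude": np.hypot(loadings[:, 0], loadings[:, 1]),
        "angle": np.arctan2(loadings[:, 1], loadings[:, 0]),
    }, index=vals.columns)
    scores = pd.DataFrame(U[:, :2] * S[:2], index=vals.index,
                          columns=["PC1", "PC2"])
    return contrib, scores


def top_contributors(contributions: pd.DataFrame, annotation: pd.DataFrame,
                     k: int | None = None, quantile: float | None = None,
                     biotype: str | None = "lncRNA") -> pd.DataFrame:
    """Rank genes by PC1/PC2 hypotenuse magnitude, optionally per biotype.

    Ties break by gene id for determinism; ``k`` limits to the top k,
    ``quantile`` to magnitudes at or above that quantile.
    """
    out = contributions.copy()
    if biotype is not None:
        bt = annotation.set_index("gene_id")["biotype"]
        out = out[bt.reindex(out.index) == biotype]
    out = out.iloc[np.lexsort((out.index, -out["magnitude"].values))]
    if quantile is not None:
        out = out[out["magnitude"] >= out["magnitude"].quantile(quantile)]
    if k is not None:
        out = out.head(k)
    return out
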