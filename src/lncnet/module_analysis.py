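"""Module eigengenes, merging, membership (kME), intramodular connectivity,
module-trait correlation, gene-trait significance, and composition statistics.

An eigengene is the first principal component of a module's gene-standardized
expression, oriented to correlate positively with the module's average
expression, and scaled to unit variance so modules are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix
from .network import GREY, CoexpressionNetwork, ModuleAssignment


@dataclass
class ModuleEigengenes:
    """Per-module first principal components with gene weight vectors.

    ``scores``: samples x modules, unit variance per column.
    ``weights``: per module, the gene weight vector (right singular vector)
    together with the gene means/sds used for standardization, enabling
    projection of new samples onto the same eigengene definitions.
    ``variance_explained``: fraction of the module's standardized variance
    captured by the first component.
    """

    scores: pd.DataFrame
    variance_explained: pd.Series
    weights: dict = field(repr=False, default_factory=dict)


def _standardize(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant gene in module")
    return (vals - mu) / sd, mu, sd


def eigengenes(expr: ExpressionMatrix, assignment: ModuleAssignment,
               include_grey: bool = False) -> ModuleEigengenes:
    """First principal component per module, sign-oriented and unit-variance."""
    scores, varexp, weights = {}, {}, {}
    modules = assignment.modules + ([GREY] if include_grey else [])
    for mod in modules:
        genes = assignment.genes_of(mod)
        genes = genes[genes.isin(expr.genes)]
        if len(genes) < 2:
            raise ValueError(f"module {mod} has fewer than 2 genes")
        X, mu, sd = _standardize(expr.values[genes].values)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        me = U[:, 0] * S[0]
        w = Vt[0]
        # orient positively with the module's average standardized expression
        # (anti-correlated pairs cancel to a constant average: keep the sign)
        avg = X.mean(axis=1)
        if avg.std() > 0 and np.corrcoef(me, avg)[0, 1] < 0:
            me, w = -me, -w
        me_sd = me.std(ddof=0)
        scores[mod] = me / me_sd
        varexp[mod] = S[0] ** 2 / (S ** 2).sum()
        weights[mod] = {"genes": list(genes), "w": w, "mean": mu, "sd": sd,
                        "scale": S[0] / me_sd}
    return ModuleEigengenes(
        scores=pd.DataFrame(scores, index=expr.samples),
        variance_explained=pd.Series(varexp, name="variance_explained"),
        weights=weights,
    )


def project_eigengenes(expr: ExpressionMatrix, mes: ModuleEigengenes) -> pd.DataFrame:
    """Score new samples on previously defined eigengene weight vectors.

    Genes absent from ``expr`` are dropped (with renormalized weights).
    """
    out = {}
    for mod, w in mes.weights.items():
        genes = [g for g in w["genes"] if g in expr.genes]
        keep = [i for i, g in enumerate(w["genes"]) if g in expr.genes]
        X = (expr.values[genes].values - w["mean"][keep]) / w["sd"][keep]
        out[mod] = X @ w["w"][keep]
    proj = pd.DataFrame(out, index=expr.samples)
    return (proj - proj.mean()) / proj.std(ddof=0)


def merge_modules(
    mes: ModuleEigengenes,
    assignment: ModuleAssignment,
    expr: ExpressionMatrix,
    cut_height: float = 0.20,
) -> tuple[ModuleAssignment, ModuleEigengenes, dict]:
    """Merge modules whose eigengenes are highly correlated.

    Average-linkage clustering of the eigengene dissimilarity
    1 - cor(ME_i, ME_j); clusters joined below ``cut_height`` are merged,
    the merged module inheriting the larger constituent's label.  Returns
    the merged assignment, recomputed eigengenes, and a lineage map
    old label -> merged label.
    """
    mods = list(mes.scores.columns)
    if len(mods) < 2:
        return assignment, mes, {m: m for m in mods}
    corr = np.corrcoef(mes.scores.values, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    sizes = assignment.sizes()
    lineage = {}
    for cid in np.unique(flat):
        members = [mods[i] for i in np.where(flat == cid)[0]]
        winner = max(members, key=lambda m: (sizes.get(m, 0), m))
        for m in members:
            lineage[m] = winner
    labels = assignment.labels.map(lambda m: lineage.get(m, m)).rename("module")
    merged = ModuleAssignment(labels)
    new_mes = eigengenes(expr, merged)
    return merged, new_mes, lineage


def kme(expr: ExpressionMatrix, mes: ModuleEigengenes) -> pd.DataFrame:
    """Module membership: Pearson correlation of each gene with each eigengene.

    Constant genes get NaN.
    """
    X = expr.values.values
    sd = X.std(axis=0, ddof=0)
    Xc = X - X.mean(axis=0)
    M = mes.scores.values
    Mc = M - M.mean(axis=0)
    num = Xc.T @ Mc
    denom = np.outer(sd, Mc.std(axis=0, ddof=0)) * len(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, num / denom, np.nan)
    return pd.DataFrame(out, index=expr.genes, columns=mes.scores.columns)


def intramodular_connectivity(net: CoexpressionNetwork,
                              assignment: ModuleAssignment,
                              include_grey: bool = False) -> pd.Series:
    """kIM_i = sum of adjacency from gene i to other genes of its module."""
    labels = assignment.labels.reindex(net.genes)
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    out = pd.Series(np.nan, index=net.genes, name="kIM")
    modules = assignment.modules + ([GREY] if include_grey else [])
    codes = labels.values
    for mod in modules:
        idx = np.where(codes == mod)[0]
        if len(idx) == 0:
            continue
        out.iloc[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    return out


STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cutoff, mark in STAR_LEVELS:
        if p < cutoff:
            return mark
    return ""


def module_trait_correlation(mes: ModuleEigengenes, traits: pd.DataFrame):
    """Pearson r, two-sided p, and star annotations per (module, trait).

    Missing trait values are handled pairwise-complete; cells with fewer
    than 3 complete observations are left missing.  P values are raw
    (annotation thresholds 0.05 / 0.01 / 0.001).
    """
    traits = traits.loc[mes.scores.index]
    r = pd.DataFrame(index=mes.scores.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for trait in traits.columns:
        tv = traits[trait].astype(float)
        ok = tv.notna()
        for mod in mes.scores.columns:
            if ok.sum() < 3:
                continue
            rr, pp = stats.pearsonr(mes.scores.loc[ok, mod], tv[ok])
            r.loc[mod, trait], p.loc[mod, trait] = rr, pp
    stars = p.map(lambda v: "" if pd.isna(v) else _stars(v))
    return r, p, stars


def gene_trait_significance(expr: ExpressionMatrix, trait: pd.Series) -> pd.Series:
    """Per-gene Pearson correlation with a trait (NaN for constant genes)."""
    tv = trait.reindex(expr.samples).astype(float)
    ok = tv.notna().values
    X = expr.values.values[ok]
    t = tv.values[ok]
    sd = X.std(axis=0, ddof=0)
    tc = t - t.mean()
    num = (X - X.mean(axis=0)).T @ tc
    denom = sd * tc.std(ddof=0) * len(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        gs = np.where(denom > 0, num / denom, np.nan)
    return pd.Series(gs, index=expr.genes, name="gene_trait_significance")


def module_composition(assignment: ModuleAssignment, annotation: pd.DataFrame,
                       window: int = 50_000) -> pd.DataFrame:
    """Per-module biotype fractions and lncRNA-to-coding proximity.

    For each module: its size, lncRNA fraction, and the fraction of its
    lncRNAs whose gene body extended by ``window`` bp on each side overlaps
    the body of a protein-coding gene of the same module.
    """
    ann = annotation.set_index("gene_id")
    rows = []
    for mod in assignment.modules + [GREY]:
        genes = assignment.genes_of(mod)
        genes = genes[genes.isin(ann.index)]
        if len(genes) == 0:
            continue
        sub = ann.loc[genes]
        lnc = sub[sub["biotype"] == "lncRNA"]
        pc = sub[sub["biotype"] == "protein_coding"]
        prox = np.nan
        if len(lnc):
            hits = 0
            for rec in lnc.itertuples():
                lo, hi = max(0, rec.start - window), rec.end + window
                same = pc[pc["chrom"] == rec.chrom]
                if ((same["start"] < hi) & (same["end"] > lo)).any():
                    hits += 1
            prox = hits / len(lnc)
        rows.append({"module": mod, "n_genes": len(sub),
                     "lncRNA_fraction": len(lnc) / len(sub),
                     "lnc_near_coding_fraction": prox})
    return pd.DataFrame(rows).set_index("module")
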