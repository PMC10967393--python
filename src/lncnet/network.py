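"""Weighted gene coexpression network: covariate residualization,
soft-threshold selection, adjacency, topological overlap, and module
detection by dynamic cutting of the average-linkage dendrogram.

Conventions: the network is unsigned, a_ij = |cor(x_i, x_j)|^beta (a signed
variant ((1+r)/2)^beta is available behind a flag); connectivity excludes
the self term; TOM carries a unit diagonal and the clustering uses the
dissimilarity d = 1 - TOM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression import ExpressionMatrix

GREY = "grey"

#: deterministic module label palette, assigned by decreasing module size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta", "sienna3", "yellowgreen", "skyblue3",
    "plum1", "orangered4", "mediumpurple3", "lightsteelblue1", "lightcyan1",
    "ivory", "floralwhite", "darkslateblue", "coral1", "brown4", "lightpink4",
    "salmon4", "bisque4", "palevioletred3", "navajowhite2", "plum2",
    "thistle2", "thistle1", "honeydew1", "lavenderblush3", "maroon",
    "coral2", "antiquewhite4",
)


def regress_covariates(logtpm: ExpressionMatrix, covariates: list[str]) -> ExpressionMatrix:
    """Residualize each gene on the covariate design, re-centered to its mean.

    Categorical metadata columns are dummy-coded; a rank-deficient design is
    an error naming the collinear columns.
    """
    meta = logtpm.sample_meta
    missing = [c for c in covariates if c not in meta.columns]
    if missing:
        raise KeyError(f"covariates not in metadata: {missing}")
    design = pd.get_dummies(meta[covariates], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(meta)), design.values])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {X.shape[1]}); "
            f"columns: {['intercept'] + list(design.columns)}")
    Y = logtpm.values.values
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    resid += Y.mean(axis=0, keepdims=True)
    out = pd.DataFrame(resid, index=logtpm.values.index, columns=logtpm.values.columns)
    return ExpressionMatrix(out, meta, scale="residual")


@dataclass
class CoexpressionNetwork:
    """Correlation / adjacency / TOM matrices for one gene set."""

    genes: pd.Index
    correlation: np.ndarray
    beta: float
    adjacency: np.ndarray
    connectivity: np.ndarray     # k_i = sum_{j != i} a_ij
    tom: np.ndarray | None = None

    @property
    def dissimilarity(self) -> np.ndarray:
        if self.tom is None:
            raise ValueError("TOM not computed")
        return 1.0 - self.tom


def _correlation(expr: ExpressionMatrix) -> tuple[pd.Index, np.ndarray]:
    vals = expr.values
    sd = vals.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant genes from the network")
        vals = vals.drop(columns=constant)
    r = np.corrcoef(vals.values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return vals.columns, r


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k, regresses log10 p(k) on log10 mean(k) over occupied bins, and
    returns (signed R^2, slope); R^2 is negated when the slope is positive.
    """
    k = np.asarray(k, dtype=float)
    if k.max() <= 0 or np.ptp(k) == 0:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    logp, logk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        km = k[mask].mean()
        if km <= 0:
            continue
        logp.append(np.log10(mask.mean()))
        logk.append(np.log10(km))
    if len(logk) < 3:
        return float("nan"), float("nan")
    slope, _ = np.polyfit(logk, logp, 1)
    r2 = np.corrcoef(logk, logp)[0, 1] ** 2
    return (-r2 if slope > 0 else r2), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    candidate_powers=range(1, 21),
    r2_target: float = 0.80,
    signed: bool = False,
) -> tuple[int | None, pd.DataFrame]:
    """Choose the soft power beta for approximate scale-free topology.

    Returns ``(beta, table)`` where the table holds, per power, the signed
    scale-free R^2, the slope, and mean/median connectivity; beta is the
    smallest candidate with R^2 >= ``r2_target``, or None if no candidate
    reaches the target (caller may force one; the study used 8).
    """
    if len(expr.samples) < 20:
        raise ValueError("need at least 20 samples for soft-threshold selection")
    _, r = _correlation(expr)
    sim = (1 + r) / 2 if signed else np.abs(r)
    degenerate = np.isclose(np.abs(r), 1.0).all()
    rows = []
    for power in candidate_powers:
        a = sim ** power
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": power, "sft_r2": r2, "slope": slope,
                     "mean_k": k.mean(), "median_k": np.median(k)})
    table = pd.DataFrame(rows)
    table["degenerate"] = degenerate
    ok = table[table["sft_r2"] >= r2_target]
    beta = int(ok["power"].iloc[0]) if len(ok) else None
    return beta, table


def adjacency(expr: ExpressionMatrix, beta: float, signed: bool = False) -> CoexpressionNetwork:
    """Soft-thresholded adjacency a_ij = |r_ij|^beta (unsigned default)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    genes, r = _correlation(expr)
    sim = (1 + r) / 2 if signed else np.abs(r)
    a = sim ** beta
    np.fill_diagonal(a, 1.0)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    return CoexpressionNetwork(genes=genes, correlation=r, beta=beta,
                               adjacency=a, connectivity=a0.sum(axis=1))


def tom(net: CoexpressionNetwork) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    L_ij = sum_{u != i,j} a_iu a_uj, and TOM_ii = 1.
    """
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (L + a) / denom
    np.fill_diagonal(t, 1.0)
    net.tom = t
    return t


def tom_oracle(adj: np.ndarray) -> np.ndarray:
    """Brute-force triple-loop topological overlap, for cross-checking."""
    n = adj.shape[0]
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (L + a[i, j]) / (min(ki, kj) + 1.0 - a[i, j])
    return out


@dataclass
class ModuleAssignment:
    """gene -> module label; 'grey' holds unassigned genes."""

    labels: pd.Series  # index gene_id, values color names

    @property
    def modules(self) -> list[str]:
        sizes = self.sizes()
        return [m for m in sizes.index if m != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes_of(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]


def _assign_colors(raw_labels: pd.Series) -> pd.Series:
    """Map integer cluster ids to color names ordered by decreasing size."""
    sizes = raw_labels[raw_labels >= 0].value_counts()
    palette = {}
    for rank, cid in enumerate(sizes.index):
        palette[cid] = (MODULE_COLORS[rank] if rank < len(MODULE_COLORS)
                        else f"module{rank + 1}")
    return raw_labels.map(lambda c: palette.get(c, GREY)).astype(object).rename("module")


def _cohesion_z(d: np.ndarray, members: np.ndarray,
                global_mean: float, global_sd: float) -> float:
    """How much denser a gene set is than the network background.

    Z-score of the set's mean within-set dissimilarity against the global
    mean, scaled by the global spread over the number of within-set pairs.
    Real modules score very high; arbitrary slices of the background score
    near zero.
    """
    s = len(members)
    npairs = s * (s - 1) / 2
    sub = d[np.ix_(members, members)]
    within = (sub.sum() - np.trace(sub)) / (2 * npairs)
    if global_sd == 0:
        return np.inf if within < global_mean else 0.0
    return (global_mean - within) / (global_sd / np.sqrt(npairs))


def detect_modules(
    dissimilarity: np.ndarray,
    genes: pd.Index,
    min_module_size: int = 30,
    cohesion_z: float = 10.0,
    n_grid: int = 128,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with an adaptive tree cut.

    The dendrogram of d = 1 - TOM is cut at a data-chosen static height:
    candidate heights just below each merge (subsampled to ``n_grid``) are
    scanned, and at each cut the clusters of at least ``min_module_size``
    genes that are significantly denser than the network background
    (cohesion z >= ``cohesion_z``) count as modules.  The cut retained is
    the one yielding the most modules, ties resolved toward the highest
    cut so that weakly attached genes still adhere to their branch.
    Everything else is grey.  Labels are color names by decreasing size.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n != len(genes):
        raise ValueError("dissimilarity and gene list disagree")
    if n < min_module_size:
        return ModuleAssignment(pd.Series(GREY, index=genes, name="module"))

    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    global_mean = condensed.mean()
    global_sd = condensed.std(ddof=0)

    heights = np.unique(Z[:, 2])
    if len(heights) > n_grid:
        pick = np.unique(np.linspace(0, len(heights) - 1, n_grid).astype(int))
        heights = heights[pick]
    eps = 1e-9 * max(1.0, heights.max())
    cuts = heights - eps

    best = (-1, None, None)  # (n_modules, cut, labels)
    for t in cuts:
        flat = hierarchy.fcluster(Z, t=t, criterion="distance")
        labels = np.full(n, -1)
        nmod = 0
        for cid in np.unique(flat):
            members = np.where(flat == cid)[0]
            if len(members) < min_module_size:
                continue
            if _cohesion_z(d, members, global_mean, global_sd) >= cohesion_z:
                labels[members] = nmod
                nmod += 1
        if nmod >= best[0]:  # >= prefers higher cuts on ties
            best = (nmod, t, labels)

    labels = pd.Series(best[2] if best[2] is not None else np.full(n, -1))
    colored = _assign_colors(labels)
    colored.index = genes
    return ModuleAssignment(colored)
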