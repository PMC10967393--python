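"""Pooled CRISPRa screen scoring: per-sgRNA log2 fold-changes across sorted
bins and a rank-based binomial gene score with permutation FDR.

The scorer follows the STARS scheme: sgRNAs are ranked by log2 fold-change,
and a gene with guides inside the top fraction of the ranking is scored by
the binomial upper-tail probability of seeing that many of its guides so
deep in the list, taking the score at the deepest qualifying guide.
Significance comes from permuting the guide-to-gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CONTROL_GENES = ("CTRL",)


def sgRNA_log2fc(table: pd.DataFrame, numerator: str, denominator: str,
                 pseudocount: float = 1.0) -> pd.Series:
    """Per-sgRNA log2 ratio of reads-per-million (plus pseudocount).

    Invariant to uniform depth changes of either bin; a bin with zero total
    reads is an error.
    """
    for col in (numerator, denominator):
        if col not in table.columns:
            raise KeyError(f"bin {col!r} not in screen table")
        if table[col].sum() <= 0:
            raise ValueError(f"bin {col!r} has zero total reads")
    rpm_n = table[numerator] / table[numerator].sum() * 1e6
    rpm_d = table[denominator] / table[denominator].sum() * 1e6
    out = np.log2(rpm_n + pseudocount) - np.log2(rpm_d + pseudocount)
    return pd.Series(out.values, index=table["sgRNA"].values, name="log2fc")


def _binom_tail_score(m: int, j: int, r_j: int, n_total: int,
                      tail: bool = True) -> float:
    """-log10 P(X >= j), X ~ Binomial(m, r_j / N) (or the point PMF)."""
    p = r_j / n_total
    if tail:
        prob = float(stats.binom.sf(j - 1, m, p))
    else:
        prob = float(stats.binom.pmf(j, m, p))
    return -np.log10(max(prob, 1e-300))


def binom_tail_oracle(m: int, j: int, r_j: int, n_total: int) -> float:
    """Brute-force enumeration of the binomial upper tail, for cross-checks."""
    p = r_j / n_total
    from math import comb
    prob = sum(comb(m, x) * p ** x * (1 - p) ** (m - x) for x in range(j, m + 1))
    return -np.log10(prob)


def stars_score(
    log2fc: pd.Series,
    guide_gene: pd.Series,
    direction: str = "enriched",
    top_frac: float = 0.04,
    min_guides: int = 2,
    tail: bool = True,
    deepest: bool = True,
) -> pd.DataFrame:
    """Rank-based binomial gene score over the top fraction of sgRNAs.

    sgRNAs are ranked by log2 fold-change (descending for ``enriched``,
    ascending for ``depleted``).  For a gene with m guides whose guides
    inside the top ceil(top_frac * N) hold global ranks r_1 < ... < r_J,
    score_j = -log10 P(X >= j) with X ~ Binomial(m, r_j / N); the gene
    score is taken at the deepest qualifying guide (j = J; the best-rank
    variant is available via ``deepest=False``).  Genes with fewer than
    ``min_guides`` guides in the top bin are unscored; control guides are
    never scored as genes.
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    guide_gene = guide_gene.reindex(log2fc.index)
    n_total = len(log2fc)
    top_n = int(np.ceil(top_frac * n_total))
    if top_n < 1:
        raise ValueError("library too small for the top fraction")

    order = np.lexsort((log2fc.index,
                        log2fc.values if direction == "depleted" else -log2fc.values))
    ranks = pd.Series(np.empty(n_total, dtype=int), index=log2fc.index)
    ranks.iloc[order] = np.arange(1, n_total + 1)

    genes, codes = np.unique(guide_gene.values.astype(str), return_inverse=True)
    m_per_gene = np.bincount(codes, minlength=len(genes))
    table = _score_from_ranks(ranks.values, codes, m_per_gene, n_total, top_n,
                              min_guides, tail, deepest)
    table["gene"] = genes[table.pop("code")]
    out = pd.DataFrame(table, columns=["gene", "n_guides", "n_in_top", "j",
                                       "rank_j", "score"]).set_index("gene")
    return out.drop(index=[g for g in CONTROL_GENES if g in out.index])


def _score_from_ranks(ranks: np.ndarray, codes: np.ndarray,
                      m_per_gene: np.ndarray, n_total: int, top_n: int,
                      min_guides: int, tail: bool, deepest: bool) -> dict:
    """Vectorized scoring core shared by the observed fit and permutations.

    Only guides inside the top bin can contribute, so the work is
    proportional to ``top_n`` regardless of library size.
    """
    in_top = ranks <= top_n
    top_codes = codes[in_top]
    top_ranks = ranks[in_top]
    order = np.lexsort((top_ranks, top_codes))
    top_codes, top_ranks = top_codes[order], top_ranks[order]
    uniq, start, J = np.unique(top_codes, return_index=True, return_counts=True)
    keep = J >= min_guides
    uniq, start, J = uniq[keep], start[keep], J[keep]

    if deepest:
        j_sel = J
        r_sel = top_ranks[start + J - 1]
    else:
        j_sel = np.empty(len(uniq), dtype=int)
        r_sel = np.empty(len(uniq), dtype=int)
        for i, (s0, jj) in enumerate(zip(start, J)):
            cand = [(j, top_ranks[s0 + j - 1]) for j in range(min_guides, jj + 1)]
            scores = [_binom_tail_score(m_per_gene[uniq[i]], j, r, n_total, tail)
                      for j, r in cand]
            b = int(np.argmax(scores))
            j_sel[i], r_sel[i] = cand[b]

    m = m_per_gene[uniq]
    p = r_sel / n_total
    if tail:
        prob = stats.binom.sf(j_sel - 1, m, p)
    else:
        prob = stats.binom.pmf(j_sel, m, p)
    score = -np.log10(np.maximum(prob, 1e-300))
    return {"code": uniq, "n_guides": m, "n_in_top": J, "j": j_sel,
            "rank_j": r_sel, "score": score}


@dataclass
class StarsResult:
    direction: str
    comparison: tuple[str, str]
    table: pd.DataFrame  # per gene: score, p, fdr, n_guides_in_top


def stars_fdr(
    log2fc: pd.Series,
    guide_gene: pd.Series,
    direction: str = "enriched",
    comparison: tuple[str, str] = ("", ""),
    n_perm: int = 1000,
    seed: int = 0,
    top_frac: float = 0.04,
    min_guides: int = 2,
) -> StarsResult:
    """Permutation p-values and BH FDR for the binomial gene scores.

    The null permutes the guide-to-gene assignment among targeting guides
    (controls stay controls), preserving each gene's guide count; null
    scores are pooled over genes and permutations and
    p = (1 + #null >= observed) / (1 + #null).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    observed = stars_score(log2fc, guide_gene, direction,
                           top_frac=top_frac, min_guides=min_guides)

    rng = np.random.default_rng(seed)
    guide_gene = guide_gene.reindex(log2fc.index)
    genes, codes = np.unique(guide_gene.values.astype(str), return_inverse=True)
    m_per_gene = np.bincount(codes, minlength=len(genes))
    control_codes = {i for i, g in enumerate(genes) if g in CONTROL_GENES}
    targeting = ~np.isin(codes, list(control_codes))

    n_total = len(log2fc)
    top_n = int(np.ceil(top_frac * n_total))
    order = np.lexsort((log2fc.index,
                        log2fc.values if direction == "depleted" else -log2fc.values))
    ranks = np.empty(n_total, dtype=int)
    ranks[order] = np.arange(1, n_total + 1)

    null_scores = []
    codes_null = codes.copy()
    for _ in range(n_perm):
        codes_null[targeting] = rng.permutation(codes[targeting])
        res = _score_from_ranks(ranks, codes_null, m_per_gene, n_total, top_n,
                                min_guides, tail=True, deepest=True)
        keep = ~np.isin(res["code"], list(control_codes))
        null_scores.append(res["score"][keep])
    null_pool = np.sort(np.concatenate(null_scores)) if null_scores else np.array([])

    n_null = len(null_pool)
    if len(observed):
        # count of null >= s via binary search on the sorted pool
        ge = n_null - np.searchsorted(null_pool, observed["score"].values - 1e-12)
        pvals = (1 + ge) / (1 + n_null)
        fdr = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals, fdr = np.array([]), np.array([])
    table = observed.assign(p=pvals, fdr=fdr)
    return StarsResult(direction, comparison, table)


HIGH_TNF_BINS = ("TNF_pos", "TNF_hi")
LOW_TNF_BINS = ("TNF_neg", "TNF_lo")


def call_hits(results: list[StarsResult], fdr_cutoff: float = 0.25) -> pd.DataFrame:
    """Collect FDR-significant genes across directions/comparisons.

    Guides enriched in a TNF-high sort (or depleted in a TNF-low sort)
    mark positive regulators of the TNF response, and conversely for
    negative regulators; the FDR cutoff is strict (<).
    """
    rows = []
    for res in results:
        numerator = res.comparison[0]
        bin_sign = -1 if numerator in LOW_TNF_BINS else 1
        dir_sign = 1 if res.direction == "enriched" else -1
        regulator = "positive" if bin_sign * dir_sign > 0 else "negative"
        sig = res.table[res.table["fdr"] < fdr_cutoff]
        for gene, rec in sig.iterrows():
            rows.append({
                "gene": gene,
                "direction": res.direction,
                "regulator": regulator,
                "comparison": "_vs_".join(res.comparison),
                "score": rec["score"], "p": rec["p"], "fdr": rec["fdr"],
                "n_guides_in_top": rec["n_in_top"],
            })
    return pd.DataFrame(rows, columns=["gene", "direction", "regulator",
                                       "comparison", "score", "p", "fdr",
                                       "n_guides_in_top"])
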