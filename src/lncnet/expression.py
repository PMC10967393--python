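"""Expression matrices: thresholding, TPM normalization, log transform,
tissue specificity, and descriptive biotype statistics.

Counts are filtered per disease class (a gene is kept if it exceeds a read
threshold in a sufficient fraction of at least one class's libraries), then
TPM-normalized over the retained genes only, and log2(TPM+1)-transformed for
all downstream modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Samples x genes expression with per-sample metadata.

    ``values`` rows are samples, columns genes.  ``scale`` declares the unit:
    raw ``counts``, ``TPM`` (rows sum to 1e6), or ``logTPM`` (log2(TPM+1)).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self):
        if self.scale not in ("counts", "TPM", "logTPM", "residual"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale in ("counts", "TPM") and (np.asarray(self.values) < 0).any():
            raise ValueError("negative expression values")
        if not self.values.index.is_unique:
            raise ValueError("duplicate sample ids")
        if not self.values.index.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.values.index]

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[sample_ids],
                       sample_meta=self.sample_meta.loc[sample_ids])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return replace(self, values=self.values[list(gene_ids)])


def threshold_genes(
    counts: ExpressionMatrix,
    min_reads: int = 10,
    min_frac: float = 0.40,
    group_by: str = "disease",
    require_all_groups: bool = False,
    annotation: pd.DataFrame | None = None,
):
    """Call genes expressed by per-group library support.

    A gene is retained iff, within at least one level of ``group_by``
    (every level when ``require_all_groups``), strictly more than
    ``min_reads`` reads are seen in at least ``min_frac`` of that group's
    libraries.  Returns ``(retained_gene_index, per_biotype_retention)``;
    the retention table is empty unless an annotation is supplied.
    """
    if counts.scale != "counts":
        raise ValueError("thresholding requires raw counts")
    if group_by not in counts.sample_meta.columns:
        raise KeyError(f"unknown group key {group_by!r}")

    passes = []
    for _, idx in counts.sample_meta.groupby(group_by, observed=True).groups.items():
        sub = counts.values.loc[idx]
        frac = (sub > min_reads).mean(axis=0)
        passes.append(frac >= min_frac)
    passed = pd.concat(passes, axis=1)
    keep = passed.all(axis=1) if require_all_groups else passed.any(axis=1)
    retained = counts.genes[keep]

    retention = pd.DataFrame()
    if annotation is not None:
        ann = annotation.set_index("gene_id").loc[counts.genes]
        retention = (
            pd.DataFrame({"biotype": ann["biotype"].values, "retained": keep.values})
            .groupby("biotype")["retained"].mean().to_frame("retained_fraction")
        )
    return retained, retention


def tpm_normalize(counts: ExpressionMatrix, lengths: pd.Series, retained=None) -> ExpressionMatrix:
    """Transcripts-per-million over the retained gene set.

    TPM_gs = (count_gs / length_g) / sum_g'(count_g's / length_g') * 1e6.
    Rows of the result sum to 1e6.
    """
    if counts.scale != "counts":
        raise ValueError("TPM normalization requires raw counts")
    if retained is not None:
        counts = counts.subset_genes(retained)
    lens = lengths.reindex(counts.genes)
    if lens.isna().any() or (lens <= 0).any():
        missing = counts.genes[lens.isna() | (lens <= 0)].tolist()
        raise ValueError(f"missing or nonpositive lengths for genes: {missing[:5]}")
    rate = counts.values / lens.values[None, :]
    totals = rate.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.samples[totals <= 0].tolist()
        raise ValueError(f"samples with zero total length-normalized rate: {bad}")
    tpm = rate.div(totals, axis=0) * 1e6
    return ExpressionMatrix(tpm, counts.sample_meta, scale="TPM")


def log_transform(tpm: ExpressionMatrix, median_center: bool = False) -> ExpressionMatrix:
    """log2(TPM + 1); optionally gene-wise median-centered afterwards."""
    if tpm.scale != "TPM":
        raise ValueError("log transform expects TPM input")
    vals = np.log2(tpm.values + 1.0)
    if median_center:
        vals = vals - vals.median(axis=0)
    return ExpressionMatrix(vals, tpm.sample_meta, scale="logTPM")


def tissue_specific_genes(
    tpm: ExpressionMatrix, min_tpm: float = 0.5, min_frac: float = 0.30,
    tissue_key: str = "tissue",
) -> dict[str, pd.Index]:
    """Tissue-restricted expression calls.

    A gene is specific to tissue T iff TPM > ``min_tpm`` in >= ``min_frac``
    of T's samples while failing that criterion in every other tissue.  The
    resulting sets are pairwise disjoint by construction.
    """
    if tpm.scale not in ("TPM",):
        raise ValueError("tissue specificity is defined on TPM")
    tissues = tpm.sample_meta[tissue_key].unique()
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    passed = {}
    for t in tissues:
        sub = tpm.values.loc[tpm.sample_meta[tissue_key] == t]
        passed[t] = (sub > min_tpm).mean(axis=0) >= min_frac
    out = {}
    for t in tissues:
        others = [passed[u] for u in tissues if u != t]
        exclusive = passed[t] & ~np.logical_or.reduce(others)
        out[t] = tpm.genes[exclusive]
    return out


def normalized_sd(expr: ExpressionMatrix, genes=None) -> pd.Series:
    """Coefficient of variation per gene (sample sd / mean) on the given scale.

    Zero-mean genes are excluded (value undefined).
    """
    vals = expr.values if genes is None else expr.values[list(genes)]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    ok = mean > 0
    if not ok.all():
        import warnings
        warnings.warn(f"{(~ok).sum()} zero-mean genes excluded from normalized SD")
    return (sd[ok] / mean[ok]).rename("normalized_sd")


@dataclass
class BiotypeReport:
    ks_connectivity: tuple[float, float] | None
    t_normalized_sd: tuple[float, float]
    t_mean_expression: tuple[float, float]
    n_lncRNA: int
    n_protein_coding: int


def biotype_stats(
    expr: ExpressionMatrix,
    annotation: pd.DataFrame,
    connectivity: pd.Series | None = None,
) -> BiotypeReport:
    """Compare lncRNA vs protein-coding distributions.

    KS test on intramodular connectivity (if supplied) and two-sided t-tests
    on normalized SD and mean expression.
    """
    ann = annotation.set_index("gene_id")["biotype"].reindex(expr.genes)
    is_lnc = (ann == "lncRNA").values
    if is_lnc.all() or (~is_lnc).all():
        raise ValueError("both biotypes must be present")

    nsd = normalized_sd(expr)
    nsd_lnc = nsd[nsd.index.isin(expr.genes[is_lnc])]
    nsd_pc = nsd[nsd.index.isin(expr.genes[~is_lnc])]
    mean = expr.values.mean(axis=0)

    ks = None
    if connectivity is not None:
        k_lnc = connectivity[connectivity.index.isin(expr.genes[is_lnc])]
        k_pc = connectivity[connectivity.index.isin(expr.genes[~is_lnc])]
        ks = tuple(stats.ks_2samp(k_lnc, k_pc)[:2])

    t_nsd = tuple(stats.ttest_ind(nsd_lnc, nsd_pc, equal_var=False)[:2])
    t_mean = tuple(stats.ttest_ind(mean[is_lnc], mean[~is_lnc], equal_var=False)[:2])
    return BiotypeReport(ks, t_nsd, t_mean, int(is_lnc.sum()), int((~is_lnc).sum()))
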