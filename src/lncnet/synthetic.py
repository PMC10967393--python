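"""Synthetic multi-tissue IBD cohort, SNP catalog, and CRISPRa screen generator.

Emulates the statistical structure the downstream analysis assumes: a
repeated-biopsy patient cohort with planted coexpression modules whose
eigengenes are driven by clinical traits, biotype-dependent expression level
and dispersion, logistic dropout producing zero inflation, SNP catalogs with
planted window enrichment, and a pooled sgRNA screen with planted positive
and negative regulators.

The latent model, per sample s and gene g in module m:

    ME_ms      = sum_t effect_mt * z(trait_ts) + N(0, 1)
    logmu_gs   = baseline_g + loading_g * ME_m(g),s
    counts_gs ~ NegBin(mean prop. to 2^logmu * length, dispersion_g)
    counts_gs  zeroed w.p. logistic(-(logmu - midpoint) * slope)

Background genes have loading 0; lncRNAs get a lower baseline
(``lnc_expression_shift``) and inflated dispersion (``lnc_dispersion_mult``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import make_annotation
from .expression import ExpressionMatrix

TISSUES = ("ileum", "colon", "rectum")
DISEASES = ("HC", "UC", "CD")
SEVERITIES = ("inactive", "mild", "moderate", "severe")

#: synthetic genome: 5 chromosomes of 50 Mb, 0-based half-open coordinates
CHROMS = tuple(f"chr{i}" for i in range(1, 6))
CHROM_LEN = 50_000_000


class ConfigError(ValueError):
    pass


def _default_trait_effects(n_modules: int) -> tuple:
    """One driving trait per module, cycling through the clinical traits."""
    menu = [
        {"inflamed": 0.8},
        {"severity_score": 0.8},
        {"rectum": 0.8},
        {"UC": 0.7},
        {"CD": 0.7},
        {"inflamed": -0.7},
    ]
    return tuple(menu[i % len(menu)] for i in range(n_modules))


@dataclass
class CohortConfig:
    n_patients: int = 120
    tissues: tuple = TISSUES
    diseases: dict = field(default_factory=lambda: {"HC": 0.2, "UC": 0.4, "CD": 0.4})
    severity_levels: tuple = SEVERITIES
    n_batches: int = 5
    n_genes: int = 2000
    frac_lncRNA: float = 0.5
    n_modules: int = 6
    module_sizes: tuple = (200, 160, 130, 100, 80, 60)
    module_loading: float = 0.7
    loading_jitter: float = 0.1
    trait_effects: tuple | None = None
    lnc_expression_shift: float = -2.0
    lnc_dispersion_mult: float = 2.0
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.15
    dropout_midpoint: float = 0.5
    dropout_slope: float = 1.5
    library_size_range: tuple = (2_000_000, 5_000_000)
    co_locate_modules: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.trait_effects is None:
            self.trait_effects = _default_trait_effects(self.n_modules)
        if abs(sum(self.diseases.values()) - 1.0) > 1e-9:
            raise ConfigError("disease proportions must sum to 1")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module_sizes exceed n_genes")
        for name, v in (("n_patients", self.n_patients), ("n_genes", self.n_genes),
                        ("n_batches", self.n_batches)):
            if v <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.frac_lncRNA <= 1:
            raise ConfigError("frac_lncRNA must be in [0,1]")


@dataclass
class PlantedTruth:
    """Ground truth of the generator, for recovery tests."""

    gene_module: dict          # gene_id -> module label ("M1".., or "grey")
    trait_effects: dict        # module label -> {trait: effect}
    snp_enriched_modules: list = field(default_factory=list)
    screen_regulators: dict = field(default_factory=dict)  # gene -> signed log2 effect

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sample_metadata(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    diseases = list(config.diseases)
    probs = [config.diseases[d] for d in diseases]
    for p in range(config.n_patients):
        disease = rng.choice(diseases, p=probs)
        severity = "inactive" if disease == "HC" else rng.choice(config.severity_levels)
        # 1-6 biopsies per patient across tissue x inflammation slots
        slots = [(t, inf) for t in config.tissues
                 for inf in (("no",) if disease == "HC" else ("no", "yes"))]
        n_biopsies = int(rng.integers(1, min(6, len(slots)) + 1))
        chosen = rng.choice(len(slots), size=n_biopsies, replace=False)
        crp = float(np.round(np.exp(
            rng.normal(1.0 + 0.6 * SEVERITIES.index(severity), 0.5)), 2))
        for k in chosen:
            tissue, inflamed = slots[k]
            rows.append({
                "patient": f"P{p:04d}", "disease": disease, "tissue": tissue,
                "inflamed": inflamed, "severity": severity,
                "batch": f"B{int(rng.integers(config.n_batches)):02d}", "CRP": crp,
            })
    meta = pd.DataFrame(rows)
    meta.index = pd.Index([f"S{i:04d}" for i in range(len(meta))], name="sample_id")
    return meta


def trait_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Numeric traits derivable from sample metadata, standardized."""
    raw = pd.DataFrame({
        "inflamed": (meta["inflamed"] == "yes").astype(float),
        "severity_score": meta["severity"].map(
            {s: i for i, s in enumerate(SEVERITIES)}).astype(float),
        "rectum": (meta["tissue"] == "rectum").astype(float),
        "UC": (meta["disease"] == "UC").astype(float),
        "CD": (meta["disease"] == "CD").astype(float),
        "CRP": np.log(meta["CRP"].astype(float)),
    }, index=meta.index)
    sd = raw.std(ddof=0).replace(0.0, 1.0)
    return (raw - raw.mean()) / sd


def _gene_annotation(config: CohortConfig, module_of: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    is_lnc = rng.random(n) < config.frac_lncRNA
    lengths = np.exp(rng.uniform(np.log(500), np.log(20_000), size=n)).astype(int)
    if config.co_locate_modules:
        # genes of one module placed in a contiguous neighborhood of one chromosome
        chrom = np.empty(n, dtype=object)
        start = np.empty(n, dtype=int)
        for m in range(config.n_modules):
            idx = np.where(module_of == m)[0]
            c = CHROMS[m % len(CHROMS)]
            anchor = rng.integers(0, CHROM_LEN - 5_000_000)
            chrom[idx] = c
            start[idx] = anchor + rng.integers(0, 3_000_000, size=len(idx))
        bg = np.where(module_of < 0)[0]
        chrom[bg] = rng.choice(CHROMS, size=len(bg))
        start[bg] = rng.integers(0, CHROM_LEN - 25_000, size=len(bg))
    else:
        chrom = rng.choice(CHROMS, size=n)
        start = rng.integers(0, CHROM_LEN - 25_000, size=n)
    end = start + lengths
    return make_annotation(pd.DataFrame({
        "gene_id": gene_ids,
        "biotype": np.where(is_lnc, "lncRNA", "protein_coding"),
        "source": "synthetic",
        "chrom": chrom, "start": start, "end": end,
        "strand": rng.choice(["+", "-"], size=n),
        "length": lengths,
    }))


def generate_cohort(config: CohortConfig):
    """Generate (annotation, sample metadata, counts, truth) for one cohort.

    Deterministic given ``config.seed``; counts are nonnegative integers.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_metadata(config, rng)
    n_samples, n_genes = len(meta), config.n_genes

    # module membership: first sum(module_sizes) genes, shuffled
    module_of = np.full(n_genes, -1)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module_of[pos:pos + size] = m
        pos += size
    rng.shuffle(module_of)

    annotation = _gene_annotation(config, module_of, rng)
    is_lnc = (annotation["biotype"] == "lncRNA").values
    lengths = annotation["length"].values.astype(float)

    traits = trait_design(meta)
    eigengenes = np.zeros((n_samples, config.n_modules))
    for m, effects in enumerate(config.trait_effects):
        drive = sum(eff * traits[t].values for t, eff in effects.items())
        eigengenes[:, m] = drive + rng.standard_normal(n_samples)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    baseline[is_lnc] += config.lnc_expression_shift
    loading = np.zeros(n_genes)
    in_mod = module_of >= 0
    loading[in_mod] = config.module_loading + rng.normal(
        0, config.loading_jitter, in_mod.sum())
    loading = np.clip(loading, 0.0, 0.99)

    logmu = baseline[None, :] + loading[None, :] * np.where(
        in_mod[None, :], eigengenes[:, np.clip(module_of, 0, None)], 0.0)

    # negative binomial via gamma-poisson, then logistic dropout
    rel = np.exp2(logmu) * lengths[None, :]
    frac = rel / rel.sum(axis=1, keepdims=True)
    libsize = rng.integers(*config.library_size_range, size=n_samples)
    mu = frac * libsize[:, None]
    disp = np.full(n_genes, config.dispersion)
    disp[is_lnc] *= config.lnc_dispersion_mult
    shape = 1.0 / disp
    lam = rng.gamma(shape[None, :], 1.0, size=mu.shape) * disp[None, :] * mu
    counts = rng.poisson(lam)
    p_drop = 1.0 / (1.0 + np.exp(config.dropout_slope * (logmu - config.dropout_midpoint)))
    counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    counts_df = pd.DataFrame(counts, index=meta.index, columns=annotation["gene_id"])
    counts_em = ExpressionMatrix(counts_df, meta, scale="counts")

    labels = {g: (f"M{module_of[i] + 1}" if module_of[i] >= 0 else "grey")
              for i, g in enumerate(annotation["gene_id"])}
    truth = PlantedTruth(
        gene_module=labels,
        trait_effects={f"M{m + 1}": dict(config.trait_effects[m])
                       for m in range(config.n_modules)},
    )
    return annotation, meta, counts_em, truth


# ---------------------------------------------------------------------------
# SNP catalog
# ---------------------------------------------------------------------------

def generate_snp_catalog(
    annotation: pd.DataFrame,
    enriched_modules: list,
    truth: PlantedTruth,
    n_snps: int = 300,
    frac_uc: float = 0.35,
    frac_cd: float = 0.35,
    frac_shared: float = 0.30,
    enrichment_excess: float = 0.5,
    window: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """SNP loci on the synthetic genome with planted module-window enrichment.

    A fraction ``enrichment_excess`` of SNPs is placed inside the +/- window
    of genes belonging to ``enriched_modules``; the rest land uniformly.
    Each SNP is labeled UC-specific, CD-specific, or shared.
    """
    if abs(frac_uc + frac_cd + frac_shared - 1.0) > 1e-9:
        raise ConfigError("disease label fractions must sum to 1")
    known = set(truth.gene_module.values())
    unknown = set(enriched_modules) - known
    if unknown:
        raise ConfigError(f"unknown module labels: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    target_genes = [g for g, m in truth.gene_module.items() if m in enriched_modules]
    ann = annotation.set_index("gene_id")

    n_excess = int(round(enrichment_excess * n_snps)) if target_genes else 0
    rows = []
    for i in range(n_snps):
        if i < n_excess:
            g = ann.loc[target_genes[int(rng.integers(len(target_genes)))]]
            lo = max(0, int(g["start"]) - window)
            hi = min(CHROM_LEN, int(g["end"]) + window)
            chrom, pos = g["chrom"], int(rng.integers(lo, hi))
        else:
            chrom = CHROMS[int(rng.integers(len(CHROMS)))]
            pos = int(rng.integers(0, CHROM_LEN))
        label = rng.choice(["UC-specific", "CD-specific", "shared"],
                           p=[frac_uc, frac_cd, frac_shared])
        rows.append({"snp_id": f"rs{i:06d}", "chrom": chrom, "position": pos,
                     "disease": label})
    truth.snp_enriched_modules = list(enriched_modules)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CRISPRa screen
# ---------------------------------------------------------------------------

SCREEN_BINS = ("pooled", "TNF_pos", "TNF_neg", "TNF_hi", "TNF_lo")
#: direction in which a positive regulator's guides shift in each sorted bin
BIN_SIGN = {"TNF_pos": +1.0, "TNF_hi": +1.0, "TNF_neg": -1.0, "TNF_lo": -1.0}


def generate_screen(
    n_genes: int = 300,
    guides_per_gene: int = 6,
    n_controls: int = 300,
    regulators: dict | None = None,
    bins: tuple = SCREEN_BINS,
    depth: int = 2_000_000,
    guide_noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled CRISPRa screen counts with planted signed regulators.

    ``regulators`` maps target gene ids (``T0000``-style) to signed log2
    effects; positive regulators are enriched in TNF-high bins and depleted
    in TNF-low bins.  Control sgRNAs (``CTRL`` target) have zero effect.
    Pooled counts follow a multinomial over sgRNAs; sorted-bin counts shift
    each sgRNA's abundance by the gene effect plus guide-level noise.
    """
    if depth <= 0:
        raise ConfigError("sequencing depth must be positive")
    regulators = dict(regulators or {})
    if regulators and guides_per_gene < 2:
        raise ConfigError("regulator genes need at least 2 guides")

    rng = np.random.default_rng(seed)
    genes = [f"T{i:04d}" for i in range(n_genes)]
    unknown = set(regulators) - set(genes)
    if unknown:
        raise ConfigError(f"regulator ids outside the library: {sorted(unknown)}")

    guide_ids, guide_gene = [], []
    for g in genes:
        for k in range(guides_per_gene):
            guide_ids.append(f"{g}_sg{k}")
            guide_gene.append(g)
    for k in range(n_controls):
        guide_ids.append(f"CTRL_sg{k}")
        guide_gene.append("CTRL")
    n_guides = len(guide_ids)

    base = np.exp(rng.normal(0, 0.4, n_guides))          # library representation
    effect = np.array([regulators.get(g, 0.0) for g in guide_gene])

    table = pd.DataFrame({"sgRNA": guide_ids, "gene": guide_gene})
    for b in bins:
        sign = BIN_SIGN.get(b, 0.0)
        shift = sign * effect + (rng.normal(0, guide_noise_sd, n_guides)
                                 if sign else 0.0)
        w = base * np.exp2(shift)
        table[b] = rng.multinomial(depth, w / w.sum())
    return table


# ---------------------------------------------------------------------------
# persistence helpers
# ---------------------------------------------------------------------------

def write_cohort(outdir, annotation, meta, counts: ExpressionMatrix,
                 truth: PlantedTruth) -> None:
    """Write a generated cohort to plain-text files under ``outdir``."""
    from pathlib import Path
    from . import annotation as ann_io
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ann_io.write_gtf(annotation, out / "annotation.gtf")
    ann_io.write_bed(annotation, out / "annotation.bed")
    counts.values.to_csv(out / "counts.tsv", sep="\t")
    meta.to_csv(out / "samples.tsv", sep="\t")
    truth.to_json(out / "truth.json")


def write_snps(snps: pd.DataFrame, path) -> None:
    """SNP catalog as BED (position, position+1) with id and disease label."""
    bed = pd.DataFrame({
        "chrom": snps["chrom"], "start": snps["position"],
        "end": snps["position"] + 1, "name": snps["snp_id"],
        "score": 0, "strand": ".", "disease": snps["disease"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_snps(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand",
                             "disease"])
    return pd.DataFrame({"snp_id": bed["name"], "chrom": bed["chrom"],
                         "position": bed["start"], "disease": bed["disease"]})
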