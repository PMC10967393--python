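# lncnet

Coexpression-network analysis of long noncoding RNAs (lncRNAs) in
inflammatory bowel disease (IBD) gut transcriptomes, packaged as a tested,
reusable pipeline.

Most IBD risk variants fall outside protein-coding genes, and lncRNAs —
transcripts > 200 nt without coding capacity — are strong candidates for
carrying that noncoding disease signal. Because lncRNA function can rarely
be read from sequence, the workhorse strategy is *guilt by association*:
build a weighted gene coexpression network over biopsy transcriptomes,
partition it into modules of coordinately expressed genes, and interpret
each lncRNA through the module it joins, the clinical traits that module
tracks, and the disease genetics that cluster near it.

`lncnet` implements that full analysis chain:

1. **Annotation** — merge GENCODE-like protein-coding, LNCipedia-like
   lncRNA, and de novo lncRNA catalogs into one nonredundant gene set
   (GTF/BED IO, 0-based half-open internally).
2. **Expression** — per-disease-class read thresholding (> 10 reads in
   ≥ 40 % of a class's libraries), TPM normalization over retained genes,
   log2(TPM+1), tissue-specificity calls, biotype statistics.
3. **Differential expression** — a zero-inflated Gaussian model per gene:
   logistic regression for the zero mass plus a Gaussian linear mixed
   model (random intercepts for batch and/or patient, REML) on the
   positive values, with an all-observations LMM fallback and BH FDR.
4. **Network** — covariate residualization, soft-threshold selection by
   scale-free fit R² ≥ 0.8, unsigned adjacency a<sub>ij</sub> = |cor(x<sub>i</sub>,x<sub>j</sub>)|<sup>β</sup>,
   topological overlap TOM<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>)/(min(k<sub>i</sub>,k<sub>j</sub>) + 1 − a<sub>ij</sub>),
   and module detection by an adaptive cut of the average-linkage
   dendrogram of 1 − TOM.
5. **Modules** — eigengenes (first PC per module), merging at eigengene
   dissimilarity 0.2, kME, intramodular connectivity, module–trait
   correlation with star annotation, gene-trait significance, and
   biotype/proximity composition.
6. **Preservation** — stratified 70/30 train/test split, cross-set kME,
   permutation **Zsummary** (high > 10, moderate 5–10, low < 5), and
   betweenness-centrality overlap of high-influence nodes.
7. **Genetics** — SNP adjacency within ±50 kb gene windows, per-module
   enrichment by a 10,000-draw composition-matched bootstrap, UC/CD
   disease-specific SNP proportions, hypergeometric module–DE overlap.
8. **Screen** — pooled CRISPRa screen scoring: per-sgRNA log2
   fold-changes across sorted TNF-α bins, a binomial rank score over the
   top 4 % of guides (≥ 2 guides required), permutation FDR, and hit
   calling at FDR < 0.25.
9. **Synthetic data** — a cohort generator planting coexpression modules,
   trait-driven eigengenes, biotype-dependent expression and zero
   inflation, SNP window enrichment, and screen regulators, so the whole
   pipeline is testable without any data download.

## Worked example

```python
from lncnet.synthetic import CohortConfig, generate_cohort
from lncnet.expression import threshold_genes, tpm_normalize, log_transform
from lncnet import network as nw, module_analysis as ma

cfg = CohortConfig(seed=1)                     # ~380 biopsies, 2,000 genes
ann, meta, counts, truth = generate_cohort(cfg)
retained, _ = threshold_genes(counts, annotation=ann)
tpm = tpm_normalize(counts, ann.set_index("gene_id")["length"], retained)
resid = nw.regress_covariates(log_transform(tpm), ["batch"])
net = nw.adjacency(resid, beta=6)
nw.tom(net)
modules = nw.detect_modules(net.dissimilarity, net.genes)
print(modules.sizes())
```

prints

```
module
grey         1189
turquoise     189
blue          156
brown         122
yellow         96
green          77
red            58
```

i.e. six detected coexpression modules (color names ordered by size) plus
1,189 unassigned (grey) genes — matching the six planted modules of the
generator; the adjusted Rand index against the planted labels is 1.0
after eigengene merging.

The full pipeline, end to end with one seed and a provenance manifest:

```bash
lncnet demo --seed 13 --out demo_run     # or: lncnet run --config cfg.yaml
```

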