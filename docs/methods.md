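# Methods

This note documents the models, defaults, and numerical choices behind
`lncnet`, and what the synthetic-data tests do and do not demonstrate.

## Synthetic cohort model

The generator emulates a multi-tissue IBD biopsy cohort with the features
the downstream analysis assumes, under an explicit latent model. Patients
(default 120) are assigned a disease (HC 20 %, UC 40 %, CD 40 %) and
contribute 1–6 biopsies across tissue × inflammation slots (healthy
controls are never inflamed), in one of 5 sequencing batches, giving
roughly 380 samples. Per-biopsy severity is one of inactive/mild/
moderate/severe; CRP is log-normal with a severity-dependent mean.

Each of the default 6 planted modules has a driving clinical trait
(inflammation, severity, rectal location, UC, CD): the module eigengene per
sample is the standardized trait times its effect (default 0.7–0.8) plus
standard normal noise. A module gene's log2 mean is a gene baseline
(N(4, 1.5²) log2-TPM-like units) plus loading × eigengene, loadings 0.7 ±
0.1 for module genes and 0 for background. Counts are negative binomial
(gamma–Poisson) with dispersion 0.15, allocated to a library of 2–5 M reads
proportionally to 2^logmean × gene length; gene lengths are log-uniform
500–20,000 bp so TPM- and count-based filters genuinely differ. Exact
zeros are added with a logistic dropout probability decreasing in log
mean (midpoint 0.5, slope 1.5). lncRNAs (half the genes) get a −2 shift
on the log2 baseline and doubled dispersion, reproducing the qualitative
biotype contrasts (lower expression, higher relative variability, more
zeros). Coordinates live on 5 synthetic chromosomes of 50 Mb, 0-based
half-open; module genes can optionally be co-located.

What this does **not** emulate: isoforms and length biases within genes,
correlated library-composition effects, LD among SNPs, read-level error.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not performance on real cohort data.

## Zero-inflated differential expression

Each gene's log2(TPM+1) is modeled in two parts: a logistic regression of
the zero indicator on the fixed effects, and a Gaussian linear mixed model
on the positive observations. For a continuous response with a point mass
at zero this hurdle factorization *is* the zero-inflated likelihood — the
two likelihood terms separate — so the continuous-part coefficients are
invariant to how zeros would be attributed to a latent class (asserted in
tests). Fixed effects are the combined disease × inflammation factor
(reference HC-noninf) plus optional adjustment covariates; random
intercepts are batch for ileum and rectum and patient + batch for the
nonrectal colon (fit by REML; the second factor enters as a variance
component). Fold-changes and Wald tests are reported from the continuous
part; a combined two-part chi-square test exists but is off by default,
since fold-change interpretation belongs to the continuous component.
Genes whose mixed fit fails to converge fall back to a Gaussian LMM on all
observations; genes without two groups of ≥ 3 positive values are excluded
with a reason. BH adjustment is applied across genes within a location ×
contrast.

Calibration under the generative model (n = 400, batch SD 0.5, 30 % zeros):
type-I error at α = 0.05 within [0.035, 0.065] over 2,000 null genes, a
β = 1 effect recovered within ±0.1 with 95 % CI coverage in [0.90, 0.98]
over 200 replicates (the acceptance script re-computes these at 600 null
genes / 100 replicates to keep the run short).

## Network construction and module detection

Expression is residualized on nuisance covariates (dummy-coded, rank
checked) and re-centered. The soft power β is chosen as the smallest
candidate whose connectivity distribution fits scale-free topology with
signed R² ≥ 0.80 (log10 p(k) vs log10 k over 10 connectivity bins, R²
negated for positive slopes); the full diagnostic table is always
returned and the caller may force a power. The network is unsigned,
a_ij = |r_ij|^β (a signed option ((1+r)/2)^β is provided); topological
overlap uses the standard formula with unit diagonal, verified against a
triple-loop oracle to 1e-12.

Module detection cuts the average-linkage dendrogram of d = 1 − TOM
adaptively. At high soft powers the merge heights compress into a dense
band near 1 and no fixed height separates modules reliably, so the cut
height is chosen from the data: candidate cuts just below each merge
height (subsampled to 128) are scanned; at each cut, clusters of at least
`min_module_size` (default 30) genes count as modules only if their mean
within-cluster dissimilarity is far below the network background — a
cohesion z-score ≥ 10, scaling the global dissimilarity spread by the
number of within-cluster pairs, which arbitrary background slices cannot
reach. The retained cut maximizes the module count, ties resolved toward
the higher cut so weakly attached genes still adhere to their branch.
Everything else is grey. Labels are color names in a fixed documented
palette ordered by decreasing size, so runs are reproducible and
permutation-invariant up to naming.

Eigengenes are first principal components of gene-standardized module
expression, unit variance, oriented to correlate positively with the
module's mean profile (sign rule fixed; degenerate constant-mean modules
keep the SVD sign). Modules are merged by average-linkage clustering of
1 − cor(ME) at cut height 0.2, the merged module inheriting the larger
constituent's label (ties broken lexicographically), with the lineage
recorded and eigengenes recomputed.

## Module preservation

The Zsummary composite follows the permutation framework: in the test
data (adjacency at the reference β), each reference module yields a
density statistic (mean within-module adjacency) and three connectivity
statistics (correlations of intramodular connectivity, of kME against the
set's own first PC, and of adjacency entries, between reference and test).
The null reassigns labels to random same-size gene sets, recomputing every
statistic on both data sets per draw (200 permutations by default, one
shared null per distinct module size). Zdensity is the density z-score,
Zconnectivity the median of the three connectivity z-scores, and
Zsummary their mean; > 10 is read as high preservation, 5–10 moderate,
< 5 low. kME under permutation uses |correlation| since the sign of a
random set's first PC is arbitrary. Note that with near-uniform planted
loadings the connectivity correlations carry little signal (gene hubness
is preserved even for random sets), so Zsummary is driven mainly by
density on synthetic data; on real data both components contribute.

Betweenness centrality is computed on binarized graphs (edge iff TOM ≥
threshold, unweighted shortest paths); "high-influence" nodes are the top
quartile per network (configurable), and overlap fractions are reported
per biotype.

## SNP-adjacency bootstrap

A gene is SNP-adjacent when a SNP falls in [max(0, start − 50 kb),
end + 50 kb) on its chromosome (half-open; the lower window boundary is
inclusive, mirroring interval intersection semantics). Enrichment per
module draws 10,000 size- and biotype-composition-matched gene sets from
the network universe without replacement; since a draw enters the
statistic only through its adjacency count, the count is sampled directly
from the corresponding hypergeometric distribution — distributionally
identical to sampling gene sets, and orders of magnitude faster. The
one-sided p is (1 + #{draws ≥ observed})/(1 + n_boot). This estimator is
conservative when the statistic is coarse (small modules, low adjacency
rates, large tie mass at the observed count); calibration checks therefore
use the near-continuous regime (module size ~150, adjacency ~0.3), where
null p-values are indistinguishable from uniform, and small-module p
values should be read as slightly conservative, never anti-conservative.

## Screen scoring

Per-sgRNA log2 fold-changes are reads-per-million ratios with pseudocount
1 (depth-invariant). The gene score ranks sgRNAs by fold-change
(descending for enrichment, ascending for depletion); for a gene with m
guides whose guides inside the top 4 % hold global ranks r_1 < … < r_J
(J ≥ 2 required), the score is −log10 P(X ≥ j) with X ~ Binomial(m,
r_j/N), evaluated at the deepest qualifying guide j = J. The upper tail is
used rather than the point PMF because the tail is monotone in evidence;
a point-PMF variant and a best-rank variant are flags. The permutation
null shuffles the guide-to-gene assignment among targeting guides
(controls stay controls, guide counts per gene preserved); p-values pool
null scores over genes and permutations, and BH FDR is applied within a
direction × comparison. Hits at FDR < 0.25 (strict) are labeled positive
or negative regulators according to the sorted bin and direction.

## Problem sizes and defaults

The packaged demo cohort (60 patients, 800 genes, 4 modules) exercises
every stage in a few CPU-minutes; the recovery and calibration analyses
use the full default cohort (2,000 genes, ~380 samples), 2,000–10,000
bootstrap draws, 200 preservation permutations, and 1,000 screen
permutations. These sizes were chosen so the whole suite runs comfortably
on a laptop core while keeping Monte-Carlo error well below the decision
margins of each check.

## Known limitations

- The adaptive module cut assumes modules are denser than an exchangeable
  background; overlapping or nested modules are out of scope.
- The two-random-factor LMM treats the second factor as a variance
  component within a single grand group, which is exact for crossed
  intercepts but slower than the one-factor path.
- Trait p-values in the module–trait matrix are raw (annotation
  thresholds 0.05/0.01/0.001), deliberately not multiplicity-adjusted.
- The generic hypergeometric gene-set overlap is plumbing; no pathway
  database or term-enrichment integration is included.
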