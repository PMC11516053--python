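# Methods

## The inference problem

Somatic copy-number alterations (CNAs) change the dosage of every gene
they span, and dosage changes propagate to mRNA abundance (the
cis-dosage effect). `acecna` inverts that relationship: given paired
tumor/non-tumor expression profiles and a genomic gene annotation, it
infers recurrent focal CNAs without any DNA-level assay. The key
observation is geometric — a CNA perturbs a *contiguous* block of genes,
whereas transcriptional programs select genes scattered across the
genome — so averaging differential-expression evidence over genomic
neighborhoods amplifies CNA signal and suppresses everything else.

## Neighborhood scores

For each gene *g* a differential statistic is computed:

- **cohort mode** — the paired t statistic of tumor-minus-matched-normal
  differences, `t = mean(d) / (sd(d)/sqrt(n))` with the sample (n−1) sd;
- **single-sample mode** — the z-score of one tumor against the mean and
  sample sd of all non-tumor samples in the cohort.

Genes with zero spread are mapped to 0 when the mean difference is also
0 and clamped to ±`t_clamp` (default 50) otherwise; 50 is far beyond any
t or z attainable at realistic cohort sizes, so clamping only removes
infinities without reordering significance.

The neighborhood score of gene *i* is the kernel-weighted sum of the
statistics of all same-chromosome genes within the kernel support,
including gene *i* itself at weight 1:

    NS_i = Σ_j w(|m_j − m_i|) · stat_j,    w(d) = max(0, 1 − d/h)

with gene position *m* = annotation-interval midpoint and a triangular
kernel of half-width *h* = 2 Mb by default. The kernel family is a
design choice: the weighting is required to be distance-decaying with
compact support, and the triangular form is the simplest member whose
single-gene limit (an isolated gene keeps exactly its own statistic) and
focal resolution (support 4 Mb, matching the ~0.7–16 Mb focal CNAs this
class of method targets) are both sensible. Both the shape parameter and
half-width live in the config so alternatives can be dropped in.
Chromosome boundaries are hard: inter-chromosome distance is treated as
infinite.

The production computation locates each gene's window by binary search
and takes the weighted sum directly over the window, so its
floating-point result coincides with the naive all-pairs sum; an O(G²)
reference implementation is kept for the oracle-equivalence tests.

## Permutation significance

Two null ensembles are generated (defaults: 1000 replicates each):

- **sample-label permutation** — within each tumor/normal pair the
  labels are swapped independently with probability ½, i.e. the sign of
  the pair's difference vector is flipped. This preserves pairing,
  per-gene variances, and the genomic autocorrelation of the t track
  while destroying the tumor/normal contrast. Sign flips leave Σd²
  untouched, so all replicate t tracks are computed from a single
  genes×replicates mean matrix.
- **gene-name permutation** — the observed per-gene statistics are
  shuffled across genomic positions, preserving their marginal
  distribution while destroying contiguity.

For each direction (amplification = large positive NS, deletion = large
negative NS, handled by negation) the empirical FDR at gene *i* with
score `s_i` is

    FDR_i = min(1, (mean #null ≥ s_i + 1/B) / max(1, #observed ≥ s_i))

where B is the replicate count; the 1/B pseudocount prevents exact-zero
FDRs. Raw values are monotonized into q-values by the step-up rule
`q_i = min{ raw_j : s_j ≤ s_i }`, which makes FDR non-increasing in
score — the property the downstream thresholding relies on. The
estimator is per-gene; the run-length rule below is what turns per-gene
calls into segment-level claims.

A gene is **aberrant** only when its FDR clears `alpha` (default 0.001)
under **both** null schemes in the same direction — the conservative
combination of the two nulls — and the sign of its NS matches the
direction. Maximal runs of consecutive same-direction aberrant genes
within a chromosome become segments when they contain at least
`min_run` genes (default 10); segment coordinates are the first gene's
annotated start through the last gene's annotated end.

## Cross-cohort consensus

Same-direction segments from different cohorts are grouped by transitive
interval overlap. A group supported by at least `min_cohorts` cohorts
(default: half the cohorts, rounded up) yields the **minimal common
interval**: the intersection (max of starts, min of ends) of one segment
per supporting cohort, chosen — exhaustively over the per-cohort
alternatives, leftmost on ties — to maximize the intersection. If a
transitive chain has no common core the group is split into
pairwise-overlap components and retried (logged).

## Single-sample assessment and stratification

One tumor offers nothing to permute at the sample level, so the
single-sample call uses the gene-name null only, with the same `alpha`
and `min_run`. A sample is **high** at a target region when a
qualifying aberrant run of the region's direction overlaps the region —
the same operational rule as the cohort segment caller, rather than a
region-mean test, so cohort and single-sample calls agree on what
"significant NS at a locus" means. The mRNA stratifier is independent of
NS: linear fold change `2^(tumor − normal) ≥ 2` (inclusive) marks a
sample high for a given gene.

## Orthogonal validation readouts

- **qPCR relative copy number** — comparative-Ct with a three-gene
  internal reference panel (mean Ct of the reference genes within each
  tissue; ΔΔCt of target vs reference, tumor vs matched normal;
  `rcn = 2^(−ΔΔCt)`), averaged arithmetically over the three target
  genes; gain is strictly `rcn > 1.25`. Averaging Cts (geometric mean of
  linear quantities) rather than linear quantities across the reference
  genes is a declared choice; with the three-target mean taken on the
  linear scale the readouts differ negligibly at qPCR noise levels.
- **array log-ratio calls** — segment-mean log2 ratio, gain if `> 0.3`,
  loss if `< −0.3`, both strict.
- **NS↔array concordance** — Pearson correlation (scipy) between
  per-sample region-mean NS and per-sample region log-ratio.
- **IHC combined score** — proportion category 0–5 plus intensity
  category 1–4 for positive slides; zero-proportion slides score 0, so
  the attainable set is exactly {0, 2…9}.
- **xenograft tumor volume** — caliper ellipsoid `V = L·W²/2` in mm³.

## Synthetic cohorts

The generator emulates exactly the structure the inference assumes, so
the test suite can interrogate every stage against known truth:

| parameter | default | rationale |
|---|---|---|
| `n_genes` / `n_chromosomes` | 5000 / 5 | ~1000 genes per chromosome at human-like density keeps runs desk-scale while leaving each chromosome ~100 Mb |
| `gene_spacing_bp` | 100 kb (exponential) | human gene density is ~1 gene per 100–150 kb; exponential gaps exercise kernel-edge behavior |
| `n_pairs` | 30 | a mid-sized discovery cohort |
| baseline | Normal(8, sd 2) per gene | log2 microarray scale |
| `noise_sd` | 0.5 | per-observation log2 noise, a realistic biological+technical spread |
| `dosage_slope` | 1.0 | pure cis-dosage: expression shifts by log2(copy/2) |
| `array_noise_sd` | 0.2 | segment-mean log-ratio noise |
| `qpcr_ct_noise_sd` | 0.15 | per-well Ct repeatability |

Tumor expression is `baseline + slope·log2(copy/2)·[gene in region,
sample a carrier] + noise`; the matched normal omits the dosage term.
Carriers are Bernoulli draws at `carrier_fraction` per region. Matched
observables: per-region array log-ratio `log2(copy/2) + noise` per
tumor, and a qPCR panel whose target genes amplify `log2(copy/2)` cycles
earlier in tumor tissue than the reference genes. Everything derives
from the single config seed.

The generator deliberately omits tumor purity admixture, subclonality,
count-level (negative-binomial) noise, trans-effects, and expression
correlation between neighboring genes beyond the CNA itself. Passing
tests therefore demonstrate correctness of the statistical machinery
under the cis-dosage model, not robustness to impure or subclonal real
tumors; on real data the effective dosage slope is attenuated by purity
and the nulls must absorb co-expression structure.

## Numerical and procedural choices

- Presence filter strictly `> 0.9` non-missing fraction; probe
  summarization is the arithmetic mean over exonic probes only.
- log2 pseudocount 1 (configurable); quantile normalization maps every
  column onto the mean-of-sorted-columns reference, ties receiving the
  mean of the reference values at their tied ranks (idempotent to
  1e-12); residual missing cells are imputed by the gene's median within
  the sample's group before normalization, avoiding tumor/normal
  leakage. Tumor and non-tumor arrays are normalized jointly by default
  (`quantile_joint: false` switches to separate).
- All internal coordinates are 1-based inclusive; BED emission/ingestion
  converts exactly once. Segment BEDs carry two extra columns
  (n_genes, mean NS) so records round-trip exactly.
- Scaled problem sizes: the calibration and recovery suites and the
  acceptance script run 200 permutation replicates per scheme (the
  library default is 1000) on 5000-gene, 30-pair cohorts — at these
  sizes the empirical FDR floor (1/B per replicate set) still sits well
  below the 0.001 threshold for multi-gene regions.

## Known limitations

- The FDR is per-gene with a run-length segment filter; no
  segment-level multiplicity correction is attempted.
- `min_run` interacts with gene density: in gene-poor regions a real
  2 Mb CNA may span fewer than 10 genes and be missed.
- The kernel half-width caps boundary resolution at ±2 Mb; reported
  segment edges inherit the smoothing.
- Consensus intersects one segment per cohort; nested or multi-peak
  amplicons within one cohort are reduced to the best-intersecting one.
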