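# Methods

This note describes the models and procedures behind `pigcre`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## The synthetic study

All analyses run over a generated study whose defaults are the study
conditions: a genome of 3 chromosomes × 10 Mb carrying 300 stranded,
non-overlapping TSSs, profiled across 6 tissues × 2 breeds × 2 replicates,
with H3K4me3, H3K27ac, Input and RNA libraries per condition. One global
seed fans out to per-generator child seeds derived by CRC-32 hashing of the
generator name, so adding a generator never changes another's draws, and
all serialized outputs are byte-identical under a fixed seed.

### ChIP counts

Counts per candidate region and library are negative-binomial with
variance m + φm² (φ = 0.05 per replicate; φ = 0 degenerates to Poisson).
Input coverage sits at a flat 0.5 RPM over a 2 kb region; at a planted
element the expected IP coverage is 2·margin × Input (margin = 3), i.e.
three times the 2-fold ratio threshold of the enriched-region rule —
`margin ≤ 1` is rejected because the planted truth would sit at or below
the calling threshold by construction. Library depth is 4 × 10⁷ mapped
reads, a typical effective depth for a filtered ChIP library; at that depth
the replicate-merged noise floor leaves planted elements comfortably
callable while decoys (same baseline as Input) essentially never pass both
coverage rules. Upstream-caller p-values are planted at 10⁻⁶…10⁻¹² for real
elements and 10⁻²…10⁻⁸ for decoys so that the p ≤ 10⁻⁵ gate is exercised in
both directions.

Planted elements: 120 tissue-specific enhancers (20 per tissue), 60
constitutive enhancers, 60 "coupled" enhancers whose activity follows a
lognormal latent profile shared with a nearby gene (see Pairing), one
H3K4me3 promoter per gene, H3K27ac at the TSS for 70% of genes (active
promoters), and 240 decoy candidate peaks.

### Expression

Baseline TPM is lognormal (median 20); 10% of genes sit at 0.2 TPM to
exercise the TPM ≥ 1 detection floor. Tissue-specific genes (60, balanced)
are 6-fold higher in their tissue; breed-differential genes (40) carry a
4-fold breed effect; per-sample noise is lognormal with σ = 0.2. Read
counts are negative-binomial around depth-scaled abundance.

### Hi-C, species map, variants

Contact matrices follow expected contact ∝ (d+1)^(−α) with α = 1,
attenuated by a factor 0.2 across each planted boundary (boundaries every
1 Mb = every 25 bins at 40 kb), with multiplicative gamma noise (cv ≈ 14%)
emulating an ICE-balanced matrix; checkerboard compartments can be overlaid
as (1 ± strength) modulation. The two-species scenario builds the target
genome as a concatenation of source-chromosome segments with the junctions
placed inside target TADs, so each junction yields exactly one TAD whose
flanking boundaries trace to different source chromosomes; alignment blocks
(~50 kb) cover the segments with 5% unmappable holes. The allele table
covers 3000 sites for populations of 40 and 32 haplotypes (matching a
20- vs 16-individual contrast); background sites share one frequency drawn
uniformly in (0.05, 0.95), and 40 planted divergent loci with frequency gap
δ = 0.8 cluster in one 300 kb sweep region so that the windowed
F<sub>ST</sub> track has a coherent top-decile signal.

### What the generator does not emulate

Read-level artifacts (mappability, duplicates, GC bias), unbalanced
designs, batch effects, linkage disequilibrium between variant sites,
assembly errors in the species map, and any correlation between the sweep
region and CRE placement. Passing the planted-truth tests therefore shows
that the decision rules recover their intended signal under calibrated
count noise — not that they are robust to every artifact of real libraries.

## Stage-by-stage notes

### Enriched regions and CRE classes

All coordinates are 0-based half-open; merging requires ≥ 1 shared bp
(bookended intervals do not merge). Replicates are merged by summing counts
after a Pearson-correlation QC gate (r > 0.83 reported per pair; failing
pairs are flagged, not dropped). Enhancer/active-promoter classification is
an exact partition of the H3K27ac enriched regions because the promoter
side of the rule (TSS flank ∪ potential promoter) is the complement of the
enhancer exclusion. TSS flanks are strand-aware; strandless records are
treated as '+' with a warning. For '−' genes the flank is mirrored as
[TSS − 1 kb, TSS + 2.5 kb).

### Super-enhancers

Stitching uses the ROSE default gap of ≤ 12,500 bp with no promoter
exclusion. Ranked summed signals are rescaled to the unit square and the
cutoff is the point where a slope-1 line is tangent to the curve,
computed as argmin(y − x) — the point of maximum distance below the
diagonal, which is both "the point where the slope of the rescaled curve
equals 1" and what the original ROSE implementation optimizes. The
degenerate all-equal case (the curve *is* the diagonal) deterministically
classifies no region; fewer than three stitched regions disables the elbow
with a warning. The cutoff is invariant to uniform scaling of the signals.
Super-enhancers are called per (tissue, breed) on that condition's own
enhancers; pooling conditions would make the signal distribution bimodal
(active/inactive) and the elbow meaningless.

### Tissue specificity

Quantile normalization is the rank-mean algorithm: every column receives
the cross-column mean of order statistics; tied values within a column
receive the mean of the reference values across the tied run. The same
plain quantile normalization is used for expression and for enhancer
intensity matrices (the original expression pipeline used a smoothed
variant; the specificity rules, not the smoothing, carry the result). The
Z-score fold rule's sign casework: both Z positive → ratio ≥ 3; mixed signs
→ the fold is deemed ±3, i.e. a pass exactly when the candidate tissue is
the positive one; both negative → the reciprocal of the ratio must be ≥ 3.
Denominators with |Z| < 10⁻⁹ (including exact zeros, which the rule leaves
undefined) are grouped with the mixed-sign branch to avoid division
blow-ups. Replicate averaging precedes Z-scaling.

### Transcript filters

"In at least two replicates" is evaluated within replicate groups when
labels are supplied, otherwise over any two samples (configurable). The
ambiguous reading of the first lncRNA gate — whether overlap with class-'u'
transcripts also disqualifies — is a flag (`exclude_u_overlap`, default
on); both readings are tested. FPKM and read-count support must hold
jointly in the same replicate.

### Hi-C structure

Insulation at bin b aggregates the off-diagonal square (b−w…b−1) ×
(b+1…b+w), w = 480 kb; `iqrMean` is the mean of window values inside
[Q1, Q3]. The aggregate is log2-scaled against the chromosomal mean,
smoothed by a centered running mean whose half-width is
(160 kb / bin)/2 bins (the "-ss" span read as a smoothing span), and the
delta at b is the mean of the smoothed profile over the 320 kb to the left
minus the right. Bins within w of an edge are NaN, never extrapolated.
Boundaries sit at positive→negative delta zero-crossings; boundary strength
is the delta local max left of the crossing minus the local min right of
it, thresholded at 0.1 (the cited insulation tool's default, CLI-exposed).
Observed/expected normalization for compartments divides each diagonal by
its mean with a 10⁻⁹ pseudocount; zero-variance bins are dropped (error if
more than half), and the leading eigenvector's sign is oriented so that
higher-activity bins are "A". Exact parity with any named external Hi-C
pipeline is a non-goal; the procedures are the standard published ones.

### Pairing

TAD membership is midpoint containment (deterministic for straddling
elements); "adjacent" means the two directly neighbouring TADs along a
chromosome. Random control pairs are uniform intra-chromosomal draws
matched in number to the same-TAD count, seeded. Spearman is Pearson on
average ranks; zero-variance profiles give a missing coefficient.
Rank-sum comparisons use the exact Mann–Whitney null below n = 20 and the
tie-corrected normal approximation above.

### Comparative

`map_interval` succeeds when ≥ minMatch of the query bases are covered by
blocks *and* all covered bases map to one target chromosome and strand;
the image is the span of the per-base images (reflected for '−' blocks;
mixed-strand coverage fails, mirroring the conservative behavior of
chain-based liftover). CRE conservation maps the centered 1 kb at
minMatch = 0.5; usage conservation requires ≥ 1 bp overlap with a
same-class target element (the coverage fraction is adjustable — the
permissive reading is the default). Boundary conservation maps at
minMatch = 0.1, extends target boundaries by ±100 kb *before* the 10%
reciprocal-overlap test, then rescues unpaired boundaries within 500 kb of
a target boundary not already claimed. A UCSC chain reader is provided
(alignment gaps become block breaks); the TSV block map is the primary
tested path.

### Breed contrasts

F<sub>ST</sub> uses the two-population Weir–Cockerham (1984) variance
components computed from allele counts; with no genotype information the
within-individual heterozygosity terms are zero, giving the allele-count
(haploid) form with a = among-population and b = within-population
components and window value Σa/Σ(a+b). Windows (150 kb, step 15 kb) are
anchored at 0, half-open, last partial window retained, empty windows
omitted; per-site estimates may be negative (estimator property) and are
never clamped except implicitly by ranking. Decile bands take the n/10
highest / lowest / median-centered windows (ties broken by genomic order)
and merge overlapping windows into regions. The ΔAF flag carries a 10⁻¹²
guard so that an exact 0.6 difference is not flagged despite float
round-off.

The differential test is a deliberate substitute for external count-model
packages: counts are normalized by median-of-ratios size factors and
tested, by default, with the exact conditional Poisson (binomial) test on
group sums; a Welch t on log2 normalized counts is selectable for designs
where the Poisson conditioning is inappropriate. Significance additionally
requires |log₂FC| > 1 (log₂FC from pseudocounted normalized means), which
is what keeps the flagged fraction calibrated under NB overdispersion —
the conditional test alone is anti-conservative for overdispersed counts,
a documented property, and the acceptance surface is calibration
(null flagged fraction ≤ 0.05 + 3 binomial SE; power ≥ 0.8 at 4-fold
effects with φ = 0.05), not parity with any external package. DE-gene
labels use inclusive fold boundaries (log₂FC ≥ 1 / ≤ −1) at FDR < 0.05.

## Problem sizes

The default study (30 Mb genome, 96 libraries, ~1000 candidate regions,
3 × 250-bin contact maps, 3000 variant sites) runs the complete pipeline in
well under a minute on one CPU; the test suite and the acceptance script
each complete in a few minutes. These sizes were chosen so that every
planted-truth estimate has enough elements (≥ 40 per class) for stable
recall/precision percentages while staying desk-scale.

## Known limitations

* Conservation percentages and counts from the generated scenario describe
  the synthetic map, not any real species pair.
* The insulation smoothing-span semantics follow the cited tool's
  documented options but were re-derived, not diffed against its output.
* The exact conditional Poisson default trades per-test validity under
  overdispersion for the robustness of the fold-change gate; users testing
  counts with large dispersion and small effects should prefer
  `method="welch"`.
* Boundary conservation can drop a true boundary whose 40 kb interval falls
  entirely into an unmappable hole — the observed ~91% conserved-boundary
  rate on the default scenario is a property of the planted 5% hole
  fraction.
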