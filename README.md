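# pigcre

A desk-scale pipeline for regulatory-genomics analyses of the pig genome:
annotation of cis-regulatory elements (CREs) from histone-mark ChIP
coverage, tissue-specificity scoring of genes and enhancers, Hi-C derived
chromatin structure (TADs and A/B compartments), enhancer–gene pairing
within TADs, cross-species conservation and TAD-rearrangement
classification, and breed-level population contrasts (ΔAF and windowed
F<sub>ST</sub>).

It is aimed at people who want the *bespoke decision rules* of a
multi-tissue, multi-breed epigenome compendium as tested, reusable code:
every classification threshold and procedure is implemented against a
synthetic-data generator that plants known ground truth, so each stage is
scored by recall/precision rather than by eye.

## The rules at the core

* **Enriched regions.** A candidate peak (upstream caller p ≤ 10⁻⁵) is
  enriched iff IP_RPM > 2 × INPUT_RPM and IP_RPM − INPUT_RPM > 1, where
  RPM = reads per million mapped reads over the 2 kb window at the peak
  midpoint; overlapping survivors are merged and re-centered into fixed
  2 kb regions.
* **CRE classes.** H3K4me3 enriched regions are potential promoters.
  H3K27ac enriched regions split exactly in two: those overlapping a
  strand-aware TSS flank (−2.5 kb … +1 kb) or a potential promoter are
  active promoters, the rest are enhancers. Broad H3K4me3 domains require
  p < 10⁻⁸, fold > 4, width > 5 kb and TSS overlap. Super-enhancers follow
  ROSE: stitch enhancers with gaps ≤ 12.5 kb, rank by summed signal, cut at
  the slope-1 elbow of the rescaled rank curve.
* **Tissue specificity.** Genes: quantile-normalize TPM, average
  replicates, row-Z-score, then require ≥ 3-fold higher values in every
  sample of one tissue vs every sample of every other tissue, with the sign
  casework for Z scores (mixed signs count as a pass when the candidate is
  the positive one; two negatives use the reciprocal ratio). Tau:
  τ = Σ(1 − x̂ᵢ)/(n − 1), x̂ᵢ = xᵢ/max(x). Enhancers: quantile-normalized
  IP−Input change > 1 in the tissue for every breed and < 0.5 everywhere
  else.
* **Hi-C.** Insulation scores over 480 kb off-diagonal windows (iqrMean
  aggregation, 160 kb smoothing, 320 kb delta spans); boundaries at
  positive→negative delta zero-crossings with strength ≥ 0.1.
  Directionality index DI = sign(B−A)·[(A−E)²/E + (B−E)²/E]. Compartments
  from the leading eigenvector of the distance-normalized correlation
  matrix, sign-oriented by an activity track.
* **Pairing.** Spearman correlation of enhancer intensity and gene
  expression profiles; same-TAD vs adjacent-TAD vs random pair catalogues;
  significance at R > 0.5 (enhancer–enhancer, enhancer–gene) and R > 0.8
  (gene–gene).
* **Comparative.** Minimal liftover through an alignment-block map with
  minMatch semantics (0.5 for the centered 1 kb of CREs, 0.1 for
  boundaries); sequence- vs usage-conservation labels; conserved boundary
  pairing (±100 kb extension with 10% reciprocal overlap, then a 500 kb
  nearest-free-partner rescue); a TAD is rearranged when its two flanking
  boundaries pair with boundaries on different chromosomes of the other
  genome.
* **Breed contrasts.** ΔAF = |p₁ − p₂| flagged at > 0.6; Weir–Cockerham
  F<sub>ST</sub> variance components summed over 150 kb windows stepping
  15 kb (weighted Σa/Σ(a+b+c)); decile bands of the window track;
  differential CREs and DE genes at FDR < 0.05 and |log₂FC| ≥ 1 with the
  low-change and super-enhancer pre-filters.

## Worked example

```bash
pigcre simulate --seed 1 --outdir study
pigcre call-cres --study study --outdir res
pigcre tissue-specific genes --study study --outdir res
pigcre hic tads --study study --outdir res
```

Running the analysis drivers in order reproduces the whole narrative; for
example:

```
$ python analysis/02_call_cres.py
CRE records: 7664 across 12 conditions
total enhancers: 240 (all 2 kb)
planted-enhancer recall 99.9%, precision 100.0%
super-enhancers: 220 across conditions (elbow on the rescaled rank curve)

$ python analysis/04_hic_structure.py
boundaries: 27/27 planted recovered within 1 bin, 0 spurious
compartments: 100.0% of bins match the planted checkerboard

$ python analysis/07_breed_contrasts.py
dAF: 40/3000 sites above 0.6 (planted divergent: 40)
...
planted divergent loci inside top decile: 100%
```

The recall/precision lines compare each stage's calls with the planted
truth recorded by the generator: 240 planted enhancers are recovered at
99.9% recall by the coverage rules, all 27 planted TAD boundaries are found
within one 40 kb bin with no spurious calls, and all 40 planted
high-divergence loci fall in the top F<sub>ST</sub> decile.

## Layout

```
src/pigcre/        library: synthetic, cre, specificity, transcripts, hic,
                   pairing, comparative, popgen, pipeline, io, cli
analysis/          numbered narrative drivers (01_simulate … 07_breed_contrasts)
scripts/           acceptance.py
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    methods note
```
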