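#!/usr/bin/env python
"""Generate the synthetic study and serialize it under results/study.

The study plants ground truth for every later stage: enhancers and
promoters in the ChIP counts, tissue-specific genes in the expression
matrix, TAD boundaries in the contact maps, inter-chromosomal
rearrangements in the species map, and divergent loci in the allele table.
"""

from pathlib import Path

from pigcre.io import write_study
from pigcre.synthetic import StudyConfig, simulate_study

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main():
    study = simulate_study(StudyConfig(), seed=SEED)
    outdir = ROOT / "results" / "study"
    write_study(study, outdir)
    t = study.truth
    print(f"genome: {len(study.sizes)} chromosomes, {sum(study.sizes.values()):,} bp")
    print(f"samples: {len(study.sheet)} ({len(study.sheet.tissues)} tissues x "
          f"{len(study.sheet.breeds)} breeds)")
    print(f"planted CREs: {len(t.cres)} "
          f"({(t.cres['cre_class'] == 'enhancer').sum()} enhancers, "
          f"{(t.cres['cre_class'] == 'decoy').sum()} decoys)")
    print(f"planted tissue-specific genes: {len(t.ts_genes)}; "
          f"breed-DE genes: {len(t.de_genes)}; coupled pairs: {len(t.coupled_pairs)}")
    print(f"planted TAD boundaries: {len(t.tad_boundaries)}; "
          f"divergent loci: {len(t.divergent_loci)}")
    print(f"written to {outdir}")


if __name__ == "__main__":
    main()
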