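"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: BED for intervals, TSV matrices with a header row
of sample ids, a TSV sample sheet, a TSV block map, a TSV allele-count
table, dense whitespace matrices for contacts, and a minimal VCF site
reader. BED output follows 0-based half-open convention; 1-based inputs
(VCF) are converted at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

FLOAT_FORMAT = "%.6g"


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label,
              float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_contact_matrix(m: np.ndarray, path) -> None:
    np.savetxt(path, m, fmt=FLOAT_FORMAT, delimiter="\t")


def read_contact_matrix(path) -> np.ndarray:
    m = np.loadtxt(path, delimiter="\t")
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"{path}: not a square dense matrix")
    return m


def write_chrom_sizes(sizes, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path):
    from .intervals import ChromSizes
    sizes = {}
    with open(path) as fh:
        for line in fh:
            chrom, length = line.split()
            sizes[chrom] = int(length)
    return ChromSizes(sizes)


def read_vcf_sites(path, pop1: list[str], pop2: list[str]) -> pd.DataFrame:
    """Minimal VCF 4.x site reader: hard-called GT fields to allele counts.

    Returns the standard allele-count table (chrom, pos 0-based, per-
    population ref/alt counts) for biallelic sites.
    """
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.rstrip("\n").lstrip("#").split("\t")
                continue
            if header is None:
                raise InputError("VCF has no #CHROM header line")
            f = line.rstrip("\n").split("\t")
            rec = dict(zip(header, f))
            if "," in rec["ALT"]:
                continue  # multi-allelic sites skipped
            fmt = rec["FORMAT"].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                continue
            counts = {}
            for name in pop1 + pop2:
                gt = rec[name].split(":")[gt_idx]
                alleles = gt.replace("|", "/").split("/")
                counts[name] = [a for a in alleles if a in ("0", "1")]
            c1 = [a for n in pop1 for a in counts[n]]
            c2 = [a for n in pop2 for a in counts[n]]
            if not c1 or not c2:
                continue
            rows.append((
                rec["CHROM"], int(rec["POS"]) - 1,
                c1.count("0"), c1.count("1"), c2.count("0"), c2.count("1"),
            ))
    return pd.DataFrame(rows, columns=["chrom", "pos", "pop1_ref", "pop1_alt",
                                       "pop2_ref", "pop2_alt"])


def write_study(study, outdir) -> None:
    """Serialize a SyntheticStudy to a directory of text files."""
    import yaml
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(study.config)
    cfg["tissues"] = list(cfg["tissues"])
    cfg["breeds"] = list(cfg["breeds"])
    cfg["n_haplotypes"] = list(cfg["n_haplotypes"])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg, "seed": study.seed}, fh, sort_keys=True)
    write_chrom_sizes(study.sizes, outdir / "chrom.sizes")
    study.sheet.to_tsv(outdir / "samples.tsv")
    study.truth.to_dir(outdir)
    study.chip.candidates.to_csv(outdir / "candidate_peaks.tsv", sep="\t",
                                 index=False, float_format="%.6e")
    write_matrix(study.chip.counts, outdir / "chip_counts.tsv", index_label="element_id")
    write_matrix(study.tpm.round(4), outdir / "tpm.tsv", index_label="gene_id")
    write_matrix(study.rna_counts, outdir / "rna_counts.tsv", index_label="gene_id")
    for chrom, m in study.hic.items():
        write_contact_matrix(m, outdir / f"hic_{chrom}.tsv")
    study.variants.to_csv(outdir / "allele_counts.tsv", sep="\t", index=False)
    sp = study.species
    sp["block_map"].to_csv(outdir / "block_map.tsv", sep="\t", index=False)
    sp["src_boundaries"].to_csv(outdir / "src_boundaries.bed", sep="\t",
                                index=False, header=False)
    sp["tgt_boundaries"].to_csv(outdir / "tgt_boundaries.bed", sep="\t",
                                index=False, header=False)
    sp["tgt_tads"].to_csv(outdir / "tgt_tads.bed", sep="\t", index=False, header=False)
    with open(outdir / "rearranged_ids.txt", "w") as fh:
        for tid in sp["rearranged_ids"]:
            fh.write(tid + "\n")
    study.transcripts.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)


def load_study(outdir):
    """Reload a serialized SyntheticStudy from :func:`write_study` output."""
    import yaml

    from .intervals import ChromSizes
    from .samples import SampleSheet
    from .synthetic import GroundTruth, ChipSim, StudyConfig, SyntheticStudy

    outdir = Path(outdir)
    with open(outdir / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    cfg_dict = meta["config"]
    cfg_dict["tissues"] = tuple(cfg_dict["tissues"])
    cfg_dict["breeds"] = tuple(cfg_dict["breeds"])
    cfg_dict["n_haplotypes"] = tuple(cfg_dict["n_haplotypes"])
    cfg = StudyConfig(**cfg_dict)
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    sheet = SampleSheet.from_tsv(outdir / "samples.tsv")
    truth = GroundTruth.from_dir(outdir)
    candidates = pd.read_csv(outdir / "candidate_peaks.tsv", sep="\t")
    counts = read_matrix(outdir / "chip_counts.tsv")
    chip = ChipSim(candidates=candidates, counts=counts, coupling=pd.DataFrame())
    tpm = read_matrix(outdir / "tpm.tsv")
    rna_counts = read_matrix(outdir / "rna_counts.tsv")
    hic = {}
    hic_bins = {}
    for chrom in sizes:
        hic[chrom] = read_contact_matrix(outdir / f"hic_{chrom}.tsv")
        hic_bins[chrom] = [
            int(p) // cfg.hic_bin_size
            for p in truth.tad_boundaries.loc[
                truth.tad_boundaries["chrom"] == chrom, "pos"]]
    variants = pd.read_csv(outdir / "allele_counts.tsv", sep="\t")
    species = {
        "block_map": pd.read_csv(outdir / "block_map.tsv", sep="\t"),
        "src_boundaries": pd.read_csv(outdir / "src_boundaries.bed", sep="\t",
                                      header=None, names=["chrom", "start", "end"]),
        "tgt_boundaries": pd.read_csv(outdir / "tgt_boundaries.bed", sep="\t",
                                      header=None, names=["chrom", "start", "end"]),
        "tgt_tads": pd.read_csv(outdir / "tgt_tads.bed", sep="\t", header=None,
                                names=["chrom", "start", "end", "tad_id"]),
        "rearranged_ids": [
            line.strip() for line in open(outdir / "rearranged_ids.txt")
            if line.strip()],
    }
    transcripts = pd.read_csv(outdir / "transcripts.tsv", sep="\t")
    return SyntheticStudy(
        config=cfg, seed=int(meta["seed"]), sizes=sizes, sheet=sheet, truth=truth,
        chip=chip, tpm=tpm, rna_counts=rna_counts, hic=hic,
        hic_boundary_bins=hic_bins, variants=variants, species=species,
        transcripts=transcripts)
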