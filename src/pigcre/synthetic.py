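"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes is generated here, together with a record
of what was planted, so that each downstream stage (CRE calling, tissue
specificity, Hi-C structure, pairing, cross-species comparison, breed
contrasts) can be scored against known truth without any external download.

Design of the default study
---------------------------
A toy genome of 3 chromosomes x 10 Mb carries 300 genes across a design of
6 tissues x 2 breeds x 2 replicates. ChIP read counts per candidate region
are negative-binomial around an expected coverage: Input at a flat baseline,
IP at ``2 * margin`` times Input at planted elements (the enriched-region
caller uses a 2-fold ratio rule, so *margin* is the factor by which planted
elements exceed that threshold). Hi-C matrices follow a power-law distance
decay attenuated across planted boundaries. Two populations of haplotypes
share background allele frequencies except at planted divergent loci.

One global seed fans out to per-generator child seeds derived by stable
hashing (CRC-32) of the generator name, so adding a generator never perturbs
the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoordinateError, InputError, SizingError
from .intervals import ChromSizes
from .samples import SampleSheet


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Derive an independent generator for *name* from the global seed."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StudyConfig:
    """Parameters of the synthetic study. Defaults are the study conditions."""

    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    n_genes: int = 300
    tissues: tuple = ("muscle", "liver", "heart", "spleen", "fat", "kidney")
    breeds: tuple = ("LW", "MS")
    n_replicates: int = 2
    chip_depth: float = 4e7
    rna_depth: float = 2e7

    # planted regulatory elements
    n_ts_enhancers: int = 120       # tissue-specific, balanced across tissues
    n_const_enhancers: int = 60     # active in every tissue
    n_coupled_pairs: int = 60       # enhancer-gene pairs sharing a latent activity profile
    n_decoys: int = 240             # candidate peaks with no planted signal
    frac_active_promoters: float = 0.7  # genes whose TSS also carries H3K27ac

    # ChIP noise model
    margin: float = 3.0             # planted IP = 2 * margin * Input (ratio rule threshold is 2)
    dispersion: float = 0.05        # NB overdispersion per replicate
    base_input_rpm: float = 0.5     # flat Input coverage over a 2 kb region

    # expression
    n_ts_genes: int = 60            # tissue-specific genes, balanced across tissues
    n_de_genes: int = 40            # breed-differential genes
    specific_fold: float = 6.0      # planted tissue fold for specific genes
    de_fold: float = 4.0            # planted breed fold for DE genes
    expr_noise_sigma: float = 0.2   # lognormal noise per sample
    coupling_sigma: float = 0.7     # latent activity spread of coupled pairs

    # genome geometry
    tss_min_gap: int = 20_000
    edge_margin: int = 200_000
    enhancer_width: int = 2000
    tad_spacing: int = 1_000_000

    # Hi-C
    hic_bin_size: int = 40_000
    hic_alpha: float = 1.0
    hic_insulation_factor: float = 0.2
    hic_noise_shape: float = 50.0   # gamma shape of multiplicative noise (cv ~ 14%)

    # variants
    n_variant_sites: int = 3000
    n_divergent: int = 40
    delta_af: float = 0.8
    n_haplotypes: tuple = (40, 32)  # two populations (e.g. 20 + 16 diploids)
    sweep_span: int = 300_000

    # cross-species map
    block_length: int = 50_000
    unmappable_fraction: float = 0.05
    n_rearranged: int = 3


@dataclass
class GroundTruth:
    """Everything that was planted, for scoring downstream calls."""

    genes: pd.DataFrame            # gene_id, chrom, tss, strand
    cres: pd.DataFrame             # element_id, chrom, start, end, cre_class, tissue
    ts_genes: pd.DataFrame         # gene_id, tissue
    de_genes: pd.DataFrame         # gene_id, direction
    coupled_pairs: pd.DataFrame    # enhancer_id, gene_id
    tad_boundaries: pd.DataFrame   # chrom, pos (bp)
    divergent_loci: pd.DataFrame   # chrom, pos (0-based)

    _FRAMES = (
        "genes", "cres", "ts_genes", "de_genes",
        "coupled_pairs", "tad_boundaries", "divergent_loci",
    )

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._FRAMES:
            getattr(self, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, outdir) -> "GroundTruth":
        outdir = Path(outdir)
        frames = {
            name: pd.read_csv(outdir / f"truth_{name}.tsv", sep="\t")
            for name in cls._FRAMES
        }
        return cls(**frames)

    def __eq__(self, other) -> bool:
        return all(
            getattr(self, n).reset_index(drop=True).equals(
                getattr(other, n).reset_index(drop=True))
            for n in self._FRAMES
        )


# ---------------------------------------------------------------------------
# genome and design


def generate_genome(cfg: StudyConfig, seed: int) -> tuple[ChromSizes, pd.DataFrame]:
    """Chromosome sizes plus a stranded, non-overlapping TSS annotation.

    TSS positions sit on a jittered grid with a guaranteed minimum gap of
    ``tss_min_gap / 2`` so that promoter flanks of neighbouring genes never
    collide with planted enhancers by construction.
    """
    rng = child_rng(seed, "genome")
    sizes = ChromSizes(cfg.chrom_sizes)
    chroms = list(sizes)
    capacities = {
        c: max(0, (sizes[c] - 2 * cfg.edge_margin) // cfg.tss_min_gap) for c in chroms
    }
    total_cap = sum(capacities.values())
    if total_cap < cfg.n_genes:
        raise SizingError(
            f"genome can hold at most {total_cap} genes at gap {cfg.tss_min_gap}, "
            f"requested {cfg.n_genes}"
        )
    # allocate genes proportionally to chromosome length
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(cfg.n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < cfg.n_genes:
        alloc[int(np.argmin(alloc / np.maximum(lengths, 1)))] += 1
    records = []
    gene_idx = 0
    for c, k in zip(chroms, alloc):
        slots = rng.choice(capacities[c], size=k, replace=False)
        slots.sort()
        jitter = rng.integers(0, cfg.tss_min_gap // 2, size=k)
        pos = cfg.edge_margin + slots * cfg.tss_min_gap + jitter
        strands = rng.choice(["+", "-"], size=k)
        for p, s in zip(pos, strands):
            records.append((f"gene{gene_idx:04d}", c, int(p), s))
            gene_idx += 1
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "tss", "strand"])
    return sizes, genes


def make_sample_sheet(cfg: StudyConfig) -> SampleSheet:
    rows = []
    for tissue in cfg.tissues:
        for breed in cfg.breeds:
            for assay in ("H3K4me3", "H3K27ac"):
                for rep in range(1, cfg.n_replicates + 1):
                    rows.append((f"{assay}_{tissue}_{breed}_r{rep}", tissue, breed,
                                 rep, assay, cfg.chip_depth,
                                 f"Input_{tissue}_{breed}_r{rep}"))
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((f"Input_{tissue}_{breed}_r{rep}", tissue, breed,
                             rep, "Input", cfg.chip_depth, ""))
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((f"RNA_{tissue}_{breed}_r{rep}", tissue, breed,
                             rep, "RNA", cfg.rna_depth, ""))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "tissue", "breed", "replicate", "assay",
                       "depth", "input_id"]))


def _tad_boundaries_bp(sizes: ChromSizes, spacing: int) -> pd.DataFrame:
    rows = []
    for chrom, length in sizes.items():
        for pos in range(spacing, length, spacing):
            if pos + spacing <= length:
                rows.append((chrom, pos))
            elif length - pos >= spacing // 2:
                rows.append((chrom, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def plant_ground_truth(cfg: StudyConfig, sizes: ChromSizes,
                       genes: pd.DataFrame, seed: int) -> GroundTruth:
    """Place promoters, enhancers (tissue-specific / constitutive / coupled),
    tissue-specific and breed-differential genes, and TAD boundaries."""
    rng = child_rng(seed, "truth")
    width = cfg.enhancer_width
    half = width // 2

    # allowed enhancer midpoints: a 6 kb grid kept clear of every TSS flank
    grid_step = 6000
    clearance = 6000
    free: list[tuple[str, int]] = []
    for chrom, length in sizes.items():
        tss = np.sort(genes.loc[genes["chrom"] == chrom, "tss"].to_numpy())
        for mid in range(cfg.edge_margin, length - cfg.edge_margin, grid_step):
            j = np.searchsorted(tss, mid)
            near = min(
                abs(mid - tss[j - 1]) if j > 0 else np.inf,
                abs(tss[j] - mid) if j < len(tss) else np.inf,
            )
            if near > clearance:
                free.append((chrom, mid))
    n_needed = cfg.n_ts_enhancers + cfg.n_const_enhancers + cfg.n_coupled_pairs + cfg.n_decoys
    if len(free) < n_needed:
        raise SizingError(f"only {len(free)} enhancer slots for {n_needed} elements")

    cres = []
    eid = 0

    def add_enhancer(chrom, mid, tissue):
        nonlocal eid
        cres.append((f"enh{eid:04d}", chrom, mid - half, mid - half + width,
                     "enhancer", tissue))
        eid += 1
        return cres[-1][0]

    # promoters: every gene gets H3K4me3; a fraction also gets H3K27ac at TSS
    active_mask = rng.random(len(genes)) < cfg.frac_active_promoters
    for i, row in genes.reset_index(drop=True).iterrows():
        cres.append((f"prom_{row.gene_id}", row.chrom, row.tss - half,
                     row.tss - half + width, "promoter", "all"))
        if active_mask[i]:
            cres.append((f"aprom_{row.gene_id}", row.chrom, row.tss - half,
                         row.tss - half + width, "active_promoter", "all"))

    order = rng.permutation(len(free))
    slot_iter = iter(order)

    def next_slot():
        return free[next(slot_iter)]

    # tissue-specific enhancers, balanced across tissues
    per_tissue = cfg.n_ts_enhancers // len(cfg.tissues)
    for tissue in cfg.tissues:
        for _ in range(per_tissue):
            chrom, mid = next_slot()
            add_enhancer(chrom, mid, tissue)
    for _ in range(cfg.n_const_enhancers):
        chrom, mid = next_slot()
        add_enhancer(chrom, mid, "all")

    # coupled enhancer-gene pairs: enhancer near its gene (same TAD when possible)
    spacing = cfg.tad_spacing
    coupled = []
    pool = genes.sample(n=min(cfg.n_coupled_pairs, len(genes)), random_state=int(
        rng.integers(2**31)))
    free_by_chrom: dict[str, list[int]] = {}
    used = set(order[: cfg.n_ts_enhancers // len(cfg.tissues) * len(cfg.tissues)
                     + cfg.n_const_enhancers])
    for k in order:
        if k not in used:
            free_by_chrom.setdefault(free[k][0], []).append(k)
    taken = set()
    for _, g in pool.iterrows():
        tad_lo = (g.tss // spacing) * spacing
        tad_hi = tad_lo + spacing
        best = None
        for k in free_by_chrom.get(g.chrom, []):
            if k in taken:
                continue
            mid = free[k][1]
            if tad_lo + half <= mid <= tad_hi - half:
                d = abs(mid - g.tss)
                if best is None or d < best[1]:
                    best = (k, d)
        if best is None:
            continue
        taken.add(best[0])
        enh_id = add_enhancer(g.chrom, free[best[0]][1], "all")
        coupled.append((enh_id, g.gene_id))

    # decoys: remaining free slots
    decoys = []
    remaining = [k for ks in free_by_chrom.values() for k in ks if k not in taken]
    for k in remaining[: cfg.n_decoys]:
        chrom, mid = free[k]
        decoys.append((f"decoy{len(decoys):04d}", chrom, mid - half,
                       mid - half + width, "decoy", "none"))
    cres.extend(decoys)

    cres_df = pd.DataFrame(
        cres, columns=["element_id", "chrom", "start", "end", "cre_class", "tissue"])
    sizes.validate(cres_df)

    # tissue-specific genes, balanced; drawn from genes not in coupled pairs
    coupled_gene_ids = {g for _, g in coupled}
    candidates = [g for g in genes["gene_id"] if g not in coupled_gene_ids]
    picks = rng.choice(len(candidates), size=cfg.n_ts_genes + cfg.n_de_genes,
                       replace=False)
    per_tissue_g = cfg.n_ts_genes // len(cfg.tissues)
    ts_rows = []
    i = 0
    for tissue in cfg.tissues:
        for _ in range(per_tissue_g):
            ts_rows.append((candidates[picks[i]], tissue))
            i += 1
    de_rows = []
    for j in range(cfg.n_de_genes):
        direction = "up" if j % 2 == 0 else "down"  # up = higher in second breed
        de_rows.append((candidates[picks[i]], direction))
        i += 1

    # divergent variant loci clustered in one sweep region on the first chromosome
    first_chrom = next(iter(sizes))
    sweep_start = sizes[first_chrom] // 2
    div_pos = np.sort(rng.integers(sweep_start, sweep_start + cfg.sweep_span,
                                   size=cfg.n_divergent))
    div_pos = np.unique(div_pos)
    while len(div_pos) < cfg.n_divergent:  # re-draw collisions
        extra = rng.integers(sweep_start, sweep_start + cfg.sweep_span,
                             size=cfg.n_divergent - len(div_pos))
        div_pos = np.unique(np.concatenate([div_pos, extra]))
    divergent = pd.DataFrame({"chrom": first_chrom, "pos": div_pos[: cfg.n_divergent]})

    return GroundTruth(
        genes=genes.copy(),
        cres=cres_df,
        ts_genes=pd.DataFrame(ts_rows, columns=["gene_id", "tissue"]),
        de_genes=pd.DataFrame(de_rows, columns=["gene_id", "direction"]),
        coupled_pairs=pd.DataFrame(coupled, columns=["enhancer_id", "gene_id"]),
        tad_boundaries=_tad_boundaries_bp(sizes, cfg.tad_spacing),
        divergent_loci=divergent,
    )


# ---------------------------------------------------------------------------
# ChIP counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = m + dispersion * m^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _coupling_latent(truth: GroundTruth, sheet: SampleSheet,
                     cfg: StudyConfig, seed: int) -> pd.DataFrame:
    """Latent per-(tissue, breed) log-activity shared by each coupled
    enhancer-gene pair; drawn from its own child seed so the ChIP and
    expression generators agree without passing state."""
    rng = child_rng(seed, "coupling")
    ids = sorted(set(truth.coupled_pairs["enhancer_id"]))
    columns = [(t, b) for t in sheet.tissues for b in sheet.breeds]
    return pd.DataFrame(
        rng.normal(0.0, cfg.coupling_sigma, size=(len(ids), len(columns))),
        index=ids,
        columns=pd.MultiIndex.from_tuples(columns, names=["tissue", "breed"]),
    )


@dataclass
class ChipSim:
    """Candidate peaks plus the IP/Input count matrix over them."""

    candidates: pd.DataFrame   # element_id, chrom, start, end, p_value, cre_class, tissue
    counts: pd.DataFrame       # regions x samples, indexed by element_id
    coupling: pd.DataFrame     # per coupled enhancer: latent log-activity per (tissue, breed)


def simulate_chip_counts(truth: GroundTruth, sheet: SampleSheet,
                         cfg: StudyConfig, seed: int) -> ChipSim:
    """IP and Input read counts over every planted element and decoy.

    At planted elements the expected IP/Input ratio is ``2 * margin`` in the
    samples where the element is active (its tissue, or everywhere for
    constitutive elements); decoys sit at the Input baseline. Counts are
    negative-binomial per replicate. Coupled enhancers carry a per-column
    latent activity shared with their gene's expression profile.
    """
    if cfg.margin <= 1:
        raise ConfigurationError(
            f"margin {cfg.margin} <= 1: planted elements would not exceed the "
            "2-fold calling threshold")
    rng = child_rng(seed, "chip")
    cand = truth.cres.copy()

    # upstream-caller p-values: planted strongly significant, decoys mixed
    planted = cand["cre_class"] != "decoy"
    pvals = np.empty(len(cand))
    pvals[planted.to_numpy()] = 10.0 ** -rng.uniform(6, 12, planted.sum())
    pvals[(~planted).to_numpy()] = 10.0 ** -rng.uniform(2, 8, (~planted).sum())
    cand["p_value"] = pvals

    coupled_ids = set(truth.coupled_pairs["enhancer_id"])
    latent = _coupling_latent(truth, sheet, cfg, seed)

    base = cfg.base_input_rpm
    counts = {}
    for _, s in sheet.table.iterrows():
        if s.assay == "RNA":
            continue
        scale = s.depth / 1e6
        rpm = np.full(len(cand), base)
        if s.assay in ("H3K27ac", "H3K4me3"):
            if s.assay == "H3K27ac":
                active = (
                    cand["cre_class"].isin(["enhancer", "active_promoter"])
                    & cand["tissue"].isin(["all", s.tissue])
                ).to_numpy()
            else:
                active = (cand["cre_class"] == "promoter").to_numpy()
            rpm = np.where(active, 2 * cfg.margin * base, base)
            if s.assay == "H3K27ac":
                for i, (elem, cls) in enumerate(zip(cand["element_id"], cand["cre_class"])):
                    if cls == "enhancer" and elem in coupled_ids:
                        rpm[i] = 2 * cfg.margin * base * float(
                            np.exp(latent.loc[elem, (s.tissue, s.breed)]))
        counts[s.sample_id] = _nb_draw(rng, rpm * scale, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=cand["element_id"])
    return ChipSim(candidates=cand, counts=counts_df, coupling=latent)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(truth: GroundTruth, sheet: SampleSheet,
                        cfg: StudyConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TPM and read-count matrices over RNA samples.

    Tissue-specific genes get ``specific_fold`` higher expression in their
    tissue; DE genes get a ``de_fold`` breed effect; coupled genes follow the
    latent profile shared with their enhancer.
    """
    rng = child_rng(seed, "expression")
    latent = _coupling_latent(truth, sheet, cfg, seed)
    enh_of_gene = dict(zip(truth.coupled_pairs["gene_id"], truth.coupled_pairs["enhancer_id"]))

    genes = truth.genes["gene_id"].tolist()
    base = np.exp(rng.normal(np.log(20.0), 1.0, size=len(genes)))
    low = rng.random(len(genes)) < 0.1  # genes below the TPM >= 1 detection floor
    base[low] = 0.2
    ts_map = dict(zip(truth.ts_genes["gene_id"], truth.ts_genes["tissue"]))
    de_map = dict(zip(truth.de_genes["gene_id"], truth.de_genes["direction"]))

    rna = sheet.samples(assay="RNA")
    tpm = np.zeros((len(genes), len(rna)))
    for j, (_, s) in enumerate(rna.iterrows()):
        mean = base.copy()
        for i, g in enumerate(genes):
            if ts_map.get(g) == s.tissue:
                mean[i] *= cfg.specific_fold
            d = de_map.get(g)
            if d is not None and s.breed == sheet.breeds[-1]:
                mean[i] *= cfg.de_fold if d == "up" else 1.0 / cfg.de_fold
            if g in enh_of_gene:
                mean[i] = 20.0 * float(np.exp(latent.loc[enh_of_gene[g], (s.tissue, s.breed)]))
        tpm[:, j] = mean * np.exp(rng.normal(0, cfg.expr_noise_sigma, len(genes)))
    tpm_df = pd.DataFrame(tpm, index=genes, columns=rna["sample_id"].tolist())

    depth_scale = rna["depth"].to_numpy() / 1e6
    count_mean = tpm * depth_scale[None, :] / 10.0  # ~ depth-scaled abundance
    counts = _nb_draw(rng, count_mean, cfg.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=rna["sample_id"].tolist())
    return tpm_df, counts_df


# ---------------------------------------------------------------------------
# Hi-C


def simulate_hic(n_bins: int, bin_size: int, boundaries: list[int],
                 alpha: float = 1.0, insulation_factor: float = 0.2,
                 noise_shape: float = 50.0, seed: int = 0,
                 compartments: np.ndarray | None = None,
                 compartment_strength: float = 0.0) -> np.ndarray:
    """Symmetric contact matrix with power-law decay and planted structure.

    Expected contact at bin distance d is ``(d+1)**-alpha`` within a TAD,
    multiplied by ``insulation_factor`` for every planted boundary between
    the two bins, and optionally modulated by a checkerboard compartment
    pattern. Multiplicative gamma noise (unit mean, shape ``noise_shape``)
    emulates an ICE-normalized matrix.
    """
    boundaries = sorted(int(b) for b in boundaries)
    if any(b <= 0 or b >= n_bins for b in boundaries):
        raise CoordinateError("boundary bin outside chromosome")
    if any(b2 - b1 < 2 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise CoordinateError("boundaries closer than 2 bins")
    rng = child_rng(seed, "hic")
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = 100.0 * (dist + 1.0) ** (-alpha)
    # count of boundaries strictly between i and j
    bcount = np.zeros(n_bins)
    for b in boundaries:
        bcount[b:] += 1
    crossings = np.abs(bcount[:, None] - bcount[None, :])
    expected *= float(insulation_factor) ** crossings
    if compartments is not None and compartment_strength > 0:
        s = np.asarray(compartments, dtype=float)
        if len(s) != n_bins:
            raise InputError("compartment label vector length mismatch")
        expected *= 1.0 + compartment_strength * np.outer(s, s)
    noise = rng.gamma(noise_shape, 1.0 / noise_shape, size=(n_bins, n_bins))
    mat = expected * noise
    upper = np.triu(mat)
    return upper + np.triu(mat, 1).T


# ---------------------------------------------------------------------------
# cross-species block map


def simulate_species_map(source: ChromSizes, target: ChromSizes,
                         rearrangements: list[tuple[str, int, int, str]] | None = None,
                         block_length: int = 50_000,
                         unmappable_fraction: float = 0.1,
                         seed: int = 0) -> pd.DataFrame:
    """Ordered alignment blocks source -> target.

    Each source chromosome maps to the target chromosome of the same rank,
    except for planted *rearrangements*: source intervals
    ``(chrom, start, end, target_chrom)`` whose blocks are sent to a distinct
    target chromosome. A ``unmappable_fraction`` of source bp is covered by
    no block. Blocks never overlap on source or on target.
    """
    rearrangements = rearrangements or []
    riv = sorted(rearrangements, key=lambda r: (r[0], r[1]))
    for a, b in zip(riv, riv[1:]):
        if a[0] == b[0] and b[1] < a[2]:
            raise InputError("overlapping rearrangement intervals")
    rng = child_rng(seed, "speciesmap")
    src_chroms = list(source)
    tgt_chroms = list(target)
    default_tgt = {c: tgt_chroms[i % len(tgt_chroms)] for i, c in enumerate(src_chroms)}
    cursor = {c: 0 for c in tgt_chroms}
    rows = []
    for chrom in src_chroms:
        length = source[chrom]
        cuts = {0, length}
        for r in riv:
            if r[0] == chrom:
                cuts.update((max(0, r[1]), min(length, r[2])))
        cuts = sorted(cuts)
        for seg_start, seg_end in zip(cuts, cuts[1:]):
            tgt = default_tgt[chrom]
            for r in riv:
                if r[0] == chrom and r[1] <= seg_start and seg_end <= r[2]:
                    tgt = r[3]
            pos = seg_start
            while pos < seg_end:
                blen = int(rng.integers(block_length // 2, block_length * 3 // 2))
                end = min(pos + blen, seg_end)
                if rng.random() >= unmappable_fraction:
                    t0 = cursor[tgt]
                    if t0 + (end - pos) > target[tgt]:
                        raise SizingError(f"target chromosome {tgt} overflows")
                    rows.append((chrom, pos, end, tgt, t0, "+"))
                    cursor[tgt] = t0 + (end - pos)
                pos = end
    return pd.DataFrame(
        rows, columns=["src_chrom", "src_start", "src_end", "tgt_chrom",
                       "tgt_start", "strand"])


def simulate_rearrangement_scenario(cfg: StudyConfig, seed: int) -> dict:
    """A two-species scenario with planted inter-chromosomal TAD rearrangements.

    The target ("human-like") genome is built from source ("pig-like")
    segments; at each planted junction the source chromosome switches inside
    a target TAD, so exactly that TAD's two flanking boundaries trace back to
    different source chromosomes.
    """
    rng = child_rng(seed, "rearrange")
    spacing = cfg.tad_spacing
    n_tads = 12
    tgt_len = n_tads * spacing
    tgt_sizes = ChromSizes({"hchr1": tgt_len})
    # junction TADs: distinct, away from the chromosome ends
    junction_tads = sorted(rng.choice(np.arange(1, n_tads - 1), size=cfg.n_rearranged,
                                      replace=False))
    junctions = [int(t * spacing + spacing // 2) for t in junction_tads]
    cuts = [0] + junctions + [tgt_len]
    n_seg = len(cuts) - 1
    src_sizes = ChromSizes({f"pchr{i+1}": (cuts[i + 1] - cuts[i]) + 200_000
                            for i in range(n_seg)})
    # blocks: contiguous cover of each segment with small unmappable holes
    rows = []
    for i in range(n_seg):
        seg_start, seg_end = cuts[i], cuts[i + 1]
        src_chrom = f"pchr{i+1}"
        pos = seg_start
        while pos < seg_end:
            blen = int(rng.integers(cfg.block_length // 2, cfg.block_length * 3 // 2))
            end = min(pos + blen, seg_end)
            if rng.random() >= cfg.unmappable_fraction:
                rows.append((src_chrom, pos - seg_start, end - seg_start,
                             "hchr1", pos, "+"))
            pos = end
    block_map = pd.DataFrame(
        rows, columns=["src_chrom", "src_start", "src_end", "tgt_chrom",
                       "tgt_start", "strand"])

    half_bw = 20_000  # boundary interval half-width
    tgt_boundaries = pd.DataFrame({
        "chrom": "hchr1",
        "start": [k * spacing - half_bw for k in range(1, n_tads)],
        "end": [k * spacing + half_bw for k in range(1, n_tads)],
    })
    # source boundaries: exact preimages of target boundaries
    src_rows = []
    for _, b in tgt_boundaries.iterrows():
        mid = (b.start + b.end) // 2
        for i in range(n_seg):
            if cuts[i] <= mid < cuts[i + 1]:
                off = cuts[i]
                src_rows.append((f"pchr{i+1}", b.start - off, b.end - off))
                break
    src_boundaries = pd.DataFrame(src_rows, columns=["chrom", "start", "end"])
    tgt_tads = pd.DataFrame({
        "chrom": "hchr1",
        "start": [k * spacing for k in range(n_tads)],
        "end": [(k + 1) * spacing for k in range(n_tads)],
        "tad_id": [f"htad{k}" for k in range(n_tads)],
    })
    return {
        "source_sizes": src_sizes,
        "target_sizes": tgt_sizes,
        "block_map": block_map,
        "src_boundaries": src_boundaries,
        "tgt_boundaries": tgt_boundaries,
        "tgt_tads": tgt_tads,
        "rearranged_ids": [f"htad{t}" for t in junction_tads],
    }


# ---------------------------------------------------------------------------
# variants


def simulate_variants(truth: GroundTruth, sizes: ChromSizes, cfg: StudyConfig,
                      seed: int) -> pd.DataFrame:
    """Per-site allele counts for two populations.

    Background sites draw one shared frequency; planted divergent loci have a
    frequency gap of ``delta_af`` between the populations.
    """
    n1, n2 = cfg.n_haplotypes
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("need >= 2 haplotypes per population")
    if cfg.n_divergent > 0 and cfg.delta_af <= 0:
        raise ConfigurationError("divergent loci requested with delta 0")
    if cfg.delta_af > 1:
        raise ConfigurationError("delta must be in (0, 1]")
    rng = child_rng(seed, "variants")
    rows = []
    div = set(zip(truth.divergent_loci["chrom"], truth.divergent_loci["pos"]))
    n_bg = cfg.n_variant_sites - len(div)
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    counts_per = np.floor(n_bg * lengths / lengths.sum()).astype(int)
    counts_per[0] += n_bg - counts_per.sum()
    positions = []
    for c, k in zip(chroms, counts_per):
        pos = np.sort(rng.choice(sizes[c], size=k, replace=False))
        positions.extend((c, int(p)) for p in pos)
    positions.extend(sorted(div))
    positions.sort()
    for chrom, pos in positions:
        if (chrom, pos) in div:
            p1 = min(1.0, 0.5 + cfg.delta_af / 2)
            p2 = max(0.0, p1 - cfg.delta_af)
        else:
            p1 = p2 = rng.uniform(0.05, 0.95)
        a1 = int(rng.binomial(n1, p1))
        a2 = int(rng.binomial(n2, p2))
        rows.append((chrom, pos, n1 - a1, a1, n2 - a2, a2))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "pop1_ref", "pop1_alt", "pop2_ref", "pop2_alt"])


# ---------------------------------------------------------------------------
# transcripts (attribute tables for the filter cascades)


def simulate_transcripts(seed: int, n: int = 400) -> pd.DataFrame:
    """Assembled-transcript attribute table with planted lncRNAs.

    Columns carry everything the lncRNA / new-transcript cascades gate on;
    ``planted`` marks records constructed to pass the lncRNA cascade.
    """
    rng = child_rng(seed, "transcripts")
    rows = []
    for i in range(n):
        planted = rng.random() < 0.25
        if planted:
            class_code = rng.choice(["x", "i", "."])
            length = int(rng.integers(200, 5000))
            exons = int(rng.integers(2, 12))
            n_samples = int(rng.integers(2, 6))
            fpkm = rng.uniform(1.0, 30.0, size=4).round(3)
            reads = rng.integers(5, 500, size=4)
            coding, known, u_overlap, strand_overlap = False, False, False, False
        else:
            class_code = rng.choice(["x", "i", "u", ".", "="])
            length = int(rng.integers(50, 5000))
            exons = int(rng.integers(1, 12))
            n_samples = int(rng.integers(1, 6))
            fpkm = rng.uniform(0.0, 30.0, size=4).round(3)
            reads = rng.integers(0, 500, size=4)
            coding = bool(rng.random() < 0.3)
            known = bool(rng.random() < 0.3)
            u_overlap = bool(rng.random() < 0.2)
            strand_overlap = bool(rng.random() < 0.2)
        rows.append({
            "transcript_id": f"tx{i:04d}", "class_code": class_code,
            "length": length, "exon_count": exons, "n_samples_observed": n_samples,
            "fpkm_r1": fpkm[0], "fpkm_r2": fpkm[1], "fpkm_r3": fpkm[2], "fpkm_r4": fpkm[3],
            "reads_r1": int(reads[0]), "reads_r2": int(reads[1]),
            "reads_r3": int(reads[2]), "reads_r4": int(reads[3]),
            "coding_flag": coding, "known_overlap": known,
            "u_overlap": u_overlap, "same_strand_exon_overlap": strand_overlap,
            "strand": str(rng.choice(["+", "-"])), "planted": planted,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the whole study


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    sizes: ChromSizes
    sheet: SampleSheet
    truth: GroundTruth
    chip: ChipSim
    tpm: pd.DataFrame
    rna_counts: pd.DataFrame
    hic: dict            # chrom -> contact matrix
    hic_boundary_bins: dict
    variants: pd.DataFrame
    species: dict
    transcripts: pd.DataFrame


def simulate_study(cfg: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate every input of the pipeline for one seed."""
    cfg = cfg or StudyConfig()
    sizes, genes = generate_genome(cfg, seed)
    sheet = make_sample_sheet(cfg)
    truth = plant_ground_truth(cfg, sizes, genes, seed)
    chip = simulate_chip_counts(truth, sheet, cfg, seed)
    tpm, rna_counts = simulate_expression(truth, sheet, cfg, seed)
    hic = {}
    hic_bins = {}
    for i, (chrom, length) in enumerate(sizes.items()):
        n_bins = length // cfg.hic_bin_size
        bounds = [int(p) // cfg.hic_bin_size
                  for p in truth.tad_boundaries.loc[
                      truth.tad_boundaries["chrom"] == chrom, "pos"]]
        hic[chrom] = simulate_hic(
            n_bins, cfg.hic_bin_size, bounds, alpha=cfg.hic_alpha,
            insulation_factor=cfg.hic_insulation_factor,
            noise_shape=cfg.hic_noise_shape, seed=seed * 31 + i)
        hic_bins[chrom] = bounds
    variants = simulate_variants(truth, sizes, cfg, seed)
    species = simulate_rearrangement_scenario(cfg, seed)
    transcripts = simulate_transcripts(seed)
    return SyntheticStudy(
        config=cfg, seed=seed, sizes=sizes, sheet=sheet, truth=truth, chip=chip,
        tpm=tpm, rna_counts=rna_counts, hic=hic, hic_boundary_bins=hic_bins,
        variants=variants, species=species, transcripts=transcripts)
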