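"""Generator contracts: determinism, planted effect sizes, error paths."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pigcre.errors import ConfigurationError, CoordinateError, SizingError
from pigcre.intervals import ChromSizes
from pigcre.synthetic import (
    GroundTruth, StudyConfig, generate_genome, make_sample_sheet,
    plant_ground_truth, simulate_chip_counts, simulate_hic, simulate_species_map,
    simulate_study, simulate_variants,
)
from pigcre.popgen import site_fst


def small_cfg(**overrides):
    base = dict(
        chrom_sizes={"chr1": 4_000_000, "chr2": 4_000_000},
        n_genes=60, n_ts_enhancers=24, n_const_enhancers=12,
        n_coupled_pairs=12, n_decoys=24, n_ts_genes=12, n_de_genes=6,
        n_variant_sites=400, n_divergent=10,
    )
    base.update(overrides)
    return StudyConfig(**base)


def test_genome_deterministic_and_seed_sensitive():
    cfg = small_cfg()
    s1, g1 = generate_genome(cfg, seed=1)
    s2, g2 = generate_genome(cfg, seed=1)
    assert g1.equals(g2) and s1 == s2
    _, g3 = generate_genome(cfg, seed=2)
    assert not g1.equals(g3)


def test_genome_tss_non_overlapping():
    _, genes = generate_genome(small_cfg(), seed=3)
    for _, sub in genes.groupby("chrom"):
        pos = np.sort(sub["tss"].to_numpy())
        assert (np.diff(pos) > 0).all()


def test_genome_sizing_error():
    with pytest.raises(SizingError):
        generate_genome(small_cfg(chrom_sizes={"chr1": 1000}, n_genes=100), seed=1)


def test_chip_margin_configuration_error(study):
    cfg = StudyConfig(margin=1.0)
    with pytest.raises(ConfigurationError):
        simulate_chip_counts(study.truth, study.sheet, cfg, seed=1)


def test_planted_ip_input_ratio_exceeds_threshold_margin(study):
    """Mean IP/Input RPM ratio over planted constitutive sites is at least
    the configured margin (expected 2 x margin at the planted elements)."""
    cfg = study.config
    cand = study.chip.candidates
    counts = study.chip.counts
    sheet = study.sheet
    planted = cand["cre_class"].isin(["enhancer", "active_promoter"]) & (
        cand["tissue"] == "all")
    ratios = []
    for tissue in sheet.tissues:
        ip = sheet.samples(assay="H3K27ac", tissue=tissue)
        for _, s in ip.iterrows():
            ip_rpm = counts[s.sample_id] / (s.depth / 1e6)
            inp = counts[s.input_id] / (sheet.depth(s.input_id) / 1e6)
            r = (ip_rpm[planted.to_numpy()] / inp[planted.to_numpy()].clip(lower=0.01))
            ratios.append(r.to_numpy())
    ratios = np.concatenate(ratios)
    assert len(ratios) >= 1000
    assert ratios.mean() >= cfg.margin  # expected value is 2 * margin


def test_decoy_call_rate_matches_nb_tail(study):
    """Monte-Carlo rate at which decoys pass the coverage rules vs the
    analytic tail of the negative-binomial noise model."""
    cfg = study.config
    cand = study.chip.candidates
    counts = study.chip.counts
    sheet = study.sheet
    decoy = (cand["cre_class"] == "decoy").to_numpy()
    scale = cfg.chip_depth / 1e6
    passes = []
    for tissue in sheet.tissues:
        for breed in sheet.breeds:
            ip_samples = sheet.samples(assay="H3K27ac", tissue=tissue, breed=breed)
            ip_cols = ip_samples["sample_id"].tolist()
            in_cols = sorted(set(ip_samples["input_id"]))
            ip = counts[ip_cols].sum(axis=1)[decoy] / (scale * len(ip_cols))
            inp = counts[in_cols].sum(axis=1)[decoy] / (scale * len(in_cols))
            passes.append(((ip > 2 * inp) & (ip - inp > 1)).to_numpy())
    rate = np.concatenate(passes).mean()
    # analytic: merged counts are sums of NB draws with mean base*scale each;
    # enumerate the Input distribution and take the IP tail above the rule
    mean = cfg.base_input_rpm * scale
    size = 1.0 / cfg.dispersion
    n_rep = 2
    ip_dist = stats.nbinom(n_rep * size, size / (size + mean))
    in_dist = stats.nbinom(n_rep * size, size / (size + mean))
    ks = np.arange(0, int(in_dist.ppf(1 - 1e-9)))
    pk = in_dist.pmf(ks)
    thresh = np.maximum(2 * ks, ks + n_rep * scale)  # both rules in count units
    analytic = float(np.sum(pk * ip_dist.sf(thresh)))
    n = np.concatenate(passes).size
    se = np.sqrt(max(analytic, rate) * (1 - min(analytic, rate)) / n) + 1e-9
    assert abs(rate - analytic) <= 5 * se + 1e-3


def test_ground_truth_round_trip(tmp_path, study):
    study.truth.to_dir(tmp_path)
    again = GroundTruth.from_dir(tmp_path)
    for name in GroundTruth._FRAMES:
        a = getattr(study.truth, name).reset_index(drop=True)
        b = getattr(again, name).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)


def test_hic_matrix_symmetric_and_boundary_contrast():
    m = simulate_hic(100, 40000, [50], alpha=1.0, insulation_factor=0.2, seed=4)
    assert np.array_equal(m, m.T)
    assert (m >= 0).all()
    # within-block vs cross-block contact at matched distance
    d = 10
    within = [m[i, i + d] for i in range(0, 40)]
    cross = [m[i, i + d] for i in range(45, 50)]
    assert np.mean(within) > np.mean(cross)


def test_hic_boundary_errors():
    with pytest.raises(CoordinateError):
        simulate_hic(100, 40000, [100], seed=0)
    with pytest.raises(CoordinateError):
        simulate_hic(100, 40000, [50, 51], seed=0)


def test_species_map_full_coverage_when_unmappable_zero():
    src = ChromSizes({"s1": 500_000})
    tgt = ChromSizes({"t1": 700_000})
    bm = simulate_species_map(src, tgt, unmappable_fraction=0.0, seed=1)
    covered = int((bm["src_end"] - bm["src_start"]).sum())
    assert covered == 500_000
    # non-overlapping on source
    b = bm.sort_values("src_start")
    assert (b["src_start"].to_numpy()[1:] >= b["src_end"].to_numpy()[:-1]).all()


def test_species_map_unmappable_fraction_recovered():
    src = ChromSizes({"s1": 2_000_000})
    tgt = ChromSizes({"t1": 2_500_000})
    bm = simulate_species_map(src, tgt, unmappable_fraction=0.4,
                              block_length=20_000, seed=2)
    covered = (bm["src_end"] - bm["src_start"]).sum() / 2_000_000
    assert abs((1 - covered) - 0.4) < 0.1


def test_species_map_rearrangement_targets():
    src = ChromSizes({"s1": 1_000_000})
    tgt = ChromSizes({"t1": 1_200_000, "tB": 1_200_000})
    bm = simulate_species_map(
        src, tgt, rearrangements=[("s1", 200_000, 400_000, "tB")],
        unmappable_fraction=0.0, seed=3)
    inside = bm[(bm["src_start"] >= 200_000) & (bm["src_end"] <= 400_000)]
    assert (inside["tgt_chrom"] == "tB").all()
    outside = bm[(bm["src_end"] <= 200_000) | (bm["src_start"] >= 400_000)]
    assert (outside["tgt_chrom"] == "t1").all()


def test_species_map_overlapping_rearrangements_rejected():
    src = ChromSizes({"s1": 1_000_000})
    tgt = ChromSizes({"t1": 1_200_000, "tB": 1_200_000})
    with pytest.raises(ValueError):
        simulate_species_map(src, tgt, rearrangements=[
            ("s1", 100_000, 300_000, "tB"), ("s1", 200_000, 400_000, "tB")],
            seed=1)


def test_variants_fixed_difference_gives_fst_one():
    cfg = small_cfg(n_divergent=5, delta_af=1.0, n_haplotypes=(100, 100))
    sizes, genes = generate_genome(cfg, seed=5)
    truth = plant_ground_truth(cfg, sizes, genes, seed=5)
    table = simulate_variants(truth, sizes, cfg, seed=5)
    fst = site_fst(table)
    merged = fst.merge(truth.divergent_loci, on=["chrom", "pos"])
    assert len(merged) == 5
    assert (merged["fst"] > 0.95).all()


def test_variants_background_fst_near_zero():
    cfg = small_cfg(n_divergent=0, n_variant_sites=1000)
    sizes, genes = generate_genome(cfg, seed=6)
    truth = plant_ground_truth(cfg, sizes, genes, seed=6)
    truth.divergent_loci = truth.divergent_loci.iloc[0:0]
    table = simulate_variants(truth, sizes, cfg, seed=6)
    fst = site_fst(table)["fst"].dropna()
    se = fst.std() / np.sqrt(len(fst))
    assert abs(fst.mean()) <= 3 * se + 0.01


def test_variants_error_paths():
    cfg = small_cfg(n_haplotypes=(1, 40))
    sizes, genes = generate_genome(cfg, seed=7)
    truth = plant_ground_truth(cfg, sizes, genes, seed=7)
    with pytest.raises(ConfigurationError):
        simulate_variants(truth, sizes, cfg, seed=7)
    cfg2 = small_cfg(delta_af=0.0)
    with pytest.raises(ConfigurationError):
        simulate_variants(truth, sizes, cfg2, seed=7)


def test_study_serialization_deterministic(tmp_path):
    from pigcre.io import write_study
    cfg = small_cfg()
    for d in ("a", "b"):
        write_study(simulate_study(cfg, seed=9), tmp_path / d)
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
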