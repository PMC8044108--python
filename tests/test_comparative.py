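"""Block-map liftover, conservation labels, boundary pairing, rearranged TADs."""

import numpy as np
import pandas as pd
import pytest

from pigcre.comparative import (
    BlockMap, classify_conservation, conserved_boundaries,
    detect_rearranged_tads, map_interval,
)
from pigcre.errors import InputError
from pigcre.intervals import ChromSizes
from pigcre.synthetic import StudyConfig, simulate_rearrangement_scenario, \
    simulate_species_map


def bm_from(rows):
    return BlockMap(pd.DataFrame(
        rows, columns=["src_chrom", "src_start", "src_end", "tgt_chrom",
                       "tgt_start", "strand"]))


def per_base_map(bm, chrom, start, end, min_match=0.5):
    """Brute-force oracle: map every base, then aggregate."""
    images = []
    for p in range(start, end):
        for b in bm.table.itertuples():
            if b.src_chrom == chrom and b.src_start <= p < b.src_end:
                if b.strand == "+":
                    images.append((b.tgt_chrom, b.strand,
                                   b.tgt_start + (p - b.src_start)))
                else:
                    images.append((b.tgt_chrom, b.strand,
                                   b.tgt_start + (b.src_end - 1 - p)))
                break
    if len(images) < min_match * (end - start) or not images:
        return None
    keys = {(c, s) for c, s, _ in images}
    if len(keys) > 1:
        return None
    pos = [p for _, _, p in images]
    (c, s), = keys
    return (c, min(pos), max(pos) + 1, s, len(images))


def test_map_inside_single_block_affine():
    bm = bm_from([("chr1", 0, 10_000, "hchr2", 50_000, "+")])
    m = map_interval(bm, "chr1", 2000, 3000)
    assert (m.chrom, m.start, m.end) == ("hchr2", 52_000, 53_000)
    assert m.matched_bp == 1000


def test_min_match_failure():
    bm = bm_from([("chr1", 0, 400, "hchr2", 0, "+")])
    assert map_interval(bm, "chr1", 0, 1000, min_match=0.5) is None
    assert map_interval(bm, "chr1", 0, 1000, min_match=0.4) is not None


def test_split_targets_failure_and_missing_chrom():
    bm = bm_from([("chr1", 0, 500, "hchr2", 0, "+"),
                  ("chr1", 500, 1000, "hchr3", 0, "+")])
    assert map_interval(bm, "chr1", 0, 1000) is None
    assert map_interval(bm, "chrX", 0, 1000) is None


def test_minus_strand_reflection():
    bm = bm_from([("chr1", 0, 1000, "hchr2", 5000, "-")])
    m = map_interval(bm, "chr1", 100, 200)
    # base 100 -> 5000 + (1000-1-100) = 5899; base 199 -> 5800
    assert (m.start, m.end, m.strand) == (5800, 5900, "-")


def test_mixed_strand_coverage_fails():
    bm = bm_from([("chr1", 0, 500, "hchr2", 0, "+"),
                  ("chr1", 500, 1000, "hchr2", 5000, "-")])
    assert map_interval(bm, "chr1", 0, 1000) is None


def test_map_matches_per_base_oracle():
    rng = np.random.default_rng(18)
    for _ in range(15):
        rows = []
        pos = 0
        for _ in range(int(rng.integers(2, 8))):
            gap = int(rng.integers(0, 100))
            length = int(rng.integers(50, 400))
            tgt = rng.choice(["h1", "h2"])
            strand = rng.choice(["+", "-"])
            rows.append(("chr1", pos + gap, pos + gap + length, tgt,
                         int(rng.integers(0, 50_000)), strand))
            pos += gap + length
        bm = bm_from(rows)
        for _ in range(8):
            s = int(rng.integers(0, pos))
            e = s + int(rng.integers(1, 600))
            got = map_interval(bm, "chr1", s, e)
            exp = per_base_map(bm, "chr1", s, e)
            if exp is None:
                assert got is None
            else:
                assert got is not None
                assert (got.chrom, got.start, got.end, got.strand,
                        got.matched_bp) == exp


def test_blockmap_rejects_source_overlap():
    with pytest.raises(InputError):
        bm_from([("chr1", 0, 1000, "h1", 0, "+"),
                 ("chr1", 500, 1500, "h1", 5000, "+")])


def elements(rows):
    return pd.DataFrame(rows, columns=["element_id", "chrom", "start", "end"])


def test_conservation_labels():
    bm = bm_from([("chr1", 0, 100_000, "h1", 0, "+")])
    elems = elements([("e1", "chr1", 10_000, 12_000),
                      ("e2", "chr1", 50_000, 52_000),
                      ("e3", "chr2", 0, 2000)])
    targets = pd.DataFrame({"chrom": ["h1"], "start": [10_500], "end": [11_500]})
    out = classify_conservation(elems, bm, targets)
    assert out.set_index("element_id")["label"].to_dict() == {
        "e1": "usage_conserved", "e2": "sequence_conserved", "e3": "non_conserved"}


def test_conservation_label_hierarchy_counts():
    cfg = StudyConfig()
    src = ChromSizes({"s1": 1_000_000})
    tgt = ChromSizes({"t1": 1_300_000})
    bm_df = simulate_species_map(src, tgt, unmappable_fraction=0.3,
                                 block_length=5_000, seed=19)
    bm = BlockMap(bm_df)
    rng = np.random.default_rng(19)
    starts = rng.integers(0, 998_000, 200)
    elems = elements([(f"e{i}", "s1", int(s), int(s) + 2000)
                      for i, s in enumerate(starts)])
    # copy some images as target elements
    imgs = []
    for e in elems.itertuples():
        m = map_interval(bm, "s1", e.start + 500, e.start + 1500)
        if m and rng.random() < 0.5:
            imgs.append(("t1", m.start, m.end))
    targets = pd.DataFrame(imgs, columns=["chrom", "start", "end"])
    out = classify_conservation(elems, bm, targets)
    counts = out["label"].value_counts()
    assert counts.sum() == len(elems)
    assert set(counts.index) <= {"non_conserved", "sequence_conserved",
                                 "usage_conserved"}


def test_full_coverage_copied_targets_all_usage_conserved():
    src = ChromSizes({"s1": 500_000})
    tgt = ChromSizes({"t1": 700_000})
    bm = BlockMap(simulate_species_map(src, tgt, unmappable_fraction=0.0,
                                       block_length=20_000, seed=20))
    rng = np.random.default_rng(20)
    starts = rng.integers(2000, 496_000, 50)
    elems = elements([(f"e{i}", "s1", int(s), int(s) + 2000)
                      for i, s in enumerate(starts)])
    imgs = []
    for e in elems.itertuples():
        m = map_interval(bm, "s1", e.start + 500, e.start + 1500)
        imgs.append((m.chrom, m.start, m.end))
    targets = pd.DataFrame(imgs, columns=["chrom", "start", "end"])
    out = classify_conservation(elems, bm, targets)
    assert (out["label"] == "usage_conserved").all()


def boundary(chrom, mid, hw=20_000):
    return {"chrom": chrom, "start": mid - hw, "end": mid + hw}


def test_boundary_stage1_within_extension():
    bm = bm_from([("chr1", 0, 2_000_000, "h1", 0, "+")])
    src = pd.DataFrame([boundary("chr1", 500_000)])
    tgt = pd.DataFrame([boundary("h1", 550_000)])  # 50 kb away
    out = conserved_boundaries(src, bm, tgt)
    assert out["stage"].iloc[0] == 1 and out["tgt_index"].iloc[0] == 0


def test_boundary_stage2_rescue_and_exclusivity():
    bm = bm_from([("chr1", 0, 2_000_000, "h1", 0, "+")])
    tgt = pd.DataFrame([boundary("h1", 500_000)])
    src_far = pd.DataFrame([boundary("chr1", 800_000)])  # 300 kb away
    out = conserved_boundaries(src_far, bm, tgt)
    assert out["stage"].iloc[0] == 2
    # partner already taken by a stage-1 pairing -> no rescue
    src_two = pd.DataFrame([boundary("chr1", 520_000), boundary("chr1", 800_000)])
    out2 = conserved_boundaries(src_two, bm, tgt)
    assert out2["stage"].tolist() == [1, 0]
    # beyond 500 kb -> not conserved at all
    src_vfar = pd.DataFrame([boundary("chr1", 1_100_000)])
    assert conserved_boundaries(src_vfar, bm, tgt)["stage"].iloc[0] == 0


def test_rearranged_tads_planted_scenario():
    cfg = StudyConfig(n_rearranged=3)
    sp = simulate_rearrangement_scenario(cfg, seed=21)
    bm = BlockMap(sp["block_map"])
    pairings = conserved_boundaries(sp["src_boundaries"], bm, sp["tgt_boundaries"])
    res = detect_rearranged_tads(sp["tgt_tads"], sp["tgt_boundaries"], pairings)
    assert sorted(res.loc[res["rearranged"], "tad_id"]) == sorted(sp["rearranged_ids"])


def test_rearranged_tads_different_source_chromosomes_rule():
    # left flank from chr4, right flank from chr9 -> rearranged
    pairings = pd.DataFrame({
        "src_chrom": ["chr4", "chr9"], "tgt_index": [0, 1], "stage": [1, 1]})
    tgt_b = pd.DataFrame([boundary("h1", 1_000_000), boundary("h1", 2_000_000)])
    tads = pd.DataFrame({"chrom": ["h1"], "start": [1_000_000],
                         "end": [2_000_000], "tad_id": ["T"]})
    res = detect_rearranged_tads(tads, tgt_b, pairings)
    assert res["rearranged"].iloc[0]
    # both flanks same chromosome -> not rearranged
    pair2 = pairings.assign(src_chrom=["chr1", "chr1"])
    assert not detect_rearranged_tads(tads, tgt_b, pair2)["rearranged"].iloc[0]


def test_no_false_positives_without_interchromosomal_blocks():
    cfg = StudyConfig(n_rearranged=0)
    sp = simulate_rearrangement_scenario(cfg, seed=22)
    bm = BlockMap(sp["block_map"])
    pairings = conserved_boundaries(sp["src_boundaries"], bm, sp["tgt_boundaries"])
    res = detect_rearranged_tads(sp["tgt_tads"], sp["tgt_boundaries"], pairings)
    assert not res["rearranged"].any()


def test_chain_reader_matches_tsv_blocks(tmp_path):
    chain = tmp_path / "toy.chain"
    chain.write_text(
        "chain 1000 chr1 100000 + 1000 3100 h1 200000 + 5000 7100 1\n"
        "1000\t100\t100\n"
        "1000\n"
        "\n"
        "chain 900 chr2 50000 + 0 500 h2 40000 - 39000 39500 2\n"
        "500\n"
        "\n")
    bm = BlockMap.from_chain(chain)
    t = bm.table
    plus = t[t["src_chrom"] == "chr1"].reset_index(drop=True)
    assert plus.iloc[0].tolist() == ["chr1", 1000, 2000, "h1", 5000, "+"]
    assert plus.iloc[1].tolist() == ["chr1", 2100, 3100, "h1", 6100, "+"]
    minus = t[t["src_chrom"] == "chr2"].iloc[0]
    # q_size 40000, reversed-strand start 39000 size 500 -> forward 500..1000
    assert minus.tolist() == ["chr2", 0, 500, "h2", 500, "-"]
    m = map_interval(bm, "chr1", 1200, 1300)
    assert (m.chrom, m.start, m.end) == ("h1", 5200, 5300)
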