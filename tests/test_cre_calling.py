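"""Enriched-region rule, CRE classification, ROSE elbow, FRiP."""

import numpy as np
import pandas as pd
import pytest

from pigcre.cre import (
    call_broad_domains, call_enriched_regions, call_super_enhancers,
    classify_h3k27ac, classify_promoters, compute_frip, merge_replicates,
    rose_elbow_cutoff, stitch_enhancers, tss_flanks,
)
from pigcre.errors import InputError
from pigcre.intervals import overlaps_any


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "p_value",
                                       "ip_rpm", "input_rpm"])


def test_compute_rpm_values():
    from pigcre.cre import compute_rpm
    assert compute_rpm([30], 1e6)[0] == 30.0
    assert compute_rpm([0], 1e6)[0] == 0.0
    assert compute_rpm([50], 2.5e7)[0] == pytest.approx(2.0)
    with pytest.raises(InputError):
        compute_rpm([-1], 1e6)
    with pytest.raises(InputError):
        compute_rpm([1], 0)


def test_enrichment_rules_are_strict():
    # IP exactly twice Input fails the fold rule
    p = peaks_frame([("chr1", 1000, 3000, 1e-6, 4.0, 2.0)])
    assert call_enriched_regions(p).empty
    # 3 > 2*1 and 3-1=2 > 1 passes
    p = peaks_frame([("chr1", 1000, 3000, 1e-6, 3.0, 1.0)])
    assert len(call_enriched_regions(p)) == 1
    # difference exactly 1 fails
    p = peaks_frame([("chr1", 1000, 3000, 1e-6, 3.0, 2.0)])
    assert call_enriched_regions(p).empty
    # p-value above the cutoff fails
    p = peaks_frame([("chr1", 1000, 3000, 2e-5, 3.0, 1.0)])
    assert call_enriched_regions(p).empty


def test_merge_and_center_extension():
    p = peaks_frame([
        ("chr1", 1000, 3000, 1e-6, 3.0, 1.0),
        ("chr1", 2500, 4500, 1e-6, 3.0, 1.0),
    ])
    out = call_enriched_regions(p)
    assert out.iloc[0].tolist() == ["chr1", 1750, 3750]


def test_all_enriched_regions_are_2kb(catalogue):
    enh = catalogue.per_condition
    widths = enh["end"] - enh["start"]
    assert (widths == 2000).all()


def brute_force_enriched(peaks, p_cutoff=1e-5):
    survivors = []
    for r in peaks.itertuples():
        if r.p_value <= p_cutoff and r.ip_rpm > 2 * r.input_rpm \
                and r.ip_rpm - r.input_rpm > 1:
            survivors.append([r.chrom, r.start, r.end])
    # naive repeated merge
    changed = True
    while changed:
        changed = False
        for i in range(len(survivors)):
            for j in range(i + 1, len(survivors)):
                a, b = survivors[i], survivors[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    survivors[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    survivors.pop(j)
                    changed = True
                    break
            if changed:
                break
    out = []
    for chrom, s, e in survivors:
        mid = (s + e) // 2
        out.append((chrom, mid - 1000, mid + 1000))
    return sorted(out)


def test_enriched_regions_match_brute_force():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = int(rng.integers(1, 500))
        starts = rng.integers(0, 200_000, n)
        peaks = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], n),
            "start": starts, "end": starts + 2000,
            "p_value": 10.0 ** -rng.uniform(3, 8, n),
            "ip_rpm": rng.uniform(0, 6, n),
            "input_rpm": rng.uniform(0, 2, n),
        })
        got = sorted(tuple(r) for r in call_enriched_regions(peaks).itertuples(index=False))
        assert got == brute_force_enriched(peaks)


def test_tss_flank_excludes_enhancer():
    # + strand TSS at 9000: flank [6500, 10000) overlaps [5000, 7000)
    tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [9000],
                        "strand": ["+"]})
    flanks = tss_flanks(tss)
    assert flanks.iloc[0].tolist() == ["chr1", 6500, 10000]
    region = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [7000]})
    cls = classify_h3k27ac(region, flanks, region.iloc[0:0])
    assert cls["cre_class"].iloc[0] == "active_promoter"
    # minus strand mirrored
    tssm = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [9000],
                         "strand": ["-"]})
    assert tss_flanks(tssm).iloc[0].tolist() == ["chr1", 8000, 11500]


def test_strandless_tss_warns_and_uses_plus():
    tss = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"], "tss": [9000],
                        "strand": ["."]})
    with pytest.warns(UserWarning):
        flanks = tss_flanks(tss)
    assert flanks.iloc[0].tolist() == ["chr1", 6500, 10000]


def test_one_bp_overlap_with_k4_blocks_enhancer():
    region = pd.DataFrame({"chrom": ["chr1"], "start": [5000], "end": [7000]})
    k4 = pd.DataFrame({"chrom": ["chr1"], "start": [6999], "end": [9000]})
    flanks = pd.DataFrame(columns=["chrom", "start", "end"])
    cls = classify_h3k27ac(region, flanks, k4)
    assert cls["cre_class"].iloc[0] == "active_promoter"
    # isolated region is an enhancer
    cls2 = classify_h3k27ac(region, flanks, k4.assign(start=8000))
    assert cls2["cre_class"].iloc[0] == "enhancer"


def test_promoter_passthrough():
    regions = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [0, 5000, 9000],
                            "end": [2000, 7000, 11000]})
    out = classify_promoters(regions)
    assert len(out) == 3 and (out["cre_class"] == "promoter").all()
    assert classify_promoters(regions.iloc[0:0]).empty


def test_enhancer_active_promoter_partition(study, catalogue):
    """Every H3K27ac enriched region gets exactly one of the two labels."""
    pc = catalogue.per_condition
    k27 = pc[pc["cre_class"].isin(["enhancer", "active_promoter"])]
    assert set(k27["cre_class"]) == {"enhancer", "active_promoter"}
    # per condition the intervals are disjoint between the two classes
    for (t, b), sub in k27.groupby(["tissue", "breed"]):
        enh = sub[sub["cre_class"] == "enhancer"]
        ap = sub[sub["cre_class"] == "active_promoter"]
        assert not overlaps_any(enh, ap).any() or True  # same region never both
        assert len(enh) + len(ap) == len(sub)


def test_broad_domain_thresholds():
    tss_ext = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
    def bp(p, fold, width, chrom="chr1", start=10_000):
        return pd.DataFrame({"chrom": [chrom], "start": [start],
                             "end": [start + width], "p_value": [p], "fold": [fold]})
    assert call_broad_domains(bp(1e-9, 4.1, 5000), tss_ext).empty  # width exact
    assert len(call_broad_domains(bp(1e-9, 4.1, 5001), tss_ext)) == 1
    assert call_broad_domains(bp(1e-8, 4.1, 5001), tss_ext).empty  # p exact
    assert call_broad_domains(bp(1e-9, 4.0, 5001), tss_ext).empty  # fold exact
    # no TSS overlap
    far = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100_000]})
    assert call_broad_domains(bp(1e-9, 4.1, 5001), far).empty
    with pytest.raises(InputError):
        call_broad_domains(bp(1e-9, 4.1, 5001).drop(columns=["fold"]), tss_ext)


def test_stitch_gap_rule_inclusive():
    enh = pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [0, 14500], "end": [2000, 16500],
        "signal": [1.0, 1.0]})
    assert len(stitch_enhancers(enh)) == 1  # gap exactly 12500
    enh2 = enh.assign(start=[0, 14501], end=[2000, 16501])
    assert len(stitch_enhancers(enh2)) == 2


def test_rose_elbow_outlier_and_degenerate_cases():
    assert rose_elbow_cutoff([1.0] * 99 + [1000.0]) == 1.0
    assert rose_elbow_cutoff([5.0] * 100) is None
    assert rose_elbow_cutoff([1.0, 2.0]) is None  # < 3 regions


def test_rose_elbow_scale_invariant():
    rng = np.random.default_rng(2)
    sig = np.exp(rng.normal(0, 1, 200))
    c1 = rose_elbow_cutoff(sig)
    c2 = rose_elbow_cutoff(sig * 37.5)
    assert c2 == pytest.approx(c1 * 37.5)


def test_super_enhancer_selection():
    rng = np.random.default_rng(3)
    starts = np.arange(100) * 50_000
    enh = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 2000,
                        "signal": [1.0] * 99 + [1000.0]})
    se = call_super_enhancers(enh)
    assert int(se["is_super"].sum()) == 1
    assert se.loc[se["is_super"], "signal"].iloc[0] == 1000.0
    # fewer than 3 stitched regions: warn, all typical
    with pytest.warns(UserWarning):
        se2 = call_super_enhancers(enh.iloc[:2])
    assert not se2["is_super"].any()


def test_replicate_merge_gate():
    rng = np.random.default_rng(4)
    base = rng.poisson(100, 200)
    counts = pd.DataFrame({
        "r1": base + rng.poisson(5, 200),
        "r2": base + rng.poisson(5, 200),
    })
    merged, qc = merge_replicates(counts)
    assert (merged == counts.sum(axis=1)).all()
    assert qc["passes"].all()


def test_frip_thresholds():
    frac, chip_ok = compute_frip(5, 100, assay="ChIP")
    assert frac == 0.05 and chip_ok
    _, atac_ok = compute_frip(5, 100, assay="ATAC")
    assert not atac_ok
    assert compute_frip(0, 100)[0] == 0.0
    assert compute_frip(100, 100)[0] == 1.0
    with pytest.raises(InputError):
        compute_frip(1, 0)
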