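"""dAF, Weir-Cockerham FST, windows and bands, substitute differential test."""

import numpy as np
import pandas as pd
import pytest

from pigcre.errors import InputError
from pigcre.popgen import (
    classify_de_genes, delta_af, differential_cres, differential_test,
    overlap_fraction, quantile_regions, site_fst, size_factors,
    wc_fst_components, windowed_fst,
)


def sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "pop1_ref", "pop1_alt",
                                       "pop2_ref", "pop2_alt"])


def literal_wc(n1, a1, n2, a2):
    """Independent literal transcription of the two-population W&C (1984)
    variance components from allele counts (heterozygosity terms zero)."""
    r = 2
    p1, p2 = a1 / n1, a2 / n2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    pq = p_bar * (1 - p_bar)
    a = (n_bar / n_c) * (s2 - (1.0 / (n_bar - 1)) * (pq - s2 * (r - 1) / r))
    b = (n_bar / (n_bar - 1)) * (pq - s2 * (r - 1) / r)
    return a, a + b


def test_delta_af_values_and_boundary():
    t = sites([("chr1", 10, 0, 10, 10, 0),    # p1=1, p2=0
               ("chr1", 20, 2, 8, 8, 2),      # 0.8 vs 0.2 -> exactly 0.6
               ("chr1", 30, 3, 1, 1, 3)])     # 0.25 vs 0.75
    out = delta_af(t)
    assert out["delta_af"].tolist() == [1.0, pytest.approx(0.6), 0.5]
    assert out["flagged"].tolist() == [True, False, False]  # strict >


def test_delta_af_symmetric_in_population_order():
    t = sites([("chr1", 10, 3, 7, 8, 2)])
    swapped = t.rename(columns={"pop1_ref": "pop2_ref", "pop1_alt": "pop2_alt",
                                "pop2_ref": "pop1_ref", "pop2_alt": "pop1_alt"})
    assert delta_af(t)["delta_af"].iloc[0] == delta_af(swapped)["delta_af"].iloc[0]


def test_wc_components_match_literal_oracle():
    rng = np.random.default_rng(23)
    n1 = rng.integers(4, 200, 1000)
    n2 = rng.integers(4, 200, 1000)
    a1 = rng.integers(0, n1 + 1)
    a2 = rng.integers(0, n2 + 1)
    a, denom = wc_fst_components(n1, a1, n2, a2)
    for i in range(1000):
        ea, ed = literal_wc(float(n1[i]), float(a1[i]), float(n2[i]), float(a2[i]))
        assert a[i] == pytest.approx(ea, abs=1e-12)
        assert denom[i] == pytest.approx(ed, abs=1e-12)


def test_fixed_difference_fst_near_one():
    t = sites([("chr1", 10, 0, 100, 100, 0)])
    assert site_fst(t)["fst"].iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_null_sites_fst_mean_near_zero():
    rng = np.random.default_rng(24)
    rows = []
    for i in range(1000):
        p = rng.uniform(0.1, 0.9)
        a1 = rng.binomial(40, p)
        a2 = rng.binomial(32, p)
        rows.append(("chr1", i, 40 - a1, a1, 32 - a2, a2))
    f = site_fst(sites(rows))["fst"].dropna()
    se = f.std() / np.sqrt(len(f))
    assert abs(f.mean()) <= 3 * se + 1e-3


def test_window_tiling_arithmetic():
    rng = np.random.default_rng(25)
    pos = np.sort(rng.choice(1_000_000, 500, replace=False))
    rows = [("chr1", int(p), 20, 20, 16, 16) for p in pos]
    track = windowed_fst(sites(rows), {"chr1": 1_000_000})
    # every step position whose window intersects the chromosome, and with
    # sites, appears; with 500 uniform sites every window has sites
    import math
    assert len(track) == math.ceil(1_000_000 / 15_000)
    assert (track["end"] - track["start"]).max() == 150_000
    assert track["end"].max() == 1_000_000  # last partial window clipped


def test_quantile_bands_and_merging():
    rows = []
    for i in range(100):
        rows.append(("chr1", i * 10_000, i * 10_000 + 10_000, float(i), 5))
    track = pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_sites"])
    top = quantile_regions(track, "top10")
    bottom = quantile_regions(track, "bottom10")
    middle = quantile_regions(track, "middle10")
    # 10 windows per band; adjacent (bookended windows are non-overlapping
    # here, so no merging) -> top covers the 10 highest
    assert top["start"].min() == 90 * 10_000
    assert bottom["end"].max() == 10 * 10_000
    assert middle["start"].min() == 45 * 10_000
    with pytest.raises(InputError):
        quantile_regions(track, "middle50")
    # overlapping selected windows merge into one region
    t2 = pd.DataFrame([("chr1", 0, 150_000, 1.0, 5),
                       ("chr1", 15_000, 165_000, 0.9, 5),
                       ("chr1", 500_000, 650_000, 0.0, 5)] * 4,
                      columns=track.columns)
    top2 = quantile_regions(t2, "top10")
    assert len(top2) == 1


def test_size_factors_recover_depth_ratio():
    rng = np.random.default_rng(26)
    base = rng.poisson(100, 500).astype(float) + 1
    counts = pd.DataFrame({"a": base, "b": base * 2.0})
    sf = size_factors(counts)
    assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-6)


def test_differential_test_flags_planted_effect():
    rng = np.random.default_rng(27)
    n = 400
    mean = np.exp(rng.normal(np.log(200), 0.5, n))
    effect = np.ones(n)
    effect[:40] = 4.0
    def draw(m):
        size = 20.0  # dispersion 0.05
        return rng.negative_binomial(size, size / (size + m))
    counts = pd.DataFrame({
        "a1": draw(mean), "a2": draw(mean),
        "b1": draw(mean * effect), "b2": draw(mean * effect)})
    res = differential_test(counts, ["a1", "a2"], ["b1", "b2"])
    flagged = (res["fdr"] < 0.05) & (res["log2fc"].abs() > 1)
    assert flagged[:40].mean() >= 0.8     # power at 4-fold
    assert flagged[40:].mean() <= 0.02    # nulls rarely exceed the lfc gate


def test_differential_welch_method():
    rng = np.random.default_rng(28)
    n = 200
    mean = rng.poisson(500, n).astype(float) + 1
    effect = np.ones(n)
    effect[:20] = 4.0
    def draw(m):
        return rng.poisson(m).astype(float)
    counts = pd.DataFrame({
        "a1": draw(mean), "a2": draw(mean),
        "b1": draw(mean * effect), "b2": draw(mean * effect)})
    res = differential_test(counts, ["a1", "a2"], ["b1", "b2"], method="welch")
    assert (res["log2fc"][:20] > 1.5).all()
    assert res["log2fc"][20:].abs().mean() < 0.2
    with pytest.raises(InputError):
        differential_test(counts, ["a1"], ["b1", "b2"], method="welch")


def test_differential_cre_low_change_filter():
    counts = pd.DataFrame({"a1": [100, 100], "a2": [100, 100],
                           "b1": [100, 400], "b2": [100, 400]},
                          index=["low", "high"])
    changes_a = pd.Series([0.8, 2.0], index=["low", "high"])
    changes_b = pd.Series([0.9, 3.0], index=["low", "high"])
    res = differential_cres(counts, ["a1", "a2"], ["b1", "b2"],
                            changes_a, changes_b)
    assert list(res.index) == ["high"]  # 'low' removed by filter (i)


def test_de_gene_label_boundaries():
    from pigcre.popgen import label_de
    # fold boundary inclusive: log2FC exactly 1 with small FDR is 'up'
    assert label_de([1.0], [0.01])[0] == "up"
    assert label_de([-1.0], [0.01])[0] == "down"
    assert label_de([2.0], [0.2])[0] == "stable"   # not significant
    assert label_de([0.99], [0.001])[0] == "stable"


def test_classify_de_genes_on_counts():
    rng = np.random.default_rng(29)
    n = 300
    mean = rng.poisson(800, n).astype(float) + 1
    effect = np.ones(n)
    effect[:20] = 4.0
    effect[20:40] = 0.25
    counts = pd.DataFrame({
        "a1": rng.poisson(mean), "a2": rng.poisson(mean),
        "b1": rng.poisson(mean * effect), "b2": rng.poisson(mean * effect)})
    res = classify_de_genes(counts, ["a1", "a2"], ["b1", "b2"])
    assert (res["label"][:20] == "up").mean() >= 0.9
    assert (res["label"][20:40] == "down").mean() >= 0.9
    assert (res["label"][40:] == "stable").mean() >= 0.95


def test_overlap_fraction_cases():
    regions = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 5000],
                            "end": [1000, 6000]})
    cres = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [700]})
    frac, table = overlap_fraction(regions, cres)
    assert frac == 0.5 and table["hit"].tolist() == [True, False]
    frac2, _ = overlap_fraction(regions, regions)
    assert frac2 == 1.0
    disjoint = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100]})
    assert overlap_fraction(regions, disjoint)[0] == 0.0
    with pytest.raises(InputError):
        overlap_fraction(regions.iloc[0:0], cres)
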