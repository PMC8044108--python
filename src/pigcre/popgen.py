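"""Breed-contrast layer.

Per-site allele-frequency differences (dAF), Weir-Cockerham FST variance
components with 150 kb / 15 kb sliding windows, FST decile region selection,
the differential-CRE filter cascade with a substitute count test, DE gene
classification, and region/CRE overlap statistics.

The FST estimator uses the two-population Weir & Cockerham (1984) variance
components computed from allele counts (no genotype information, so the
heterozygosity terms are zero); the windowed value is sum(a) over
sum(a+b+c) across the sites in a window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .intervals import merge_intervals, overlaps_any


REQUIRED_SITE_COLUMNS = ["chrom", "pos", "pop1_ref", "pop1_alt", "pop2_ref", "pop2_alt"]


def _check_sites(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_SITE_COLUMNS) - set(table.columns)
    if missing:
        raise InputError(f"allele table missing columns {sorted(missing)}")
    n1 = table["pop1_ref"] + table["pop1_alt"]
    n2 = table["pop2_ref"] + table["pop2_alt"]
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise InputError("every retained site needs > 0 called alleles per population")
    return table


def delta_af(table: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """|p1 - p2| per site with a flag at > threshold (strict).

    A 1e-12 guard keeps sites whose exact frequency difference equals the
    threshold (e.g. 0.8 vs 0.2) unflagged despite floating-point round-off.
    """
    t = _check_sites(table).copy()
    p1 = t["pop1_alt"] / (t["pop1_ref"] + t["pop1_alt"])
    p2 = t["pop2_alt"] / (t["pop2_ref"] + t["pop2_alt"])
    t["delta_af"] = (p1 - p2).abs()
    t["flagged"] = t["delta_af"] > threshold + 1e-12
    return t


def wc_fst_components(n1, alt1, n2, alt2) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site components (a, a+b+c) for two
    populations from allele counts, vectorized.

    With allele counts only, the within-individual heterozygosity terms
    vanish; a is the among-population variance component and b the
    within-population component.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(alt1, dtype=float) / n1
    p2 = np.asarray(alt2, dtype=float) / n2
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2)
        )
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2)
    denom = a + b  # c = 0 without heterozygote information
    return a, denom


def site_fst(table: pd.DataFrame) -> pd.DataFrame:
    t = _check_sites(table).copy()
    a, denom = wc_fst_components(
        t["pop1_ref"] + t["pop1_alt"], t["pop1_alt"],
        t["pop2_ref"] + t["pop2_alt"], t["pop2_alt"])
    t["fst_a"] = a
    t["fst_denom"] = denom
    with np.errstate(divide="ignore", invalid="ignore"):
        t["fst"] = np.where(denom != 0, a / denom, np.nan)
    return t


def windowed_fst(table: pd.DataFrame, chrom_lengths: dict,
                 window: int = 150_000, step: int = 15_000) -> pd.DataFrame:
    """Weighted FST (sum a / sum(a+b+c)) in sliding windows.

    Windows are anchored at 0 per chromosome, half-open, the last partial
    window retained; windows containing no site are omitted from the track.
    """
    sites = site_fst(table)
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        a = sub["fst_a"].to_numpy()
        denom = sub["fst_denom"].to_numpy()
        start = 0
        while start < length:
            end = min(start + window, length)
            sel = (pos >= start) & (pos < end)
            if sel.any():
                d = denom[sel].sum()
                val = a[sel].sum() / d if d != 0 else np.nan
                rows.append((chrom, start, end, val, int(sel.sum())))
            start += step
            if start + 1 > length:
                break
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_sites"])


def quantile_regions(track: pd.DataFrame, band: str) -> pd.DataFrame:
    """Merge the windows of one FST decile band into regions.

    ``band`` is 'top10' (highest decile), 'bottom10' (lowest) or 'middle10'
    (the decile centered on the median window). Ties at decile edges are
    broken by genomic order.
    """
    if track.empty:
        raise InputError("empty FST track")
    t = track.dropna(subset=["fst"]).reset_index(drop=True)
    n = len(t)
    k = max(1, n // 10)
    order = t.sort_values(["fst", "chrom", "start"], kind="mergesort")
    if band == "top10":
        sel = order.iloc[n - k:]
    elif band == "bottom10":
        sel = order.iloc[:k]
    elif band == "middle10":
        lo = (n - k) // 2
        sel = order.iloc[lo:lo + k]
    else:
        raise InputError(f"unknown band {band!r}")
    return merge_intervals(sel[["chrom", "start", "end"]])


# ---------------------------------------------------------------------------
# substitute differential test


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (geometric-mean reference)."""
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log = np.log(x)
    log[~np.isfinite(log)] = np.nan
    ref = np.nanmean(log, axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise InputError("no element with nonzero counts in all samples")
    sf = np.exp(np.nanmedian(log[usable] - ref[usable, None], axis=0))
    return pd.Series(sf, index=counts.columns)


def differential_test(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
                      method: str = "poisson") -> pd.DataFrame:
    """Two-group differential test on size-factor-normalized counts.

    ``poisson``: exact conditional test — given the summed count of an
    element, the group-A sum is binomial with probability proportional to
    the group-A size factors. ``welch``: Welch t on log2 normalized counts
    (needs >= 2 replicates per group). Benjamini-Hochberg FDR across
    elements. Elements with zero counts everywhere are dropped.
    """
    keep = counts[group_a + group_b].sum(axis=1) > 0
    c = counts.loc[keep, group_a + group_b]
    sf = size_factors(c)
    norm = c / sf
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    pseudo = 0.5
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))

    pvals = np.ones(len(c))
    if method == "poisson":
        sa = c[group_a].sum(axis=1).to_numpy()
        sb = c[group_b].sum(axis=1).to_numpy()
        pi_a = sf[group_a].sum() / sf[group_a + group_b].sum()
        for i, (x, tot) in enumerate(zip(sa, sa + sb)):
            pvals[i] = stats.binomtest(int(x), int(tot), float(pi_a)).pvalue
    elif method == "welch":
        if len(group_a) < 2 or len(group_b) < 2:
            raise InputError("welch needs >= 2 replicates per group")
        la = np.log2(norm[group_a].to_numpy() + pseudo)
        lb = np.log2(norm[group_b].to_numpy() + pseudo)
        res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
        pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    else:
        raise InputError(f"unknown method {method!r}")
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "p_value": pvals, "fdr": fdr,
    }, index=c.index)


def differential_cres(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
                      changes_a: pd.Series, changes_b: pd.Series,
                      elements: pd.DataFrame | None = None,
                      super_enhancers: pd.DataFrame | None = None,
                      fdr: float = 0.05, lfc: float = 1.0,
                      method: str = "poisson") -> pd.DataFrame:
    """Differential CREs between two breeds with the pre-test filter cascade.

    Filter (i): drop elements whose normalized coverage change (IP_RPM -
    INPUT_RPM) is below 1 in both breeds. Filter (ii), enhancers only: drop
    elements overlapping a super-enhancer of either breed (pass
    ``elements`` with coordinates and ``super_enhancers``). The survivors
    are tested (see :func:`differential_test`); the significance flag is
    FDR < ``fdr`` AND |log2FC| > ``lfc`` (both strict).
    """
    keep = ~((changes_a < 1.0) & (changes_b < 1.0))
    kept_ids = changes_a.index[keep.to_numpy()]
    if super_enhancers is not None and elements is not None and not super_enhancers.empty:
        el = elements.set_index("element_id").loc[kept_ids].reset_index()
        hit = overlaps_any(el, super_enhancers)
        kept_ids = el.loc[~hit, "element_id"]
    res = differential_test(counts.loc[kept_ids], group_a, group_b, method=method)
    res["significant"] = (res["fdr"] < fdr) & (res["log2fc"].abs() > lfc)
    return res


def label_de(log2fc, fdr, lfc: float = 1.0, alpha: float = 0.05) -> np.ndarray:
    """Three-way DE label: up (log2FC >= lfc, FDR < alpha), down
    (log2FC <= -lfc, FDR < alpha) or stable. Fold boundaries inclusive."""
    log2fc = np.asarray(log2fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    return np.where(
        (fdr < alpha) & (log2fc >= lfc), "up",
        np.where((fdr < alpha) & (log2fc <= -lfc), "down", "stable"))


def classify_de_genes(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
                      fdr: float = 0.05, lfc: float = 1.0,
                      method: str = "poisson") -> pd.DataFrame:
    """Per-gene test plus the three-way up / down / stable label."""
    res = differential_test(counts, group_a, group_b, method=method)
    res["label"] = label_de(res["log2fc"], res["fdr"], lfc=lfc, alpha=fdr)
    return res


def overlap_fraction(regions: pd.DataFrame, cres: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Fraction of regions sharing >= 1 bp with any CRE, plus per-region hits."""
    if regions.empty:
        raise InputError("empty region set")
    hit = overlaps_any(regions, cres)
    out = regions.copy()
    out["hit"] = hit
    return float(hit.mean()), out
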