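"""CRE catalogue construction from IP/Input coverage.

Implements the enriched-region rule (p <= 1e-5, IP_RPM > 2 x INPUT_RPM,
IP_RPM - INPUT_RPM > 1, merge, 2 kb center-extension), the promoter /
enhancer / active-promoter / broad-domain classification, ROSE-style
super-enhancer stitching with the rank-curve elbow, and FRiP QC.

Overlap semantics throughout this module: two intervals overlap iff they
share at least one base (half-open coordinates, so bookended intervals do
not overlap).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InputError
from .intervals import center_extend, merge_intervals, overlaps_any, sort_intervals

FRIP_CHIP_MIN = 0.01   # ChIP library passes QC above 1%
FRIP_ATAC_MIN = 0.2    # ATAC library passes QC above 20%


def compute_rpm(counts, depth: float):
    """Reads-per-million normalization: count / (depth / 1e6)."""
    counts = np.asarray(counts, dtype=float)
    if depth <= 0:
        raise InputError(f"library depth must be > 0, got {depth}")
    if (counts < 0).any():
        raise InputError("negative read count")
    return counts / (depth / 1e6)


def merge_replicates(counts: pd.DataFrame, min_r: float = 0.83) -> tuple[pd.Series, pd.DataFrame]:
    """Sum replicate count columns after a Pearson reproducibility gate.

    Returns the summed counts and a table of pairwise replicate correlations
    with pass flags at ``min_r`` (replicates failing the gate are still
    summed — the gate is a QC report, mirroring how irreproducible libraries
    are flagged rather than silently dropped).
    """
    cols = list(counts.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(np.corrcoef(counts[cols[i]], counts[cols[j]])[0, 1])
            rows.append((cols[i], cols[j], r, r > min_r))
    qc = pd.DataFrame(rows, columns=["sample_a", "sample_b", "pearson_r", "passes"])
    return counts.sum(axis=1), qc


def call_enriched_regions(peaks: pd.DataFrame, p_cutoff: float = 1e-5,
                          width: int = 2000) -> pd.DataFrame:
    """Enriched 2 kb regions from candidate peaks with coverage columns.

    *peaks* must carry ``chrom, start, end, p_value, ip_rpm, input_rpm``
    (coverage computed over the 2 kb window centered at each peak midpoint).
    A peak survives iff p <= p_cutoff AND ip_rpm > 2 * input_rpm (strict)
    AND ip_rpm - input_rpm > 1 (strict). Survivors are merged (>= 1 shared
    bp) and each merged region is replaced by the fixed-width window
    centered at its midpoint.
    """
    required = {"chrom", "start", "end", "p_value", "ip_rpm", "input_rpm"}
    missing = required - set(peaks.columns)
    if missing:
        raise InputError(f"peak table missing columns {sorted(missing)}")
    if peaks.empty:
        return peaks.iloc[0:0][["chrom", "start", "end"]].copy()
    keep = (
        (peaks["p_value"] <= p_cutoff)
        & (peaks["ip_rpm"] > 2 * peaks["input_rpm"])
        & (peaks["ip_rpm"] - peaks["input_rpm"] > 1)
    )
    survivors = peaks.loc[keep, ["chrom", "start", "end"]]
    if survivors.empty:
        return survivors.reset_index(drop=True)
    return center_extend(merge_intervals(survivors), width=width)


def tss_flanks(tss: pd.DataFrame, upstream: int = 2500, downstream: int = 1000) -> pd.DataFrame:
    """Strand-aware TSS flanks: *upstream* bp before and *downstream* bp
    after the TSS in gene orientation. Records without a strand are treated
    as '+' with a warning."""
    t = tss.copy()
    unknown = ~t["strand"].isin(["+", "-"])
    if unknown.any():
        warnings.warn(f"{int(unknown.sum())} TSS records without strand treated as '+'")
        t.loc[unknown, "strand"] = "+"
    pos = t["tss"].to_numpy()
    plus = (t["strand"] == "+").to_numpy()
    start = np.where(plus, pos - upstream, pos - downstream)
    end = np.where(plus, pos + downstream, pos + upstream)
    out = pd.DataFrame({"chrom": t["chrom"], "start": np.maximum(start, 0), "end": end})
    return out.reset_index(drop=True)


def classify_promoters(h3k4me3_enriched: pd.DataFrame) -> pd.DataFrame:
    """H3K4me3 enriched regions are potential promoters (pass-through label)."""
    out = h3k4me3_enriched.copy()
    out["cre_class"] = "promoter"
    return out


def classify_h3k27ac(h3k27ac_enriched: pd.DataFrame, flanks: pd.DataFrame,
                     h3k4me3_enriched: pd.DataFrame) -> pd.DataFrame:
    """Partition H3K27ac enriched regions into enhancers and active promoters.

    A region overlapping a TSS flank or an H3K4me3 enriched region (the
    potential promoters) is an active promoter; otherwise it is an enhancer.
    The two labels are complementary by construction.
    """
    out = h3k27ac_enriched.copy()
    if out.empty:
        out["cre_class"] = pd.Series(dtype=str)
        return out
    near_tss = overlaps_any(out, flanks)
    near_k4 = overlaps_any(out, h3k4me3_enriched)
    out["cre_class"] = np.where(near_tss | near_k4, "active_promoter", "enhancer")
    return out


def classify_enhancers(h3k27ac_enriched, flanks, h3k4me3_enriched) -> pd.DataFrame:
    c = classify_h3k27ac(h3k27ac_enriched, flanks, h3k4me3_enriched)
    return c[c["cre_class"] == "enhancer"].reset_index(drop=True)


def call_active_promoters(h3k27ac_enriched, flanks, h3k4me3_enriched) -> pd.DataFrame:
    c = classify_h3k27ac(h3k27ac_enriched, flanks, h3k4me3_enriched)
    return c[c["cre_class"] == "active_promoter"].reset_index(drop=True)


def call_broad_domains(broad_peaks: pd.DataFrame, tss_extended: pd.DataFrame,
                       p_max: float = 1e-8, fold_min: float = 4.0,
                       width_min: int = 5000) -> pd.DataFrame:
    """Broad H3K4me3 domains: p < 1e-8, fold > 4, width > 5 kb (all strict),
    and overlapping a TSS-extended region."""
    required = {"chrom", "start", "end", "p_value", "fold"}
    missing = required - set(broad_peaks.columns)
    if missing:
        raise InputError(f"broad peak table missing columns {sorted(missing)}")
    bp = broad_peaks.copy()
    width = bp["end"] - bp["start"]
    keep = (bp["p_value"] < p_max) & (bp["fold"] > fold_min) & (width > width_min)
    bp = bp[keep]
    if bp.empty:
        out = bp.copy()
        out["cre_class"] = pd.Series(dtype=str)
        return out.reset_index(drop=True)
    bp = bp[overlaps_any(bp, tss_extended)].reset_index(drop=True)
    bp["cre_class"] = "broad_domain"
    return bp


def stitch_enhancers(enhancers: pd.DataFrame, stitch_distance: int = 12500) -> pd.DataFrame:
    """ROSE-style stitching: enhancers whose gap is <= stitch_distance join
    one region; per-region signal is the sum of member signals (floored at 0).

    *enhancers* needs ``chrom, start, end, signal``.
    """
    if enhancers.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "signal", "n_members"])
    df = sort_intervals(enhancers)
    sig = np.maximum(df["signal"].to_numpy(dtype=float), 0.0)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        cur_sig, n = float(sig[idx[0]]), 1
        for k in range(1, len(idx)):
            if starts[k] - cur_e <= stitch_distance:  # gap rule is inclusive
                cur_e = max(cur_e, int(ends[k]))
                cur_sig += float(sig[idx[k]])
                n += 1
            else:
                rows.append((chrom, cur_s, cur_e, cur_sig, n))
                cur_s, cur_e = int(starts[k]), int(ends[k])
                cur_sig, n = float(sig[idx[k]]), 1
        rows.append((chrom, cur_s, cur_e, cur_sig, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal", "n_members"])


def rose_elbow_cutoff(signals: np.ndarray) -> float | None:
    """Signal cutoff from the rescaled rank curve.

    Regions are ranked ascending by signal; both axes are rescaled to [0, 1]
    and the cutoff is the signal at the point where a slope-1 tangent
    touches the curve — equivalently where y - x is minimal, i.e. the point
    of maximum distance below the diagonal (the ROSE criterion). Returns
    None when the curve is degenerate (all signals equal, the rescaled
    curve IS the diagonal with slope 1 everywhere), in which case no region
    is above the elbow.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3:
        return None
    smin, smax = s[0], s[-1]
    if smax == smin:
        return None  # rescaled curve is the diagonal; slope 1 everywhere
    y = (s - smin) / (smax - smin)
    x = np.arange(n) / (n - 1)
    i = int(np.argmin(y - x))  # ties -> lowest rank, deterministic
    return float(s[i])


def call_super_enhancers(enhancers: pd.DataFrame,
                         stitch_distance: int = 12500) -> pd.DataFrame:
    """Stitched regions ranked by summed H3K27ac signal; regions above the
    rank-curve elbow are super-enhancers."""
    stitched = stitch_enhancers(enhancers, stitch_distance)
    if stitched.empty:
        stitched["is_super"] = pd.Series(dtype=bool)
        stitched["rank"] = pd.Series(dtype=int)
        return stitched
    if len(stitched) < 3:
        warnings.warn("fewer than 3 stitched regions: elbow undefined, all typical")
        cutoff = None
    else:
        cutoff = rose_elbow_cutoff(stitched["signal"].to_numpy())
    stitched = stitched.sort_values("signal", kind="mergesort").reset_index(drop=True)
    stitched["rank"] = np.arange(1, len(stitched) + 1)
    stitched["is_super"] = (
        stitched["signal"] > cutoff if cutoff is not None
        else np.zeros(len(stitched), dtype=bool)
    )
    return stitched


def compute_frip(reads_in_peaks: float, total_reads: float,
                 assay: str = "ChIP") -> tuple[float, bool]:
    """Fraction of reads in peaks plus the QC pass flag for the assay."""
    if total_reads <= 0:
        raise InputError("total mapped reads must be > 0")
    frac = float(reads_in_peaks) / float(total_reads)
    threshold = FRIP_ATAC_MIN if assay.upper() == "ATAC" else FRIP_CHIP_MIN
    return frac, frac > threshold
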