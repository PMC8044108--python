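"""CRE-gene correlation within TAD context.

Spearman pairing of enhancer intensity and gene expression profiles,
same-TAD vs adjacent-TAD pair catalogues with matched random controls,
significant-pair filtering, binned-signal correlation around genes, and
enhancer density around SNPs with random-position controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties).

    NaN when either vector has zero variance; requires >= 4 matched samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise InputError("vectors must be sample-matched")
    if len(x) < 4:
        raise InputError("need >= 4 matched samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def assign_tads(elements: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """TAD id per element by midpoint containment (NaN when outside all TADs).

    *tads* needs ``chrom, start, end, tad_id`` sorted within chromosome.
    """
    out = pd.Series(pd.NA, index=elements.index, dtype=object)
    mid = (elements["start"].to_numpy() + elements["end"].to_numpy()) // 2
    for chrom, sub in tads.groupby("chrom"):
        sel = (elements["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["tad_id"].to_numpy()
        pos = mid[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        vals = np.where(ok, ids[np.clip(j, 0, len(ids) - 1)], None)
        out.iloc[np.nonzero(sel)[0]] = vals
    return out


def _tad_rank(tads: pd.DataFrame) -> dict:
    """Ordinal position of each TAD along its chromosome (for adjacency)."""
    rank = {}
    for chrom, sub in tads.groupby("chrom"):
        for k, tid in enumerate(sub.sort_values("start")["tad_id"]):
            rank[tid] = (chrom, k)
    return rank


def pair_within_tads(enhancers: pd.DataFrame, genes: pd.DataFrame,
                     tads: pd.DataFrame, enh_profiles: pd.DataFrame,
                     gene_profiles: pd.DataFrame, n_random: int | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Catalogue of same-TAD, adjacent-TAD and random control pairs.

    Emits every enhancer-enhancer, enhancer-gene and gene-gene pair whose
    members share one TAD or sit in directly adjacent TADs, plus random
    intra-chromosomal control pairs matched in number to the same-TAD count.
    Elements outside all TADs are excluded (their count is reported in
    ``attrs['n_unassigned']``). Spearman coefficients come from the
    sample-matched profile matrices (rows = ids).
    """
    rng = np.random.default_rng(seed)
    enh = enhancers.copy()
    gen = genes.copy()
    enh["tad_id"] = assign_tads(enh, tads)
    gen["tad_id"] = assign_tads(gen, tads)
    n_unassigned = int(enh["tad_id"].isna().sum() + gen["tad_id"].isna().sum())
    enh = enh.dropna(subset=["tad_id"])
    gen = gen.dropna(subset=["tad_id"])
    rank = _tad_rank(tads)

    members = (
        [(i, "enhancer") for i in enh.itertuples()]
        + [(i, "gene") for i in gen.itertuples()]
    )

    def profile(elem_id, kind):
        mat = enh_profiles if kind == "enhancer" else gene_profiles
        return mat.loc[elem_id].to_numpy()

    def relation(ta, tb):
        ca, ka = rank[ta]
        cb, kb = rank[tb]
        if ca != cb:
            return None
        if ka == kb:
            return "same"
        if abs(ka - kb) == 1:
            return "adjacent"
        return None

    rows = []
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            ra, ka = members[a]
            rb, kb = members[b]
            rel = relation(ra.tad_id, rb.tad_id)
            if rel is None:
                continue
            ids = sorted([(ka, ra), (kb, rb)], key=lambda t: t[0])
            kind = "-".join(k for k, _ in ids)
            r = spearman(profile(ra.element_id, ka), profile(rb.element_id, kb))
            rows.append((ra.element_id, rb.element_id, kind, rel, r))
    cat = pd.DataFrame(rows, columns=["id_a", "id_b", "pair_type", "tad_relation", "r"])

    n_same = int((cat["tad_relation"] == "same").sum())
    n_ctrl = n_same if n_random is None else n_random
    ctrl_rows = []
    by_chrom: dict[str, list] = {}
    for rec, kind in members:
        by_chrom.setdefault(rec.chrom, []).append((rec, kind))
    chroms = [c for c in by_chrom if len(by_chrom[c]) >= 2]
    attempts = 0
    while len(ctrl_rows) < n_ctrl and attempts < 50 * max(1, n_ctrl):
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pool = by_chrom[chrom]
        i, j = rng.choice(len(pool), size=2, replace=False)
        (ra, ka), (rb, kb) = pool[i], pool[j]
        kind = "-".join(k for k, _ in sorted([(ka, ra), (kb, rb)], key=lambda t: t[0]))
        r = spearman(profile(ra.element_id, ka), profile(rb.element_id, kb))
        ctrl_rows.append((ra.element_id, rb.element_id, kind, "random", r))
    if ctrl_rows:
        cat = pd.concat(
            [cat, pd.DataFrame(ctrl_rows, columns=cat.columns)], ignore_index=True)
    cat.attrs["n_unassigned"] = n_unassigned
    return cat


SIGNIFICANCE_THRESHOLDS = {
    "enhancer-enhancer": 0.5,
    "gene-gene": 0.8,
    "enhancer-gene": 0.5,
}


def significant_pairs(catalogue: pd.DataFrame, r_ee: float = 0.5,
                      r_gg: float = 0.8, r_eg: float = 0.5) -> pd.DataFrame:
    """Same-TAD pairs above the per-type correlation thresholds (strict >)."""
    thr = {"enhancer-enhancer": r_ee, "gene-gene": r_gg, "enhancer-gene": r_eg}
    same = catalogue[catalogue["tad_relation"] == "same"]
    cut = same["pair_type"].map(thr)
    return same[same["r"] > cut].reset_index(drop=True)


def binned_signal_correlation(genes: pd.DataFrame, tracks: dict,
                              chrom_lengths: dict, flank: int = 500_000,
                              bin_size: int = 5000) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of signal binned around genes.

    ``tracks`` maps sample -> {chrom -> per-bin signal array at bin_size}.
    Per gene, the +-flank window around the TSS is cut into bins; vectors
    are concatenated across genes and correlated pairwise with missing bins
    (genes near chromosome edges) dropped per pair.
    """
    if flank % bin_size != 0:
        raise InputError("flank must be a multiple of bin size")
    k = flank // bin_size
    samples = sorted(tracks)
    vectors = {s: [] for s in samples}
    for g in genes.itertuples():
        c = g.chrom
        center_bin = int(g.tss) // bin_size
        n_bins_chrom = int(np.ceil(chrom_lengths[c] / bin_size))
        for s in samples:
            arr = tracks[s][c]
            vec = np.full(2 * k, np.nan)
            lo = center_bin - k
            for i in range(2 * k):
                b = lo + i
                if 0 <= b < min(len(arr), n_bins_chrom):
                    vec[i] = arr[b]
            vectors[s].append(vec)
    stacked = {s: np.concatenate(v) for s, v in vectors.items()}
    n = len(samples)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = stacked[samples[i]], stacked[samples[j]]
            ok = ~(np.isnan(a) | np.isnan(b))
            out[i, j] = out[j, i] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return pd.DataFrame(out, index=samples, columns=samples)


def enhancer_density_near_points(points: pd.DataFrame, enhancers: pd.DataFrame,
                                 chrom_lengths: dict,
                                 distances=(10_000, 25_000, 50_000, 100_000),
                                 n_random: int = 1, seed: int = 0) -> pd.DataFrame:
    """Enhancer counts within +-d of each (deduplicated) point vs random
    positions matched per chromosome, with a rank-sum comparison per d.

    Returns one row per distance: observed/random mean counts and the
    two-sided Mann-Whitney p-value (exact below n=20, tie-corrected normal
    approximation otherwise).
    """
    rng = np.random.default_rng(seed)
    pts = points.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    enh_sorted = {
        c: np.sort(np.stack([sub["start"].to_numpy(), sub["end"].to_numpy()], axis=1),
                   axis=0)
        for c, sub in enhancers.groupby("chrom")
    }

    def counts_at(table: pd.DataFrame, d: int) -> np.ndarray:
        out = np.zeros(len(table), dtype=int)
        for i, (c, p) in enumerate(zip(table["chrom"], table["pos"])):
            arr = enh_sorted.get(c)
            if arr is None:
                continue
            starts, ends = arr[:, 0], arr[:, 1]
            out[i] = int(((starts < p + d) & (ends > p - d)).sum())
        return out

    rand_rows = []
    for _ in range(max(1, n_random)):
        for c, sub in pts.groupby("chrom"):
            pos = rng.integers(0, chrom_lengths[c], size=len(sub))
            rand_rows.extend((c, int(p)) for p in pos)
    rand = pd.DataFrame(rand_rows, columns=["chrom", "pos"])

    rows = []
    for d in distances:
        obs = counts_at(pts, d)
        ctl = counts_at(rand, d)
        method = "exact" if min(len(obs), len(ctl)) < 20 else "asymptotic"
        try:
            res = stats.mannwhitneyu(obs, ctl, alternative="two-sided", method=method)
            pval = float(res.pvalue)
        except ValueError:
            pval = float("nan")
        rows.append((d, float(obs.mean()), float(ctl.mean()), pval))
    return pd.DataFrame(rows, columns=["distance", "observed_mean",
                                       "random_mean", "p_value"])
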