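"""End-to-end orchestration of the pipeline over a synthetic study.

Each function is a thin composition of the stage modules; the analysis
drivers, the CLI and the acceptance checks all call these so that every
surface exercises the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cre, hic, pairing, popgen, specificity
from .intervals import center_extend, merge_intervals, overlaps_any
from .synthetic import SyntheticStudy


# ---------------------------------------------------------------------------
# coverage plumbing


def region_counts(candidates: pd.DataFrame, counts: pd.DataFrame,
                  regions: pd.DataFrame) -> pd.DataFrame:
    """Counts over arbitrary regions: each candidate's reads are assigned to
    the region containing its midpoint (candidates are disjoint read
    containers, emulating BED-file coverage counting)."""
    mid = (candidates["start"].to_numpy() + candidates["end"].to_numpy()) // 2
    out = np.zeros((len(regions), counts.shape[1]))
    cvals = counts.to_numpy()
    for ri, reg in enumerate(regions.itertuples()):
        sel = ((candidates["chrom"] == reg.chrom).to_numpy()
               & (mid >= reg.start) & (mid < reg.end))
        if sel.any():
            out[ri] = cvals[sel].sum(axis=0)
    idx = regions["element_id"] if "element_id" in regions.columns else regions.index
    return pd.DataFrame(out, index=idx, columns=counts.columns)


def merged_coverage(study: SyntheticStudy, assay: str, tissue: str,
                    breed: str) -> tuple[pd.Series, pd.Series]:
    """Replicate-merged IP and Input RPM per candidate region."""
    sheet = study.sheet
    ip = sheet.samples(assay=assay, tissue=tissue, breed=breed)
    ip_cols = ip["sample_id"].tolist()
    input_ids = sorted(set(ip["input_id"]))
    ip_counts, _ = cre.merge_replicates(study.chip.counts[ip_cols])
    ip_depth = float(ip["depth"].sum())
    ip_rpm = pd.Series(cre.compute_rpm(ip_counts, ip_depth),
                       index=study.chip.counts.index)
    in_counts = study.chip.counts[input_ids].sum(axis=1)
    in_depth = float(sum(sheet.depth(i) for i in input_ids))
    in_rpm = pd.Series(cre.compute_rpm(in_counts, in_depth),
                       index=study.chip.counts.index)
    return ip_rpm, in_rpm


def peak_table(study: SyntheticStudy, assay: str, tissue: str,
               breed: str) -> pd.DataFrame:
    """Candidate peaks with coverage columns, ready for enriched-region calling."""
    ip_rpm, in_rpm = merged_coverage(study, assay, tissue, breed)
    t = study.chip.candidates[["element_id", "chrom", "start", "end", "p_value"]].copy()
    t["ip_rpm"] = ip_rpm.to_numpy()
    t["input_rpm"] = in_rpm.to_numpy()
    return t


# ---------------------------------------------------------------------------
# CRE catalogue


@dataclass
class CRECatalogue:
    per_condition: pd.DataFrame   # chrom,start,end,cre_class,tissue,breed
    total_enhancers: pd.DataFrame  # element_id,chrom,start,end (2 kb, merged)
    change_matrix: pd.DataFrame    # total enhancers x (tissue|breed) IP-Input change
    qn_change: pd.DataFrame
    col_tissue: pd.Series
    col_breed: pd.Series


def call_catalogue(study: SyntheticStudy) -> CRECatalogue:
    """Run enriched-region calling and CRE classification for every
    (tissue, breed), then build the total-enhancer catalogue and its
    quantile-normalized intensity-change matrix."""
    sheet = study.sheet
    tss = study.truth.genes.rename(columns={})[["gene_id", "chrom", "tss", "strand"]]
    flanks = cre.tss_flanks(tss)
    frames = []
    for tissue in sheet.tissues:
        for breed in sheet.breeds:
            k4 = cre.call_enriched_regions(peak_table(study, "H3K4me3", tissue, breed))
            k27 = cre.call_enriched_regions(peak_table(study, "H3K27ac", tissue, breed))
            prom = cre.classify_promoters(k4)
            cls = cre.classify_h3k27ac(k27, flanks, k4)
            for df in (prom, cls):
                df = df.copy()
                df["tissue"] = tissue
                df["breed"] = breed
                frames.append(df)
    per_condition = pd.concat(frames, ignore_index=True)

    enh = per_condition[per_condition["cre_class"] == "enhancer"]
    total = center_extend(merge_intervals(enh[["chrom", "start", "end"]]), 2000)
    total.insert(0, "element_id", [f"TE{i:05d}" for i in range(len(total))])

    cols = {}
    col_tissue, col_breed = {}, {}
    cand = study.chip.candidates
    for tissue in sheet.tissues:
        for breed in sheet.breeds:
            ip_rpm, in_rpm = merged_coverage(study, "H3K27ac", tissue, breed)
            # change per total enhancer via midpoint-assigned candidates
            change = pd.Series(ip_rpm.to_numpy() - in_rpm.to_numpy(),
                               index=cand["element_id"])
            assigned = region_counts(
                cand, change.to_frame("chg"), total)["chg"]
            name = f"{tissue}|{breed}"
            cols[name] = assigned
            col_tissue[name] = tissue
            col_breed[name] = breed
    change_matrix = pd.DataFrame(cols)
    qn = specificity.quantile_normalize(change_matrix)
    return CRECatalogue(
        per_condition=per_condition, total_enhancers=total,
        change_matrix=change_matrix, qn_change=qn,
        col_tissue=pd.Series(col_tissue), col_breed=pd.Series(col_breed))


def evaluate_enhancer_calls(study: SyntheticStudy,
                            catalogue: CRECatalogue) -> dict:
    """Planted-truth recovery of enhancer calling.

    Recall over planted enhancers with deterministic activity (tissue-
    specific in their tissue plus constitutive); precision over all called
    enhancer regions, a hit being >= 1 bp overlap with any planted enhancer.
    """
    truth = study.truth.cres
    planted_enh = truth[truth["cre_class"] == "enhancer"]
    coupled = set(study.truth.coupled_pairs["enhancer_id"])
    called = catalogue.per_condition[
        catalogue.per_condition["cre_class"] == "enhancer"]
    tp = 0
    fn = 0
    for tissue in study.sheet.tissues:
        for breed in study.sheet.breeds:
            sub = called[(called["tissue"] == tissue) & (called["breed"] == breed)]
            expected = planted_enh[
                planted_enh["tissue"].isin(["all", tissue])
                & ~planted_enh["element_id"].isin(coupled)]
            hit = overlaps_any(expected, sub)
            tp += int(hit.sum())
            fn += int((~hit).sum())
    recall = tp / (tp + fn) if tp + fn else float("nan")
    hits = overlaps_any(called, planted_enh)
    precision = float(hits.mean()) if len(called) else float("nan")
    return {"recall": recall, "precision": precision,
            "n_called": int(len(called)), "n_expected": tp + fn}


# ---------------------------------------------------------------------------
# tissue specificity


def tissue_specific_genes(study: SyntheticStudy) -> pd.DataFrame:
    rna = study.sheet.samples(assay="RNA")
    sample_tissue = pd.Series(rna["tissue"].to_numpy(), index=rna["sample_id"])
    group = pd.Series((rna["tissue"] + "|" + rna["breed"]).to_numpy(),
                      index=rna["sample_id"])
    return specificity.zscore_specific_genes(study.tpm, sample_tissue, group)


def evaluate_ts_calls(called: pd.DataFrame, truth: pd.DataFrame,
                      id_col: str) -> dict:
    truth_set = set(zip(truth[id_col], truth["tissue"]))
    called_set = set(zip(called[id_col], called["tissue"]))
    tp = len(truth_set & called_set)
    recall = tp / len(truth_set) if truth_set else float("nan")
    precision = tp / len(called_set) if called_set else float("nan")
    return {"recall": recall, "precision": precision,
            "n_called": len(called_set), "n_truth": len(truth_set)}


def tissue_specific_enhancer_calls(study: SyntheticStudy,
                                   catalogue: CRECatalogue) -> pd.DataFrame:
    return specificity.tissue_specific_enhancers(
        catalogue.qn_change, catalogue.col_tissue, catalogue.col_breed)


def map_total_to_planted(study: SyntheticStudy,
                         catalogue: CRECatalogue) -> pd.Series:
    """element_id of the planted enhancer overlapping each total enhancer
    (empty string when none)."""
    truth = study.truth.cres
    planted = truth[truth["cre_class"] == "enhancer"]
    out = {}
    for reg in catalogue.total_enhancers.itertuples():
        sub = planted[(planted["chrom"] == reg.chrom)
                      & (planted["start"] < reg.end)
                      & (planted["end"] > reg.start)]
        out[reg.element_id] = sub["element_id"].iloc[0] if len(sub) else ""
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Hi-C


def call_tads(study: SyntheticStudy) -> dict:
    """Insulation profiles and boundary calls per chromosome."""
    out = {}
    for chrom, m in study.hic.items():
        profile = hic.insulation_score(m, study.config.hic_bin_size)
        tads = hic.call_boundaries(profile, chrom=chrom)
        out[chrom] = {"profile": profile, "tads": tads}
    return out


def evaluate_boundaries(study: SyntheticStudy, tad_calls: dict,
                        tol_bins: int = 1) -> dict:
    n_true = n_found = n_extra = 0
    for chrom, planted in study.hic_boundary_bins.items():
        called = tad_calls[chrom]["tads"].boundaries
        for b in planted:
            n_true += 1
            if any(abs(c - b) <= tol_bins for c in called):
                n_found += 1
        for c in called:
            if not any(abs(c - b) <= tol_bins for b in planted):
                n_extra += 1
    return {"recall": n_found / n_true if n_true else float("nan"),
            "n_true": n_true, "n_found": n_found, "n_spurious": n_extra}


def tads_bp_frame(tad_calls: dict, bin_size: int) -> pd.DataFrame:
    """Called TADs as bp intervals for pairing."""
    rows = []
    for chrom, res in tad_calls.items():
        for k, t in enumerate(res["tads"].tads.itertuples()):
            rows.append((chrom, t.start_bin * bin_size, t.end_bin * bin_size,
                         f"{chrom}_tad{k}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tad_id"])


# ---------------------------------------------------------------------------
# pairing


def pair_catalogue(study: SyntheticStudy, catalogue: CRECatalogue,
                   tads: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Spearman pair catalogue of total enhancers and expressed genes over
    matched (tissue, breed) profiles."""
    rna = study.sheet.samples(assay="RNA")
    group = (rna["tissue"] + "|" + rna["breed"]).to_numpy()
    gene_prof = specificity.average_replicates(
        study.tpm, pd.Series(group, index=rna["sample_id"]))
    gene_prof = gene_prof[catalogue.change_matrix.columns]
    expressed = gene_prof.max(axis=1) >= 1.0
    gene_prof = gene_prof.loc[expressed]
    genes = study.truth.genes[study.truth.genes["gene_id"].isin(gene_prof.index)]
    gene_iv = pd.DataFrame({
        "element_id": genes["gene_id"], "chrom": genes["chrom"],
        "start": genes["tss"], "end": genes["tss"] + 1})
    enh_iv = catalogue.total_enhancers[["element_id", "chrom", "start", "end"]]
    return pairing.pair_within_tads(
        enh_iv, gene_iv, tads, catalogue.change_matrix, gene_prof, seed=seed)


def evaluate_coupled_recall(study: SyntheticStudy, catalogue: CRECatalogue,
                            pairs: pd.DataFrame) -> dict:
    """Recall of planted coupled enhancer-gene pairs among significant
    same-TAD enhancer-gene pairs."""
    total_to_planted = map_total_to_planted(study, catalogue)
    planted_of_total = total_to_planted.to_dict()
    sig = pairing.significant_pairs(pairs)
    sig_eg = sig[sig["pair_type"] == "enhancer-gene"]
    found = set()
    for row in sig_eg.itertuples():
        a, b = row.id_a, row.id_b
        enh_id, gene_id = (a, b) if a.startswith("TE") else (b, a)
        planted = planted_of_total.get(enh_id, "")
        if planted:
            found.add((planted, gene_id))
    truth_pairs = set(zip(study.truth.coupled_pairs["enhancer_id"],
                          study.truth.coupled_pairs["gene_id"]))
    # only pairs whose enhancer made it into the catalogue are recoverable
    catalogued = {p for p in planted_of_total.values() if p}
    reachable = {(e, g) for e, g in truth_pairs if e in catalogued}
    tp = len(found & truth_pairs)
    return {"recall": tp / len(reachable) if reachable else float("nan"),
            "n_truth": len(truth_pairs), "n_reachable": len(reachable),
            "n_recovered": tp}


# ---------------------------------------------------------------------------
# breed contrasts


def breed_differential_genes(study: SyntheticStudy, tissue: str = "muscle",
                             method: str = "poisson") -> pd.DataFrame:
    sheet = study.sheet
    a = sheet.samples(assay="RNA", tissue=tissue, breed=sheet.breeds[0])
    b = sheet.samples(assay="RNA", tissue=tissue, breed=sheet.breeds[1])
    return popgen.classify_de_genes(
        study.rna_counts, a["sample_id"].tolist(), b["sample_id"].tolist(),
        method=method)


def condition_super_enhancers(study: SyntheticStudy, catalogue: CRECatalogue,
                              tissue: str, breed: str) -> pd.DataFrame:
    """ROSE super-enhancers of one (tissue, breed): stitch that condition's
    called enhancers with their IP-Input change as signal."""
    pc = catalogue.per_condition
    enh = pc[(pc["cre_class"] == "enhancer") & (pc["tissue"] == tissue)
             & (pc["breed"] == breed)][["chrom", "start", "end"]].reset_index(drop=True)
    if enh.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "signal",
                                     "n_members", "rank", "is_super"])
    ip_rpm, in_rpm = merged_coverage(study, "H3K27ac", tissue, breed)
    cand = study.chip.candidates
    change = pd.DataFrame(
        {"chg": ip_rpm.to_numpy() - in_rpm.to_numpy()}, index=cand["element_id"])
    enh = enh.copy()
    enh["signal"] = region_counts(cand, change, enh)["chg"].to_numpy()
    return cre.call_super_enhancers(enh[["chrom", "start", "end", "signal"]])


def breed_differential_enhancers(study: SyntheticStudy, catalogue: CRECatalogue,
                                 tissue: str = "muscle",
                                 method: str = "poisson") -> pd.DataFrame:
    """Differential enhancers between the two breeds in one tissue:
    low-change filter, super-enhancer exclusion per breed, then the
    substitute count test over replicate H3K27ac counts."""
    sheet = study.sheet
    breeds = sheet.breeds
    cand = study.chip.candidates
    total = catalogue.total_enhancers
    counts = region_counts(cand, study.chip.counts, total)
    cols_a = sheet.samples(assay="H3K27ac", tissue=tissue,
                           breed=breeds[0])["sample_id"].tolist()
    cols_b = sheet.samples(assay="H3K27ac", tissue=tissue,
                           breed=breeds[1])["sample_id"].tolist()
    changes_a = catalogue.change_matrix[f"{tissue}|{breeds[0]}"]
    changes_b = catalogue.change_matrix[f"{tissue}|{breeds[1]}"]
    se_frames = []
    for breed in breeds:
        se = condition_super_enhancers(study, catalogue, tissue, breed)
        sup = se[se["is_super"]][["chrom", "start", "end"]]
        if len(sup):
            se_frames.append(sup)
    supers = (pd.concat(se_frames, ignore_index=True) if se_frames
              else pd.DataFrame(columns=["chrom", "start", "end"]))
    return popgen.differential_cres(
        counts, cols_a, cols_b, changes_a, changes_b,
        elements=total, super_enhancers=supers, method=method)


def fst_band_capture(study: SyntheticStudy) -> dict:
    """Windowed FST track, decile bands, and the fraction of planted
    divergent loci inside the top-10% band."""
    track = popgen.windowed_fst(study.variants, dict(study.sizes))
    bands = {b: popgen.quantile_regions(track, b)
             for b in ("top10", "middle10", "bottom10")}
    loci = study.truth.divergent_loci
    pts = pd.DataFrame({"chrom": loci["chrom"], "start": loci["pos"],
                        "end": loci["pos"] + 1})
    captured = overlaps_any(pts, bands["top10"])
    return {"track": track, "bands": bands,
            "capture": float(captured.mean()) if len(pts) else float("nan")}
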