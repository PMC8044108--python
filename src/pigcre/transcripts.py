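"""Record-level filter cascades defining lncRNAs and other new transcripts.

Each gate is computed as its own boolean column so the cascade equals the
conjunction of single-gate survivors and every decision is auditable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

LNCRNA_CLASSES = {"x", "i", "."}
NEW_TX_CLASSES = {"x", "i", "u"}


def _replicate_groups(columns: list[str], replicate_groups: dict | None):
    """Group FPKM/read columns into replicate sets. With no labels, any two
    samples count as replicates (one group holding all columns)."""
    if replicate_groups is None:
        return {"all": columns}
    groups: dict[str, list[str]] = {}
    for col, g in replicate_groups.items():
        groups.setdefault(g, []).append(col)
    return groups


def _n_supporting(records: pd.DataFrame, fpkm_cols: list[str],
                  read_cols: list[str] | None, min_fpkm: float,
                  min_reads: float | None, groups: dict | None) -> pd.Series:
    """Max over replicate groups of the number of replicates where the
    FPKM (and, when requested, read-count) thresholds hold jointly."""
    per_col = {}
    for i, fc in enumerate(fpkm_cols):
        ok = records[fc] >= min_fpkm
        if read_cols is not None and min_reads is not None:
            ok &= records[read_cols[i]] >= min_reads
        per_col[fc] = ok
    ok_df = pd.DataFrame(per_col)
    grouped = _replicate_groups(fpkm_cols, groups)
    best = pd.Series(0, index=records.index)
    for cols in grouped.values():
        best = np.maximum(best, ok_df[cols].sum(axis=1))
    return best


def filter_lncrna(records: pd.DataFrame, fpkm_cols: list[str],
                  read_cols: list[str], min_len: int = 200, min_exons: int = 2,
                  min_fpkm: float = 1.0, min_reads: int = 5, min_reps: int = 2,
                  exclude_u_overlap: bool = True,
                  replicate_groups: dict | None = None) -> pd.DataFrame:
    """Four-gate lncRNA cascade.

    (i) eligible class code ('x', 'i' or '.') observed in >= 2 samples and no
    overlap with known transcripts (optionally nor with class-'u'
    transcripts); (ii) length >= 200 bp and >= 2 exons; (iii) FPKM >= 1 AND
    reads >= 5 jointly in >= 2 replicates; (iv) no coding potential.
    Records missing the coding flag are skipped with a warning. Returns the
    table with one boolean column per gate plus ``kept``.
    """
    rec = records.copy()
    missing_flag = rec["coding_flag"].isna()
    if missing_flag.any():
        warnings.warn(f"{int(missing_flag.sum())} records missing coding_flag skipped")
        rec = rec[~missing_flag].copy()
    gate1 = (
        rec["class_code"].isin(LNCRNA_CLASSES)
        & (rec["n_samples_observed"] >= 2)
        & ~rec["known_overlap"].astype(bool)
    )
    if exclude_u_overlap and "u_overlap" in rec.columns:
        gate1 &= ~rec["u_overlap"].astype(bool)
    gate2 = (rec["length"] >= min_len) & (rec["exon_count"] >= min_exons)
    n_support = _n_supporting(rec, fpkm_cols, read_cols, min_fpkm, min_reads,
                              replicate_groups)
    gate3 = n_support >= min_reps
    gate4 = ~rec["coding_flag"].astype(bool)
    rec["gate_class"] = gate1
    rec["gate_structure"] = gate2
    rec["gate_expression"] = gate3
    rec["gate_noncoding"] = gate4
    rec["kept"] = gate1 & gate2 & gate3 & gate4
    return rec


def filter_new_transcripts(records: pd.DataFrame, fpkm_cols: list[str],
                           lncrna_ids: set | None = None, min_fpkm: float = 5.0,
                           min_reps: int = 2,
                           replicate_groups: dict | None = None) -> pd.DataFrame:
    """New-transcript cascade: class code 'x', 'i' or 'u', FPKM >= 5 in >= 2
    replicates, previously identified lncRNAs and same-strand exon overlaps
    with known transcripts excluded."""
    rec = records.copy()
    lncrna_ids = lncrna_ids or set()
    gate_class = rec["class_code"].isin(NEW_TX_CLASSES)
    gate_not_lnc = ~rec["transcript_id"].isin(lncrna_ids)
    gate_strand = ~rec.get(
        "same_strand_exon_overlap", pd.Series(False, index=rec.index)).astype(bool)
    n_support = _n_supporting(rec, fpkm_cols, None, min_fpkm, None, replicate_groups)
    gate_expr = n_support >= min_reps
    rec["gate_class"] = gate_class
    rec["gate_not_lncrna"] = gate_not_lnc
    rec["gate_strand"] = gate_strand
    rec["gate_expression"] = gate_expr
    rec["kept"] = gate_class & gate_not_lnc & gate_strand & gate_expr
    return rec
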