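"""Cross-species machinery.

A minimal alignment-block interval mapper with minMatch semantics (the role
of a liftover chain), sequence/usage conservation classification of CREs,
conserved TAD boundary pairing with a distance rescue stage, and detection
of inter-chromosomally rearranged TADs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .intervals import overlap_length

BLOCK_COLUMNS = ["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "strand"]


class BlockMap:
    """Ordered source -> target alignment blocks.

    Blocks are non-overlapping on the source; each block maps an equal-length
    target span starting at ``tgt_start`` ('+' colinear, '-' reflected).
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(BLOCK_COLUMNS) - set(table.columns)
        if missing:
            raise InputError(f"block map missing columns {sorted(missing)}")
        t = table.sort_values(["src_chrom", "src_start"]).reset_index(drop=True)
        for _, sub in t.groupby("src_chrom"):
            starts = sub["src_start"].to_numpy()
            ends = sub["src_end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise InputError("blocks overlap on source")
        self.table = t
        self._by_chrom = {c: sub.reset_index(drop=True)
                          for c, sub in t.groupby("src_chrom")}

    def __len__(self) -> int:
        return len(self.table)

    def blocks_for(self, chrom: str) -> pd.DataFrame | None:
        return self._by_chrom.get(chrom)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, columns=BLOCK_COLUMNS)

    @classmethod
    def from_tsv(cls, path) -> "BlockMap":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_chain(cls, path) -> "BlockMap":
        """Read a UCSC chain file; alignment gaps become block breaks.

        The chain's target genome (tName) is treated as the source side of
        the map and its query genome as the target side, matching how an
        A-to-B over.chain lifts coordinates from A to B. Query '-' strand
        blocks are converted to forward-strand coordinates with reflection.
        """
        rows = []
        with open(path) as fh:
            header = None
            t_pos = q_pos = 0
            for raw in fh:
                line = raw.strip()
                if not line:
                    header = None
                    continue
                if line.startswith("chain"):
                    f = line.split()
                    header = {
                        "t_name": f[2], "t_size": int(f[3]), "t_start": int(f[5]),
                        "q_name": f[7], "q_size": int(f[8]), "q_strand": f[9],
                        "q_start": int(f[10]),
                    }
                    t_pos, q_pos = header["t_start"], header["q_start"]
                    continue
                if header is None:
                    continue
                f = line.split()
                size = int(f[0])
                if header["q_strand"] == "+":
                    rows.append((header["t_name"], t_pos, t_pos + size,
                                 header["q_name"], q_pos, "+"))
                else:
                    # chain stores reversed-strand query coords; convert
                    fwd_start = header["q_size"] - (q_pos + size)
                    rows.append((header["t_name"], t_pos, t_pos + size,
                                 header["q_name"], fwd_start, "-"))
                if len(f) == 3:
                    t_pos += size + int(f[1])
                    q_pos += size + int(f[2])
                else:
                    header = None
        return cls(pd.DataFrame(rows, columns=BLOCK_COLUMNS))


@dataclass
class MappedInterval:
    chrom: str
    start: int
    end: int
    strand: str
    matched_bp: int


def map_interval(bm: BlockMap, chrom: str, start: int, end: int,
                 min_match: float = 0.5) -> MappedInterval | None:
    """Map an interval through the block map (liftover semantics).

    Succeeds iff at least ``min_match`` of the interval's bases fall inside
    blocks AND every covered base maps to a single target chromosome and
    strand; the image is the span from the minimum to the maximum of the
    per-base images. Returns None on failure.
    """
    if end <= start:
        raise InputError("empty interval")
    blocks = bm.blocks_for(chrom)
    if blocks is None:
        return None
    covered = 0
    tgt_chrom = None
    tgt_strand = None
    lo, hi = None, None
    for b in blocks.itertuples():
        s = max(start, b.src_start)
        e = min(end, b.src_end)
        if e <= s:
            continue
        covered += e - s
        if tgt_chrom is None:
            tgt_chrom, tgt_strand = b.tgt_chrom, b.strand
        elif (b.tgt_chrom, b.strand) != (tgt_chrom, tgt_strand):
            return None  # split across target chromosomes or strands
        if b.strand == "+":
            seg_lo = b.tgt_start + (s - b.src_start)
            seg_hi = b.tgt_start + (e - b.src_start)
        else:
            # reflected: source base p -> tgt_start + (src_end - 1 - p)
            seg_lo = b.tgt_start + (b.src_end - e)
            seg_hi = b.tgt_start + (b.src_end - s)
        lo = seg_lo if lo is None else min(lo, seg_lo)
        hi = seg_hi if hi is None else max(hi, seg_hi)
    if covered < min_match * (end - start) or covered == 0:
        return None
    return MappedInterval(chrom=tgt_chrom, start=int(lo), end=int(hi),
                          strand=tgt_strand, matched_bp=int(covered))


def center_1kb(start: int, end: int, width: int = 1000) -> tuple[int, int]:
    mid = (start + end) // 2
    return mid - width // 2, mid - width // 2 + width


def classify_conservation(elements: pd.DataFrame, bm: BlockMap,
                          target_elements: pd.DataFrame,
                          min_match: float = 0.5,
                          use_center_1kb: bool = True) -> pd.DataFrame:
    """Sequence/usage conservation of CREs against a target-genome catalogue.

    The centered 1 kb of each element is mapped (minMatch 0.5). Unmapped
    elements are non_conserved; mapped elements are sequence_conserved, and
    usage_conserved when the image shares >= 1 bp with a same-class target
    element.
    """
    tgt_by_chrom = {c: sub[["start", "end"]].to_numpy()
                    for c, sub in target_elements.groupby("chrom")}
    rows = []
    for e in elements.itertuples():
        s, t = (center_1kb(e.start, e.end) if use_center_1kb else (e.start, e.end))
        mapped = map_interval(bm, e.chrom, s, t, min_match=min_match)
        if mapped is None:
            rows.append((e.element_id, "non_conserved", "", -1, -1))
            continue
        label = "sequence_conserved"
        arr = tgt_by_chrom.get(mapped.chrom)
        if arr is not None and (
                (arr[:, 0] < mapped.end) & (arr[:, 1] > mapped.start)).any():
            label = "usage_conserved"
        rows.append((e.element_id, label, mapped.chrom, mapped.start, mapped.end))
    return pd.DataFrame(rows, columns=["element_id", "label", "tgt_chrom",
                                       "tgt_start", "tgt_end"])


def conserved_boundaries(src_boundaries: pd.DataFrame, bm: BlockMap,
                         tgt_boundaries: pd.DataFrame, extend: int = 100_000,
                         rescue: int = 500_000, min_match: float = 0.1,
                         reciprocal_frac: float = 0.1) -> pd.DataFrame:
    """Two-stage conserved pairing of TAD boundaries.

    Stage 1: a source boundary mapped through the block map (minMatch 0.1)
    is conserved when it reciprocally overlaps (>= 10% of each side) a
    +-extend target boundary (extension applied before the reciprocal test).
    Stage 2 (rescue): a still-unpaired mapped boundary within ``rescue`` bp
    of its nearest target boundary is conserved when no already-conserved
    source boundary claimed that target boundary.

    Returns one row per source boundary with mapped coordinates, the paired
    target boundary index (-1 if none) and the stage of the call.
    """
    tgt = tgt_boundaries.reset_index(drop=True)
    rows = []
    mapped_list = []
    for i, b in enumerate(src_boundaries.itertuples()):
        m = map_interval(bm, b.chrom, b.start, b.end, min_match=min_match)
        mapped_list.append(m)
        rows.append({
            "src_index": i, "src_chrom": b.chrom, "src_start": b.start,
            "src_end": b.end,
            "mapped_chrom": m.chrom if m else "",
            "mapped_start": m.start if m else -1,
            "mapped_end": m.end if m else -1,
            "tgt_index": -1, "stage": 0,
        })
    taken = set()
    # stage 1: reciprocal overlap with extended target boundaries
    for row, m in zip(rows, mapped_list):
        if m is None:
            continue
        for j, t in tgt.iterrows():
            if t["chrom"] != m.chrom:
                continue
            ts, te = t["start"] - extend, t["end"] + extend
            ov = overlap_length((m.start, m.end), (ts, te))
            if ov >= reciprocal_frac * (m.end - m.start) and \
               ov >= reciprocal_frac * (te - ts):
                row["tgt_index"] = int(j)
                row["stage"] = 1
                taken.add(int(j))
                break
    # stage 2: distance rescue to an unclaimed nearest target boundary
    for row, m in zip(rows, mapped_list):
        if m is None or row["stage"] == 1:
            continue
        best_j, best_d = -1, None
        mid = (m.start + m.end) // 2
        for j, t in tgt.iterrows():
            if t["chrom"] != m.chrom:
                continue
            tmid = (t["start"] + t["end"]) // 2
            d = abs(tmid - mid)
            if best_d is None or d < best_d:
                best_j, best_d = int(j), d
        if best_j >= 0 and best_d <= rescue and best_j not in taken:
            row["tgt_index"] = best_j
            row["stage"] = 2
            taken.add(best_j)
    return pd.DataFrame(rows)


def detect_rearranged_tads(tgt_tads: pd.DataFrame, tgt_boundaries: pd.DataFrame,
                           pairings: pd.DataFrame) -> pd.DataFrame:
    """Target TADs whose two flanking boundaries' conserved source partners
    lie on different source chromosomes.

    TADs with an unpartnered flank are not classifiable and are excluded
    (count in ``attrs['n_unclassifiable']``).
    """
    tgt = tgt_boundaries.reset_index(drop=True)
    partner_chrom = {}
    for row in pairings.itertuples():
        if row.stage > 0 and row.tgt_index >= 0:
            partner_chrom[int(row.tgt_index)] = row.src_chrom
    bmids = ((tgt["start"] + tgt["end"]) // 2).to_numpy()
    rows = []
    n_unclassifiable = 0
    for tad in tgt_tads.itertuples():
        same_chrom = tgt["chrom"] == tad.chrom
        left = None
        right = None
        for j in np.nonzero(same_chrom.to_numpy())[0]:
            if abs(bmids[j] - tad.start) <= (tgt["end"][j] - tgt["start"][j]):
                left = j
            if abs(bmids[j] - tad.end) <= (tgt["end"][j] - tgt["start"][j]):
                right = j
        if left is None or right is None:
            continue  # chromosome-end TAD: no flanking boundary on one side
        if left not in partner_chrom or right not in partner_chrom:
            n_unclassifiable += 1
            continue
        rearranged = partner_chrom[left] != partner_chrom[right]
        rows.append((tad.tad_id, tad.chrom, tad.start, tad.end,
                     partner_chrom[left], partner_chrom[right], rearranged))
    out = pd.DataFrame(rows, columns=["tad_id", "chrom", "start", "end",
                                      "left_src_chrom", "right_src_chrom",
                                      "rearranged"])
    out.attrs["n_unclassifiable"] = n_unclassifiable
    return out
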