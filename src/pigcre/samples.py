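"""Sample sheet: the tissue x breed x assay design of the compendium."""

from __future__ import annotations

import pandas as pd

ASSAYS = {"H3K4me3", "H3K27ac", "ATAC", "RNA", "Input"}

COLUMNS = ["sample_id", "tissue", "breed", "replicate", "assay", "depth", "input_id"]


class SampleSheet:
    """Per-sample metadata table.

    Each IP sample (H3K4me3 / H3K27ac / ATAC) references exactly one Input
    sample via ``input_id``; RNA and Input samples carry an empty reference.
    """

    def __init__(self, table: pd.DataFrame):
        missing = set(COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if (table["depth"] <= 0).any():
            raise ValueError("library depth must be > 0")
        bad = set(table["assay"]) - ASSAYS
        if bad:
            raise ValueError(f"unknown assays {sorted(bad)}")
        ip = table[table["assay"].isin({"H3K4me3", "H3K27ac", "ATAC"})]
        inputs = set(table.loc[table["assay"] == "Input", "sample_id"])
        dangling = set(ip["input_id"]) - inputs
        if dangling:
            raise ValueError(f"IP samples reference unknown Input samples {sorted(dangling)}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def samples(self, assay: str | None = None, tissue: str | None = None,
                breed: str | None = None) -> pd.DataFrame:
        t = self.table
        if assay is not None:
            t = t[t["assay"] == assay]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if breed is not None:
            t = t[t["breed"] == breed]
        return t

    def depth(self, sample_id: str) -> float:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return float(row["depth"].iloc[0])

    def input_for(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["input_id"].iloc[0])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].dropna().unique())

    @property
    def breeds(self) -> list[str]:
        return sorted(self.table["breed"].dropna().unique())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, columns=COLUMNS)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", keep_default_na=False))
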