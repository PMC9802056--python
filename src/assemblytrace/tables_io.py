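"""Tabular I/O: OTU count tables, sample metadata, and DNA/RNA pairing.

All on-disk formats are plain TSV with a header row.  Count tables are
OTU x sample with OTU identifiers in the first column; metadata tables
carry one row per sequencing sample.  A sample is considered DNA or RNA
according to which count table its identifier appears in; the metadata
``pair_id`` column joins the two members of a pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered habitat continuum, most upstream first.
HABITAT_ORDER: tuple[str, ...] = ("river", "vegetated", "lake")

DNA = "DNA"
RNA = "RNA"

SAMPLE_INFO_COLUMNS = ("sample_id", "habitat", "campaign", "site_index", "pair_id")


class TableValidationError(ValueError):
    """A table violated a structural invariant (duplicates, negatives, ...)."""


def _check_unique(values: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise TableValidationError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CountTable:
    """An OTU x sample count matrix tagged with its molecule of origin.

    ``data`` holds OTUs on the index and samples on the columns.  Raw
    tables are integer-valued with positive column sums; mean-rarefied
    tables may hold fractional counts.
    """

    data: pd.DataFrame
    molecule: str

    def __post_init__(self) -> None:
        if self.molecule not in (DNA, RNA):
            raise TableValidationError(f"molecule must be DNA or RNA, got {self.molecule!r}")
        _check_unique(self.data.index.astype(str), "OTU ids")
        _check_unique(self.data.columns.astype(str), "sample ids")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("count table contains non-numeric values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative count at OTU {self.data.index[r]!r}, sample {self.data.columns[c]!r}"
            )

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def is_integer(self) -> bool:
        values = self.data.to_numpy()
        return bool(np.all(values == np.round(values)))

    def validate_raw(self) -> None:
        """Enforce the extra invariants of un-rarefied tables."""
        if not self.is_integer():
            raise TableValidationError("raw count table must be integer-valued")
        sums = self.column_sums()
        empty = sums[sums <= 0]
        if len(empty):
            raise TableValidationError(f"raw table has empty sample columns: {list(empty.index)}")


def read_count_table(path, molecule: str) -> CountTable:
    """Read a TSV count matrix (OTUs in rows, samples in columns)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample ids")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(df.index, "OTU ids")
    try:
        numeric = df.astype(float)
    except ValueError:
        for otu, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise TableValidationError(
                        f"non-numeric count {cell!r} at OTU {otu!r}, sample {sample!r}"
                    ) from None
        raise
    bad = np.argwhere(numeric.to_numpy() < 0)
    if len(bad):
        r, c = bad[0]
        raise TableValidationError(
            f"negative count at OTU {numeric.index[r]!r}, sample {numeric.columns[c]!r}"
        )
    if np.all(numeric.to_numpy() == np.round(numeric.to_numpy())):
        numeric = numeric.astype(np.int64)
    numeric.index.name = None
    return CountTable(numeric, molecule)


def write_count_table(table: CountTable, path) -> None:
    df = table.data
    if table.is_integer():
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="otu_id")


@dataclass
class SampleSheet:
    """Validated per-sample metadata (habitat, campaign, site, pairing)."""

    frame: pd.DataFrame
    habitats: tuple[str, ...] = HABITAT_ORDER

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_INFO_COLUMNS if c not in self.frame.columns]
        if missing:
            raise TableValidationError(f"sample info missing columns: {missing}")
        if len(self.frame) == 0:
            return
        frame = self.frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        _check_unique(frame["sample_id"], "sample ids")
        frame["habitat"] = frame["habitat"].astype(str).str.lower()
        unknown = set(frame["habitat"]) - set(self.habitats)
        if unknown:
            raise TableValidationError(
                f"unknown habitat labels {sorted(unknown)}; expected one of {self.habitats}"
            )
        frame["site_index"] = frame["site_index"].astype(int)
        if (frame["site_index"] < 1).any():
            raise TableValidationError("site_index must be >= 1")
        # site_index must be unique across pairs within (campaign, habitat);
        # the DNA and RNA members of one pair legitimately share it.
        per_pair = frame.drop_duplicates(["campaign", "habitat", "pair_id"])
        dup = per_pair.duplicated(["campaign", "habitat", "site_index"])
        if dup.any():
            row = per_pair[dup].iloc[0]
            raise TableValidationError(
                f"site_index {row['site_index']} reused within "
                f"({row['campaign']}, {row['habitat']})"
            )
        n_per_pair = frame.groupby("pair_id")["sample_id"].count()
        over = n_per_pair[n_per_pair > 2]
        if len(over):
            raise TableValidationError(f"pair_id bound to more than two samples: {list(over.index)}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def campaigns(self) -> list[str]:
        return list(dict.fromkeys(self.frame["campaign"]))

    def habitat_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["habitat"]

    def habitat_counts(self, campaign: str | None = None) -> dict[str, int]:
        frame = self.frame
        if campaign is not None:
            frame = frame[frame["campaign"] == campaign]
        per_pair = frame.drop_duplicates(["campaign", "habitat", "pair_id"])
        return per_pair["habitat"].value_counts().to_dict()


def read_sample_info(path, habitats: tuple[str, ...] = HABITAT_ORDER) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if len(frame) and "site_index" in frame.columns:
        frame["site_index"] = frame["site_index"].astype(int)
    if len(frame) == 0:
        frame = pd.DataFrame(columns=list(SAMPLE_INFO_COLUMNS))
    return SampleSheet(frame, habitats=habitats)


def write_sample_info(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_copy_numbers(path) -> pd.Series:
    """Read per-OTU 16S gene copy-number estimates (otu_id, copies).

    Missing estimates are simply absent rows, never zeros.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    frame.columns = ["otu_id", "copies"]
    copies = frame.set_index("otu_id")["copies"].astype(float)
    _check_unique(copies.index, "OTU ids")
    if (copies <= 0).any():
        bad = copies[copies <= 0].index[0]
        raise TableValidationError(f"non-positive copy number for OTU {bad!r}")
    return copies


def read_cell_counts(path) -> pd.Series:
    """Read per-sample flow-cytometry total cell counts (sample_id, cells_per_ml)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    frame.columns = ["sample_id", "cells_per_ml"]
    cells = frame.set_index("sample_id")["cells_per_ml"].astype(float)
    _check_unique(cells.index, "sample ids")
    if (cells <= 0).any():
        bad = cells[cells <= 0].index[0]
        raise TableValidationError(f"non-positive cell count for sample {bad!r}")
    return cells


@dataclass
class PairedTables:
    """DNA and RNA matrices aligned column-by-column through pair_id.

    Both frames share an identical OTU index (the union of the inputs,
    zero-filled) and identical columns named by pair_id.  ``pairs`` maps
    each pair_id to its habitat, campaign, site and source sample ids.
    """

    dna: pd.DataFrame
    rna: pd.DataFrame
    pairs: pd.DataFrame
    habitats: tuple[str, ...] = HABITAT_ORDER

    def __post_init__(self) -> None:
        if not self.dna.index.equals(self.rna.index):
            raise TableValidationError("paired tables must share one OTU index")
        if not self.dna.columns.equals(self.rna.columns):
            raise TableValidationError("paired tables must share pair columns")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.dna.index)

    @property
    def campaigns(self) -> list[str]:
        return list(dict.fromkeys(self.pairs["campaign"]))

    def subset_campaign(self, campaign: str) -> "PairedTables":
        keep = self.pairs.index[self.pairs["campaign"] == campaign]
        if len(keep) == 0:
            raise TableValidationError(f"no sample pairs for campaign {campaign!r}")
        return PairedTables(
            self.dna[keep], self.rna[keep], self.pairs.loc[keep], habitats=self.habitats
        )

    def pairs_for(self, habitat: str) -> list[str]:
        return list(self.pairs.index[self.pairs["habitat"] == habitat])


def align_pairs(dna: CountTable, rna: CountTable, info: SampleSheet) -> PairedTables:
    """Join DNA and RNA tables into a pair-aligned view.

    OTU sets are unioned with exact-zero fill; samples lacking a partner
    (or any metadata) are excluded with a warning rather than raised, so
    one lost sample does not sink a campaign.
    """
    if len(info) == 0:
        raise TableValidationError("empty sample sheet: nothing to pair")
    meta = info.frame.set_index("sample_id")
    dna_cols = set(dna.sample_ids)
    rna_cols = set(rna.sample_ids)
    records = []
    dropped: list[str] = []
    for pair_id, group in meta.groupby("pair_id", sort=False):
        in_dna = [s for s in group.index if s in dna_cols]
        in_rna = [s for s in group.index if s in rna_cols]
        if len(in_dna) > 1:
            raise TableValidationError(f"pair_id {pair_id!r} bound to two DNA samples: {in_dna}")
        if len(in_rna) > 1:
            raise TableValidationError(f"pair_id {pair_id!r} bound to two RNA samples: {in_rna}")
        if len(in_dna) == 1 and len(in_rna) == 1:
            row = group.loc[in_dna[0]]
            records.append(
                {
                    "pair_id": pair_id,
                    "habitat": row["habitat"],
                    "campaign": row["campaign"],
                    "site_index": int(row["site_index"]),
                    "dna_sample": in_dna[0],
                    "rna_sample": in_rna[0],
                }
            )
        else:
            dropped.extend(in_dna + in_rna)
    unlisted = sorted((dna_cols | rna_cols) - set(meta.index))
    if unlisted:
        dropped.extend(unlisted)
    if dropped:
        warnings.warn(f"excluding unpaired samples: {sorted(dropped)}", stacklevel=2)
        logger.warning("excluding unpaired samples: %s", sorted(dropped))
    if not records:
        raise TableValidationError("no complete DNA/RNA pairs after alignment")
    pairs = pd.DataFrame.from_records(records).set_index("pair_id")
    order = {h: i for i, h in enumerate(info.habitats)}
    pairs = pairs.sort_values(
        by=["campaign", "habitat", "site_index"],
        key=lambda col: col.map(order) if col.name == "habitat" else col,
        kind="stable",
    )
    union = list(dna.data.index) + [o for o in rna.data.index if o not in set(dna.data.index)]
    dna_al = dna.data.reindex(index=union, fill_value=0)[pairs["dna_sample"]]
    rna_al = rna.data.reindex(index=union, fill_value=0)[pairs["rna_sample"]]
    dna_al.columns = pairs.index
    rna_al.columns = pairs.index
    return PairedTables(dna_al, rna_al, pairs, habitats=info.habitats)
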