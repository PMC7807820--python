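"""Tabular formats used by the pipeline and the packaged study design.

Three tab-separated, UTF-8 dialects are supported:

* **OTU count table** — QIIME "classic" layout: a header line whose first
  cell is ``#OTU ID``, one row per OTU, integer counts, and an optional
  trailing ``taxonomy`` column holding a Greengenes-style lineage string.
* **Sample metadata** — one row per sample with the four design factors
  (farm, batch, antibiotic, feeding) and optional weekly body-weight
  columns named ``weight_<age_days>``.
* **Taxonomy map** — two columns, OTU identifier and a semicolon-separated
  lineage with rank prefixes (``k__;p__;c__;o__;f__;g__;s__``); an empty
  name after a prefix marks the rank as unassigned.

The packaged :func:`design_fixture` reproduces the 425-animal distribution
of the two-farm rabbit study design (two farms, five batches, antibiotic
supplementation, ad libitum vs restricted feeding).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, LookupError_

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "UNASSIGNED",
    "CountTable",
    "TaxonomyMap",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "design_fixture",
    "validate_metadata",
    "weight_columns",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNASSIGNED = "unassigned"

FARMS = ("A", "B")
BATCHES = (1, 2, 3, 4, 5)
ANTIBIOTICS = ("with", "without")
FEEDINGS = ("AL", "R")
#: batch determines farm: batches 1-4 were run in farm A, batch 5 in farm B
BATCH_TO_FARM = {1: "A", 2: "A", 3: "A", 4: "A", 5: "B"}

METADATA_COLUMNS = ["sample_id", "farm", "batch", "antibiotic", "feeding"]

# (farm, batch, antibiotic, feeding, n) — the printed distribution of the
# 425 rabbits over the 12 design cells.
_DESIGN_CELLS = [
    ("A", 1, "with", "AL", 27),
    ("A", 1, "with", "R", 30),
    ("A", 2, "with", "AL", 35),
    ("A", 2, "with", "R", 41),
    ("A", 3, "with", "AL", 61),
    ("A", 3, "with", "R", 53),
    ("A", 4, "with", "AL", 57),
    ("A", 4, "with", "R", 32),
    ("B", 5, "with", "AL", 32),
    ("B", 5, "with", "R", 34),
    ("B", 5, "without", "AL", 12),
    ("B", 5, "without", "R", 11),
]


@dataclass
class CountTable:
    """Integer OTU-by-sample count matrix with identifier lists.

    Rows are OTUs, columns are samples (the classic orientation). Counts
    must be non-negative integers and identifier lists must be free of
    duplicates.
    """

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise FormatError("duplicate OTU identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integral")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise FormatError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.otu_ids, name="#OTU ID"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_otus(self, keep: np.ndarray) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountTable([self.otu_ids[i] for i in idx], list(self.sample_ids),
                          self.counts[idx, :])

    def select_samples(self, keep: np.ndarray) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountTable(list(self.otu_ids), [self.sample_ids[i] for i in idx],
                          self.counts[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (self.otu_ids == other.otu_ids and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))


@dataclass
class TaxonomyMap:
    """OTU → ranked lineage map (kingdom … species).

    Stored as a DataFrame indexed by OTU id with one column per rank;
    unassigned ranks hold :data:`UNASSIGNED`. Lineages are hierarchical:
    an assigned rank may not follow an unassigned one.
    """

    lineages: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(RANKS)))

    def __post_init__(self) -> None:
        df = self.lineages
        if list(df.columns) != list(RANKS):
            raise FormatError(f"taxonomy columns must be {RANKS}")
        if df.index.has_duplicates:
            raise FormatError("duplicate OTU identifiers in taxonomy")
        vals = df.to_numpy(dtype=object)
        assigned = vals != UNASSIGNED
        # hierarchical check: no assigned rank after an unassigned one
        for i in range(vals.shape[0]):
            row = assigned[i]
            if row.any() and not row.all():
                first_un = int(np.argmin(row)) if not row[0] else int(np.flatnonzero(~row)[0])
                if row[first_un:].any():
                    raise FormatError(
                        f"non-hierarchical lineage for OTU {df.index[i]!r}"
                    )
        self.lineages = df

    @classmethod
    def from_lineage_strings(cls, mapping: Mapping[str, str]) -> "TaxonomyMap":
        rows = {otu: parse_lineage(s) for otu, s in mapping.items()}
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        df.index.name = "otu_id"
        return cls(df)

    def lineage(self, otu_id: str) -> tuple[str, ...]:
        try:
            return tuple(self.lineages.loc[otu_id])
        except KeyError as exc:
            raise LookupError_(f"OTU {otu_id!r} missing from taxonomy") from exc

    def rank_of(self, otu_ids: Sequence[str], rank: str) -> pd.Series:
        if rank not in RANKS:
            raise FormatError(f"unknown rank {rank!r}")
        missing = [o for o in otu_ids if o not in self.lineages.index]
        if missing:
            raise LookupError_(f"OTUs missing from taxonomy: {missing[:5]}")
        return self.lineages.loc[list(otu_ids), rank]

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages.index

    def __len__(self) -> int:
        return len(self.lineages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyMap):
            return NotImplemented
        return self.lineages.sort_index().equals(other.lineages.sort_index())


def parse_lineage(s: str) -> list[str]:
    """Parse ``k__Bacteria; p__Firmicutes; c__; ...`` into rank names."""
    parts = [p.strip() for p in s.split(";")]
    if len(parts) > len(RANKS):
        raise FormatError(f"lineage has more than {len(RANKS)} ranks: {s!r}")
    names = []
    for i, part in enumerate(parts):
        prefix = RANK_PREFIXES[i]
        if not part.startswith(prefix):
            raise FormatError(f"expected prefix {prefix!r} at rank {i} in {s!r}")
        name = part[len(prefix):].strip()
        names.append(name if name else UNASSIGNED)
    names.extend([UNASSIGNED] * (len(RANKS) - len(names)))
    return names


def format_lineage(names: Sequence[str]) -> str:
    parts = []
    for prefix, name in zip(RANK_PREFIXES, names):
        parts.append(prefix + ("" if name == UNASSIGNED else name))
    return "; ".join(parts)


# ---------------------------------------------------------------------------
# OTU count table IO

def read_count_table(path: str | Path) -> tuple[CountTable, TaxonomyMap | None]:
    """Read a QIIME classic OTU table.

    Returns the count table and, if the file carries a trailing
    ``taxonomy`` column, the parsed taxonomy map (otherwise ``None``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    if df.columns[0] != "#OTU ID":
        raise FormatError(f"{path}: first header cell must be '#OTU ID', "
                          f"got {df.columns[0]!r}")
    df = df.set_index("#OTU ID")
    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        taxonomy = TaxonomyMap.from_lineage_strings(dict(zip(df.index, df.iloc[:, -1])))
        df = df.iloc[:, :-1]
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample identifiers")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate OTU identifiers")
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count cell") from exc
    if np.any(~np.isfinite(counts)) or np.any(counts < 0) or np.any(counts % 1 != 0):
        raise FormatError(f"{path}: counts must be non-negative integers")
    table = CountTable(list(df.index), list(df.columns), counts.astype(np.int64))
    return table, taxonomy


def write_count_table(path: str | Path, table: CountTable,
                      taxonomy: TaxonomyMap | None = None) -> None:
    df = table.to_frame()
    if taxonomy is not None:
        df = df.copy()
        df["taxonomy"] = [format_lineage(taxonomy.lineage(o)) for o in table.otu_ids]
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata IO

def weight_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the weekly body-weight columns (``weight_<age_days>``)."""
    return [c for c in meta.columns if re.fullmatch(r"weight_\d+", c)]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate factor levels and the batch/farm, farm/antibiotic rules."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing columns {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise FormatError("duplicate sample identifiers in metadata")
    try:
        meta["batch"] = meta["batch"].astype(int)
    except ValueError as exc:
        raise FormatError("batch must be an integer 1..5") from exc
    for col, levels in (("farm", FARMS), ("antibiotic", ANTIBIOTICS),
                        ("feeding", FEEDINGS)):
        bad = set(meta[col].astype(str)) - set(levels)
        if bad:
            raise FormatError(f"unknown {col} level(s) {sorted(bad)}")
        meta[col] = meta[col].astype(str)
    if not meta["batch"].isin(BATCHES).all():
        raise FormatError("batch outside 1..5")
    expected_farm = meta["batch"].map(BATCH_TO_FARM)
    if (meta["farm"] != expected_farm).any():
        bad = meta.loc[meta["farm"] != expected_farm, "sample_id"].tolist()[:5]
        raise ConsistencyError(f"batch/farm mismatch for samples {bad}")
    if ((meta["farm"] == "A") & (meta["antibiotic"] != "with")).any():
        raise ConsistencyError("farm A samples must have antibiotic='with'")
    for col in weight_columns(meta):
        w = pd.to_numeric(meta[col], errors="coerce")
        if (w <= 0).any():
            raise FormatError(f"non-positive body weight in {col}")
        meta[col] = w
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", header=0, dtype=str)
    return validate_metadata(meta)


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy IO

def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns[:2]) != ["otu_id", "taxonomy"]:
        raise FormatError(f"{path}: expected columns otu_id, taxonomy")
    return TaxonomyMap.from_lineage_strings(dict(zip(df["otu_id"], df["taxonomy"])))


def write_taxonomy(path: str | Path, tax: TaxonomyMap) -> None:
    rows = [(otu, format_lineage(tuple(tax.lineages.loc[otu])))
            for otu in tax.lineages.index]
    pd.DataFrame(rows, columns=["otu_id", "taxonomy"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Study design fixture

def design_fixture() -> pd.DataFrame:
    """The 425-animal design: 12 cells of farm x batch x antibiotic x feeding.

    Farm A holds 336 animals over four batches, all on antibiotic feed;
    farm B holds 89 animals in a single batch, 23 of them antibiotic-free.
    Sample identifiers are generated (``S001`` … ``S425``).
    """
    rows = []
    for farm, batch, antibiotic, feeding, n in _DESIGN_CELLS:
        rows.extend([(farm, batch, antibiotic, feeding)] * n)
    meta = pd.DataFrame(rows, columns=["farm", "batch", "antibiotic", "feeding"])
    meta.insert(0, "sample_id", [f"S{i + 1:03d}" for i in range(len(meta))])
    return validate_metadata(meta)
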