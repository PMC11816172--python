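"""In-memory domain containers shared by every pipeline stage.

All stages after :mod:`boargwas.io_formats` operate exclusively on these
types; no stage re-reads files. The containers are thin wrappers around
pandas/numpy objects with the invariants the pipeline relies on checked at
construction time.

Coordinate convention: marker positions and gene intervals are 1-based
inclusive throughout (GFF convention); BED input is converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "FormatError",
    "PedigreeTable",
    "PhenotypeTable",
    "GenotypeData",
    "GeneAnnotation",
    "ExpressionMatrix",
]

#: Names of the semen traits carried by a PhenotypeTable.
TRAIT_COLUMNS = ["spmot", "sppmot", "spabr", "spcount"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, self-parenting)."""


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


@dataclass
class PedigreeTable:
    """Animal/sire/dam triples; unknown parents are ``None``.

    Parents referenced but never listed as animals are auto-added as
    founders. Construction verifies acyclicity and records a topological
    order (parents before offspring).
    """

    df: pd.DataFrame  # columns: animal, sire, dam (object dtype, None = unknown)
    _order: list = field(default=None, repr=False)

    def __post_init__(self):
        df = self.df.copy()
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree missing column {col!r}")
            df[col] = df[col].astype(object).where(df[col].notna(), None)
        missing_codes = {"", "0", ".", "NA", None}
        for col in ("sire", "dam"):
            df[col] = [None if (v in missing_codes) else str(v) for v in df[col]]
        df["animal"] = df["animal"].astype(str)
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")
        known = set(df["animal"])
        extra = []
        for col in ("sire", "dam"):
            for v in df[col]:
                if v is not None and v not in known:
                    known.add(v)
                    extra.append({"animal": v, "sire": None, "dam": None})
        if extra:
            df = pd.concat([pd.DataFrame(extra), df], ignore_index=True)
        g = nx.DiGraph()
        g.add_nodes_from(df["animal"])
        for _, row in df.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent is not None:
                    g.add_edge(parent, row["animal"])
        try:
            order = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = [e[0] for e in nx.find_cycle(g)]
            raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
        pos = {a: i for i, a in enumerate(order)}
        df = df.sort_values("animal", key=lambda s: s.map(pos)).reset_index(drop=True)
        self.df = df
        self._order = list(df["animal"])

    @property
    def animals(self) -> list:
        """Animal ids in topological order (parents first)."""
        return list(self._order)

    def parents(self) -> dict:
        """Map animal -> (sire-or-None, dam-or-None)."""
        return {
            a: (s, d)
            for a, s, d in zip(self.df["animal"], self.df["sire"], self.df["dam"])
        }

    def __len__(self):
        return len(self.df)


@dataclass
class PhenotypeTable:
    """Repeated semen records, one row per (animal, collection date).

    Columns: animal, date (datetime64), year_season, parity, age_months,
    interval_days (NaN for an animal's first record), volume_ml and the four
    trait columns spmot/sppmot/spabr/spcount. Percentage traits live in
    [0, 100]; spcount is positive.
    """

    df: pd.DataFrame

    REQUIRED = ["animal", "date", "year_season", "parity", "age_months", "volume_ml"]

    def __post_init__(self):
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"phenotype table missing column {col!r}")
        df["animal"] = df["animal"].astype(str)
        df["date"] = pd.to_datetime(df["date"])
        dup = df.duplicated(subset=["animal", "date"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise FormatError(
                f"duplicate phenotype record for animal {row['animal']} on "
                f"{row['date'].date()}"
            )
        df = df.sort_values(["animal", "date"], kind="mergesort").reset_index(drop=True)
        if "interval_days" not in df.columns:
            delta = df.groupby("animal")["date"].diff()
            df["interval_days"] = delta.dt.days.astype(float)
        self.df = df

    def records_for(self, trait: str) -> pd.DataFrame:
        if trait not in self.df.columns:
            raise KeyError(f"unknown trait {trait!r}")
        return self.df[self.df[trait].notna()]

    def __len__(self):
        return len(self.df)


@dataclass
class GenotypeData:
    """Animals x markers dosage matrix with its marker map.

    ``dosages`` is float (NaN = missing call) counting copies of allele_B —
    the per-file minor allele as recorded in the map. The map has columns
    marker, chrom, pos (1-based bp), allele_a, allele_b.
    """

    dosages: np.ndarray
    marker_map: pd.DataFrame
    animal_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise FormatError("dosage matrix must be 2-dimensional")
        n, m = self.dosages.shape
        if len(self.marker_map) != m:
            raise FormatError(
                f"marker map length {len(self.marker_map)} != {m} dosage columns"
            )
        if len(self.animal_ids) != n:
            raise FormatError("animal id list does not match dosage rows")
        self.animal_ids = [str(a) for a in self.animal_ids]
        self.marker_map = self.marker_map.reset_index(drop=True)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("dosages must be 0, 1, 2 or missing")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_animals(self, ids) -> "GenotypeData":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [idx[str(a)] for a in ids]
        return GenotypeData(self.dosages[rows], self.marker_map.copy(), list(ids))

    def subset_markers(self, mask) -> "GenotypeData":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return GenotypeData(
            self.dosages[:, cols],
            self.marker_map.iloc[cols].reset_index(drop=True),
            list(self.animal_ids),
        )

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive on both ends."""

    df: pd.DataFrame  # gene_id, gene_name, chrom, start_bp, end_bp, strand

    def __post_init__(self):
        df = self.df.copy()
        for col in ("gene_id", "chrom", "start_bp", "end_bp"):
            if col not in df.columns:
                raise FormatError(f"gene annotation missing column {col!r}")
        if "gene_name" not in df.columns:
            df["gene_name"] = df["gene_id"]
        if "strand" not in df.columns:
            df["strand"] = "+"
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if (df["start_bp"] > df["end_bp"]).any():
            raise FormatError("gene interval with start_bp > end_bp")
        df["chrom"] = df["chrom"].astype(str)
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative TPM-like values for one tissue."""

    tissue: str
    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise FormatError("duplicate gene ids in expression matrix")
        if (self.values.values < 0).any():
            raise FormatError("negative expression values")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)
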