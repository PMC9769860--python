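"""Domain types shared across the pipeline.

The analysis operates on five kinds of objects: a sample x taxon
relative-abundance matrix (percent scale), per-sample design metadata
(participant / region / location / month plus lifestyle factors), a gene
catalog (ARG or virulence-factor reference set), read-to-gene alignment
hits, and symmetric dissimilarity matrices.  Everything downstream —
diversity, core-taxon calls, resistome screening, ordination and
PERMANOVA — consumes these containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "Metadata",
    "AbundanceTable",
    "GeneCatalog",
    "AlignmentHit",
    "DistanceMatrix",
    "BinAssignment",
]

#: metadata columns with dedicated meaning; anything else is a free-form extra
KNOWN_COLUMNS = (
    "sample_id",
    "participant_id",
    "region",
    "location",
    "month_index",
    "sex",
    "yogurt",
    "alcohol",
    "smoking",
    "exercise",
    "age",
    "bmi",
)


@dataclass
class SampleRecord:
    """One sample's design factors.

    ``month_index`` is populated only for samples of the longitudinal arm
    (0-based month of collection); cross-sectional samples carry ``None``.
    Unknown columns from the metadata sheet are preserved in ``extras``.
    """

    sample_id: str
    region: str
    participant_id: str | None = None
    location: str | None = None
    month_index: int | None = None
    sex: str | None = None
    yogurt: str | None = None
    alcohol: str | None = None
    smoking: str | None = None
    exercise: str | None = None
    age: float | None = None
    bmi: float | None = None
    extras: dict = field(default_factory=dict)


class Metadata:
    """Collection of :class:`SampleRecord` backed by a DataFrame.

    Invariants enforced at construction:

    * sample ids are unique;
    * every location maps to exactly one region (locations are nested);
    * within a participant, ``month_index`` is either present for all
      samples or absent for all (a participant is longitudinal or not).
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "sample_id" not in df.columns:
            raise ValueError("metadata requires a 'sample_id' column")
        if "region" not in df.columns:
            raise ValueError("metadata requires a 'region' column")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        if "location" in df.columns:
            has_loc = df["location"].notna()
            if (has_loc & df["region"].isna()).any():
                raise ValueError("location present without region")
            nested = df.loc[has_loc].groupby("location")["region"].nunique()
            bad = nested[nested > 1]
            if len(bad):
                raise ValueError(
                    f"location(s) mapped to multiple regions: {list(bad.index)}"
                )
        if "month_index" in df.columns and "participant_id" in df.columns:
            for pid, sub in df[df["participant_id"].notna()].groupby("participant_id"):
                present = sub["month_index"].notna()
                if present.any() and not present.all():
                    raise ValueError(
                        f"participant {pid}: month_index present for some samples only"
                    )
        self.df = df.set_index("sample_id", drop=False)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def records(self) -> list[SampleRecord]:
        out = []
        for _, row in self.df.iterrows():
            known = {}
            extras = {}
            for col, val in row.items():
                if col == "sample_id":
                    continue
                if col in KNOWN_COLUMNS:
                    known[col] = None if pd.isna(val) else val
                else:
                    extras[col] = val
            if known.get("month_index") is not None:
                known["month_index"] = int(known["month_index"])
            out.append(SampleRecord(sample_id=row["sample_id"], extras=extras, **known))
        return out

    def column(self, name: str, samples: Sequence[str] | None = None) -> pd.Series:
        """Factor column aligned to ``samples`` (defaults to all samples)."""
        if name not in self.df.columns:
            raise KeyError(f"metadata has no column {name!r}")
        ser = self.df[name]
        if samples is not None:
            missing = set(samples) - set(ser.index)
            if missing:
                raise KeyError(f"samples absent from metadata: {sorted(missing)}")
            ser = ser.loc[list(samples)]
        return ser

    def subset(self, sample_ids: Sequence[str]) -> "Metadata":
        return Metadata(self.df.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class AbundanceTable:
    """Sample x taxon relative abundances in percent (0-100).

    ``data`` has samples as rows and taxa as columns.  Per-sample sums may
    fall short of 100 (unclassified mass is allowed); :meth:`renormalize`
    rescales detected taxa so each row sums to exactly 100.
    """

    data: pd.DataFrame
    rank: str = "genus"

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxa at rank {self.rank!r}: {dup}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def renormalize(self) -> "AbundanceTable":
        """Rescale each sample to sum to 100 over its detected taxa."""
        totals = self.data.sum(axis=1)
        if (totals <= 0).any():
            empty = totals.index[totals <= 0].tolist()
            raise ValueError(f"cannot renormalize all-zero sample(s): {empty}")
        return AbundanceTable(self.data.div(totals, axis=0) * 100.0, rank=self.rank)

    def subset_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        present = [t for t in taxa if t in self.data.columns]
        return AbundanceTable(self.data[present], rank=self.rank)


@dataclass
class GeneCatalog:
    """Reference gene set (ResFinder/VFDB style): id, length, class label."""

    lengths: dict[str, int]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"gene {gid!r} has non-positive length {length}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.lengths)

    def length(self, gene_id: str) -> int:
        try:
            return self.lengths[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in catalog") from None


@dataclass(frozen=True)
class AlignmentHit:
    """A read aligned to a catalog gene; coordinates 1-based inclusive."""

    read_id: str
    gene_id: str
    identity_pct: float
    ref_start: int
    ref_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.ref_start <= self.ref_end):
            raise ValueError(
                f"hit {self.read_id!r}: bad interval [{self.ref_start},{self.ref_end}]"
            )
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(
                f"hit {self.read_id!r}: identity {self.identity_pct} outside [0,100]"
            )


class DistanceMatrix:
    """Symmetric, zero-diagonal pairwise dissimilarities with sample ids."""

    def __init__(self, values: np.ndarray, ids: Sequence[str]):
        values = np.asarray(values, dtype=float)
        ids = list(ids)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        if values.shape[0] != len(ids):
            raise ValueError("ids length does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = 0.5 * (values + values.T)
        np.fill_diagonal(self.values, 0.0)
        self.ids = ids
        self._index = {s: i for i, s in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def condensed(self) -> np.ndarray:
        """Strict upper triangle, scipy ``squareform`` order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(self.values[np.ix_(idx, idx)], ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class BinAssignment:
    """A metagenome bin: its contigs and their phylum-level labels.

    ``contig_taxa`` holds one label per contig, ``None`` for unclassified
    contigs (which still count toward the bin size in the majority rule).
    """

    bin_id: str
    contig_ids: list[str]
    contig_taxa: list[str | None]

    def __post_init__(self) -> None:
        if len(self.contig_ids) != len(self.contig_taxa):
            raise ValueError(f"bin {self.bin_id!r}: contig/taxon length mismatch")
        if len(set(self.contig_ids)) != len(self.contig_ids):
            raise ValueError(f"bin {self.bin_id!r}: duplicate contig ids")
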