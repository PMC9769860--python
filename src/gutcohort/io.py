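"""Readers and writers for the external formats the pipeline touches.

Taxonomic abundances arrive either as Kraken-2-style report files (one per
sample) or as a plain taxa x samples TSV matrix.  Read-to-gene alignments
arrive as SAM (identity derived from the NM/MD edit distance) or as
12-column BLAST-style tabular (identity from ``pident``).  Metadata is a
TSV sheet.  All coordinates are 1-based inclusive on the gene reference,
matching BLAST tabular; SAM positions are converted accordingly.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data_model import AbundanceTable, AlignmentHit, GeneCatalog, Metadata

__all__ = [
    "read_abundance",
    "read_kraken_reports",
    "read_alignments",
    "read_metadata",
    "read_catalog_fasta",
    "read_catalog_tsv",
    "read_class_map",
    "write_table",
    "write_abundance",
    "write_metadata",
    "write_alignments_tabular",
    "write_catalog_fasta",
]

#: Kraken rank codes for the ranks this pipeline distinguishes
_RANK_CODES = {"genus": "G", "species": "S", "phylum": "P", "family": "F"}


def read_abundance(
    path: str | Path,
    dialect: str = "matrix",
    rank: str = "genus",
    sample_id: str | None = None,
    counts: str = "clade",
) -> AbundanceTable:
    """Read a relative-abundance table.

    ``dialect="matrix"``: TSV with taxa as rows and samples as columns
    (values in percent).  ``dialect="kraken_report"``: a standard 6-column
    report (clade percent, clade reads, direct reads, rank code, taxid,
    indented name) for ONE sample; ``sample_id`` defaults to the file stem.
    ``counts`` selects the clade-level percent column (default) or a
    percent recomputed from direct-assignment read counts.
    """
    path = Path(path)
    if dialect == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"{path}: duplicate taxon row(s) {dup}")
        out = df.T.astype(float)
        out.index.name = None
        out.columns.name = None
        return AbundanceTable(out, rank=rank)
    if dialect == "kraken_report":
        return _read_kraken_report(path, rank=rank, sample_id=sample_id, counts=counts)
    raise ValueError(f"unknown abundance dialect {dialect!r}")


def _read_kraken_report(
    path: Path, rank: str, sample_id: str | None, counts: str
) -> AbundanceTable:
    code = _RANK_CODES.get(rank)
    if code is None:
        raise ValueError(f"unsupported rank {rank!r}")
    sid = sample_id or path.stem
    rows: dict[str, float] = {}
    total_reads = 0
    saw_rank_codes: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            try:
                pct = float(fields[0])
                clade_reads = int(fields[1])
                direct_reads = int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})")
            rank_code, name = fields[3], fields[5].strip()
            saw_rank_codes.add(rank_code)
            if rank_code in ("U", "R"):
                total_reads += clade_reads
            if rank_code != code:
                continue
            if name in rows:
                raise ValueError(f"{path}:{lineno}: duplicate taxon {name!r} at rank {rank}")
            rows[name] = direct_reads if counts == "direct" else pct
    if counts == "direct" and total_reads > 0:
        rows = {k: 100.0 * v / total_reads for k, v in rows.items()}
    if not rows:
        warnings.warn(
            f"{path}: no rows at rank {rank!r} (rank codes seen: {sorted(saw_rank_codes)})"
        )
    df = pd.DataFrame([rows], index=[sid]).fillna(0.0)
    return AbundanceTable(df, rank=rank)


def read_kraken_reports(
    paths: Iterable[str | Path], rank: str = "genus", counts: str = "clade"
) -> AbundanceTable:
    """Merge one-report-per-sample Kraken files into one table (zeros filled)."""
    tables = [read_abundance(p, "kraken_report", rank=rank, counts=counts) for p in paths]
    df = pd.concat([t.data for t in tables]).fillna(0.0)
    return AbundanceTable(df, rank=rank)


# ---------------------------------------------------------------------------
# alignments


def read_alignments(
    path: str | Path,
    format: str,
    catalog: GeneCatalog,
    include_secondary: bool = True,
    on_missing_nm: str = "error",
) -> list[AlignmentHit]:
    """Read read-to-gene alignments as :class:`AlignmentHit` records.

    SAM identity is ``100 * (aligned - mismatches) / aligned`` where
    ``aligned`` counts M/=/X columns and ``mismatches`` is the NM edit
    distance minus inserted and deleted bases (NM counts indel bases; the
    per-column identity is over the aligned columns only).  Records whose
    NM tag is absent fall back to the MD tag; lacking both is an error, or
    a skip-with-warning when ``on_missing_nm="skip"``.  Unmapped records
    are always skipped; secondary/supplementary records are kept by
    default (coverage may legitimately come from multi-mapped reads).

    Tabular format is 12-column BLAST outfmt 6; hits on the minus strand
    (``sstart > send``) are flipped so ``ref_start <= ref_end``.
    """
    path = Path(path)
    if format == "sam":
        return _read_sam(path, catalog, include_secondary, on_missing_nm)
    if format == "tabular":
        return _read_tabular(path, catalog)
    raise ValueError(f"unknown alignment format {format!r}")


def _cigar_column_counts(cigartuples) -> tuple[int, int, int]:
    """(aligned M/=/X columns, inserted bases, deleted bases)."""
    aligned = ins = dele = 0
    for op, length in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            aligned += length
        elif op == 1:  # I
            ins += length
        elif op == 2:  # D
            dele += length
    return aligned, ins, dele


def _nm_from_md(md: str, ins: int, dele: int) -> int:
    """Reconstruct the NM edit distance from an MD tag plus CIGAR insertions."""
    mismatches = 0
    for token in re.findall(r"\^[A-Za-z]+|[A-Za-z]", md):
        if not token.startswith("^"):
            mismatches += 1
    return mismatches + ins + dele


def _read_sam(
    path: Path, catalog: GeneCatalog, include_secondary: bool, on_missing_nm: str
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if not include_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            gene_id = rec.reference_name
            if gene_id not in catalog:
                raise KeyError(f"{path}: gene {gene_id!r} not in catalog")
            aligned, ins, dele = _cigar_column_counts(rec.cigartuples or [])
            if aligned == 0:
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif rec.has_tag("MD"):
                nm = _nm_from_md(str(rec.get_tag("MD")), ins, dele)
            elif on_missing_nm == "skip":
                warnings.warn(f"{path}: {rec.query_name}: no NM/MD tag, skipped")
                continue
            else:
                raise ValueError(f"{path}: {rec.query_name}: record lacks both NM and MD")
            mismatches = max(nm - ins - dele, 0)
            identity = 100.0 * (aligned - mismatches) / aligned
            start = rec.reference_start + 1  # SAM POS 0-based in pysam
            end = rec.reference_end  # exclusive 0-based == inclusive 1-based
            end = min(end, catalog.length(gene_id))
            hits.append(
                AlignmentHit(
                    read_id=rec.query_name,
                    gene_id=gene_id,
                    identity_pct=max(0.0, min(100.0, identity)),
                    ref_start=start,
                    ref_end=end,
                )
            )
    return hits


def _read_tabular(path: Path, catalog: GeneCatalog) -> list[AlignmentHit]:
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hits: list[AlignmentHit] = []
    for row in df.itertuples(index=False):
        gene_id = str(row.sseqid)
        if gene_id not in catalog:
            raise KeyError(f"{path}: gene {gene_id!r} not in catalog")
        start, end = int(row.sstart), int(row.send)
        if start > end:
            start, end = end, start
        hits.append(
            AlignmentHit(
                read_id=str(row.qseqid),
                gene_id=gene_id,
                identity_pct=float(row.pident),
                ref_start=start,
                ref_end=end,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# metadata and generic tables


def read_metadata(path: str | Path) -> Metadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return Metadata(df)


def write_metadata(meta: Metadata, path: str | Path) -> None:
    meta.df.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    """Write the matrix dialect (taxa rows, sample columns)."""
    table.data.T.to_csv(path, sep="\t", index_label="taxon")


def write_table(obj, path: str | Path, format: str = "tsv") -> None:
    """Write a result table (DataFrame or dict of scalars) as TSV or JSON."""
    path = Path(path)
    if format == "json":
        if isinstance(obj, pd.DataFrame):
            obj.to_json(path, orient="split", indent=2)
        else:
            path.write_text(json.dumps(obj, indent=2, default=str))
    elif format == "tsv":
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown output format {format!r}")


def write_alignments_tabular(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    """Write hits as 12-column BLAST-style tabular (plus strand)."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.ref_end - h.ref_start + 1
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.read_id, h.gene_id, f"{h.identity_pct:.2f}", length,
                        0, 0, 1, length, h.ref_start, h.ref_end, "0.0", "0.0",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# gene catalogs and class maps


def read_catalog_fasta(
    path: str | Path, class_map: dict[str, str] | None = None
) -> GeneCatalog:
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise ValueError(f"{path}: duplicate gene id {rec.id!r}")
        lengths[rec.id] = len(rec.seq)
    return GeneCatalog(lengths, dict(class_map or {}))


def read_catalog_tsv(path: str | Path) -> GeneCatalog:
    """TSV with columns gene_id, length_bp and optional class_label."""
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    lengths = dict(zip(df["gene_id"].astype(str), df["length_bp"].astype(int)))
    classes = {}
    if "class_label" in df.columns:
        classes = dict(zip(df["gene_id"].astype(str), df["class_label"].astype(str)))
    return GeneCatalog(lengths, classes)


def read_class_map(path: str | Path) -> dict[str, str]:
    """Gene-id (or prefix) -> drug-class map, TSV columns prefix, drug_class."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_catalog_fasta(
    catalog: GeneCatalog, path: str | Path, seed: int = 0
) -> None:
    """Emit a synthetic FASTA whose sequence lengths match the catalog."""
    rng = np.random.default_rng(seed)
    records = []
    for gid, length in catalog.lengths.items():
        seq = "".join(rng.choice(list("ACGT"), size=length))
        records.append(SeqRecord(Seq(seq), id=gid, description=""))
    SeqIO.write(records, str(path), "fasta")
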