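"""Presence/absence screening of catalog genes (ARGs, virulence factors).

A gene is called present in a sample when, after discarding alignments
with identity not strictly greater than 80%, the union of the surviving
hits' reference intervals covers strictly more than 90% of the gene
(coverage percentage = total match region / gene size).  Present ARGs
roll up into curated drug classes; metagenome bins inherit a phylum label
only when one phylum strictly exceeds half of the bin's contigs.
All thresholds are configurable; the defaults are deliberately strict
inequalities.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .data_model import AlignmentHit, BinAssignment, GeneCatalog

__all__ = [
    "filter_identity",
    "merge_intervals",
    "call_presence",
    "screen_sample",
    "screen_cohort",
    "rollup",
    "bin_taxonomy",
    "default_class_map",
    "assign_class",
]

MIN_IDENTITY_PCT = 80.0
MIN_COVERAGE_PCT = 90.0
BIN_MAJORITY_FRACTION = 0.5


def filter_identity(
    hits: list[AlignmentHit], min_identity: float = MIN_IDENTITY_PCT
) -> list[AlignmentHit]:
    """Keep hits with identity strictly greater than the threshold (order kept)."""
    return [h for h in hits if h.identity_pct > min_identity]


def merge_intervals(
    hits: list[AlignmentHit], gene_length: int
) -> tuple[list[tuple[int, int]], int]:
    """Union of one gene's hit intervals and the total covered length.

    Intervals are 1-based inclusive; overlapping or touching intervals
    (end + 1 == next start) merge, since per-base coverage is the
    underlying quantity.  Returns (merged intervals, total bp).
    """
    for h in hits:
        if h.ref_end > gene_length:
            raise ValueError(
                f"hit {h.read_id!r} interval [{h.ref_start},{h.ref_end}] "
                f"exceeds gene length {gene_length}"
            )
    ivals = sorted((h.ref_start, h.ref_end) for h in hits)
    merged: list[tuple[int, int]] = []
    for start, end in ivals:
        if merged and start <= merged[-1][1] + 1:
            last_start, last_end = merged[-1]
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    total = sum(e - s + 1 for s, e in merged)
    return merged, total


def call_presence(
    merged_total: int, gene_length: int, min_coverage: float = MIN_COVERAGE_PCT
) -> tuple[bool, float]:
    """Coverage percentage and the strict >90% presence call."""
    if gene_length <= 0:
        raise ValueError("gene_length must be positive")
    if not (0 <= merged_total <= gene_length):
        raise ValueError("merged_total outside [0, gene_length]")
    coverage_pct = 100.0 * merged_total / gene_length
    return coverage_pct > min_coverage, coverage_pct


def screen_sample(
    hits: list[AlignmentHit],
    catalog: GeneCatalog,
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE_PCT,
) -> pd.DataFrame:
    """Per-gene screen of one sample's hits: identity filter, interval
    union, coverage call.  Returns a frame indexed by gene_id with
    kept_hits, merged_bp, coverage_pct and present columns (all catalog
    genes reported, absent ones with zero coverage)."""
    kept = filter_identity(hits, min_identity)
    by_gene: dict[str, list[AlignmentHit]] = {}
    for h in kept:
        if h.gene_id not in catalog:
            raise KeyError(f"hit {h.read_id!r}: gene {h.gene_id!r} not in catalog")
        by_gene.setdefault(h.gene_id, []).append(h)
    rows = []
    for gid in catalog.gene_ids:
        gene_hits = by_gene.get(gid, [])
        _, total = merge_intervals(gene_hits, catalog.length(gid))
        present, cov = call_presence(total, catalog.length(gid), min_coverage)
        rows.append((gid, len(gene_hits), total, cov, present and len(gene_hits) > 0))
    return pd.DataFrame(
        rows, columns=["gene_id", "kept_hits", "merged_bp", "coverage_pct", "present"]
    ).set_index("gene_id")


def screen_cohort(
    hits_by_sample: dict[str, list[AlignmentHit]],
    catalog: GeneCatalog,
    min_identity: float = MIN_IDENTITY_PCT,
    min_coverage: float = MIN_COVERAGE_PCT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every sample; returns (presence, coverage) gene x sample frames."""
    presence = {}
    coverage = {}
    for sid, hits in hits_by_sample.items():
        res = screen_sample(hits, catalog, min_identity, min_coverage)
        presence[sid] = res["present"]
        coverage[sid] = res["coverage_pct"]
    return pd.DataFrame(presence).astype(bool), pd.DataFrame(coverage)


def assign_class(gene_id: str, class_map: dict[str, str]) -> str:
    """Drug class of a gene: exact id match first, then longest prefix match."""
    if gene_id in class_map:
        return class_map[gene_id]
    best = ""
    label = None
    low = gene_id.lower()
    for prefix, cls in class_map.items():
        if low.startswith(prefix.lower()) and len(prefix) > len(best):
            best, label = prefix, cls
    if label is None:
        warnings.warn(f"gene {gene_id!r} has no class mapping; assigned 'unassigned'")
        return "unassigned"
    return label


def rollup(presence: pd.DataFrame, class_map: dict[str, str]) -> pd.DataFrame:
    """Count present genes per (sample, drug class).

    ``presence`` is a gene x sample boolean frame; the class map is keyed
    on exact gene ids or name prefixes (ResFinder-style).  Classes with no
    present gene in a sample get count 0; the grand total equals the
    number of present (sample, gene) pairs.
    """
    classes = pd.Series(
        {gid: assign_class(gid, class_map) for gid in presence.index}, name="drug_class"
    )
    counts = presence.groupby(classes).sum()
    counts.index.name = "drug_class"
    return counts.astype(int)


def bin_taxonomy(
    bins: list[BinAssignment], min_fraction: float = BIN_MAJORITY_FRACTION
) -> pd.Series:
    """Phylum label per bin by the strict-majority rule.

    A bin is labeled with a phylum only when that phylum's contigs
    strictly exceed ``min_fraction`` of ALL the bin's contigs
    (unclassified contigs count in the denominator); otherwise the bin is
    'ambiguous'.  Empty bins are an error.
    """
    labels = {}
    for b in bins:
        if not b.contig_ids:
            raise ValueError(f"bin {b.bin_id!r} is empty")
        n = len(b.contig_taxa)
        counts: dict[str, int] = {}
        for taxon in b.contig_taxa:
            if taxon is not None:
                counts[taxon] = counts.get(taxon, 0) + 1
        winner = "ambiguous"
        for taxon, c in counts.items():
            if c / n > min_fraction:
                winner = taxon
                break
        labels[b.bin_id] = winner
    return pd.Series(labels, name="phylum")


def default_class_map() -> dict[str, str]:
    """Packaged prefix-keyed ARG drug-class map (editable TSV)."""
    with resources.files("gutcohort").joinpath("data/arg_classes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["prefix"], df["drug_class"]))
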