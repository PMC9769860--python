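#!/usr/bin/env python
"""Resistome/virulome screen of the longitudinal arm.

Applies the presence rules (identity >80%, merged coverage >90%) to the
simulated alignments, checks the calls against the planted truth, rolls
present genes into drug classes, and demonstrates the bin-taxonomy
majority rule.  Writes presence/coverage matrices and the class rollup
under results/.
"""

from pathlib import Path

import pandas as pd

from gutcohort import io as gio
from gutcohort.data_model import BinAssignment
from gutcohort.gene_screen import bin_taxonomy, default_class_map, rollup, screen_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = gio.read_catalog_tsv(ROOT / "data" / "catalog.tsv")
    hits = {}
    for path in sorted((ROOT / "data").glob("hits_*.tsv")):
        sid = path.stem.removeprefix("hits_")
        hits[sid] = gio.read_alignments(path, "tabular", catalog)

    presence, coverage = screen_cohort(hits, catalog)
    presence.astype(int).to_csv(ROOT / "gene_presence.tsv", sep="\t")
    coverage.round(2).to_csv(ROOT / "gene_coverage.tsv", sep="\t")

    truth = pd.read_csv(ROOT / "data" / "gene_truth.tsv", sep="\t")
    truth["expected"] = (truth.label != "absent") & (truth.coverage > 0)
    calls = presence.stack()
    merged = truth.set_index(["gene_id", "sample_id"])["expected"]
    agreement = (calls.reindex(merged.index) == merged).mean()
    print(
        f"screen: {int(presence.values.sum())} present (sample, gene) calls "
        f"across {presence.shape[1]} samples; agreement with planted truth "
        f"{100 * agreement:.1f}%"
    )

    classes = rollup(presence, default_class_map())
    classes.to_csv(ROOT / "class_rollup.tsv", sep="\t")
    totals = classes.sum(axis=1).sort_values(ascending=False)
    print("drug classes by total present calls:", dict(totals.head(3)))

    bins = [
        BinAssignment("bin1", [f"c{i}" for i in range(10)],
                      ["Bacteroidetes"] * 6 + ["Firmicutes"] * 4),
        BinAssignment("bin2", [f"c{i}" for i in range(10)],
                      ["Firmicutes"] * 5 + ["Proteobacteria"] * 5),
        BinAssignment("bin3", [f"c{i}" for i in range(8)],
                      ["Proteobacteria"] * 7 + [None]),
    ]
    labels = bin_taxonomy(bins)
    labels.to_csv(ROOT / "bin_taxonomy.tsv", sep="\t")
    print(f"bin taxonomy (strict >50% majority): {labels.to_dict()}")


if __name__ == "__main__":
    main()
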