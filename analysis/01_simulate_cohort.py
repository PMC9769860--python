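#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the study design end to end: a cross-sectional arm (4 regions,
the first split into 3 locations, 4 participants per location) and a
longitudinal arm (1 region, 7 participants, 12 monthly samples), plus a
30-gene ARG/VF catalog with planted persistence truth and the alignment
hits realizing it.  Everything is written as plain TSV/FASTA under
results/data/ for the downstream analysis scripts.
"""

import sys
from pathlib import Path

import pandas as pd

from gutcohort import io as gio
from gutcohort import synthetic
from gutcohort.data_model import GeneCatalog

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    # cross-sectional arm
    cross_cfg = synthetic.default_cross_sectional(seed=SEED)
    table, meta = synthetic.simulate_cohort(cross_cfg)
    gio.write_abundance(table, OUT / "cross_abundance.tsv")
    gio.write_metadata(meta, OUT / "cross_metadata.tsv")
    print(
        f"cross-sectional arm: {len(table.sample_ids)} samples, "
        f"{cross_cfg.n_regions} regions, {cross_cfg.n_core_taxa} planted core genera"
    )

    # longitudinal arm
    long_cfg = synthetic.default_longitudinal(seed=SEED)
    ltable, lmeta = synthetic.simulate_cohort(long_cfg)
    gio.write_abundance(ltable, OUT / "long_abundance.tsv")
    gio.write_metadata(lmeta, OUT / "long_metadata.tsv")
    print(
        f"longitudinal arm: {len(ltable.sample_ids)} samples from "
        f"{long_cfg.participants_per_location} participants x {long_cfg.months} months"
    )

    # gene catalog + planted persistence truth + alignments (longitudinal arm)
    prefixes = ["tet", "bla", "aph", "erm", "sul", "qnr", "mcr", "cat", "van", "dfr"]
    catalog = GeneCatalog(
        {
            f"{prefixes[i % len(prefixes)]}{chr(65 + i // len(prefixes))}_1_SYN{i:05d}":
            600 + 40 * (i % 9)
            for i in range(30)
        }
    )
    pd.DataFrame(
        {"gene_id": catalog.gene_ids, "length_bp": list(catalog.lengths.values())}
    ).to_csv(OUT / "catalog.tsv", sep="\t", index=False)
    truth = synthetic.plant_gene_truth(
        lmeta, catalog, n_cohort_stable=5, n_individual_stable=10, n_transient=10,
        seed=SEED,
    )
    pd.DataFrame(
        [(t.sample_id, t.gene_id, t.coverage, t.identity, t.label) for t in truth],
        columns=["sample_id", "gene_id", "coverage", "identity", "label"],
    ).to_csv(OUT / "gene_truth.tsv", sep="\t", index=False)
    hits = synthetic.simulate_gene_hits(truth, catalog, seed=SEED)
    for sid, sample_hits in hits.items():
        gio.write_alignments_tabular(sample_hits, OUT / f"hits_{sid}.tsv")
    n_hits = sum(len(v) for v in hits.values())
    print(f"gene screen inputs: {len(catalog)} genes, {n_hits} alignment hits")


if __name__ == "__main__":
    main()
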