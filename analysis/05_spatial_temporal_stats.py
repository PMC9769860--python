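#!/usr/bin/env python
"""Spatial and temporal structure of the simulated cohorts.

Cross-sectional arm: within- vs between-region/location Bray-Curtis
contrasts with Wilcoxon significance and PCoA.  Longitudinal arm:
within- vs between-participant contrast, short (consecutive months) vs
long (>6 months) interval contrast, PERMANOVA factor sweep (individual,
region and lifestyle factors), and the stability classification of the
planted ARGs.  Writes contrast/ordination/PERMANOVA/stability tables
under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from gutcohort import io as gio
from gutcohort import stats
from gutcohort.gene_screen import screen_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def contrast_line(name, c):
    return (
        f"  {name}: within mean {np.mean(c.within):.4f} "
        f"vs between mean {np.mean(c.between):.4f} (Wilcoxon p = {c.p_value:.3g})"
    )


def main() -> None:
    # ---- cross-sectional arm: spatial structure -------------------------
    table = gio.read_abundance(ROOT / "data" / "cross_abundance.tsv", "matrix")
    meta = gio.read_metadata(ROOT / "data" / "cross_metadata.tsv")
    d = stats.bray_curtis(table.renormalize())

    print("spatial contrasts (cross-sectional arm):")
    rows = []
    for factor in ("region", "location"):
        c = stats.group_contrast(d, meta, factor)
        print(contrast_line(factor, c))
        rows.append((factor, np.mean(c.within), np.mean(c.between), c.p_value))
    pd.DataFrame(
        rows, columns=["factor", "within_mean", "between_mean", "wilcoxon_p"]
    ).to_csv(ROOT / "spatial_contrasts.tsv", sep="\t", index=False)

    ord_res = stats.pcoa(d, n_axes=2)
    coords = ord_res.coordinates.join(meta.df[["region", "location"]])
    coords.to_csv(ROOT / "pcoa_cross.tsv", sep="\t")
    print(
        f"  PCoA axes explain {100 * ord_res.proportion_explained[0]:.1f}% and "
        f"{100 * ord_res.proportion_explained[1]:.1f}% of the positive inertia "
        f"(negative-eigenvalue fraction {ord_res.negative_eigen_fraction:.3f})"
    )

    # ---- longitudinal arm: individual and temporal structure ------------
    ltable = gio.read_abundance(ROOT / "data" / "long_abundance.tsv", "matrix")
    lmeta = gio.read_metadata(ROOT / "data" / "long_metadata.tsv")
    ld = stats.bray_curtis(ltable.renormalize())

    print("\ntemporal/individual structure (longitudinal arm):")
    c = stats.group_contrast(ld, lmeta, "participant_id")
    print(contrast_line("participant", c))

    pairs = stats.interval_contrast(ld, lmeta)
    pairs.to_csv(ROOT / "interval_pairs.tsv", sep="\t", index=False)
    short = pairs.loc[pairs.interval == "short", "distance"]
    long = pairs.loc[pairs.interval == "long", "distance"]
    _, p = stats.wilcoxon(short, long)
    print(
        f"  interval: short (consecutive months) mean {short.mean():.4f} vs "
        f"long (>6 months) mean {long.mean():.4f} (Wilcoxon p = {p:.3g})"
    )

    factors = ["participant_id", "arm", "region", "sex", "yogurt", "alcohol",
               "smoking", "exercise"]
    # pool the two arms for the factor sweep; longitudinal participants get
    # an arm prefix so ids stay distinct across arms
    ldf = lmeta.df.reset_index(drop=True).assign(arm="longitudinal")
    ldf["participant_id"] = "L-" + ldf["participant_id"]
    cdf = meta.df.reset_index(drop=True).assign(arm="cross_sectional")
    both = pd.concat([cdf, ldf]).reset_index(drop=True)
    big_table = pd.concat([table.data, ltable.data]).fillna(0.0)
    from gutcohort.data_model import AbundanceTable, Metadata

    big_d = stats.bray_curtis(AbundanceTable(big_table).renormalize())
    sweep = stats.factor_sweep(big_d, Metadata(both), factors, n_perm=199, seed=SEED)
    sweep.to_csv(ROOT / "permanova_sweep.tsv", sep="\t")
    print("\nPERMANOVA factor sweep (pooled arms, sorted by R^2):")
    print(sweep.to_string(float_format=lambda v: f"{v:.4f}"))

    # stability of the planted ARGs
    catalog = gio.read_catalog_tsv(ROOT / "data" / "catalog.tsv")
    hits = {
        p.stem.removeprefix("hits_"): gio.read_alignments(p, "tabular", catalog)
        for p in sorted((ROOT / "data").glob("hits_*.tsv"))
    }
    presence, _ = screen_cohort(hits, catalog)
    stab = stats.stability(presence, lmeta)
    stab.per_participant.to_csv(ROOT / "stability_labels.tsv", sep="\t")
    n_cohort = int(stab.cohort_stable.sum())
    n_indiv = int(
        (
            stab.per_participant["label"]
            .groupby(level="feature")
            .agg(lambda s: (s == "individual_stable").any())
        ).sum()
        - n_cohort
    )
    print(
        f"\nARG stability: {n_cohort} cohort-stable genes, "
        f"{n_indiv} further genes stable within at least one individual; "
        "the rest transient or absent"
    )


if __name__ == "__main__":
    main()
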