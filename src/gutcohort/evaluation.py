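"""Self-validation measurements.

Each routine here regenerates its own synthetic inputs, runs the package
end to end on them, and measures how faithfully the planted structure is
recovered: GS against the exact set-containment oracle, interval merging
against a per-base oracle, presence calls against planted truth,
PERMANOVA type-I error under the null, recovery of the planted spatial /
individual / temporal effect ordering, and exactness of the core and
stability rules.  The test suite asserts on these numbers and the
acceptance script reports them.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data_model import AlignmentHit, BinAssignment, DistanceMatrix, GeneCatalog, Metadata
from .gene_screen import bin_taxonomy, merge_intervals, screen_cohort
from .kmer import build_sketch_set, genetic_similarity
from .profile import core_taxa
from .stats import bray_curtis, factor_sweep, interval_contrast, permanova, stability
from .synthetic import (
    CohortConfig,
    PlantedGene,
    plant_gene_truth,
    plant_presence,
    simulate_cohort,
    simulate_gene_hits,
    simulate_sequence_sets,
)

__all__ = [
    "gs_containment_sweep",
    "gs_accounting",
    "interval_oracle_agreement",
    "screen_truth_recovery",
    "permanova_type1_rate",
    "cohort_effect_recovery",
    "core_rule_fidelity",
    "stability_rule_fidelity",
]


def gs_containment_sweep(
    universe_size: int = 100_000,
    containments: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    seed: int = 0,
) -> dict:
    """GS error against the exact full-set containment across a grid.

    For each planted containment c the two k-mer universes are compared
    with default sketch parameters (10,000 x 10 reps) and GS is checked
    against the exact |A∩B|/min(|A|,|B|) computed on the full sets.
    """
    errors = {}
    for i, c in enumerate(containments):
        a, b = simulate_sequence_sets(universe_size, c, seed=seed * 101 + i)
        exact = len(a & b) / min(len(a), len(b))
        sk_a = build_sketch_set(a, seed=seed, sample_id="a")
        sk_b = build_sketch_set(b, seed=seed, sample_id="b")
        gs = genetic_similarity(sk_a, sk_b).gs
        errors[c] = abs(gs - exact)
    # identity / disjointness are exact by construction of the sketches
    ident, _ = simulate_sequence_sets(30_000, 1.0, seed=seed + 7)
    sk1 = build_sketch_set(ident, seed=seed, sample_id="x")
    sk2 = build_sketch_set(set(ident), seed=seed, sample_id="y")
    gs_identical = genetic_similarity(sk1, sk2).gs
    da, db = simulate_sequence_sets(30_000, 0.0, seed=seed + 8)
    gs_disjoint = genetic_similarity(
        build_sketch_set(da, seed=seed), build_sketch_set(db, seed=seed)
    ).gs
    return {
        "per_containment_abs_error": errors,
        "max_abs_error": max(errors.values()),
        "gs_identical": gs_identical,
        "gs_disjoint": gs_disjoint,
    }


def gs_accounting(seed: int = 0) -> dict:
    """N_sum and per-repetition shared counts for two saturating samples."""
    a, b = simulate_sequence_sets(100_000, 0.3, seed=seed)
    res = genetic_similarity(
        build_sketch_set(a, seed=seed, sample_id="a"),
        build_sketch_set(b, seed=seed, sample_id="b"),
    )
    return {
        "n_sum": res.n_sum,
        "max_shared_per_rep": max(res.shared_counts),
        "min_shared_per_rep": min(res.shared_counts),
        "gs": res.gs,
    }


def interval_oracle_agreement(n_fixtures: int = 1000, seed: int = 0) -> dict:
    """Fraction of randomized fixtures where the interval union equals a
    per-base boolean-array oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for i in range(n_fixtures):
        length = int(rng.integers(20, 500))
        n_hits = int(rng.integers(0, 25))
        hits = []
        for j in range(n_hits):
            s = int(rng.integers(1, length + 1))
            e = min(int(s + rng.integers(0, 80)), length)
            hits.append(AlignmentHit(f"r{j}", "g", 99.0, s, e))
        _, total = merge_intervals(hits, length)
        mask = np.zeros(length, dtype=bool)
        for h in hits:
            mask[h.ref_start - 1 : h.ref_end] = True
        agree += total == int(mask.sum())
    return {"agreement_fraction": agree / n_fixtures, "n_fixtures": n_fixtures}


def screen_truth_recovery(
    n_samples: int = 10,
    n_genes: int = 20,
    coverages: tuple[float, ...] = (0.5, 0.85, 0.90, 0.95, 1.0),
    identities: tuple[float, ...] = (75.0, 85.0, 99.0),
    seed: int = 0,
) -> dict:
    """Accuracy of presence calls against planted (coverage, identity) truth.

    Every (sample, gene) pair cycles through the coverage x identity grid,
    including the exact 90%-coverage and sub-threshold-identity boundary
    conditions; the screen must reproduce the implied truth for all pairs.
    """
    catalog = GeneCatalog({f"g{i:03d}": 1000 for i in range(n_genes)})
    grid = list(itertools.product(coverages, identities))
    truth: list[PlantedGene] = []
    k = 0
    for s in range(n_samples):
        for gid in catalog.gene_ids:
            cov, ident = grid[k % len(grid)]
            truth.append(PlantedGene(f"s{s:02d}", gid, cov, ident))
            k += 1
    hits = simulate_gene_hits(truth, catalog, seed=seed)
    presence, _ = screen_cohort(hits, catalog)
    correct = 0
    for rec in truth:
        expected = rec.expected_present(gene_length=catalog.length(rec.gene_id))
        correct += bool(presence.loc[rec.gene_id, rec.sample_id]) == expected
    return {
        "accuracy_fraction": correct / len(truth),
        "n_pairs": len(truth),
    }


def permanova_type1_rate(
    n_sims: int = 400,
    n_samples: int = 20,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the permutation test under a two-group null."""
    rng = np.random.default_rng(seed)
    labels = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
    ids = [f"s{i}" for i in range(n_samples)]
    meta = Metadata(
        pd.DataFrame({"sample_id": ids, "region": ["X"] * n_samples, "group": labels})
    )
    rejections = 0
    for i in range(n_sims):
        pts = rng.normal(size=(n_samples, 5))
        d = DistanceMatrix(squareform(pdist(pts)), ids)
        res = permanova(d, meta, "group", n_perm=n_perm, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def cohort_effect_recovery(n_seeds: int = 20, base_seed: int = 0, n_perm: int = 19) -> dict:
    """Fraction of seeds recovering each planted effect direction.

    On the default effect sizes (individual 0.8 > region 0.3 on the log
    scale; monthly drift 0.15): between-region BC above within-region,
    between-participant above within-participant, consecutive-month BC
    below >6-month BC, and PERMANOVA R^2 ranking individual above region.
    """

    def mean_within_between(d, labels):
        lab = np.asarray(labels)
        iu, ju = np.triu_indices(len(lab), k=1)
        same = lab[iu] == lab[ju]
        return (
            float(d.values[iu[same], ju[same]].mean()),
            float(d.values[iu[~same], ju[~same]].mean()),
        )

    hits = {"region": 0, "participant": 0, "interval": 0, "r2_ranking": 0}
    for s in range(n_seeds):
        cfg = CohortConfig(
            n_regions=4,
            locations_per_region=1,
            participants_per_location=3,
            months=12,
            seed=base_seed * 1000 + s,
        )
        table, meta = simulate_cohort(cfg)
        d = bray_curtis(table.renormalize())
        w, b = mean_within_between(d, meta.column("region", d.ids))
        hits["region"] += w < b
        w, b = mean_within_between(d, meta.column("participant_id", d.ids))
        hits["participant"] += w < b
        pairs = interval_contrast(d, meta)
        short = pairs.loc[pairs.interval == "short", "distance"].mean()
        long = pairs.loc[pairs.interval == "long", "distance"].mean()
        hits["interval"] += short < long
        sweep = factor_sweep(
            d, meta, ["participant_id", "region"], n_perm=n_perm, seed=cfg.seed
        )
        hits["r2_ranking"] += (
            sweep.loc["participant_id", "r_squared"] > sweep.loc["region", "r_squared"]
        )
    return {k: v / n_seeds for k, v in hits.items()} | {"n_seeds": n_seeds}


def core_rule_fidelity(seed: int = 0) -> dict:
    """Exact recovery of the planted core set by the core-taxon rule."""
    cfg = CohortConfig(seed=seed)
    table, _ = simulate_cohort(cfg)
    res = core_taxa(table)
    called = set(res.index[res.is_core])
    planted = set(table.taxon_ids[: cfg.n_core_taxa])
    tp = len(called & planted)
    sensitivity = tp / len(planted)
    specificity = 1.0 - len(called - planted) / (len(table.taxon_ids) - len(planted))
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "n_core_called": len(called),
    }


def stability_rule_fidelity(seed: int = 0) -> dict:
    """Stability labels vs planted truth on a longitudinal design, plus the
    strict >60% VF and >50% bin-majority boundary rules."""
    cfg = CohortConfig(
        n_regions=1, locations_per_region=1, participants_per_location=7,
        months=12, seed=seed,
    )
    _, meta = simulate_cohort(cfg)
    catalog = GeneCatalog({f"arg{i:03d}": 900 for i in range(30)})
    truth = plant_gene_truth(
        meta, catalog, n_cohort_stable=5, n_individual_stable=10, n_transient=10,
        seed=seed,
    )
    hits = simulate_gene_hits(truth, catalog, seed=seed)
    presence, _ = screen_cohort(hits, catalog)
    res = stability(presence, meta)

    # truth labels per (feature, participant)
    part = meta.column("participant_id")
    truth_by_pair: dict[tuple[str, str], bool] = {}
    for rec in truth:
        key = (rec.gene_id, part[rec.sample_id])
        present = rec.label != "absent" and rec.coverage > 0
        truth_by_pair.setdefault(key, True)
        truth_by_pair[key] &= present
    correct = total = 0
    for (feature, pid), all_present in truth_by_pair.items():
        expected = "individual_stable" if all_present else "transient"
        correct += res.label(feature, pid) == expected
        total += 1
    label_accuracy = correct / total

    truth_presence = plant_presence(truth)
    cohort_truth = truth_presence.all(axis=1)
    cohort_accuracy = float(
        (res.cohort_stable.reindex(cohort_truth.index) == cohort_truth).mean()
    )

    # boundary: 3 of 5 samples is NOT >60%, 4 of 5 is
    bmeta = Metadata(
        pd.DataFrame(
            {
                "sample_id": [f"m{t}" for t in range(5)],
                "participant_id": ["p"] * 5,
                "region": ["R"] * 5,
                "month_index": list(range(5)),
            }
        )
    )
    bpres = pd.DataFrame(
        {"three": [1, 1, 1, 0, 0], "four": [1, 1, 1, 1, 0]},
        index=bmeta.sample_ids,
    ).T.astype(bool)
    bres = stability(bpres, bmeta, vf_fraction=0.6)
    vf_boundary_ok = (not bool(bres.vf_stable.loc[("three", "p"), "vf_stable"])) and bool(
        bres.vf_stable.loc[("four", "p"), "vf_stable"]
    )

    # boundary: exactly half the contigs is NOT a majority, 6/10 is
    bins = [
        BinAssignment("half", [f"c{i}" for i in range(10)],
                      ["Firmicutes"] * 5 + ["Proteobacteria"] * 5),
        BinAssignment("majority", [f"c{i}" for i in range(10)],
                      ["Bacteroidetes"] * 6 + ["Firmicutes"] * 4),
    ]
    labels = bin_taxonomy(bins)
    bin_boundary_ok = labels["half"] == "ambiguous" and labels["majority"] == "Bacteroidetes"

    return {
        "label_accuracy": label_accuracy,
        "cohort_flag_accuracy": cohort_accuracy,
        "vf_boundary_ok": float(vf_boundary_ok),
        "bin_boundary_ok": float(bin_boundary_ok),
    }
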