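"""The synthetic cohort generator: determinism and planted structure."""

import numpy as np
import pandas as pd
import pytest

from gutcohort import GeneCatalog, screen_sample
from gutcohort import stats, synthetic
from gutcohort.synthetic import (
    CohortConfig,
    PlantedGene,
    plant_gene_truth,
    plant_presence,
    simulate_cohort,
    simulate_gene_hits,
    simulate_sequence_sets,
)


def _mean_within_between(d, labels):
    labels = np.asarray(labels)
    iu, ju = np.triu_indices(len(labels), k=1)
    same = labels[iu] == labels[ju]
    return d.values[iu[same], ju[same]].mean(), d.values[iu[~same], ju[~same]].mean()


class TestSimulateCohort:
    def test_same_seed_bit_identical(self):
        t1, m1 = simulate_cohort(CohortConfig(seed=5))
        t2, m2 = simulate_cohort(CohortConfig(seed=5))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(m1.df, m2.df)

    def test_different_seed_different_output(self):
        t1, _ = simulate_cohort(CohortConfig(seed=5))
        t2, _ = simulate_cohort(CohortConfig(seed=6))
        assert not t1.data.equals(t2.data)

    def test_degenerate_config_identical_samples(self):
        cfg = CohortConfig(
            region_effect_sd=0, individual_effect_sd=0, noise_sd=0, drift_sd=0, seed=1
        )
        table, _ = simulate_cohort(cfg)
        d = stats.bray_curtis(table)
        assert np.allclose(d.values, 0.0)

    def test_core_floor_guaranteed_and_transients_dip(self):
        table, _ = simulate_cohort(CohortConfig(seed=2))
        core = table.values[:, :30]
        assert (core >= 0.01).all()
        transient = table.values[:, 30:]
        assert (transient < 0.01).any(axis=0).all()

    def test_rows_sum_to_100(self):
        table, _ = simulate_cohort(CohortConfig(seed=3))
        assert np.allclose(table.values.sum(axis=1), 100.0)

    def test_individual_effect_dominates_between_participant_distance(self):
        wins = 0
        for seed in range(20):
            cfg = CohortConfig(
                n_regions=1, locations_per_region=1, participants_per_location=6,
                months=4, individual_effect_sd=1.0, region_effect_sd=0.0, seed=seed,
            )
            table, meta = simulate_cohort(cfg)
            d = stats.bray_curtis(table)
            w, b = _mean_within_between(d, meta.column("participant_id", d.ids))
            wins += w < b
        assert wins >= 19

    def test_drift_gives_short_vs_long_interval_ordering(self):
        cfg = CohortConfig(
            n_regions=1, locations_per_region=1, participants_per_location=4,
            months=10, noise_sd=0.0, drift_sd=0.3, seed=4,
        )
        table, meta = simulate_cohort(cfg)
        d = stats.bray_curtis(table)
        pairs = stats.interval_contrast(d, meta)
        short = pairs.loc[pairs.interval == "short", "distance"].mean()
        long = pairs.loc[pairs.interval == "long", "distance"].mean()
        assert short < long

    def test_longitudinal_metadata_has_month_everywhere(self, longitudinal):
        _, meta = longitudinal
        assert meta.df["month_index"].notna().all()
        assert meta.df.groupby("participant_id")["month_index"].count().eq(12).all()

    def test_enterotype_fraction_zero_means_all_bacteroides(self):
        from gutcohort import enterotype

        table, _ = simulate_cohort(CohortConfig(enterotype_fraction=0.0, seed=7))
        assert set(enterotype(table)) == {"ET_B"}

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(noise_sd=-1)
        with pytest.raises(ValueError):
            CohortConfig(n_core_taxa=200, n_taxa=100)
        with pytest.raises(ValueError):
            CohortConfig(months=3, participants_per_location=0)


class TestSimulateGeneHits:
    def _catalog(self):
        return GeneCatalog({f"g{i}": 1000 for i in range(4)})

    def test_full_coverage_called_present(self):
        cat = self._catalog()
        truth = [PlantedGene("s", "g0", 1.0, 99.0)]
        hits = simulate_gene_hits(truth, cat, read_len=150, seed=0)
        res = screen_sample(hits["s"], cat)
        assert bool(res.loc["g0", "present"])

    def test_085_coverage_called_absent(self):
        cat = self._catalog()
        truth = [PlantedGene("s", "g0", 0.85, 99.0)]
        hits = simulate_gene_hits(truth, cat, seed=0)
        res = screen_sample(hits["s"], cat)
        assert res.loc["g0", "coverage_pct"] == pytest.approx(85.0)
        assert not bool(res.loc["g0", "present"])

    def test_low_identity_filtered_regardless_of_coverage(self):
        cat = self._catalog()
        truth = [PlantedGene("s", "g0", 1.0, 75.0)]
        hits = simulate_gene_hits(truth, cat, seed=0)
        res = screen_sample(hits["s"], cat)
        assert res.loc["g0", "kept_hits"] == 0
        assert not bool(res.loc["g0", "present"])

    def test_merged_coverage_matches_planted_exactly(self):
        """Per-base oracle: union of emitted intervals == round(c * L)."""
        cat = self._catalog()
        rng = np.random.default_rng(0)
        truth = [
            PlantedGene("s", f"g{i}", float(c), 99.0)
            for i, c in enumerate(rng.uniform(0.1, 1.0, size=4))
        ]
        hits = simulate_gene_hits(truth, cat, seed=1)
        for rec in truth:
            mask = np.zeros(1000, dtype=bool)
            for h in hits["s"]:
                if h.gene_id == rec.gene_id:
                    mask[h.ref_start - 1 : h.ref_end] = True
            assert mask.sum() == round(rec.coverage * 1000)

    def test_absent_emits_no_hits(self):
        cat = self._catalog()
        truth = [PlantedGene("s", "g0", 1.0, 99.0, label="absent")]
        assert simulate_gene_hits(truth, cat, seed=0)["s"] == []

    def test_read_longer_than_gene_rejected(self):
        cat = GeneCatalog({"g0": 100})
        with pytest.raises(ValueError, match="read_len"):
            simulate_gene_hits([PlantedGene("s", "g0", 1.0, 99.0)], cat, read_len=150)


class TestPlantedPersistence:
    def test_presence_matrix_consistent_with_labels(self, longitudinal):
        _, meta = longitudinal
        cat = GeneCatalog({f"g{i}": 500 for i in range(20)})
        truth = plant_gene_truth(meta, cat, 3, 5, 6, seed=2)
        presence = plant_presence(truth)
        part = meta.column("participant_id")
        labels = {(t.sample_id, t.gene_id): t.label for t in truth}
        for gid in presence.index:
            gene_labels = {labels[(s, gid)] for s in presence.columns}
            if "cohort_stable" in gene_labels:
                assert presence.loc[gid].all()
            if gene_labels == {"absent"}:
                assert not presence.loc[gid].any()
        # individual-stable genes: all-present for carriers, absent elsewhere
        for gid in cat.gene_ids[3:8]:
            per_part = presence.loc[gid].groupby(part).mean()
            assert set(per_part.unique()) <= {0.0, 1.0}
            assert 0.0 < per_part.mean() < 1.0


class TestSequenceSets:
    def test_full_containment_identical_sets(self):
        a, b = simulate_sequence_sets(500, 1.0, seed=1)
        assert a == b

    def test_zero_containment_disjoint(self):
        a, b = simulate_sequence_sets(500, 0.0, seed=2)
        assert not (a & b)

    def test_exact_planted_containment(self):
        a, b = simulate_sequence_sets(10_000, 0.25, seed=3)
        assert len(a) == len(b) == 10_000
        assert abs(len(a & b) / 10_000 - 0.25) <= 1e-4

    def test_elements_are_canonical_31mers(self):
        from gutcohort.kmer import reverse_complement

        a, _ = simulate_sequence_sets(200, 0.5, seed=4)
        for m in list(a)[:50]:
            assert len(m) == 31 and set(m) <= set("ACGT")
            assert m <= reverse_complement(m)

    def test_invalid_containment_rejected(self):
        with pytest.raises(ValueError):
            simulate_sequence_sets(100, 1.5)
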