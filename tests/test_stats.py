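"""Dissimilarity, ordination, rank-sum and PERMANOVA machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gutcohort import AbundanceTable, DistanceMatrix, Metadata
from gutcohort.stats import (
    bray_curtis,
    factor_sweep,
    group_contrast,
    interval_classify,
    interval_contrast,
    pcoa,
    permanova,
    stability,
    wilcoxon,
)


def table_of(rows, samples=None):
    df = pd.DataFrame(rows)
    if samples:
        df.index = samples
    return AbundanceTable(df)


def meta_of(**cols):
    return Metadata(pd.DataFrame(cols))


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        t = table_of({"a": [50.0, 50.0], "b": [50.0, 50.0]})
        d = bray_curtis(t)
        assert d.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = table_of({"a": [100.0, 0.0], "b": [0.0, 100.0]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = table_of({"a": [6.0, 2.0], "b": [2.0, 2.0], "c": [2.0, 6.0]})
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.4)

    def test_all_zero_sample_rejected(self):
        t = table_of({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(t)

    def test_range_and_symmetry_on_random_tables(self):
        rng = np.random.default_rng(0)
        t = AbundanceTable(
            pd.DataFrame(rng.uniform(0, 10, size=(8, 20))).rename(columns=str)
        )
        d = bray_curtis(t)
        assert (d.values >= 0).all() and (d.values <= 1).all()
        assert np.allclose(d.values, d.values.T)

    def test_matches_scikit_bio(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, size=(6, 10))
        t = AbundanceTable(pd.DataFrame(x).rename(columns=str))
        ours = bray_curtis(t)
        ref = beta_diversity("braycurtis", x, ids=t.sample_ids)
        assert np.allclose(ours.values, ref.data)


class TestPcoa:
    def test_collinear_points_recovered_on_axis_one(self):
        # points at 0, 1, 3 on a line
        d = DistanceMatrix(
            np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]]),
            ["a", "b", "c"],
        )
        res = pcoa(d, n_axes=1)
        x = res.coordinates["PCo1"].to_numpy()
        for i, j in itertools.combinations(range(3), 2):
            assert abs(abs(x[i] - x[j]) - d.values[i, j]) < 1e-9

    def test_equilateral_simplex_two_equal_eigenvalues(self):
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ["a", "b", "c"])
        res = pcoa(d, n_axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.negative_eigen_fraction == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_samples_identical_coordinates(self):
        d = DistanceMatrix(
            np.array(
                [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
            ),
            ["a", "a2", "b"],
        )
        res = pcoa(d, n_axes=1)
        assert res.coordinates.loc["a"].to_numpy() == pytest.approx(
            res.coordinates.loc["a2"].to_numpy()
        )

    def test_too_many_axes_warns_and_truncates(self):
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), list("abc"))
        with pytest.warns(UserWarning, match="rank"):
            res = pcoa(d, n_axes=10)
        assert res.coordinates.shape[1] <= 2

    def test_matches_scikit_bio_on_euclidean_distances(self):
        import skbio

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(7)])
        ours = pcoa(d, n_axes=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.ids))
        assert np.allclose(
            np.abs(ours.coordinates.values),
            np.abs(ref.samples.values[:, :3]),
            atol=1e-8,
        )


def rank_sum_enumeration_p(x, y):
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    pooled = sorted(x + y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    n = len(pooled)
    us = []
    for combo in itertools.combinations(range(n), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n) if i not in combo]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    mean_u = nx * (n - nx) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return extreme / len(us)


class TestWilcoxon:
    def test_worked_two_plus_two_example(self):
        _, p = wilcoxon([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = wilcoxon([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = list(np.round(rng.normal(size=5), 6))
            y = list(np.round(rng.normal(size=5), 6))
            _, p = wilcoxon(x, y, method="exact")
            assert p == pytest.approx(rank_sum_enumeration_p(x, y))

    def test_exact_and_normal_agree_on_6_plus_6(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.5, 1, size=6)
            _, p_exact = wilcoxon(x, y, method="exact")
            _, p_norm = wilcoxon(x, y, method="normal")
            assert abs(p_exact - p_norm) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon([], [1.0])


class TestGroupContrast:
    def _distance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(4, 3))
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(squareform(pdist(pts)), ["s1", "s2", "s3", "s4"])

    def test_pair_counts_two_levels(self):
        d = self._distance()
        meta = meta_of(
            sample_id=["s1", "s2", "s3", "s4"],
            region=["A", "A", "B", "B"],
        )
        c = group_contrast(d, meta, "region")
        assert len(c.within) == 2 and len(c.between) == 4

    def test_single_level_rejected(self):
        d = self._distance()
        meta = meta_of(sample_id=["s1", "s2", "s3", "s4"], region=["A"] * 4)
        with pytest.raises(ValueError, match="single level"):
            group_contrast(d, meta, "region")

    def test_small_level_warns(self):
        d = self._distance()
        meta = meta_of(
            sample_id=["s1", "s2", "s3", "s4"], region=["A", "A", "A", "B"]
        )
        with pytest.warns(UserWarning, match="<2 samples"):
            c = group_contrast(d, meta, "region")
        assert len(c.within) == 3 and len(c.between) == 3


def exhaustive_permanova(d2, labels):
    """Full-enumeration oracle: R^2, F and exact permutation p."""
    labels = np.asarray(labels)
    n = len(labels)
    levels = sorted(set(labels))
    a = len(levels)

    def ss_within(lab):
        tot = 0.0
        for g in levels:
            idx = np.flatnonzero(lab == g)
            if len(idx):
                tot += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return tot

    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def f_of(lab):
        ssw = ss_within(lab)
        return ((ss_total - ssw) / (a - 1)) / (ssw / (n - a))

    f_obs = f_of(labels)
    r2 = (ss_total - ss_within(labels)) / ss_total
    fs = [f_of(np.array(p)) for p in set(itertools.permutations(labels))]
    p = sum(1 for f in fs if f >= f_obs - 1e-12) / len(fs)
    return r2, f_obs, p


class TestPermanova:
    def _fixture(self, n=6, seed=6):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        pts[n // 2 :] += 1.5
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(n)])
        meta = meta_of(
            sample_id=d.ids, region=["A"] * (n // 2) + ["B"] * (n - n // 2)
        )
        return d, meta

    def test_r2_and_f_match_exhaustive_oracle(self):
        d, meta = self._fixture()
        res = permanova(d, meta, "region", n_perm=999, seed=0)
        r2, f_obs, p_exact = exhaustive_permanova(
            d.values**2, meta.column("region", d.ids).to_numpy()
        )
        assert res.r_squared == pytest.approx(r2)
        assert res.pseudo_f == pytest.approx(f_obs)
        # sampled-permutation p within sampling error of the exact p
        assert abs(res.p_value - p_exact) < 0.08

    def test_r2_invariant_to_level_relabeling_and_order(self):
        d, meta = self._fixture(n=8)
        res1 = permanova(d, meta, "region", n_perm=99, seed=1)
        relabeled = Metadata(
            meta.df.assign(region=meta.df["region"].map({"A": "X", "B": "Y"})).reset_index(
                drop=True
            )
        )
        res2 = permanova(d, relabeled, "region", n_perm=99, seed=1)
        order = d.ids[::-1]
        res3 = permanova(d.submatrix(order), meta, "region", n_perm=99, seed=1)
        assert res1.r_squared == pytest.approx(res2.r_squared)
        assert res1.r_squared == pytest.approx(res3.r_squared)

    def test_p_reproducible_under_seed(self):
        d, meta = self._fixture(n=8)
        p1 = permanova(d, meta, "region", n_perm=199, seed=7).p_value
        p2 = permanova(d, meta, "region", n_perm=199, seed=7).p_value
        assert p1 == p2

    def test_separated_identical_groups_r2_near_one(self):
        block = np.zeros((4, 4))
        far = np.full((2, 2), 10.0)
        d = np.block([[block[:2, :2], far], [far, block[:2, :2]]])
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, list("abcd"))
        meta = meta_of(sample_id=list("abcd"), region=["A", "A", "B", "B"])
        res = permanova(dm, meta, "region", n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_level_rejected(self):
        d, meta = self._fixture()
        meta2 = Metadata(meta.df.assign(region="A").reset_index(drop=True))
        with pytest.raises(ValueError):
            permanova(d, meta2, "region")

    def test_matches_scikit_bio_pseudo_f(self):
        import skbio

        d, meta = self._fixture(n=10, seed=8)
        res = permanova(d, meta, "region", n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.ids),
            grouping=list(meta.column("region", d.ids)),
            permutations=0,
        )
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]))


class TestFactorSweep:
    def test_duplicate_factor_identical_r2_and_sorting(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(squareform(pdist(pts)), [f"s{i}" for i in range(8)])
        meta = meta_of(
            sample_id=d.ids,
            region=["A", "A", "A", "A", "B", "B", "B", "B"],
            region_copy=["A", "A", "A", "A", "B", "B", "B", "B"],
        )
        sweep = factor_sweep(d, meta, ["region", "region_copy"], n_perm=49, seed=0)
        assert sweep.loc["region", "r_squared"] == pytest.approx(
            sweep.loc["region_copy", "r_squared"]
        )
        assert list(sweep["r_squared"]) == sorted(sweep["r_squared"], reverse=True)

    def test_single_level_factor_skipped_with_warning(self):
        rng = np.random.default_rng(10)
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix(
            squareform(pdist(rng.normal(size=(4, 2)))), list("abcd")
        )
        meta = meta_of(sample_id=list("abcd"), region=["A"] * 4, site=list("XXYY"))
        with pytest.warns(UserWarning, match="skipped"):
            sweep = factor_sweep(d, meta, ["region", "site"], n_perm=19, seed=0)
        assert list(sweep.index) == ["site"]


class TestTemporal:
    @pytest.mark.parametrize(
        "mi,mj,expected",
        [(3, 4, "short"), (4, 3, "short"), (1, 8, "long"), (0, 7, "long"),
         (2, 6, "other"), (0, 6, "other"), (5, 5, "other")],
    )
    def test_interval_classification(self, mi, mj, expected):
        assert interval_classify(mi, mj) == expected

    def test_missing_month_rejected(self):
        with pytest.raises(ValueError):
            interval_classify(None, 3)

    def test_interval_contrast_only_within_participant(self, longitudinal):
        table, meta = longitudinal
        d = bray_curtis(table.renormalize())
        pairs = interval_contrast(d, meta)
        # every participant contributes C(12,2) pairs
        assert (pairs.groupby("participant_id").size() == 66).all()
        assert set(pairs["interval"]) == {"short", "long", "other"}


class TestStability:
    def _meta(self):
        return meta_of(
            sample_id=[f"{p}m{t}" for p in ("p1", "p2") for t in range(3)],
            participant_id=["p1"] * 3 + ["p2"] * 3,
            region=["R"] * 6,
            month_index=[0, 1, 2, 0, 1, 2],
        )

    def test_labels_and_cohort_flag(self):
        meta = self._meta()
        presence = pd.DataFrame(
            {
                "everywhere": [1, 1, 1, 1, 1, 1],
                "p1_only": [1, 1, 1, 0, 0, 0],
                "sometimes": [1, 0, 1, 0, 0, 0],
                "never": [0, 0, 0, 0, 0, 0],
            },
            index=meta.sample_ids,
        ).T.astype(bool)
        res = stability(presence, meta)
        assert res.label("everywhere", "p1") == "individual_stable"
        assert bool(res.cohort_stable["everywhere"])
        assert res.label("p1_only", "p1") == "individual_stable"
        assert res.label("p1_only", "p2") == "transient"
        assert not bool(res.cohort_stable["p1_only"])
        assert res.label("sometimes", "p1") == "transient"
        assert res.label("never", "p1") == "transient"

    def test_vf_rule_strictly_greater(self):
        meta = meta_of(
            sample_id=[f"m{t}" for t in range(5)],
            participant_id=["p1"] * 5,
            region=["R"] * 5,
            month_index=list(range(5)),
        )
        presence = pd.DataFrame(
            {"three_of_five": [1, 1, 1, 0, 0], "four_of_five": [1, 1, 1, 1, 0]},
            index=meta.sample_ids,
        ).T.astype(bool)
        res = stability(presence, meta, vf_fraction=0.6)
        assert not bool(res.vf_stable.loc[("three_of_five", "p1"), "vf_stable"])
        assert bool(res.vf_stable.loc[("four_of_five", "p1"), "vf_stable"])

    def test_single_sample_participant_excluded(self):
        meta = meta_of(
            sample_id=["a", "b", "c"],
            participant_id=["p1", "p1", "p2"],
            region=["R"] * 3,
            month_index=[0, 1, 0],
        )
        presence = pd.DataFrame({"f": [1, 1, 1]}, index=["a", "b", "c"]).T.astype(bool)
        with pytest.warns(UserWarning, match="excluded"):
            res = stability(presence, meta)
        assert ("f", "p2") not in res.per_participant.index
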