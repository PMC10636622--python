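"""Range standardization and Ward clustering, with brute-force and scipy
cross-checks."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sewersense as ss
from oracles import adjusted_rand, brute_force_ward


def df(values, index=None, columns=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1:
        arr = arr.T
    index = index or [f"p{i}" for i in range(arr.shape[0])]
    columns = columns or [f"f{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=index, columns=columns)


class TestRangeStandardize:
    def test_hand_example(self):
        out = ss.range_standardize(df([2.0, 4.0, 10.0]))
        np.testing.assert_allclose(out.frame["f0"], [0.0, 0.25, 1.0])

    def test_idempotent_on_spanned_unit_range(self):
        data = df([0.0, 0.3, 1.0])
        out = ss.range_standardize(data)
        np.testing.assert_allclose(out.frame, data)

    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        data = df([1.0, 3.0, 7.0, 2.0])
        out1 = ss.range_standardize(data).frame
        out2 = ss.range_standardize(a * data + b).frame
        np.testing.assert_allclose(out1, out2, atol=1e-9)

    def test_every_column_attains_zero_and_one(self, default_loads):
        wide = default_loads.pivot("cer_per_capita_ug_day")
        out = ss.range_standardize(wide)
        assert np.allclose(out.frame.min(axis=0), 0.0)
        assert np.allclose(out.frame.max(axis=0), 1.0)

    def test_constant_column_rejected_naming_analyte(self):
        data = df([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], columns=["ok", "flat"])
        with pytest.raises(ss.DegenerateDataError, match="flat"):
            ss.range_standardize(data)


class TestWardWorkedExample:
    """1-D points {0}, {1}, {5}: merges cost 0.5 then 13.5; total SS 14."""

    def run(self):
        data = df([0.0, 1.0, 5.0], index=["a", "b", "c"])
        return ss.ward_cluster(data)

    def test_merge_costs(self):
        _, merges = self.run()
        assert merges[0].cost == pytest.approx(0.5)
        assert merges[1].cost == pytest.approx(13.5)
        assert set(merges[0].members_a + merges[0].members_b) == {"a", "b"}

    def test_semipartial_r2_values_sum_to_one(self):
        _, merges = self.run()
        assert merges[0].semipartial_r2 == pytest.approx(0.5 / 14)
        assert merges[1].semipartial_r2 == pytest.approx(13.5 / 14)
        assert merges[0].semipartial_r2 == pytest.approx(0.0357, abs=1e-4)
        assert merges[1].semipartial_r2 == pytest.approx(0.9643, abs=1e-4)
        assert sum(m.semipartial_r2 for m in merges) == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_points_merge_first_at_zero_cost(self):
        data = df([3.0, 7.0, 3.0], index=["a", "b", "c"])
        _, merges = ss.ward_cluster(data)
        assert merges[0].cost == 0.0
        assert set(merges[0].members_a + merges[0].members_b) == {"a", "c"}


class TestWardProperties:
    def test_agrees_with_brute_force_ess_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, 5))
            data = df(rng.normal(size=(n, k)))
            _, merges = ss.ward_cluster(data)
            oracle = brute_force_ward(data.to_numpy(), list(data.index))
            assert len(merges) == len(oracle)
            for got, (ma, mb, cost) in zip(merges, oracle):
                assert set(got.members_a + got.members_b) == set(ma + mb)
                assert got.cost == pytest.approx(cost, rel=1e-9, abs=1e-12)

    def test_merge_heights_monotone_nondecreasing(self, rng):
        for _ in range(10):
            data = df(rng.normal(size=(10, 3)))
            _, merges = ss.ward_cluster(data)
            costs = [m.cost for m in merges]
            assert all(b >= a - 1e-12 for a, b in zip(costs, costs[1:]))

    def test_semipartial_r2_sums_to_one(self, rng):
        data = df(rng.normal(size=(12, 4)))
        _, merges = ss.ward_cluster(data)
        assert sum(m.semipartial_r2 for m in merges) == pytest.approx(1.0, abs=1e-9)

    def test_heights_match_scipy_ward(self, rng):
        from scipy.cluster.hierarchy import linkage

        data = df(rng.normal(size=(9, 3)))
        _, merges = ss.ward_cluster(data)
        z = linkage(data.to_numpy(), method="ward")
        # scipy reports h = sqrt(2 * delta-ESS)
        np.testing.assert_allclose(
            sorted(m.cost for m in merges), sorted(z[:, 2] ** 2 / 2), rtol=1e-9
        )

    def test_all_identical_plants_rejected(self):
        with pytest.raises(ss.DegenerateDataError):
            ss.ward_cluster(df([[1.0, 2.0]] * 4))

    def test_single_plant_rejected(self):
        with pytest.raises(ss.DomainError):
            ss.ward_cluster(df([[1.0]]))


class TestCutTree:
    def test_extreme_cuts(self, rng):
        data = df(rng.normal(size=(6, 2)))
        root, merges = ss.ward_cluster(data)
        assert ss.cut_tree(root, 6).nunique() == 6
        assert ss.cut_tree(root, 1).nunique() == 1
        with pytest.raises(ss.DomainError):
            ss.cut_tree(root, 0)
        with pytest.raises(ss.DomainError):
            ss.cut_tree(root, 7)

    def test_labels_ordered_by_smallest_member_id(self):
        data = df([0.0, 0.1, 10.0, 10.1], index=["d", "c", "b", "a"])
        root, _ = ss.ward_cluster(data)
        labels = ss.cut_tree(root, 2)
        # cluster containing 'a' gets label 0
        assert labels["a"] == 0 and labels["b"] == 0
        assert labels["c"] == 1 and labels["d"] == 1

    def test_planted_archetypes_recovered(self):
        """Three well-separated archetype profiles (offsets >= 5x the
        within-archetype spread) are recovered exactly at k=3 in >= 95% of
        seeds."""
        base = ss.null_config(0)
        features = list(ss.rates.CLUSTER_FEATURES)
        offsets = {
            0: {},
            1: {f: 3.0 for f in features},
            2: {f: 6.0 for f in features},
        }
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = replace(
                base,
                seed=seed,
                n_plants_west=6,
                n_plants_east=6,
                log_sd={a: 0.25 for a in base.analytes},
                correlation=None,
                triplicate_cv=0.05,
                flow_noise_cv=0.1,
                archetype_log_offsets=offsets,
                archetype_assignment=(0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2),
            )
            plants, measurements, truth = ss.generate_panel(cfg)
            loads = ss.compute_loads(plants, measurements)
            wide = np.log(loads.pivot("cer_per_capita_ug_day")[features])
            res = ss.WardClustering(wide).fit()
            labels = res.cut(3)
            truth_labels = truth.cluster_labels.sort_index()
            hits += adjusted_rand(truth_labels, labels[truth_labels.index]) == 1.0
        assert hits >= 0.95 * n_seeds


class TestExports:
    def test_newick_parses_and_preserves_leaves(self, tmp_path, default_loads):
        import dendropy

        wide = default_loads.pivot("cer_per_capita_ug_day")
        res = ss.WardClustering(wide[list(ss.rates.CLUSTER_FEATURES)]).fit()
        nwk = res.to_newick(tmp_path / "tree.nwk")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()}
        assert taxa == set(wide.index)

    def test_json_round_trips_and_matches_summary(self, tmp_path, default_loads):
        wide = default_loads.pivot("cer_per_capita_ug_day")
        res = ss.WardClustering(wide[list(ss.rates.CLUSTER_FEATURES)]).fit()
        res.to_json(tmp_path / "tree.json")
        loaded = json.loads((tmp_path / "tree.json").read_text())
        assert len(loaded["merges"]) == len(wide) - 1
        assert "Ward minimum-variance clustering" in res.summary()

    def test_linkage_matrix_is_valid_scipy_input(self, default_loads):
        from scipy.cluster.hierarchy import is_valid_linkage

        wide = default_loads.pivot("cer_per_capita_ug_day")
        res = ss.WardClustering(wide[list(ss.rates.CLUSTER_FEATURES)]).fit()
        assert is_valid_linkage(res._linkage_matrix())
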