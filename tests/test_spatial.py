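"""Composition, distances, networks, diversity, neighborhoods, interactions."""

import numpy as np
import pandas as pd
import pytest

from hifi.spatial import (
    build_network,
    cluster_neighborhoods,
    composition,
    neighborhoods,
    nn_distances,
    node_size,
    shannon_index,
    summarize_distances,
    test_interactions as run_interaction_test,
)
from hifi.synthetic import make_point_pattern


def _cells(coords_types, image_id="im0", group="g"):
    ys, xs, ts = zip(*coords_types)
    return pd.DataFrame(
        {"image_id": image_id, "group": group, "x_um": xs, "y_um": ys, "cell_type": ts}
    )


class TestComposition:
    def test_even_split(self):
        df = _cells([(i, 0, "A") for i in range(50)] + [(i, 5, "B") for i in range(50)])
        comp = composition(df)
        a = comp[comp.cell_type == "A"]
        assert a["percent"].iloc[0] == 50.0

    def test_region_only_b(self):
        df = _cells([(0, 0, "A"), (1, 1, "B"), (2, 2, "B")])
        df["in__vessel"] = [False, True, True]
        comp = composition(df, ["in__vessel"])
        vessel = comp[comp.region == "vessel"]
        assert list(vessel.cell_type) == ["B"]
        assert vessel["percent"].iloc[0] == 100.0

    def test_matches_direct_tally(self):
        df, _ = make_point_pattern(
            "csr", 500, ["A", "B", "C"], np.array([0.5, 0.3, 0.2]), seed=3
        )
        comp = composition(df)
        tally = df["cell_type"].value_counts()
        for _, row in comp.iterrows():
            assert row["count"] == tally[row["cell_type"]]
            assert row["percent"] == pytest.approx(100 * tally[row["cell_type"]] / len(df))

    def test_percents_sum_to_100(self):
        df, _ = make_point_pattern("csr", 333, ["A", "B", "C"], np.array([0.4, 0.4, 0.2]), seed=5)
        comp = composition(df)
        assert comp.groupby("image_id")["percent"].sum().iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            composition(_cells([(0, 0, "A")]).iloc[:0])


class TestNNDistances:
    def test_three_four_five(self):
        df = _cells([(0, 0, "A"), (3, 4, "B")])
        ds = nn_distances(df)
        ab = ds[(ds.type_a == "A") & (ds.type_b == "B")]
        assert ab["mean_dist"].iloc[0] == 5.0

    def test_coincident_populations_zero(self):
        pts = [(float(i), float(i)) for i in range(10)]
        df = _cells([(y, x, "A") for y, x in pts] + [(y, x, "B") for y, x in pts])
        ds = nn_distances(df)
        assert ds[(ds.type_a == "A") & (ds.type_b == "B")]["mean_dist"].iloc[0] == 0.0

    def test_matches_brute_force(self):
        df, _ = make_point_pattern(
            "csr", 200, ["A", "B"], np.array([0.5, 0.5]), window_um=(300, 300), seed=9
        )
        ds = nn_distances(df)
        xy = df[["y_um", "x_um"]].to_numpy()
        for ta in ("A", "B"):
            for tb in ("A", "B"):
                ia = np.flatnonzero(df.cell_type == ta)
                ib = np.flatnonzero(df.cell_type == tb)
                d = np.linalg.norm(xy[ia][:, None] - xy[ib][None], axis=2)
                if ta == tb:
                    np.fill_diagonal(d, np.inf)
                expected = d.min(axis=1).mean()
                got = ds[(ds.type_a == ta) & (ds.type_b == tb)]["mean_dist"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-9)

    def test_absent_type_missing_not_zero(self):
        df = _cells([(0, 0, "A"), (1, 1, "A")])
        ds = nn_distances(df)
        assert set(ds.type_a) == {"A"}
        assert "B" not in set(ds.type_b)


class TestShannon:
    def test_uniform_four_types(self):
        df = _cells([(i, 0, t) for t in "ABCD" for i in range(10)])
        h = shannon_index(composition(df))
        assert h["shannon"].iloc[0] == pytest.approx(np.log(4), abs=1e-9)

    def test_single_type_zero(self):
        df = _cells([(i, 0, "A") for i in range(10)])
        assert shannon_index(composition(df))["shannon"].iloc[0] == 0.0

    def test_half_quarter_quarter(self):
        df = _cells(
            [(i, 0, "A") for i in range(8)]
            + [(i, 1, "B") for i in range(4)]
            + [(i, 2, "C") for i in range(4)]
        )
        h = shannon_index(composition(df))["shannon"].iloc[0]
        assert h == pytest.approx(1.0397, abs=1e-4)

    def test_relabel_invariance_and_bound(self):
        r = np.random.default_rng(0)
        counts = r.integers(1, 50, 6)
        df1 = _cells([(i, k, f"T{k}") for k, c in enumerate(counts) for i in range(c)])
        df2 = _cells([(i, k, f"Z{5 - k}") for k, c in enumerate(counts) for i in range(c)])
        h1 = shannon_index(composition(df1))["shannon"].iloc[0]
        h2 = shannon_index(composition(df2))["shannon"].iloc[0]
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert h1 <= np.log(6) + 1e-12


class TestNeighborhoods:
    def test_isolated_cell_flagged(self):
        df = _cells([(0, 0, "A"), (500, 500, "B")])
        prof, _ = neighborhoods(df, radius_um=30)
        assert prof["isolated"].all()

    def test_fraction_counting(self):
        df = _cells([(0, 0, "X"), (0, 10, "A"), (10, 0, "A"), (0, -10, "B")])
        prof, types = neighborhoods(df, radius_um=15)
        row = prof.iloc[0]
        assert row["n_neighbors"] == 3
        assert row["A"] == pytest.approx(2 / 3)
        assert row["B"] == pytest.approx(1 / 3)

    def test_matches_brute_force_radius_query(self):
        df, _ = make_point_pattern(
            "csr", 300, ["A", "B", "C"], np.array([0.4, 0.3, 0.3]), window_um=(400, 400), seed=13
        )
        prof, types = neighborhoods(df, radius_um=30)
        xy = df[["y_um", "x_um"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None], axis=2)
        for i in range(len(df)):
            nbrs = np.flatnonzero((d[i] <= 30) & (np.arange(len(df)) != i))
            assert prof["n_neighbors"].iloc[i] == len(nbrs)
            if len(nbrs):
                fracs = df["cell_type"].iloc[nbrs].value_counts(normalize=True)
                for t in types:
                    assert prof[t].iloc[i] == pytest.approx(fracs.get(t, 0.0))

    def test_fractions_sum_to_one(self):
        df, _ = make_point_pattern("csr", 400, ["A", "B"], np.array([0.5, 0.5]), seed=17)
        prof, types = neighborhoods(df, radius_um=50)
        active = prof[~prof["isolated"]]
        np.testing.assert_allclose(active[types].sum(axis=1), 1.0)


class TestClusterNeighborhoods:
    def test_planted_niches_recovered(self):
        df, truth = make_point_pattern(
            "segregated", 1500, ["A", "B"], np.array([0.5, 0.5]),
            window_um=(600.0, 600.0), cluster_params={"gap_um": 100}, seed=21,
        )
        prof, types = neighborhoods(df, radius_um=30)
        cn, mean_comp, _ = cluster_neighborhoods(prof, types, k=2, seed=0)
        true_niche = (df["cell_type"] == "B").to_numpy().astype(int)
        agree = max((cn - 1 == true_niche).mean(), (cn - 1 != true_niche).mean())
        assert agree >= 0.95

    def test_k_one_everything_together(self):
        df, _ = make_point_pattern("csr", 100, ["A", "B"], np.array([0.5, 0.5]), seed=23)
        prof, types = neighborhoods(df)
        cn, _, _ = cluster_neighborhoods(prof, types, k=1)
        assert set(cn) == {1}

    def test_deterministic_under_seed(self):
        df, _ = make_point_pattern("csr", 300, ["A", "B", "C"], np.array([0.4, 0.3, 0.3]), seed=29)
        prof, types = neighborhoods(df)
        a, _, _ = cluster_neighborhoods(prof, types, k=4, seed=5)
        b, _, _ = cluster_neighborhoods(prof, types, k=4, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_composition_rows_sum_to_one(self):
        df, _ = make_point_pattern("csr", 500, ["A", "B", "C"], np.array([0.5, 0.3, 0.2]), seed=31)
        prof, types = neighborhoods(df)
        _, mean_comp, _ = cluster_neighborhoods(prof, types, k=3, seed=0)
        np.testing.assert_allclose(mean_comp[types].sum(axis=1), 1.0, atol=1e-9)


def _distance_summary(sds, mean=20.0):
    """DistanceSummary fixture over 4 types with constructed SDs."""
    types = ["A", "B", "C", "D"]
    rows = []
    i = 0
    for a in types:
        for b in types:
            if a == b:
                continue
            rows.append(
                {"group": "g", "type_a": a, "type_b": b, "mean": mean, "sd": sds[i % len(sds)]}
            )
            i += 1
    return pd.DataFrame(rows), types


class TestNetwork:
    def _comp(self, percents):
        return pd.DataFrame(
            {
                "image_id": "im0",
                "region": "all",
                "cell_type": list(percents),
                "count": [int(p * 10) for p in percents.values()],
                "percent": list(percents.values()),
            }
        )

    def test_node_size_endpoints(self):
        assert node_size(0.5) == 3
        assert node_size(1.0) == 3
        assert node_size(25.0) == 70
        assert node_size(30.0) == 70

    def test_node_size_monotone(self):
        sizes = [node_size(p) for p in np.linspace(0.5, 30, 100)]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))

    def test_equal_sds_all_edges_retained(self):
        ds, types = _distance_summary([5.0])
        comp = self._comp({t: 25.0 for t in types})
        net = build_network(ds, comp)
        assert net.graph.number_of_edges() == 6  # all unordered pairs

    def test_high_sd_edge_removed(self):
        # one pair's SD is 10x the median: its width 100/SD falls below
        # median(SD) * 0.8 and the edge is dropped
        ds, types = _distance_summary([5.0])
        ds.loc[(ds.type_a == "A") & (ds.type_b == "B"), "sd"] = 50.0
        ds.loc[(ds.type_a == "B") & (ds.type_b == "A"), "sd"] = 50.0
        comp = self._comp({t: 25.0 for t in types})
        net = build_network(ds, comp)
        assert not net.graph.has_edge("A", "B")
        assert net.graph.number_of_edges() == 5

    def test_exact_threshold_rule(self):
        r = np.random.default_rng(0)
        sds = r.uniform(2, 30, 12)
        ds, types = _distance_summary(list(sds))
        comp = self._comp({t: 25.0 for t in types})
        net = build_network(ds, comp)
        # recompute the rule from the symmetrized table
        sym = {}
        for _, row in ds.iterrows():
            key = tuple(sorted((row.type_a, row.type_b)))
            sym.setdefault(key, []).append(row.sd)
        pooled = {k: np.sqrt(np.mean(np.square(v))) for k, v in sym.items()}
        thr = np.median(list(pooled.values())) * 0.8
        for (a, b), sd in pooled.items():
            assert net.graph.has_edge(a, b) == (100.0 / sd >= thr)

    def test_row_order_invariance(self):
        r = np.random.default_rng(1)
        sds = r.uniform(2, 30, 12)
        ds, types = _distance_summary(list(sds))
        comp = self._comp({"A": 0.5, "B": 10.0, "C": 20.0, "D": 30.0})
        net1 = build_network(ds, comp, seed=3)
        net2 = build_network(ds.sample(frac=1, random_state=4), comp, seed=3)
        assert set(net1.graph.edges) == set(net2.graph.edges)
        assert net1.clusters == net2.clusters
        assert net1.graph.nodes["A"]["node_size"] == 3
        assert net1.graph.nodes["D"]["node_size"] == 70

    def test_fewer_than_two_types_rejected(self):
        ds = pd.DataFrame([{"group": "g", "type_a": "A", "type_b": "A", "mean": 1.0, "sd": 1.0}])
        comp = self._comp({"A": 100.0})
        with pytest.raises(ValueError, match="2 cell types"):
            build_network(ds, comp)


class TestInteractions:
    def test_extreme_observation_p_bound(self):
        # A and B tightly co-clustered far from a C background: observed
        # statistic above every permutation gives the add-one bound 1/1001
        rng = np.random.default_rng(0)
        ab = [(rng.uniform(0, 10), rng.uniform(0, 10), t) for t in ["A"] * 20 + ["B"] * 20]
        c = [(rng.uniform(400, 900), rng.uniform(400, 900), "C") for _ in range(200)]
        df = _cells([(y, x, t) for x, y, t in ab + c])
        res = run_interaction_test(df, radius_um=30, n_perm=1000, seed=1)
        p = res[(res.type_a == "A") & (res.type_b == "B")]["p_gt"].iloc[0]
        assert p == pytest.approx(1 / 1001)

    def test_sigval_signs(self):
        rng = np.random.default_rng(2)
        ab = [(rng.uniform(0, 30), rng.uniform(0, 30), t) for t in ["A"] * 30 + ["B"] * 30]
        far = [(rng.uniform(500, 900), rng.uniform(500, 900), "C") for _ in range(150)]
        df = _cells([(y, x, t) for x, y, t in ab + far])
        res = run_interaction_test(df, radius_um=30, n_perm=500, alpha=0.01, seed=3)
        assert res[(res.type_a == "A") & (res.type_b == "B")]["sigval"].iloc[0] == 1
        assert res[(res.type_a == "A") & (res.type_b == "C")]["sigval"].iloc[0] == -1

    def test_deterministic_under_seed(self):
        df, _ = make_point_pattern("csr", 150, ["A", "B"], np.array([0.5, 0.5]), seed=37)
        a = run_interaction_test(df, n_perm=200, seed=11)
        b = run_interaction_test(df, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_single_type_image_skipped(self):
        df = _cells([(i, 0, "A") for i in range(10)])
        res = run_interaction_test(df, n_perm=100, seed=0)
        assert res.empty
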