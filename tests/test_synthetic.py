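import json

import networkx as nx
import numpy as np
import pytest

from arealscan import (
    SimConfig,
    embed_cluster,
    expected_counts,
    generate,
    load_region_map,
    scan,
    write_bundle,
)
from arealscan.standardize import read_strata
from arealscan.sensitivity import read_undiagnosed


class TestGenerate:
    def test_same_seed_identical_bundle(self):
        b1 = generate(SimConfig(seed=42, n_regions=20, total_examinees=50_000))
        b2 = generate(SimConfig(seed=42, n_regions=20, total_examinees=50_000))
        assert b1.region_map == b2.region_map
        assert b1.counts.pop.equals(b2.counts.pop)
        assert b1.counts.cases.equals(b2.counts.cases)
        assert b1.truth == b2.truth

    def test_study_scale_totals(self):
        # grand totals near the emulated study: ~3e5 examinees, ~115 cases,
        # ~2.2e3 positives, ~2e2 undiagnosed (case total within 3 SD)
        b = generate(SimConfig(seed=99))
        t = b.truth["totals"]
        assert t["examinees"] == 295_032
        assert abs(t["cases"] - 115) <= 3 * np.sqrt(115)
        assert 1_800 <= t["screen_positive"] <= 2_700
        assert 120 <= t["undiagnosed"] <= 280

    def test_geography_connected_and_in_extent(self):
        b = generate(SimConfig(seed=3))
        assert b.region_map.n_regions == 59
        assert nx.is_connected(b.region_map.graph())
        assert b.region_map.coords[:, 0].max() <= 165.0
        assert b.region_map.coords[:, 1].max() <= 132.0

    def test_population_marginals_consistent(self):
        b = generate(SimConfig(seed=8, n_regions=15, total_examinees=10_000))
        assert int(b.counts.pop.to_numpy().sum()) == 10_000
        assert int(b.counts.stratum_cases.sum()) == int(b.counts.cases.sum())

    def test_homogeneous_pipeline_p_roughly_uniform(self):
        # end-to-end null check at reduced scale: generated studies run
        # through standardise + scan give p-values spread over (0, 1]
        ps = []
        for s in range(12):
            b = generate(SimConfig(seed=500 + s, n_regions=20, total_examinees=40_000, expected_total_cases=60.0))
            exp = expected_counts(b.counts)
            ps.append(scan(b.counts.cases, exp.expected, b.region_map, k_max=5, reps=39, seed=s).p_value)
        ps = np.array(ps)
        assert ps.min() < 0.9
        assert (ps > 0.1).sum() >= 6

    def test_zero_rates_zero_cases(self):
        with pytest.warns(UserWarning, match="degenerate"):
            b = generate(SimConfig(seed=1, n_regions=10, total_examinees=5_000, expected_total_cases=0.0))
        assert b.counts.total_cases == 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(screen_positive_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(clusters=((("contiguous", 3, "R00"), -1.0),))
        with pytest.raises(ValueError):
            SimConfig(layout="hexagon")


class TestEmbedCluster:
    def test_single_region_hotspot(self):
        b = generate(SimConfig(seed=4, n_regions=15))
        r, members = embed_cluster(b.region_map, ("contiguous", 1, "R03"), 2.5)
        assert members == ["R03"]
        assert r[b.region_map.index("R03")] == 2.5
        assert np.sum(r != 1.0) == 1

    def test_contiguous_rule_yields_connected_set(self):
        b = generate(SimConfig(seed=4))
        r, members = embed_cluster(b.region_map, ("contiguous", 8, "R10"), 3.0)
        assert len(members) == 8
        assert nx.is_connected(b.region_map.graph().subgraph(members))

    def test_radius_rule_members_within_radius(self):
        b = generate(SimConfig(seed=4))
        ci = b.region_map.index("R20")
        r, members = embed_cluster(b.region_map, ("radius", "R20", 25.0), 1.4)
        d = b.region_map.distances
        for m in members:
            assert d[ci, b.region_map.index(m)] <= 25.0

    def test_global_cluster_no_relative_signal(self):
        # uniform risk elevation is absorbed by conditioning on the total
        b = generate(SimConfig(seed=6, n_regions=20, total_examinees=40_000,
                               expected_total_cases=80.0,
                               clusters=((("contiguous", 20, "R00"), 3.0),)))
        assert np.all([v == 3.0 for v in b.truth["risk"].values()])
        exp = expected_counts(b.counts)
        res = scan(b.counts.cases, exp.expected, b.region_map, k_max=5, reps=99, seed=0)
        assert res.p_value > 0.05

    def test_disconnected_member_request_rejected(self):
        from conftest import make_map

        # B sits between A and C spatially but is only adjacent to neither:
        # a radius window around A then selects a disconnected member set
        rm = make_map(
            ["A", "B", "C"],
            [[0, 0], [10, 0], [20, 0]],
            [("A", "C")],
        )
        with pytest.raises(ValueError, match="disconnected"):
            embed_cluster(rm, ("radius", "A", 25.0), 2.0)

    def test_unknown_rule_rejected(self, line9):
        with pytest.raises(ValueError, match="unknown cluster rule"):
            embed_cluster(line9, ("lasso", 1), 2.0)


class TestRoundTrip:
    def test_bundle_files_round_trip(self, tmp_path):
        b = generate(SimConfig(seed=13, n_regions=12, total_examinees=20_000, expected_total_cases=30.0))
        paths = write_bundle(b, tmp_path)
        rm = load_region_map(paths["regions"], paths["adjacency"])
        assert rm.region_ids == b.region_map.region_ids
        assert rm.edges == b.region_map.edges
        assert np.allclose(rm.distances, b.region_map.distances)
        counts = read_strata(paths["strata"])
        assert counts.pop.astype(int).equals(b.counts.pop.astype(int))
        assert counts.cases.astype(int).equals(b.counts.cases.astype(int))
        assert counts.stratum_cases.reindex(b.counts.stratum_cases.index).equals(b.counts.stratum_cases)
        u = read_undiagnosed(paths["undiagnosed"], counts.pop.columns)
        assert u.reindex(b.pool.u.index).equals(b.pool.u.astype(int))
        truth = json.loads(paths["truth"].read_text())
        assert truth["totals"] == b.truth["totals"]
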