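import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from arealscan import (
    embed_cluster,
    enumerate_windows,
    expected_counts,
    generate,
    scan,
    scan_circular,
    window_statistic,
    SimConfig,
)
from arealscan.scan import enumerate_windows_circular

from conftest import make_map


class TestWindowStatistic:
    def test_printed_cluster_relative_risk(self):
        llr, rr = window_statistic(42, 29.76, 115, 115)
        assert round(rr, 3) == 1.411
        assert llr > 0

    def test_boundary_rate_equality_gives_zero(self):
        # inside rate exactly equals outside rate
        llr, rr = window_statistic(5, 5, 10, 10)
        assert llr == 0.0

    def test_hand_evaluated_closed_form(self):
        llr, _ = window_statistic(5, 1, 10, 10)
        assert llr == pytest.approx(5 * math.log(5) + 5 * math.log(5 / 9))

    def test_deficit_window_scores_zero(self):
        llr, rr = window_statistic(1, 5, 10, 10)
        assert llr == 0.0
        assert rr == pytest.approx(0.2)

    def test_all_cases_inside(self):
        llr, _ = window_statistic(10, 2, 10, 10)
        assert llr == pytest.approx(10 * math.log(5))

    @pytest.mark.parametrize("o_z,e_z", [(5, 0.0), (5, 10.0), (5, 12.0), (-1, 3.0), (11, 3.0)])
    def test_preconditions_rejected(self, o_z, e_z):
        with pytest.raises(ValueError):
            window_statistic(o_z, e_z, 10, 10)


class TestEnumeration:
    def test_path_graph_excludes_disconnected_pair(self, path3):
        wins = set(enumerate_windows(path3, 3))
        expected = {
            frozenset({"A"}), frozenset({"B"}), frozenset({"C"}),
            frozenset({"A", "B"}), frozenset({"B", "C"}), frozenset({"A", "B", "C"}),
        }
        assert wins == expected

    def test_star_graph_k2(self, star5):
        wins = set(enumerate_windows(star5, 2))
        singles = {frozenset({r}) for r in star5.region_ids}
        pairs = {frozenset({"S", l}) for l in ("L1", "L2", "L3", "L4")}
        assert wins == singles | pairs

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_bruteforce_connected_subsets(self, trial):
        rng = np.random.default_rng(trial)
        n = 8
        g = nx.gnp_random_graph(n, 0.45, seed=trial)
        ids = [f"N{i}" for i in range(n)]
        rm = make_map(ids, rng.uniform(0, 10, (n, 2)), [(ids[a], ids[b]) for a, b in g.edges])
        flex = set(enumerate_windows(rm, n))
        gg = rm.graph()
        brute = {
            frozenset(comb)
            for k in range(1, n + 1)
            for comb in combinations(ids, k)
            if nx.is_connected(gg.subgraph(comb))
        }
        assert flex == brute

    def test_kmax_clamped_with_warning(self, path3):
        with pytest.warns(UserWarning, match="clamp"):
            wins = list(enumerate_windows(path3, 10))
        assert len(wins) == 6

    def test_circular_windows_are_nested_neighbour_sets(self, line9):
        wins = set(enumerate_windows_circular(line9, 3))
        assert frozenset({"P0", "P1", "P2"}) in wins
        assert frozenset({"P4", "P3", "P5"}) in wins
        assert all(len(w) <= 3 for w in wins)


class TestScan:
    def test_dominant_singleton_detected(self, line9):
        o = np.array([0, 0, 0, 0, 20, 0, 0, 0, 0], dtype=float)
        e = np.full(9, 20 / 9)
        res = scan(o, e, line9, k_max=3, reps=99, seed=1)
        assert res.most_likely.members == ("P4",)
        assert res.p_value <= 0.05

    def test_all_zero_cases_p_one(self, line9):
        res = scan(np.zeros(9), np.zeros(9), line9, reps=99, seed=0, k_max=3)
        assert res.most_likely.llr == 0.0
        assert res.p_value == 1.0

    def test_uniform_cases_llr_zero_p_one(self, line9):
        o = np.full(9, 2.0)
        e = np.full(9, 2.0)
        res = scan(o, e, line9, k_max=3, reps=99, seed=0)
        assert res.most_likely.llr == 0.0
        assert res.p_value == 1.0

    def test_p_value_within_mc_bounds_and_reproducible(self, line9):
        rng = np.random.default_rng(3)
        e = np.full(9, 5.0)
        o = rng.multinomial(45, e / 45).astype(float)
        r1 = scan(o, e, line9, k_max=4, reps=99, seed=12)
        r2 = scan(o, e, line9, k_max=4, reps=99, seed=12)
        assert 1 / 100 <= r1.p_value <= 1.0
        assert r1.p_value == r2.p_value
        assert r1.most_likely == r2.most_likely

    def test_best_llr_monotone_in_kmax(self, study):
        exp = expected_counts(study.counts)
        best = []
        for k in (1, 3, 6, 10):
            res = scan(study.counts.cases, exp.expected, study.region_map, k_max=k, reps=1, seed=0)
            best.append(res.most_likely.llr)
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_kmax1_circular_equals_flexible_equals_region_max(self, line9):
        o = np.array([1, 0, 3, 0, 1, 0, 0, 0, 0], dtype=float)
        e = np.full(9, 5 / 9)
        rf = scan(o, e, line9, k_max=1, reps=99, seed=5)
        rc = scan_circular(o, e, line9, k_max=1, reps=99, seed=5)
        assert rf.most_likely == rc.most_likely
        assert rf.most_likely.members == ("P2",)

    def test_flexible_best_llr_at_least_circular(self, line9):
        # on a line with contiguity = neighbours, every circular window is connected
        rng = np.random.default_rng(9)
        e = np.full(9, 4.0)
        for _ in range(5):
            o = rng.multinomial(36, e / 36).astype(float)
            rf = scan(o, e, line9, k_max=4, reps=1, seed=0)
            rc = scan_circular(o, e, line9, k_max=4, reps=1, seed=0)
            assert rf.most_likely.llr >= rc.most_likely.llr - 1e-12

    def test_interval_truth_agreement_on_line(self, line9):
        # an interval-shaped hotspot: both window families contain the truth
        o = np.array([0, 0, 0, 8, 9, 7, 0, 0, 0], dtype=float)
        e = np.full(9, 24 / 9)
        rf = scan(o, e, line9, k_max=3, reps=99, seed=2)
        rc = scan_circular(o, e, line9, k_max=3, reps=99, seed=2)
        assert set(rf.most_likely.members) == {"P3", "P4", "P5"}
        assert set(rc.most_likely.members) == {"P3", "P4", "P5"}

    def test_embedded_cluster_recovery(self):
        # RR=3 cluster of 5 contiguous regions at study scale: the detected
        # window should overlap the truth (Jaccard > 0.5) in most runs
        # window bound matched to the designed cluster size, as a recovery
        # power study would set it
        hits = 0
        runs = 30
        for t in range(runs):
            cfg = SimConfig(seed=300 + t, clusters=((("contiguous", 5, "R20"), 3.0),))
            b = generate(cfg)
            exp = expected_counts(b.counts)
            res = scan(b.counts.cases, exp.expected, b.region_map, k_max=5, reps=19, seed=t)
            truth = set(b.truth["clusters"][0]["members"])
            got = set(res.most_likely.members)
            jac = len(truth & got) / len(truth | got)
            hits += jac > 0.5
        assert hits >= 0.8 * runs

    def test_secondary_clusters_disjoint_and_ordered(self, line9):
        o = np.array([6, 0, 0, 0, 8, 0, 0, 0, 6], dtype=float)
        e = np.full(9, 20 / 9)
        res = scan(o, e, line9, k_max=2, reps=99, seed=4)
        members = [set(res.most_likely.members)] + [set(w.members) for w in res.secondary]
        for a, b in combinations(members, 2):
            assert not (a & b)
        llrs = [res.most_likely.llr] + [w.llr for w in res.secondary]
        assert llrs == sorted(llrs, reverse=True)
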