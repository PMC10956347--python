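import math
from collections import Counter, deque
from types import SimpleNamespace

import networkx as nx
import numpy as np
import pytest

from netprio import data_io, proximity
from netprio.data_io import DrugRecord, Interactome
from netprio.exceptions import UndefinedDistanceError

from conftest import make_interactome


def bfs_closest_distance(targets, degs, graph: nx.Graph) -> float:
    """Brute-force oracle: per-target BFS to the nearest disease gene."""
    total = 0.0
    for t in targets:
        dist = {t: 0}
        queue = deque([t])
        best = math.inf
        while queue:
            node = queue.popleft()
            if node in degs:
                best = dist[node]
                break  # BFS pops in distance order: first hit is nearest
            for nb in graph.neighbors(node):
                if nb not in dist:
                    dist[nb] = dist[node] + 1
                    queue.append(nb)
        total += best
    return total / len(targets)


class TestClosestDistance:
    @pytest.mark.parametrize(
        "targets, degs, expected",
        [({3}, {1}, 2.0), ({2, 4}, {1, 5}, 1.0), ({2, 3}, {1, 2, 3}, 0.0)],
    )
    def test_path_graph_examples(self, path_graph, targets, degs, expected):
        assert proximity.closest_distance(targets, degs, path_graph) == expected

    def test_zero_iff_targets_subset_of_degs(self, path_graph):
        assert proximity.closest_distance({2}, {2, 5}, path_graph) == 0.0
        assert proximity.closest_distance({2, 3}, {2, 5}, path_graph) > 0.0

    def test_out_of_network_degs_ignored(self, path_graph):
        d = proximity.closest_distance({3}, {1, 999}, path_graph)
        assert d == 2.0

    def test_no_in_network_deg_undefined(self, path_graph):
        with pytest.raises(UndefinedDistanceError):
            proximity.closest_distance({3}, {999}, path_graph)

    def test_agrees_with_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(4, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31 - 1)))
            comp = max(nx.connected_components(g), key=len)
            if len(comp) < 3:
                continue
            inter = Interactome(g.subgraph(comp).copy())
            nodes = sorted(comp)
            targets = set(rng.choice(nodes, size=min(3, len(nodes)), replace=False).tolist())
            degs = set(rng.choice(nodes, size=min(4, len(nodes)), replace=False).tolist())
            got = proximity.closest_distance(targets, degs, inter)
            want = bfs_closest_distance(targets, degs, inter.graph)
            assert got == pytest.approx(want, abs=1e-8)

    def test_monotone_in_deg_set(self, interactome):
        rng = np.random.default_rng(0)
        nodes = sorted(interactome.nodes)
        for _ in range(20):
            targets = set(rng.choice(nodes, size=3, replace=False).tolist())
            degs = set(rng.choice(nodes, size=5, replace=False).tolist())
            extra = int(rng.choice(nodes))
            d1 = proximity.closest_distance(targets, degs, interactome)
            d2 = proximity.closest_distance(targets, degs | {extra}, interactome)
            assert d2 <= d1


def stub_graph(degree: dict[int, int]):
    return SimpleNamespace(degree=degree)


class TestDegreeBins:
    def test_two_full_bins(self):
        deg = {i: 1 for i in range(250)} | {i: 2 for i in range(250, 500)}
        bins = proximity.build_degree_bins(stub_graph(deg), min_size=100)
        assert [len(b) for b in bins.bins] == [250, 250]

    def test_trailing_undersized_bin_merges_back(self):
        deg = {i: 1 for i in range(150)} | {i: 9 for i in range(150, 180)}
        bins = proximity.build_degree_bins(stub_graph(deg), min_size=100)
        assert [len(b) for b in bins.bins] == [180]

    def test_small_graph_single_bin(self):
        deg = {i: i % 5 + 1 for i in range(50)}
        bins = proximity.build_degree_bins(stub_graph(deg), min_size=100)
        assert len(bins.bins) == 1 and len(bins.bins[0]) == 50

    def test_bins_partition_nodes_with_ascending_degrees(self, interactome):
        bins = proximity.build_degree_bins(interactome, min_size=20)
        seen = set()
        prev_max = -1
        for arr in bins.bins:
            members = set(int(x) for x in arr)
            assert not members & seen
            seen |= members
            degrees = sorted(interactome.degree[g] for g in members)
            assert degrees[0] > prev_max
            prev_max = degrees[-1]
        assert seen == interactome.nodes
        assert all(len(b) >= 20 for b in bins.bins)


class TestSampleDegreeMatched:
    def test_preserves_bin_multiset(self, interactome):
        bins = proximity.build_degree_bins(interactome, min_size=20)
        rng = np.random.default_rng(3)
        nodes = sorted(interactome.nodes)
        for _ in range(50):
            genes = set(rng.choice(nodes, size=8, replace=False).tolist())
            sampled = proximity.sample_degree_matched(genes, bins, rng)
            assert len(sampled) == len(genes)
            assert Counter(bins.bin_of[g] for g in genes) == Counter(
                bins.bin_of[g] for g in sampled
            )

    def test_deterministic_under_seed(self, interactome):
        bins = proximity.build_degree_bins(interactome, min_size=20)
        genes = sorted(interactome.nodes)[:10]
        a = proximity.sample_degree_matched(genes, bins, np.random.default_rng(11))
        b = proximity.sample_degree_matched(genes, bins, np.random.default_rng(11))
        assert a == b

    def test_forced_when_whole_bin_requested(self):
        inter = make_interactome([(1, 2), (2, 3), (3, 1)])  # triangle: one bin
        bins = proximity.build_degree_bins(inter, min_size=3)
        out = proximity.sample_degree_matched({1, 2, 3}, bins, np.random.default_rng(0))
        assert out == {1, 2, 3}

    def test_overfull_bin_request_fatal(self):
        inter = make_interactome([(1, 2), (2, 3), (3, 1), (3, 4)])
        bins = proximity.build_degree_bins(inter, min_size=10)
        with pytest.raises(ValueError, match="draws"):
            # a multiset request larger than the bin cannot be honoured
            proximity.sample_degree_matched([1, 2, 3, 4, 1], bins, np.random.default_rng(0))
        # a legitimate full-bin draw still works
        assert len(proximity.sample_degree_matched({1, 2, 3, 4}, bins,
                                                   np.random.default_rng(0))) == 4

    def test_selection_frequency_uniform_within_bin(self):
        g = nx.path_graph(range(1, 9))
        inter = Interactome(g)
        bins = proximity.build_degree_bins(inter, min_size=8)
        rng = np.random.default_rng(5)
        counts = Counter()
        n_draws = 10_000
        for _ in range(n_draws):
            counts.update(proximity.sample_degree_matched({1}, bins, rng))
        expected = n_draws / 8
        se = math.sqrt(n_draws * (1 / 8) * (7 / 8))
        for gene in range(1, 9):
            assert abs(counts[gene] - expected) < 3.5 * se


def make_drug(drug_id, targets, action="inhibit"):
    return DrugRecord(drug_id=drug_id, name=drug_id.lower(),
                      targets=frozenset(targets), action={t: action for t in targets})


def make_degs(cell_type, logfc_map, inter):
    import pandas as pd
    df = pd.DataFrame({
        "gene": list(logfc_map), "logfc": list(logfc_map.values()),
        "padj": [1e-6] * len(logfc_map),
        "in_network": [g in inter.nodes for g in logfc_map],
    })
    return data_io.CellTypeDEGs(cell_type=cell_type, table=df)


class TestProximityZ:
    def test_z_relation_and_reproducibility(self, interactome):
        bins = proximity.build_degree_bins(interactome, min_size=20)
        drug = make_drug("D1", sorted(interactome.nodes)[:3])
        degs = make_degs("A", {g: 2.0 for g in sorted(interactome.nodes)[10:20]}, interactome)
        r1 = proximity.proximity_z(drug, degs, interactome, bins, n_iter=100, seed=7)
        r2 = proximity.proximity_z(drug, degs, interactome, bins, n_iter=100, seed=7)
        assert r1 == r2  # bit-identical under a fixed seed
        assert r1.z_c == pytest.approx((r1.d_c - r1.null_mean) / r1.null_sd)

    def test_degenerate_null_gives_nan_sentinel(self):
        inter = make_interactome([(a, b) for a in range(1, 5) for b in range(a + 1, 5)])
        bins = proximity.build_degree_bins(inter, min_size=4)
        drug = make_drug("D1", [1, 2, 3, 4])
        degs = make_degs("A", {g: 2.0 for g in [1, 2, 3, 4]}, inter)
        r = proximity.proximity_z(drug, degs, inter, bins, n_iter=50, seed=0)
        assert math.isnan(r.z_c) and r.null_sd == 0.0
        assert proximity.select_candidates([r]) == {"A": set()}

    def test_n_iter_too_small_fatal(self, interactome):
        bins = proximity.build_degree_bins(interactome, min_size=20)
        drug = make_drug("D1", sorted(interactome.nodes)[:2])
        degs = make_degs("A", {1: 2.0}, interactome)
        with pytest.raises(ValueError):
            proximity.proximity_z(drug, degs, interactome, bins, n_iter=1, seed=0)


class TestSelectCandidates:
    @pytest.mark.parametrize(
        "d_c, z_c, selected",
        [(0.5, -2.0, True), (1.0, -3.0, False), (0.2, -1.64, False), (0.99, -1.65, True)],
    )
    def test_strict_dual_cutoff(self, d_c, z_c, selected):
        r = proximity.ProximityResult(
            cell_type="A", drug_id="D1", d_c=d_c, null_mean=1.0, null_sd=1.0,
            z_c=z_c, n_iter=100, seed=0,
        )
        out = proximity.select_candidates([r])
        assert ("D1" in out["A"]) is selected
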