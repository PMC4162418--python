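"""Transformation graph maintenance and chain resolution."""

import numpy as np
import pytest

from atlasdai import (
    AffineTransform,
    PointSet,
    TransformationGraph,
    TransformationRecord,
    compose,
)
from atlasdai.errors import DuplicateCode, NoPathFound, SRSMismatch, \
    UnknownSRS

from conftest import make_node_registry


def translation_record(code, src, dst, hub="hub", offset=1.0,
                       version="1.0"):
    return TransformationRecord(
        code=code, source_srs=src, target_srs=dst, hub=hub,
        method=AffineTransform.translation([offset, 0.0, 0.0]),
        version=version)


def bfs_shortest(edges, n_nodes, src, dst):
    """Independent breadth-first search oracle on an adjacency set."""
    adj = {i: set() for i in range(1, n_nodes + 1)}
    for a, b in edges:
        adj[a].add(b)
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist.get(dst)


class TestAddTransformation:
    def test_added_edge_is_listed(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        g.add_transformation(translation_record(
            "T:1", "INCF:0100", "INCF:0001", hub="ABA"))
        assert [r.code for r in g.list_transformations()] == ["T:1"]

    def test_duplicate_code_rejected(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        g.add_transformation(translation_record("T:1", "INCF:0100",
                                                "INCF:0001"))
        with pytest.raises(DuplicateCode):
            g.add_transformation(translation_record("T:1", "INCF:0101",
                                                    "INCF:0001"))

    def test_unknown_srs_rejected(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        with pytest.raises(UnknownSRS):
            g.add_transformation(translation_record("T:1", "INCF:9999",
                                                    "INCF:0001"))


class TestResolveChain:
    def test_two_hub_worked_example(self, table1):
        """AGEA -> Paxinos routes through WHS 0.9 across two hubs."""
        _, graph = table1
        chain = graph.resolve_chain("Mouse_AGEA_1.0", "Mouse_Paxinos_1.0")
        assert len(chain) == 2
        assert chain.hubs == ("ABA", "UCSD")
        assert chain.intermediate_srs == ("INCF:0001",)
        assert [s.order for s in chain.steps] == [1, 2]

    def test_same_srs_resolves_to_empty_chain(self, table1):
        _, graph = table1
        chain = graph.resolve_chain("INCF:0001", "Mouse_WHS_0.9")
        assert len(chain) == 0

    def test_no_path_raises(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        with pytest.raises(NoPathFound):
            g.resolve_chain("INCF:0001", "INCF:0200")

    def test_never_auto_inverts_one_way_edges(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        g.add_transformation(translation_record("T:1", "INCF:0100",
                                                "INCF:0001"))
        assert len(g.resolve_chain("INCF:0100", "INCF:0001")) == 1
        with pytest.raises(NoPathFound):
            g.resolve_chain("INCF:0001", "INCF:0100")

    @pytest.mark.parametrize("seed", range(25))
    def test_step_count_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        reg = make_node_registry(n)
        n_edges = int(rng.integers(n, 3 * n))
        edges = []
        for i in range(n_edges):
            a, b = rng.choice(np.arange(1, n + 1), size=2, replace=False)
            edges.append((int(a), int(b)))
        g = TransformationGraph(registry=reg)
        for i, (a, b) in enumerate(edges):
            g.add_transformation(translation_record(
                f"T:{i:03d}", f"LOCAL:{a:04d}", f"LOCAL:{b:04d}"))
        src, dst = 1, n
        expected = bfs_shortest(edges, n, src, dst)
        if expected is None:
            with pytest.raises(NoPathFound):
                g.resolve_chain(f"LOCAL:{src:04d}", f"LOCAL:{dst:04d}")
        else:
            chain = g.resolve_chain(f"LOCAL:{src:04d}", f"LOCAL:{dst:04d}")
            assert len(chain) == expected

    def test_deterministic_across_insertion_orders(self):
        rng = np.random.default_rng(42)
        reg = make_node_registry(6)
        edges = [(1, 2), (2, 6), (1, 3), (3, 6), (1, 4), (4, 6), (1, 6),
                 (2, 3), (5, 6)]
        records = [translation_record(f"T:{i:03d}", f"LOCAL:{a:04d}",
                                      f"LOCAL:{b:04d}")
                   for i, (a, b) in enumerate(edges)]
        chains = []
        for _ in range(5):
            order = rng.permutation(len(records))
            g = TransformationGraph(registry=make_node_registry(6))
            for i in order:
                g.add_transformation(records[i])
            chains.append(g.resolve_chain("LOCAL:0001", "LOCAL:0006"))
        assert all(c == chains[0] for c in chains)

    def test_parallel_edges_prefer_highest_version(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        g.add_transformation(translation_record("T:B", "INCF:0100",
                                                "INCF:0001", version="1.0"))
        g.add_transformation(translation_record("T:A", "INCF:0100",
                                                "INCF:0001", version="2.0"))
        chain = g.resolve_chain("INCF:0100", "INCF:0001")
        assert chain.steps[0].transformation_code == "T:A"

    def test_whs_intermediate_preferred_over_peer(self):
        """At equal length, the go-between WHS route wins the tie."""
        from conftest import minimal_srs
        from atlasdai import Registry
        reg = Registry()
        reg.register_srs(minimal_srs("LOCAL:0001", "SrcX", family="A"))
        reg.register_srs(minimal_srs("LOCAL:0002", "MidPlain", family="B"))
        reg.register_srs(minimal_srs("LOCAL:0003", "MidWHS", family="WHS"))
        reg.register_srs(minimal_srs("LOCAL:0004", "DstX", family="C"))
        g = TransformationGraph(registry=reg)
        for code, a, b in [("T:0", "LOCAL:0001", "LOCAL:0002"),
                           ("T:1", "LOCAL:0002", "LOCAL:0004"),
                           ("T:2", "LOCAL:0001", "LOCAL:0003"),
                           ("T:3", "LOCAL:0003", "LOCAL:0004")]:
            g.add_transformation(translation_record(code, a, b))
        chain = g.resolve_chain("LOCAL:0001", "LOCAL:0004")
        assert chain.intermediate_srs == ("LOCAL:0003",)


class TestExecuteChain:
    def test_translation_and_inverse_cancel(self, table1):
        reg, _ = table1
        g = TransformationGraph(registry=reg)
        fwd = AffineTransform.translation([1.0, 2.0, 3.0])
        g.add_transformation(TransformationRecord(
            code="T:F", source_srs="INCF:0100", target_srs="INCF:0001",
            hub="h", method=fwd))
        g.add_transformation(TransformationRecord(
            code="T:B", source_srs="INCF:0001", target_srs="INCF:0100",
            hub="h", method=fwd.inverse()))
        chain = g.resolve_chain("INCF:0100", "INCF:0100")
        assert len(chain) == 0  # same SRS: no steps
        ps = PointSet(srs_name="INCF:0100",
                      points=np.array([[1.0, 1.0, 1.0]]))
        out = g.execute_chain(g.resolve_chain("INCF:0100", "INCF:0001"), ps)
        back = g.execute_chain(g.resolve_chain("INCF:0001", "INCF:0100"),
                               out)
        assert np.abs(back.points - ps.points).max() <= 1e-9

    def test_execution_equals_composed_transforms(self, table1):
        reg, graph = table1
        chain = graph.resolve_chain("INCF:0102", "INCF:0200")
        recs = [graph.get_transformation(s.transformation_code)
                for s in chain.steps]
        composite = compose(recs)
        ps = PointSet(srs_name="INCF:0102",
                      points=np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        out = graph.execute_chain(chain, ps)
        assert np.abs(out.points - composite(ps.points)).max() <= 1e-9
        assert out.srs_name == "INCF:0200"

    def test_wrong_input_srs_rejected(self, table1):
        _, graph = table1
        chain = graph.resolve_chain("INCF:0102", "INCF:0200")
        ps = PointSet(srs_name="INCF:0100",
                      points=np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(SRSMismatch):
            graph.execute_chain(chain, ps)


class TestStarTopology:
    def test_all_non_hub_pairs_take_two_steps(self, table1):
        """With every SRS linked only to the go-between space, any chain
        between two other systems is exactly two steps."""
        reg, graph = table1
        others = [d.code for d in reg.list_srs() if d.code != "INCF:0001"]
        for a in others:
            for b in others:
                if a != b:
                    assert len(graph.resolve_chain(a, b)) == 2

    def test_round_trip_error_bounded_by_step_consistency(self, table1):
        reg, graph = table1
        fwd = graph.resolve_chain("INCF:0102", "INCF:0200")
        rev = graph.resolve_chain("INCF:0200", "INCF:0102")
        ps = PointSet(srs_name="INCF:0102",
                      points=np.random.default_rng(1).uniform(2, 8, (20, 3)))
        back = graph.execute_chain(rev, graph.execute_chain(fwd, ps))
        err = np.linalg.norm(back.points - ps.points, axis=1).max()
        budget = sum(s.mean_error
                     for s in graph.chain_consistency(fwd) if s) \
            + sum(s.mean_error for s in graph.chain_consistency(rev) if s)
        assert err <= budget + 1e-9
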