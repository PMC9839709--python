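import pytest

from karyograph import simulate
from karyograph.alignio import AlignmentRecord
from karyograph.mdm import (
    DegenerateSplitError,
    DiscordantRegion,
    decide_misassembly,
    find_discordant_regions,
    run_mdm,
    split_node,
)
from karyograph.mgraph import build_graph


def oracle_decide(n_a, n_b, n_s, n):
    """Independent re-statement of the four decision conditions."""
    conds = [
        n_a >= n / 2,
        n_b == 0 and n_a >= 2,
        n_a >= 2 and n_b / n_a <= 0.5,
        n_s > 0 and n_a >= 1 and (n_b - n_s) / n_a <= 0.6,
    ]
    return any(conds)


class TestDecisionRule:
    def test_exhaustive_truth_table(self):
        """Exact agreement with brute-force enumeration over the full grid."""
        for n in range(3, 13):
            for n_a in range(13):
                for n_b in range(13):
                    for n_s in range(13):
                        assert decide_misassembly(n_a, n_b, n_s, n) == oracle_decide(
                            n_a, n_b, n_s, n
                        ), (n_a, n_b, n_s, n)

    @pytest.mark.parametrize(
        "n_a,n_b,n_s,n,expected",
        [
            (5, 4, 0, 10, True),   # condition 1: N_A >= n/2
            (2, 0, 0, 8, True),    # condition 2: no spanning contig
            (4, 2, 0, 10, True),   # condition 3 at the 0.5 boundary
            (4, 3, 0, 10, False),  # just above the 0.5 boundary
            (1, 5, 0, 8, False),   # no condition holds
        ],
    )
    def test_printed_examples(self, n_a, n_b, n_s, n, expected):
        assert decide_misassembly(n_a, n_b, n_s, n) is expected

    def test_condition3_boundary_is_half(self):
        """Sweeping N_B at N_A=4, n=10 flags up to and including N_B/N_A = 0.5."""
        flagged = [k for k in range(9) if decide_misassembly(4, k, 0, 10)]
        assert max(k / 4 for k in flagged) == 0.5

    def test_condition4_boundary_is_point_six(self):
        """Sweeping N_B at N_A=5, N_S=1, n=20 flags up to (N_B-N_S)/N_A = 0.6."""
        flagged = [k for k in range(11) if decide_misassembly(5, k, 1, 20)]
        assert max((k - 1) / 5 for k in flagged) == 0.6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decide_misassembly(1, 1, 1, 2)
        with pytest.raises(ValueError):
            decide_misassembly(-1, 0, 0, 5)


def _graph_with_conflicts(breakpoints, partners=("B", "C", "D"), node_len=4_000_000):
    """One focal contig in layer A; each partner layer contributes an
    alignment ending internally at the given breakpoint."""
    asm = {"A": {"A_c": node_len}}
    for p in partners:
        asm[p] = {f"{p}_c": node_len}
    pairs = {(q, t): [] for q in asm for t in asm if q != t}
    for bp, p in zip(breakpoints, list(partners) * len(breakpoints)):
        # partner aligned from its own start, ending internally at bp on A_c
        rec = AlignmentRecord(
            query_name=f"{p}_c", query_len=node_len,
            query_start=0, query_end=1_000_000, strand="+",
            target_name="A_c", target_len=node_len,
            target_start=bp - 1_000_000, target_end=bp,
            n_match=1_000_000, block_len=1_000_000, mapq=60,
        )
        pairs[(p, "A")].append(rec)
    return build_graph(asm, pairs)


class TestDiscordantRegions:
    def test_no_conflict_edges_no_regions(self, built_graph):
        # pick a node from a clean layer of the integration fixture
        g = built_graph
        clean = next(
            nid for nid, n in g.nodes.items()
            if g.layers[n.layer].name == "L5"
        )
        # a clean node may collect breakpoints *from* chimeras, but a graph
        # restricted to dovetail/contained edges yields none at all
        for e in g.inter_edges:
            if e.merge_class and e.merge_class.label != "internal_conflict":
                continue
        regions = find_discordant_regions(g, clean)
        for r in regions:
            assert r.n_a >= 1

    def test_single_linkage_clusters_nearby_breakpoints(self):
        g = _graph_with_conflicts([2_000_000, 2_001_000, 2_002_000])
        nid = next(nid for nid, n in g.nodes.items() if n.name == "A_c")
        regions = find_discordant_regions(g, nid, cluster_window=10_000)
        assert len(regions) == 1
        assert regions[0].n_a == 3
        assert regions[0].m_start <= 2_000_000 <= regions[0].m_end

    def test_distant_breakpoints_split_into_regions(self):
        g = _graph_with_conflicts([1_000_000, 3_000_000])
        nid = next(nid for nid, n in g.nodes.items() if n.name == "A_c")
        regions = find_discordant_regions(g, nid, cluster_window=10_000)
        assert len(regions) == 2

    def test_fixture_chimera_region_contains_junction(self, built_graph, fx):
        g = built_graph
        layer, contig, junction, _ = fx.truth.chimera_junctions[0]
        li = g.layer_by_name(layer).index
        (node,) = g.contig_fragments(li, contig)
        regions = find_discordant_regions(g, node.node_id)
        hits = [r for r in regions if r.m_start <= junction <= r.m_end]
        assert len(hits) == 1
        assert hits[0].n_b == 0  # nothing spans a chimeric junction


class TestSplitNode:
    def test_conservation_and_interval(self):
        g = _graph_with_conflicts([2_000_000] * 3)
        nid = next(nid for nid, n in g.nodes.items() if n.name == "A_c")
        (region,) = find_discordant_regions(g, nid)
        g, event = split_node(g, region)
        left, right = (g.nodes[x] for x in event.resulting_nodes)
        assert event.split_coordinate == 2_000_000
        assert left.length + right.length == 4_000_000
        assert left.end == right.start == 2_000_000

    def test_edge_reassigned_by_majority_overlap(self):
        g = _graph_with_conflicts([2_000_000] * 3)
        nid = next(nid for nid, n in g.nodes.items() if n.name == "A_c")
        # edges cover [1.0, 2.0] Mb on A_c: after a cut at 2.0 Mb they belong left
        (region,) = find_discordant_regions(g, nid)
        g, event = split_node(g, region)
        left_id = event.resulting_nodes[0]
        assert all(e.b == left_id for e in g.inter_edges)

    def test_majority_overlap_prefers_bigger_side(self):
        g = _graph_with_conflicts([2_000_000] * 3)
        nid = next(nid for nid, n in g.nodes.items() if n.name == "A_c")
        # add an edge spanning the cut with more bases on the right
        extra = AlignmentRecord(
            query_name="B_c", query_len=4_000_000, query_start=0, query_end=1_500_000,
            strand="+", target_name="A_c", target_len=4_000_000,
            target_start=1_500_000, target_end=3_000_000,
            n_match=1_500_000, block_len=1_500_000, mapq=60,
        )
        from karyograph.mgraph import InterLayerEdge

        bnid = next(nid for nid, n in g.nodes.items() if n.name == "B_c")
        g.inter_edges.append(InterLayerEdge(bnid, nid, extra))
        region = next(
            r for r in find_discordant_regions(g, nid)
            if r.m_start <= 2_000_000 <= r.m_end
        )
        g, event = split_node(g, region)
        right_id = event.resulting_nodes[1]
        assert g.inter_edges[-1].b == right_id  # 1.0 Mb right vs 0.5 Mb left

    def test_degenerate_cut_rejected(self):
        g = _graph_with_conflicts([2_000_000] * 3)
        nid = next(nid for nid, n in g.nodes.items() if n.name == "A_c")
        bogus = DiscordantRegion(nid, 0, 1000, 1, 0, 0, (0,))
        with pytest.raises(DegenerateSplitError):
            split_node(g, bogus)


class TestRunMdm:
    def test_clean_fixture_zero_splits(self):
        truth = simulate.simulate_genome(3, [900_000, 700_000, 500_000], seed=7)
        layers = ["A", "B", "C", "D"]
        for i, name in enumerate(layers):
            simulate.fragment_layer(truth, name, 250_000 + 50_000 * i, seed=11 + i)
        asm = {n: truth.layer_lengths(n) for n in layers}
        recip = simulate.emit_truth_alignments(
            truth, [(q, t) for q in layers for t in layers if q != t]
        )
        g = build_graph(asm, recip)
        g, events = run_mdm(g)
        assert events == []

    def test_single_chimera_single_split_near_truth(self):
        truth = simulate.simulate_genome(2, [1_200_000, 900_000], seed=21)
        layers = ["A", "B", "C", "D", "E"]
        for i, name in enumerate(layers):
            simulate.fragment_layer(truth, name, 300_000 + 40_000 * i, seed=31 + i)
        pos_a = simulate._mid_fragment_position(truth, "A", "chr1")
        pos_b = simulate._mid_fragment_position(truth, "A", "chr2")
        simulate.inject_chimeras(truth, "A", [("chr1", pos_a, "chr2", pos_b)])
        asm = {n: truth.layer_lengths(n) for n in layers}
        recip = simulate.emit_truth_alignments(
            truth, [(q, t) for q in layers for t in layers if q != t]
        )
        g = build_graph(asm, recip)
        g, events = run_mdm(g, cluster_window=10_000)
        assert len(events) == 1
        (_, contig, junction, _) = truth.chimera_junctions[0]
        assert events[0].original_node.split(":")[1] == contig
        assert abs(events[0].split_coordinate - junction) <= 10_000

    def test_fixture_all_junctions_recovered_no_false_splits(self, mdm_result, fx):
        g, events = mdm_result
        assert len(events) == len(fx.truth.chimera_junctions) == 3
        by_contig = {c: j for _, c, j, _ in fx.truth.chimera_junctions}
        for e in events:
            contig = e.original_node.split(":")[1]
            assert contig in by_contig  # no split of a clean contig
            assert abs(e.split_coordinate - by_contig[contig]) <= 10_000

    def test_fixpoint_no_region_decides_true(self, mdm_result):
        g, _ = mdm_result
        n = g.n_layers
        for nid, node in g.nodes.items():
            if g.layers[node.layer].kind != "assembly":
                continue
            for r in find_discordant_regions(g, nid):
                assert not decide_misassembly(r.n_a, r.n_b, r.n_s, n)

    def test_base_conservation_per_layer(self, mdm_result, fx):
        g, _ = mdm_result
        for layer in g.layers:
            total = sum(
                n.length for n in g.nodes.values() if n.layer == layer.index
            )
            assert total == sum(fx.assemblies[layer.name].values())

    def test_split_log_deterministic(self, fx, mdm_result):
        g2 = build_graph(fx.assemblies, fx.reciprocal_alignments)
        _, events2 = run_mdm(g2)
        _, events1 = mdm_result
        assert [(e.original_node, e.split_coordinate) for e in events1] == [
            (e.original_node, e.split_coordinate) for e in events2
        ]

    def test_requires_three_layers(self):
        from karyograph.mgraph import MultiLayerGraph

        g = MultiLayerGraph()
        g.add_layer("A")
        g.add_layer("B")
        with pytest.raises(ValueError, match="at least 3"):
            run_mdm(g)
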