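"""Mis-assembly (chimera) detection and node splitting.

A chimeric contig joins sequence from two genomic loci.  Against the other
assembly layers this shows up as *partial mappings*: partner contigs whose
alignments stop dead in the chimera's interior although both sequences
continue.  Breakpoints of such internal conflicts are clustered into candidate
discordant regions M; each region is scored by

* ``N_A`` — distinct partner contigs partially mapped to M,
* ``N_B`` — distinct partner contigs whose alignment spans M completely,
* ``N_S`` — distinct partner contigs that start or end at M,

and flagged as a genuine mis-assembly if any of four conditions holds (see
:func:`decide_misassembly`).  Flagged nodes are split at the median supporting
breakpoint and their edges re-assigned; the procedure iterates until the
whole graph is free of flagged regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .alignio import AlignmentRecord, default_tolerance
from .mgraph import (
    ASSEMBLY_LAYER_KIND,
    ContigNode,
    IntraLayerEdge,
    MultiLayerGraph,
)

__all__ = [
    "DiscordantRegion",
    "SplitEvent",
    "DegenerateSplitError",
    "find_discordant_regions",
    "decide_misassembly",
    "split_node",
    "run_mdm",
    "write_split_log",
    "split_contig_names",
]


class DegenerateSplitError(ValueError):
    """Split coordinate falls on a node boundary; nothing to split."""


@dataclass(frozen=True)
class DiscordantRegion:
    """A candidate mis-assembly locus M on one node (original coordinates)."""

    node: str
    m_start: int
    m_end: int
    n_a: int
    n_b: int
    n_s: int
    supporting_breakpoints: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.m_start >= self.m_end:
            raise ValueError("empty region M")
        if self.n_a < 1:
            raise ValueError("a discordant region needs at least one partial mapping")


@dataclass(frozen=True)
class SplitEvent:
    original_node: str
    split_coordinate: int
    resulting_nodes: tuple[str, str]
    iteration: int
    region: DiscordantRegion


def decide_misassembly(n_a: int, n_b: int, n_s: int, n: int) -> bool:
    """The four-condition decision rule for a discordant region M.

    M is a genuine mis-assembly if any of:

    1. ``N_A >= n/2``                      — half the layers disagree;
    2. ``N_B == 0 and N_A >= 2``           — nobody spans M;
    3. ``N_A >= 2 and N_B/N_A <= 0.5``     — spanning support is weak;
    4. ``N_S > 0 and (N_B - N_S)/N_A <= 0.6`` — contigs end right at M and
       net spanning support is weak (requires ``N_A >= 1``; with no partial
       mapping there is no discordance to evaluate).
    """
    if n < 3:
        raise ValueError("decision rule requires at least 3 assembly layers")
    if min(n_a, n_b, n_s) < 0:
        raise ValueError("counts must be non-negative")
    if n_a >= n / 2:
        return True
    if n_b == 0 and n_a >= 2:
        return True
    if n_a >= 2 and n_b / n_a <= 0.5:
        return True
    if n_s > 0 and n_a >= 1 and (n_b - n_s) / n_a <= 0.6:
        return True
    return False


def _termini(local: AlignmentRecord, node_is_query: bool):
    """Per terminus of a node-local alignment: (node-side overhang,
    partner-side overhang, node-local coordinate of the terminus)."""
    q_left, q_right = local.query_start, local.query_len - local.query_end
    t_left, t_right = local.target_start, local.target_len - local.target_end
    if node_is_query:
        if local.strand == "+":
            return [
                (q_left, t_left, local.query_start),
                (q_right, t_right, local.query_end),
            ]
        return [
            (q_left, t_right, local.query_start),
            (q_right, t_left, local.query_end),
        ]
    if local.strand == "+":
        return [
            (t_left, q_left, local.target_start),
            (t_right, q_right, local.target_end),
        ]
    return [
        (t_left, q_right, local.target_start),
        (t_right, q_left, local.target_end),
    ]


def _partner_key(g: MultiLayerGraph, node_id: str) -> tuple[int, str]:
    n = g.nodes[node_id]
    return (n.layer, n.name)


def find_discordant_regions(
    g: MultiLayerGraph,
    node_id: str,
    cluster_window: int = 10_000,
    tol: int | None = None,
    flank: int | None = None,
) -> list[DiscordantRegion]:
    """Cluster internal-conflict breakpoints on one node into regions M and
    count the partner support N_A, N_B, N_S.

    Breakpoints within ``cluster_window`` of each other (single linkage) form
    one region ``[min - flank, max + flank]`` clipped to the node.  Only
    partners from assembly layers are counted; coordinates are on the
    original contig.  ``tol`` defaults per alignment to the merge-geometry
    tolerance; ``flank`` defaults to ``tol`` (or 500 bp when tol is
    per-alignment).
    """
    node = g.nodes[node_id]
    assembly_layers = {
        l.index for l in g.layers if l.kind == ASSEMBLY_LAYER_KIND
    }
    if node.layer not in assembly_layers:
        raise ValueError("discordance scan applies to assembly-layer nodes")

    # (coord on node, partner key) breakpoints; plus per-edge geometry cache
    breakpoints: list[tuple[int, tuple[int, str]]] = []
    spans: list[tuple[int, int, tuple[int, str]]] = []  # node-side aligned interval
    ends_at: list[tuple[int, tuple[int, str]]] = []  # partner-end coords on node

    for edge in g.inter_edges:
        if node_id not in (edge.a, edge.b):
            continue
        node_is_query = edge.a == node_id
        partner_id = edge.b if node_is_query else edge.a
        if g.nodes[partner_id].layer not in assembly_layers:
            continue
        local = g.clipped_alignment(edge)
        if local is None:
            continue
        eff_tol = tol if tol is not None else default_tolerance(local)
        pkey = _partner_key(g, partner_id)
        if node_is_query:
            lo, hi = local.query_start, local.query_end
        else:
            lo, hi = local.target_start, local.target_end
        spans.append((lo + node.start, hi + node.start, pkey))
        for node_over, partner_over, coord in _termini(local, node_is_query):
            abs_coord = coord + node.start
            if node_over > eff_tol and partner_over > eff_tol:
                breakpoints.append((abs_coord, pkey))
            if partner_over <= eff_tol:
                ends_at.append((abs_coord, pkey))

    if not breakpoints:
        return []

    eff_flank = flank if flank is not None else (tol if tol is not None else 500)
    breakpoints.sort()
    clusters: list[list[tuple[int, tuple[int, str]]]] = [[breakpoints[0]]]
    for bp in breakpoints[1:]:
        if bp[0] - clusters[-1][-1][0] <= cluster_window:
            clusters[-1].append(bp)
        else:
            clusters.append([bp])

    regions = []
    for cl in clusters:
        coords = [c for c, _ in cl]
        m_start = max(min(coords) - eff_flank, node.start)
        m_end = min(max(coords) + eff_flank, node.end)
        if m_end <= m_start:
            m_start, m_end = max(coords[0] - 1, node.start), min(coords[0] + 1, node.end)
        n_a_partners = {p for _, p in cl}
        span_lo = max(m_start - eff_flank, node.start)
        span_hi = min(m_end + eff_flank, node.end)
        n_b_partners = {
            p for lo, hi, p in spans if lo <= span_lo and hi >= span_hi
        }
        n_s_partners = {p for c, p in ends_at if m_start <= c < m_end}
        regions.append(
            DiscordantRegion(
                node=node_id,
                m_start=m_start,
                m_end=m_end,
                n_a=len(n_a_partners),
                n_b=len(n_b_partners),
                n_s=len(n_s_partners),
                supporting_breakpoints=tuple(coords),
            )
        )
    return regions


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def split_node(
    g: MultiLayerGraph, region: DiscordantRegion, iteration: int = 0
) -> tuple[MultiLayerGraph, SplitEvent]:
    """Split a flagged node at the (lower) median supporting breakpoint.

    Incident inter-layer edges move to the side holding the majority of their
    aligned interval; intra-layer edges with a known coordinate follow it,
    those without are re-attached to both sides.
    """
    node = g.nodes[region.node]
    cut = _lower_median(region.supporting_breakpoints)
    if cut <= node.start or cut >= node.end:
        raise DegenerateSplitError(
            f"cut {cut} is at the boundary of node {region.node}"
        )
    left = ContigNode(node.layer, node.name, node.start, cut, node.split_generation + 1)
    right = ContigNode(node.layer, node.name, cut, node.end, node.split_generation + 1)
    g.remove_node(region.node)
    g.add_node(left)
    g.add_node(right)

    for edge in g.inter_edges:
        for attr in ("a", "b"):
            if getattr(edge, attr) != region.node:
                continue
            r = edge.alignment
            if attr == "a":
                lo, hi = r.query_start, r.query_end
            else:
                lo, hi = r.target_start, r.target_end
            ov_left = min(hi, cut) - max(lo, node.start)
            ov_right = min(hi, node.end) - max(lo, cut)
            setattr(edge, attr, (left if ov_left >= ov_right else right).node_id)

    new_intra: list[IntraLayerEdge] = []
    for edge in g.intra_edges:
        touched = False
        for attr, pos_attr in (("a", "pos_a"), ("b", "pos_b")):
            if getattr(edge, attr) != region.node:
                continue
            touched = True
            pos = getattr(edge, pos_attr)
            if pos is not None:
                setattr(edge, attr, (left if pos < cut else right).node_id)
            else:
                other = IntraLayerEdge(
                    edge.a, edge.b, edge.evidence, edge.weight, edge.pos_a, edge.pos_b
                )
                setattr(edge, attr, left.node_id)
                setattr(other, attr, right.node_id)
                new_intra.append(other)
        if touched and edge.a == edge.b:
            edge.a = left.node_id
            edge.b = right.node_id
    g.intra_edges.extend(e for e in new_intra if e.a != e.b)

    g.refresh_merge_classes()
    event = SplitEvent(
        original_node=region.node,
        split_coordinate=cut,
        resulting_nodes=(left.node_id, right.node_id),
        iteration=iteration,
        region=region,
    )
    return g, event


def run_mdm(
    g: MultiLayerGraph,
    cluster_window: int = 10_000,
    tol: int | None = None,
    flank: int | None = None,
    max_passes: int = 50,
) -> tuple[MultiLayerGraph, list[SplitEvent]]:
    """Iterate discordance detection and node splitting to a fixpoint.

    Nodes are scanned in deterministic order (descending length, then layer,
    then name); each pass splits every node whose first flagged region decides
    true, and the loop stops at the first pass with no split.  On the returned
    graph no region decides true.
    """
    if g.n_layers < 3:
        raise ValueError("mis-assembly detection requires at least 3 assembly layers")
    n = g.n_layers
    events: list[SplitEvent] = []
    for iteration in range(max_passes):
        scan = sorted(
            (
                nid
                for nid, node in g.nodes.items()
                if g.layers[node.layer].kind == ASSEMBLY_LAYER_KIND
            ),
            key=lambda nid: (-g.nodes[nid].length, g.nodes[nid].layer, g.nodes[nid].name),
        )
        split_this_pass = 0
        for nid in scan:
            if nid not in g.nodes:  # replaced earlier in this pass
                continue
            regions = find_discordant_regions(g, nid, cluster_window, tol, flank)
            for region in sorted(regions, key=lambda r: r.m_start):
                if decide_misassembly(region.n_a, region.n_b, region.n_s, n):
                    try:
                        g, event = split_node(g, region, iteration)
                    except DegenerateSplitError:
                        continue
                    events.append(event)
                    split_this_pass += 1
                    break  # node replaced; its halves are re-scanned next pass
        if split_this_pass == 0:
            g.mdm_done = True
            return g, events
    raise RuntimeError(
        f"mis-assembly splitting did not converge within {max_passes} passes; "
        f"{len(events)} splits so far, last: {events[-1] if events else None}"
    )


def write_split_log(events: Sequence[SplitEvent], tsv_path, bed_path=None) -> None:
    """Persist the split log as TSV (and optionally BED of cut points)."""
    with open(tsv_path, "w") as fh:
        fh.write("original_node\tcontig\tcut\titeration\tleft\tright\tN_A\tN_B\tN_S\n")
        for e in events:
            contig = e.original_node.split(":")[1]
            fh.write(
                f"{e.original_node}\t{contig}\t{e.split_coordinate}\t{e.iteration}\t"
                f"{e.resulting_nodes[0]}\t{e.resulting_nodes[1]}\t"
                f"{e.region.n_a}\t{e.region.n_b}\t{e.region.n_s}\n"
            )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for e in events:
                contig = e.original_node.split(":")[1]
                fh.write(f"{contig}\t{e.split_coordinate}\t{e.split_coordinate + 1}\n")


def split_contig_names(g: MultiLayerGraph, layer: int, contig: str) -> list[tuple[str, ContigNode]]:
    """Suffixed output names for the (possibly split) fragments of a contig:
    name.split1, name.split2, ... in coordinate order (plain name if unsplit)."""
    frags = g.contig_fragments(layer, contig)
    if len(frags) == 1 and frags[0].split_generation == 0:
        return [(contig, frags[0])]
    return [(f"{contig}.split{i + 1}", f) for i, f in enumerate(frags)]
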