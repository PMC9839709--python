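"""Contig clustering: connected components of the multi-layer graph become
scaffolding groups, ideally one per chromosome (or chromosome arm).

Also handles the loose ends: short contigs that were below the graph's
length threshold are rescued into the group that absorbs the majority of
their alignment bases, and single-contig single-layer groups are flagged as
orphans (frequent contaminant / organelle signatures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .alignio import AlignmentRecord, FilterThresholds
from .mgraph import (
    ASSEMBLY_LAYER_KIND,
    READS_LAYER_KIND,
    ContigNode,
    MultiLayerGraph,
)

__all__ = [
    "ScaffoldingGroup",
    "cluster",
    "accelerate_reachability",
    "rescue_short_contigs",
    "label_orphans",
    "write_group_table",
]


@dataclass
class ScaffoldingGroup:
    """One cluster of nodes across layers, plus any reads assigned to it."""

    id: int
    members: list[ContigNode]
    read_members: list[str] = field(default_factory=list)
    rescued: list[str] = field(default_factory=list)
    is_orphan: bool = False
    labels: set[str] = field(default_factory=set)

    @property
    def total_bases(self) -> int:
        return sum(n.length for n in self.members)

    def bases_per_layer(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for n in self.members:
            out[n.layer] = out.get(n.layer, 0) + n.length
        return out

    def member_layers(self) -> set[int]:
        return {n.layer for n in self.members}


def _component_graph(g: MultiLayerGraph) -> nx.Graph:
    nxg = nx.Graph()
    nxg.add_nodes_from(g.nodes)
    nxg.add_edges_from((e.a, e.b) for e in g.inter_edges)
    nxg.add_edges_from((e.a, e.b) for e in g.intra_edges)
    return nxg


def cluster(
    g: MultiLayerGraph,
    min_group_reads: int = 10,
    require_mdm: bool = True,
) -> list[ScaffoldingGroup]:
    """Group nodes reachable through inter- and intra-layer edges.

    Groups are the connected components of the edge union; isolated nodes
    form singleton groups.  Components consisting only of reads are kept as
    groups only when they hold at least ``min_group_reads`` reads — smaller
    read-only components are unplaced strays, not chromosomes — and such
    groups carry the label ``"read_only"``.  Group ids are assigned by
    descending total contig bases, ties by smallest member name.
    """
    if require_mdm and not g.mdm_done:
        raise RuntimeError(
            "graph has not been through mis-assembly detection; "
            "pass require_mdm=False to cluster anyway"
        )
    reads_layers = {l.index for l in g.layers if l.kind == READS_LAYER_KIND}
    raw_groups: list[ScaffoldingGroup] = []
    for comp in nx.connected_components(_component_graph(g)):
        members = []
        read_members = []
        for nid in comp:
            node = g.nodes[nid]
            if node.layer in reads_layers:
                read_members.append(node.name)
            else:
                members.append(node)
        if not members and len(read_members) < min_group_reads:
            continue
        grp = ScaffoldingGroup(
            id=-1,
            members=sorted(members, key=lambda n: (n.layer, n.name, n.start)),
            read_members=sorted(read_members),
        )
        if not members:
            grp.labels.add("read_only")
        raw_groups.append(grp)
    raw_groups.sort(
        key=lambda grp: (
            -grp.total_bases,
            grp.members[0].name if grp.members else min(grp.read_members),
        )
    )
    for i, grp in enumerate(raw_groups):
        grp.id = i + 1
    return label_orphans(raw_groups)


def accelerate_reachability(g: MultiLayerGraph) -> MultiLayerGraph:
    """Add inferred intra-layer shortcut edges between mutually reachable
    same-layer nodes (a chain per layer per component), leaving the partition
    produced by :func:`cluster` unchanged."""
    from .mgraph import IntraLayerEdge

    existing = {frozenset((e.a, e.b)) for e in g.intra_edges}
    for comp in nx.connected_components(_component_graph(g)):
        by_layer: dict[int, list[str]] = {}
        for nid in comp:
            by_layer.setdefault(g.nodes[nid].layer, []).append(nid)
        for ids in by_layer.values():
            ids.sort()
            for a, b in zip(ids, ids[1:]):
                key = frozenset((a, b))
                if key not in existing:
                    g.intra_edges.append(IntraLayerEdge(a, b, "inferred", 1))
                    existing.add(key)
    return g


def rescue_short_contigs(
    g: MultiLayerGraph,
    groups: Sequence[ScaffoldingGroup],
    short_alignments: Sequence[AlignmentRecord],
    th: FilterThresholds | None = None,
    majority: float = 0.60,
) -> list[ScaffoldingGroup]:
    """Assign contigs below the graph's length threshold to existing groups.

    Each short contig (alignment query) is credited with its aligned query
    bases per group; it joins the group holding at least ``majority`` of its
    total aligned bases.  Ties or a sub-majority winner leave the contig
    unassigned (reported via the returned groups' ``labels`` staying
    untouched and the module logger list on the graph).
    """
    th = th or FilterThresholds()
    node_group: dict[str, int] = {}
    by_id = {grp.id: grp for grp in groups}
    for grp in groups:
        for n in grp.members:
            node_group[n.node_id] = grp.id

    per_contig: dict[str, dict[int, int]] = {}
    for rec in short_alignments:
        if (
            rec.mapq < th.min_mapq
            or rec.block_len < th.min_block_len
            or rec.identity < th.min_identity
        ):
            continue
        # locate the target node (the target may have been split)
        try:
            tlayer = next(
                l.index
                for l in g.layers
                if l.kind == ASSEMBLY_LAYER_KIND
                and g.contig_fragments(l.index, rec.target_name)
            )
        except StopIteration:
            continue
        tnode = g.node_for_interval(
            tlayer, rec.target_name, rec.target_start, rec.target_end
        )
        gid = node_group.get(tnode.node_id)
        if gid is None:
            continue
        acc = per_contig.setdefault(rec.query_name, {})
        acc[gid] = acc.get(gid, 0) + (rec.query_end - rec.query_start)

    unassigned = []
    for contig, acc in sorted(per_contig.items()):
        total = sum(acc.values())
        gid, best = max(acc.items(), key=lambda kv: (kv[1], -kv[0]))
        runners = [v for k, v in acc.items() if k != gid]
        if best / total >= majority and (not runners or best > max(runners)):
            by_id[gid].rescued.append(contig)
        else:
            unassigned.append(contig)
    if unassigned:
        g.warnings.append(
            f"{len(unassigned)} short contigs left unassigned: "
            + ",".join(unassigned[:20])
        )
    return list(groups)


def label_orphans(groups: Sequence[ScaffoldingGroup]) -> list[ScaffoldingGroup]:
    """An orphan is a single contig node from a single layer — typically
    contamination or organelle DNA; flagged for user triage."""
    for grp in groups:
        grp.is_orphan = len(grp.members) == 1 and not grp.read_members
        if grp.is_orphan:
            grp.labels.add("orphan")
    return list(groups)


def write_group_table(groups: Sequence[ScaffoldingGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tmember\tlayer\tstart\tend\tis_orphan\tlabels\n")
        for grp in groups:
            labels = ",".join(sorted(grp.labels)) or "."
            for n in grp.members:
                fh.write(
                    f"{grp.id}\t{n.name}\t{n.layer}\t{n.start}\t{n.end}\t"
                    f"{int(grp.is_orphan)}\t{labels}\n"
                )
            for r in grp.rescued:
                fh.write(f"{grp.id}\t{r}\trescued\t.\t.\t{int(grp.is_orphan)}\t{labels}\n")
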