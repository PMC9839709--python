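"""The multi-layer graph: one layer per draft assembly plus an optional
raw-reads layer.

Nodes are contig intervals — initially one node per contig, but mis-assembly
splitting replaces a node by two nodes tiling the same original sequence, so
every node carries the half-open interval of the original contig it covers.
Alignment coordinates stored on edges always refer to the *original*
sequences; classification relative to the current nodes clips the alignment
to the node intervals on the fly.  This keeps splitting cheap and exact: no
alignment coordinates are ever rewritten, only edge endpoints move.

Inter-layer edges come from reciprocal assembly-vs-assembly alignments (and
read-vs-assembly alignments for the reads layer); intra-layer edges encode
Hi-C contacts, genetic-map / reference chromosome assignments, or inferred
reachability shortcuts.
"""

from __future__ import annotations

import csv
import os
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .alignio import (
    AlignmentRecord,
    FilterThresholds,
    MergeClass,
    classify_merge,
    filter_alignments,
)

__all__ = [
    "Layer",
    "ContigNode",
    "InterLayerEdge",
    "IntraLayerEdge",
    "MultiLayerGraph",
    "build_graph",
    "add_reads_layer",
    "add_intralayer_edges",
    "chromosome_assignment_links",
    "node_sequence",
]

READS_LAYER_KIND = "reads"
ASSEMBLY_LAYER_KIND = "assembly"


@dataclass(frozen=True)
class Layer:
    index: int
    name: str
    kind: str = ASSEMBLY_LAYER_KIND


@dataclass(frozen=True)
class ContigNode:
    """A node: the [start, end) slice of one original sequence in one layer."""

    layer: int
    name: str
    start: int
    end: int
    split_generation: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty node interval for {self.name}")

    @property
    def node_id(self) -> str:
        return f"{self.layer}:{self.name}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InterLayerEdge:
    """Edge between nodes of two different layers, backed by one alignment.

    ``a`` is the node on the alignment's query sequence, ``b`` on the target.
    ``merge_class`` caches the classification relative to the *current* node
    intervals and is refreshed whenever an endpoint changes.
    """

    a: str
    b: str
    alignment: AlignmentRecord
    merge_class: MergeClass | None = None


@dataclass
class IntraLayerEdge:
    """Same-layer edge from Hi-C, a genetic map / reference, or inference."""

    a: str
    b: str
    evidence: str  # hic | genetic_map | reference | inferred
    weight: int = 1
    pos_a: int | None = None
    pos_b: int | None = None

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("intra-layer edge weight must be >= 1")


class MultiLayerGraph:
    """Layers, nodes and edges, with index structures for interval lookup."""

    def __init__(self) -> None:
        self.layers: list[Layer] = []
        self.nodes: dict[str, ContigNode] = {}
        self.inter_edges: list[InterLayerEdge] = []
        self.intra_edges: list[IntraLayerEdge] = []
        # (layer index, original contig name) -> nodes sorted by start
        self._by_contig: dict[tuple[int, str], list[ContigNode]] = {}
        self.warnings: list[str] = []
        self.mdm_done: bool = False

    # -- layer / node bookkeeping -------------------------------------------------

    @property
    def n_layers(self) -> int:
        """Number of assembly layers (the n of the n-layer graph)."""
        return sum(1 for l in self.layers if l.kind == ASSEMBLY_LAYER_KIND)

    def layer_by_name(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r}")

    def add_layer(self, name: str, kind: str = ASSEMBLY_LAYER_KIND) -> Layer:
        if kind == READS_LAYER_KIND and any(
            l.kind == READS_LAYER_KIND for l in self.layers
        ):
            raise ValueError("graph already has a reads layer")
        layer = Layer(index=len(self.layers), name=name, kind=kind)
        self.layers.append(layer)
        return layer

    def add_node(self, node: ContigNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node {node.node_id}")
        self.nodes[node.node_id] = node
        key = (node.layer, node.name)
        frags = self._by_contig.setdefault(key, [])
        frags.append(node)
        frags.sort(key=lambda n: n.start)

    def remove_node(self, node_id: str) -> None:
        node = self.nodes.pop(node_id)
        self._by_contig[(node.layer, node.name)].remove(node)

    def contig_fragments(self, layer: int, name: str) -> list[ContigNode]:
        """All current nodes tiling one original contig, sorted by start."""
        return self._by_contig.get((layer, name), [])

    def node_at(self, layer: int, name: str, pos: int) -> ContigNode:
        """The node of a (possibly split) contig containing coordinate pos."""
        frags = self.contig_fragments(layer, name)
        if not frags:
            raise KeyError(f"no contig {name!r} in layer {layer}")
        starts = [f.start for f in frags]
        i = max(bisect_right(starts, pos) - 1, 0)
        return frags[i]

    def node_for_interval(self, layer: int, name: str, start: int, end: int) -> ContigNode:
        """The node holding the majority of [start, end) on a contig."""
        frags = self.contig_fragments(layer, name)
        if not frags:
            raise KeyError(f"no contig {name!r} in layer {layer}")
        return max(frags, key=lambda f: (min(end, f.end) - max(start, f.start), -f.start))

    def edges_of(self, node_id: str) -> list[InterLayerEdge]:
        return [e for e in self.inter_edges if node_id in (e.a, e.b)]

    # -- edge geometry relative to current nodes ----------------------------------

    def clipped_alignment(self, edge: InterLayerEdge) -> AlignmentRecord | None:
        """The edge's alignment clipped to its node intervals, in node-local
        coordinates (node = the whole sequence).

        The partner interval is rescaled linearly when a node boundary cuts
        through the alignment; exact base correspondence is not tracked, which
        is adequate for geometry classification.  Returns None if the clipped
        block is empty.
        """
        na, nb = self.nodes[edge.a], self.nodes[edge.b]
        r = edge.alignment
        qs, qe = max(r.query_start, na.start), min(r.query_end, na.end)
        if qe <= qs:
            return None
        # map query clip to target coordinates
        span_q = r.query_end - r.query_start
        span_t = r.target_end - r.target_start

        def q2t(x: int) -> float:
            f = (x - r.query_start) / span_q
            if r.strand == "+":
                return r.target_start + f * span_t
            return r.target_end - f * span_t

        t_lo, t_hi = sorted((q2t(qs), q2t(qe)))
        ts = max(int(round(t_lo)), r.target_start, nb.start)
        te = min(int(round(t_hi)), r.target_end, nb.end)
        if te <= ts:
            return None
        # map target clip back to query to account for nb clipping
        def t2q(y: float) -> float:
            if r.strand == "+":
                f = (y - r.target_start) / span_t
            else:
                f = (r.target_end - y) / span_t
            return r.query_start + f * span_q

        q_lo, q_hi = sorted((t2q(ts), t2q(te)))
        qs = max(int(round(q_lo)), qs)
        qe = min(int(round(q_hi)), qe)
        if qe <= qs:
            return None
        frac = (qe - qs) / span_q
        block = max(int(round(r.block_len * frac)), 1)
        nmatch = min(int(round(r.n_match * frac)), block)
        return AlignmentRecord(
            query_name=edge.a,
            query_len=na.length,
            query_start=qs - na.start,
            query_end=qe - na.start,
            strand=r.strand,
            target_name=edge.b,
            target_len=nb.length,
            target_start=ts - nb.start,
            target_end=te - nb.start,
            n_match=nmatch,
            block_len=block,
            mapq=r.mapq,
            identity=r.identity,
        )

    def classify_edge(self, edge: InterLayerEdge, tol: int | None = None) -> MergeClass | None:
        local = self.clipped_alignment(edge)
        if local is None:
            return None
        return classify_merge(local, tol)

    def refresh_merge_classes(self, tol: int | None = None) -> None:
        for e in self.inter_edges:
            e.merge_class = self.classify_edge(e, tol)

    # -- serialization -------------------------------------------------------------

    def to_tsv_bundle(self, directory) -> None:
        """Persist as an inspectable, diffable TSV bundle."""
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "layers.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["index", "name", "kind"])
            for l in self.layers:
                w.writerow([l.index, l.name, l.kind])
        with open(os.path.join(directory, "nodes.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["layer", "name", "start", "end", "split_generation"])
            for n in sorted(self.nodes.values(), key=lambda n: n.node_id):
                w.writerow([n.layer, n.name, n.start, n.end, n.split_generation])
        with open(os.path.join(directory, "inter_edges.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(
                ["a", "b", "query_name", "query_len", "query_start", "query_end",
                 "strand", "target_name", "target_len", "target_start", "target_end",
                 "n_match", "block_len", "mapq", "identity"]
            )
            for e in self.inter_edges:
                r = e.alignment
                w.writerow(
                    [e.a, e.b, r.query_name, r.query_len, r.query_start, r.query_end,
                     r.strand, r.target_name, r.target_len, r.target_start,
                     r.target_end, r.n_match, r.block_len, r.mapq, repr(r.identity)]
                )
        with open(os.path.join(directory, "intra_edges.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["a", "b", "evidence", "weight", "pos_a", "pos_b"])
            for e in self.intra_edges:
                w.writerow(
                    [e.a, e.b, e.evidence, e.weight,
                     "" if e.pos_a is None else e.pos_a,
                     "" if e.pos_b is None else e.pos_b]
                )

    @classmethod
    def from_tsv_bundle(cls, directory) -> "MultiLayerGraph":
        g = cls()
        with open(os.path.join(directory, "layers.tsv")) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                g.layers.append(Layer(int(row["index"]), row["name"], row["kind"]))
        with open(os.path.join(directory, "nodes.tsv")) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                g.add_node(
                    ContigNode(
                        int(row["layer"]), row["name"], int(row["start"]),
                        int(row["end"]), int(row["split_generation"]),
                    )
                )
        with open(os.path.join(directory, "inter_edges.tsv")) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                rec = AlignmentRecord(
                    query_name=row["query_name"], query_len=int(row["query_len"]),
                    query_start=int(row["query_start"]), query_end=int(row["query_end"]),
                    strand=row["strand"],
                    target_name=row["target_name"], target_len=int(row["target_len"]),
                    target_start=int(row["target_start"]), target_end=int(row["target_end"]),
                    n_match=int(row["n_match"]), block_len=int(row["block_len"]),
                    mapq=int(row["mapq"]), identity=float(row["identity"]),
                )
                g.inter_edges.append(InterLayerEdge(row["a"], row["b"], rec))
        with open(os.path.join(directory, "intra_edges.tsv")) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                g.intra_edges.append(
                    IntraLayerEdge(
                        row["a"], row["b"], row["evidence"], int(row["weight"]),
                        int(row["pos_a"]) if row["pos_a"] else None,
                        int(row["pos_b"]) if row["pos_b"] else None,
                    )
                )
        g.refresh_merge_classes()
        return g


def build_graph(
    assemblies: Mapping[str, Mapping[str, int]],
    reciprocal_alignments: Mapping[tuple[str, str], Sequence[AlignmentRecord]],
    th: FilterThresholds | None = None,
    tol: int | None = None,
) -> MultiLayerGraph:
    """Build the n-layer graph from >=3 draft assemblies and their reciprocal
    alignments.

    Parameters
    ----------
    assemblies
        layer name -> {contig name: length}. Order defines layer indices.
    reciprocal_alignments
        (query layer, target layer) -> alignment records; all n(n-1) directed
        layer pairs must be present (empty lists allowed) because minimap2
        output differs with query/target exchanged.
    th
        Filtering thresholds; contigs shorter than ``th.min_contig_len`` are
        left out of the graph (they are rescued into groups later).
    """
    if len(assemblies) < 3:
        raise ValueError(
            "minimum three preliminary assemblies are required "
            f"(got {len(assemblies)})"
        )
    th = th or FilterThresholds()
    g = MultiLayerGraph()
    for name, contigs in assemblies.items():
        layer = g.add_layer(name)
        for contig, length in contigs.items():
            if length >= th.min_contig_len:
                g.add_node(ContigNode(layer.index, contig, 0, length))

    names = list(assemblies)
    expected = {(q, t) for q in names for t in names if q != t}
    provided = set(reciprocal_alignments)
    if provided != expected:
        missing = sorted(expected - provided)
        extra = sorted(provided - expected)
        raise ValueError(
            f"need all n(n-1) directed layer pairs; missing {missing}, extra {extra}"
        )

    for (qlayer, tlayer), records in reciprocal_alignments.items():
        ql, tl = g.layer_by_name(qlayer), g.layer_by_name(tlayer)
        lengths = dict(assemblies[qlayer])
        lengths.update(assemblies[tlayer])
        for rec in filter_alignments(records, th, lengths):
            qfrags = g.contig_fragments(ql.index, rec.query_name)
            tfrags = g.contig_fragments(tl.index, rec.target_name)
            if not qfrags or not tfrags:
                continue  # partner below the length threshold
            g.inter_edges.append(
                InterLayerEdge(qfrags[0].node_id, tfrags[0].node_id, rec)
            )
    g.refresh_merge_classes(tol)
    return g


def add_reads_layer(
    g: MultiLayerGraph,
    reads: Iterable[tuple[str, int]],
    read_alignments: Sequence[AlignmentRecord],
    anchor_layers: Sequence[str],
    th: FilterThresholds | None = None,
    layer_name: str = "reads",
) -> MultiLayerGraph:
    """Add the raw-reads layer: one node per read, edges to the anchor-layer
    contig nodes it aligns to after filtering.

    Alignments whose target is not in an anchor layer are ignored (counted in
    ``g.warnings``). Reads with no surviving alignment stay isolated.
    """
    from .alignio import READS_THRESHOLDS

    if not anchor_layers:
        raise ValueError("anchor_layers must be non-empty")
    anchors = {g.layer_by_name(n).index: g.layer_by_name(n) for n in anchor_layers}
    th = th or READS_THRESHOLDS
    rl = g.add_layer(layer_name, kind=READS_LAYER_KIND)
    read_lengths: dict[str, int] = {}
    for rid, length in reads:
        read_lengths[rid] = length
        g.add_node(ContigNode(rl.index, rid, 0, length))

    # contig name -> anchor layer index (contig names unique within a layer;
    # a name present in several anchor layers is resolved per-alignment below)
    contig_layer: dict[str, list[int]] = {}
    for li in anchors:
        for (layer, name), frags in list(g._by_contig.items()):
            if layer == li and frags:
                contig_layer.setdefault(name, []).append(li)

    ignored = 0
    for rec in read_alignments:
        if rec.query_name not in read_lengths:
            continue
        layer_hits = contig_layer.get(rec.target_name, [])
        if not layer_hits:
            ignored += 1
            continue
        if (
            rec.mapq < th.min_mapq
            or rec.block_len < th.min_block_len
            or rec.identity < th.min_identity
        ):
            continue
        li = layer_hits[0]
        target = g.node_for_interval(li, rec.target_name, rec.target_start, rec.target_end)
        read_node = g.node_at(rl.index, rec.query_name, 0)
        g.inter_edges.append(InterLayerEdge(read_node.node_id, target.node_id, rec))
    if ignored:
        g.warnings.append(f"{ignored} read alignments to non-anchor layers ignored")
    g.refresh_merge_classes()
    return g


def add_intralayer_edges(
    g: MultiLayerGraph,
    layer: str,
    links: Iterable[tuple],
    min_support: int = 5,
) -> MultiLayerGraph:
    """Add intra-layer edges from a link table.

    Each link is ``(seq_a, seq_b, evidence, count[, pos_a, pos_b])`` naming
    contigs of ``layer``. Links with count < min_support are dropped. If a
    linked contig was split, a link with a coordinate goes to the fragment
    containing it; without a coordinate, edges go to every fragment pair.
    """
    li = g.layer_by_name(layer).index
    for link in links:
        seq_a, seq_b, evidence, count = link[:4]
        pos_a = link[4] if len(link) > 4 else None
        pos_b = link[5] if len(link) > 5 else None
        if count < min_support:
            continue
        for name in (seq_a, seq_b):
            if not g.contig_fragments(li, name):
                found = [l for l in g.layers for key in [(l.index, name)] if g.contig_fragments(*key)]
                if found:
                    raise ValueError(
                        f"link endpoint {name!r} belongs to layer {found[0].name!r}, "
                        f"not {layer!r} (links may not cross layers)"
                    )
                raise KeyError(f"link endpoint {name!r} not found in layer {layer!r}")
        a_nodes = (
            [g.node_at(li, seq_a, pos_a)] if pos_a is not None
            else g.contig_fragments(li, seq_a)
        )
        b_nodes = (
            [g.node_at(li, seq_b, pos_b)] if pos_b is not None
            else g.contig_fragments(li, seq_b)
        )
        for na in a_nodes:
            for nb in b_nodes:
                if na.node_id == nb.node_id:
                    continue
                g.intra_edges.append(
                    IntraLayerEdge(na.node_id, nb.node_id, evidence, count, pos_a, pos_b)
                )
    return g


def chromosome_assignment_links(
    assignments: Mapping[str, str], evidence: str = "genetic_map"
) -> list[tuple[str, str, str, int]]:
    """Expand contig -> chromosome assignments (genetic map or reference) to
    pairwise same-chromosome links (a clique per chromosome)."""
    by_chrom: dict[str, list[str]] = {}
    for contig, chrom in assignments.items():
        by_chrom.setdefault(chrom, []).append(contig)
    links = []
    for members in by_chrom.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                links.append((a, b, evidence, 1))
    return links


def node_sequence(g: MultiLayerGraph, node: ContigNode, fasta) -> str:
    """The [start, end) substring of the node's original contig.

    ``fasta`` may be a pyfaidx.Fasta, a dict of strings, or anything whose
    ``[name]`` supports slicing.
    """
    try:
        seq = fasta[node.name]
    except KeyError:
        raise KeyError(f"contig {node.name!r} missing from FASTA") from None
    return str(seq[node.start:node.end])
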