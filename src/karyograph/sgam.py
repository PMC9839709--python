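"""Scaffolding-group assembly support: simplified overlap-graph merging of a
group's contigs, telomere-motif end analysis, arm-pairing proposals, and
depth-based choice among competing assemblies of the same group.

The merger is deliberately conservative: within a group, dovetail overlaps
form an overlap graph, contained contigs are retired, and a component is
merged only when it is an unbranched path — branches and cycles are reported
instead of being resolved heuristically, because a wrong join is worse than
no join.  Repeat collapse remains a known failure mode of any overlap-based
splice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio.Seq import reverse_complement

from .alignio import AlignmentRecord, classify_merge
from .ccm import ScaffoldingGroup
from .depthqc import DepthProfile, collapsed_regions

__all__ = [
    "OverlapEdge",
    "OverlapGraph",
    "MergedSequence",
    "TelomereHit",
    "build_overlap_graph",
    "merge_group",
    "telomere_scan",
    "propose_group_merges",
    "pick_better_assembly",
]


@dataclass(frozen=True)
class OverlapEdge:
    """A dovetail overlap: ``a_end``/``b_end`` name the terminus (left/right,
    on the forward strand) of each contig that participates."""

    a: str
    b: str
    overlap_len: int
    a_end: str
    b_end: str
    identity: float


@dataclass
class OverlapGraph:
    edges: list[OverlapEdge] = field(default_factory=list)
    #: (contained contig, containing contig) pairs; contained ones are retired
    containments: list[tuple[str, str]] = field(default_factory=list)

    @property
    def retired(self) -> set[str]:
        return {c for c, _ in self.containments}


@dataclass
class MergedSequence:
    name: str
    sequence: str
    #: (contig, strand, kept interval on the original contig) per segment
    provenance: list[tuple[str, str, tuple[int, int]]]


@dataclass(frozen=True)
class TelomereHit:
    contig: str
    terminus: str  # left | right
    motif: str
    copy_count: int
    window: int


def build_overlap_graph(
    contigs: Iterable[str],
    alignments: Sequence[AlignmentRecord],
    tol: int | None = None,
    min_overlap: int = 10_000,
) -> OverlapGraph:
    """Classify within-group alignments into dovetail edges and containments.

    Only dovetails with an overlap of at least ``min_overlap`` become edges;
    a contig contained in another is recorded and retired from merging.
    Internal conflicts (which should not survive mis-assembly splitting) are
    ignored here.
    """
    members = set(contigs)
    og = OverlapGraph()
    seen_pairs: set[frozenset] = set()
    for rec in alignments:
        if rec.query_name not in members or rec.target_name not in members:
            continue
        if rec.query_name == rec.target_name:
            continue
        pair = frozenset((rec.query_name, rec.target_name))
        if pair in seen_pairs:
            continue
        mc = classify_merge(rec, tol)
        if mc.label == "contained":
            og.containments.append((rec.query_name, rec.target_name))
            seen_pairs.add(pair)
        elif mc.label == "containing":
            og.containments.append((rec.target_name, rec.query_name))
            seen_pairs.add(pair)
        elif mc.label == "dovetail":
            overlap = rec.query_end - rec.query_start
            if overlap < min_overlap:
                continue
            # the participating terminus is the one nearest the aligned block;
            # relative orientation is encoded by sidedness (opposite ends for
            # + strand, same ends for -), so no explicit strand field is needed
            a_end = "right" if rec.query_start > rec.query_len - rec.query_end else "left"
            b_end = "left" if rec.target_start < rec.target_len - rec.target_end else "right"
            og.edges.append(
                OverlapEdge(
                    a=rec.query_name,
                    b=rec.target_name,
                    overlap_len=overlap,
                    a_end=a_end,
                    b_end=b_end,
                    identity=rec.identity,
                )
            )
            seen_pairs.add(pair)
    return og


def _orient_path(path: list[str], edge_map: Mapping[frozenset, OverlapEdge]):
    """Walk a path and pick per-contig orientation from edge end geometry.

    A forward contig hands over its *right* end; the next contig must receive
    on its *left* end once its own orientation is applied.
    """
    orientations = {}
    # first contig: forward if it exits via its right end
    first_edge = edge_map[frozenset(path[:2])]
    if first_edge.a == path[0]:
        out_end = first_edge.a_end
    else:
        out_end = first_edge.b_end
    orientations[path[0]] = "+" if out_end == "right" else "-"
    for prev, cur in zip(path, path[1:]):
        e = edge_map[frozenset((prev, cur))]
        in_end = e.b_end if e.b == cur else e.a_end
        # receiving end must be 'left' in merged orientation
        orientations[cur] = "+" if in_end == "left" else "-"
    return orientations


def merge_group(
    og: OverlapGraph, sequences: Mapping[str, str]
) -> tuple[list[MergedSequence], list[dict]]:
    """Merge each unbranched path of the overlap graph into one sequence.

    Contigs are spliced at the midpoint of each pairwise overlap (the left
    contig keeps its bases up to the midpoint), so the merged length is
    exactly the contig-length sum minus the overlap sum.  Components with a
    branch (degree > 2) or a cycle are reported unmerged.
    """
    active_edges = [
        e for e in og.edges if e.a not in og.retired and e.b not in og.retired
    ]
    nxg = nx.Graph()
    nxg.add_nodes_from(
        n for n in sequences if n not in og.retired
    )
    edge_map: dict[frozenset, OverlapEdge] = {}
    for e in active_edges:
        key = frozenset((e.a, e.b))
        nxg.add_edge(e.a, e.b)
        edge_map[key] = e

    merged: list[MergedSequence] = []
    reports: list[dict] = []
    for comp in sorted(nx.connected_components(nxg), key=lambda c: sorted(c)[0]):
        comp = sorted(comp)
        sub = nxg.subgraph(comp)
        if len(comp) == 1:
            name = comp[0]
            merged.append(
                MergedSequence(name, sequences[name], [(name, "+", (0, len(sequences[name])))])
            )
            continue
        degrees = dict(sub.degree())
        if max(degrees.values()) > 2:
            reports.append(
                {"component": comp, "reason": "branched",
                 "max_degree": max(degrees.values())}
            )
            continue
        endpoints = [n for n, d in degrees.items() if d == 1]
        if not endpoints:
            reports.append({"component": comp, "reason": "cyclic"})
            continue
        start = min(endpoints)
        path = [start]
        prev = None
        while True:
            nxt = [n for n in sub.neighbors(path[-1]) if n != prev]
            if not nxt:
                break
            prev = path[-1]
            path.append(nxt[0])
        orientations = _orient_path(path, edge_map)

        pieces: list[str] = []
        provenance: list[tuple[str, str, tuple[int, int]]] = []
        carry_trim = 0  # bases already contributed at the left of current contig
        for i, name in enumerate(path):
            seq = sequences[name]
            if orientations[name] == "-":
                seq = reverse_complement(seq)
            left_cut = carry_trim
            if i < len(path) - 1:
                e = edge_map[frozenset((name, path[i + 1]))]
                half = e.overlap_len // 2
                right_cut = e.overlap_len - half  # this contig keeps up to midpoint
                carry_trim = half
            else:
                right_cut = 0
                carry_trim = 0
            kept = seq[left_cut: len(seq) - right_cut]
            pieces.append(kept)
            if orientations[name] == "+":
                interval = (left_cut, len(seq) - right_cut)
            else:
                interval = (right_cut, len(seq) - left_cut)
            provenance.append((name, orientations[name], interval))
        merged.append(MergedSequence("+".join(path), "".join(pieces), provenance))
    return merged, reports


def telomere_scan(
    sequence: str,
    motif: str,
    window: int = 5_000,
    min_copies: int = 25,
    contig: str = "seq",
) -> list[TelomereHit]:
    """Count motif (and reverse-complement) copies in each terminal window.

    Counting is non-overlapping occurrence counting, appropriate for tandem
    telomeric repeats; a hit is reported when the copy count reaches
    ``min_copies``.  Scanning the reverse complement of a sequence swaps
    left and right hits.
    """
    if len(motif) < 4:
        raise ValueError("telomeric motifs are at least 4 bp")
    motif = motif.upper()
    rc = reverse_complement(motif)
    seq = sequence.upper()
    hits = []
    for terminus, win in (("left", seq[:window]), ("right", seq[-window:])):
        count = win.count(motif) + (win.count(rc) if rc != motif else 0)
        if count >= min_copies:
            hits.append(TelomereHit(contig, terminus, motif, count, window))
    return hits


def _matchings(items: list) -> list[list[tuple]]:
    """All perfect (or near-perfect for odd n) pairings of items."""
    if len(items) <= 1:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for i, other in enumerate(rest):
        remainder = rest[:i] + rest[i + 1:]
        for sub in _matchings(remainder):
            out.append([(first, other)] + sub)
    if len(items) % 2 == 1:
        # the odd one out may be any item; recurse without `first` paired
        for sub in _matchings(rest):
            out.append(sub)
    return out


def propose_group_merges(
    groups: Sequence[ScaffoldingGroup],
    end_status: Mapping[int, tuple[bool, bool]],
    expected_chromosomes: int | None = None,
) -> list[dict]:
    """Enumerate candidate pairings of arm-like groups.

    ``end_status[group id] = (left telomeric, right telomeric)``.  Groups
    telomeric at both ends are closed chromosomes and excluded; groups with
    at most one telomeric end are arm candidates.  All pairings are
    enumerated (4 arms give exactly 3 perfect pairings) and ranked by fewest
    unpaired telomere-free ends; pairings inconsistent with
    ``expected_chromosomes`` are dropped when that count is known.  Accepting
    a proposal remains the user's decision.
    """
    closed = []
    arms = []
    for grp in groups:
        if grp.is_orphan or "read_only" in grp.labels:
            continue
        left, right = end_status.get(grp.id, (False, False))
        if left and right:
            closed.append(grp.id)
        else:
            arms.append((grp.id, left or right))
    arm_ids = [gid for gid, _ in arms]
    telomeric_end = dict(arms)

    proposals = []
    for matching in _matchings(arm_ids):
        paired = {gid for pair in matching for gid in pair}
        unpaired = [gid for gid in arm_ids if gid not in paired]
        n_chrom = len(closed) + len(matching) + len(unpaired)
        if expected_chromosomes is not None and n_chrom != expected_chromosomes:
            continue
        open_ends = sum(
            (0 if telomeric_end[a] else 1) + (0 if telomeric_end[b] else 1)
            for a, b in matching
        ) + 2 * len(unpaired)
        proposals.append(
            {
                "pairs": sorted(tuple(sorted(p)) for p in matching),
                "unpaired": sorted(unpaired),
                "closed": sorted(closed),
                "n_chromosomes": n_chrom,
                "open_ends": open_ends,
            }
        )
    # dedupe (odd-count recursion can regenerate the same matching)
    unique = {}
    for p in proposals:
        key = (tuple(p["pairs"]), tuple(p["unpaired"]))
        unique.setdefault(key, p)
    return sorted(unique.values(), key=lambda p: (p["open_ends"], p["pairs"]))


def pick_better_assembly(
    depth_profiles: Mapping[str, Sequence[DepthProfile]],
    gaps: Mapping[str, Sequence] | None = None,
    collapse_multiplier: float = 2.0,
    edge_ignore: int = 500,
) -> dict:
    """Rank competing assemblies of one group by depth evidence.

    Score per candidate = (zero-depth internal positions, collapsed bases,
    gap count), compared lexicographically — fewer holes beats fewer
    collapsed bases beats fewer gaps.  Returns the full table, the winner,
    and a tie flag.
    """
    gaps = gaps or {}
    table = {}
    for name, profiles in depth_profiles.items():
        zero = 0
        collapsed_bases = 0
        for prof in profiles:
            interior = prof.depth[edge_ignore: max(len(prof.depth) - edge_ignore, edge_ignore)]
            zero += int((interior == 0).sum())
            for region in collapsed_regions(prof, multiplier=collapse_multiplier):
                collapsed_bases += region.end - region.start
        table[name] = (zero, collapsed_bases, len(gaps.get(name, [])))
    ranked = sorted(table.items(), key=lambda kv: (kv[1], kv[0]))
    tie = len(ranked) > 1 and ranked[0][1] == ranked[1][1]
    return {"table": table, "ranking": [n for n, _ in ranked],
            "best": ranked[0][0] if ranked else None, "tie": tie}
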