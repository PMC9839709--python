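"""Synthetic multi-chromosome genomes with known truth.

Everything downstream needs three kinds of input: draft assemblies (several
"layers" with different fragmentation and, optionally, injected chimeric
contigs), long reads, and the alignments among them.  This module generates
all of it from a simulated genome whose ground truth — per-contig and
per-read chromosome of origin, chimera junction coordinates, repeat and
telomere annotations — is retained, and *computes* the alignments directly
from the truth coordinates instead of running an aligner: unit tests become
exact and the package needs no external tools.

What this emulates: assembler-dependent fragmentation (distinct breakpoints
per layer with assemblable overlaps), chimeric joins, telomeric repeat
arrays, interspersed diverged repeats, and cis-enriched Hi-C contact links.
What it does not: realistic long-read error profiles (homopolymer bias,
chimeric reads) or structural heterozygosity.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .alignio import AlignmentRecord

__all__ = [
    "OriginSegment",
    "SyntheticTruth",
    "simulate_genome",
    "fragment_layer",
    "inject_chimeras",
    "sample_reads",
    "emit_truth_alignments",
    "emit_hic_links",
    "integration_fixture",
    "IntegrationFixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class OriginSegment:
    """One contiguous slice of a chromosome inside a contig or read.

    ``offset`` is where the slice starts within the contig; ``strand`` '-'
    means the slice appears reverse-complemented.
    """

    chrom: str
    start: int
    end: int
    strand: str
    offset: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_local(self, lo: int, hi: int) -> tuple[int, int]:
        """Map a chromosome sub-interval [lo, hi) of this segment to
        contig-local coordinates."""
        if self.strand == "+":
            return self.offset + (lo - self.start), self.offset + (hi - self.start)
        return self.offset + (self.end - hi), self.offset + (self.end - lo)


@dataclass
class SyntheticTruth:
    seed: int
    telomere_motif: str
    chromosomes: dict[str, str] = field(default_factory=dict)
    #: layer -> contig -> origin segments (sorted by offset)
    layers: dict[str, dict[str, list[OriginSegment]]] = field(default_factory=dict)
    #: (layer, contig, junction coordinate on contig, (chrom A, chrom B))
    chimera_junctions: list[tuple[str, str, int, tuple[str, str]]] = field(
        default_factory=list
    )
    reads: dict[str, str] = field(default_factory=dict)
    read_origins: dict[str, OriginSegment] = field(default_factory=dict)
    #: (chrom, start, end, family)
    repeats: list[tuple[str, int, int, str]] = field(default_factory=list)

    # -- derived --------------------------------------------------------------

    def contig_length(self, layer: str, contig: str) -> int:
        segs = self.layers[layer][contig]
        return max(s.offset + s.length for s in segs)

    def contig_sequence(self, layer: str, contig: str) -> str:
        parts = []
        for seg in sorted(self.layers[layer][contig], key=lambda s: s.offset):
            chunk = self.chromosomes[seg.chrom][seg.start:seg.end]
            parts.append(reverse_complement(chunk) if seg.strand == "-" else chunk)
        return "".join(parts)

    def layer_fasta(self, layer: str) -> dict[str, str]:
        return {c: self.contig_sequence(layer, c) for c in self.layers[layer]}

    def layer_lengths(self, layer: str) -> dict[str, int]:
        return {c: self.contig_length(layer, c) for c in self.layers[layer]}

    def genome_size(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def read_chromosome(self, read: str) -> str:
        return self.read_origins[read].chrom

    # -- serialization ----------------------------------------------------------

    def to_dir(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "chromosomes.fasta"), "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n{seq}\n")
        with open(os.path.join(directory, "origins.tsv"), "w") as fh:
            fh.write("layer\tcontig\tchrom\tstart\tend\tstrand\toffset\n")
            for layer, contigs in self.layers.items():
                for contig, segs in contigs.items():
                    for s in segs:
                        fh.write(
                            f"{layer}\t{contig}\t{s.chrom}\t{s.start}\t{s.end}\t"
                            f"{s.strand}\t{s.offset}\n"
                        )
        with open(os.path.join(directory, "junctions.tsv"), "w") as fh:
            fh.write("layer\tcontig\tcoordinate\tchrom_a\tchrom_b\n")
            for layer, contig, coord, (ca, cb) in self.chimera_junctions:
                fh.write(f"{layer}\t{contig}\t{coord}\t{ca}\t{cb}\n")
        with open(os.path.join(directory, "reads.fastq"), "w") as fh:
            for rid, seq in self.reads.items():
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        with open(os.path.join(directory, "read_origins.tsv"), "w") as fh:
            fh.write("read\tchrom\tstart\tend\tstrand\n")
            for rid, s in self.read_origins.items():
                fh.write(f"{rid}\t{s.chrom}\t{s.start}\t{s.end}\t{s.strand}\n")
        with open(os.path.join(directory, "repeats.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tfamily\n")
            for chrom, start, end, family in self.repeats:
                fh.write(f"{chrom}\t{start}\t{end}\t{family}\n")
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump({"seed": self.seed, "telomere_motif": self.telomere_motif}, fh)

    @classmethod
    def from_dir(cls, directory) -> "SyntheticTruth":
        with open(os.path.join(directory, "meta.json")) as fh:
            meta = json.load(fh)
        truth = cls(seed=meta["seed"], telomere_motif=meta["telomere_motif"])
        name = None
        with open(os.path.join(directory, "chromosomes.fasta")) as fh:
            for line in fh:
                line = line.rstrip()
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    truth.chromosomes[name] = ""
                elif name:
                    truth.chromosomes[name] += line
        with open(os.path.join(directory, "origins.tsv")) as fh:
            next(fh)
            for line in fh:
                layer, contig, chrom, start, end, strand, offset = line.rstrip("\n").split("\t")
                truth.layers.setdefault(layer, {}).setdefault(contig, []).append(
                    OriginSegment(chrom, int(start), int(end), strand, int(offset))
                )
        with open(os.path.join(directory, "junctions.tsv")) as fh:
            next(fh)
            for line in fh:
                layer, contig, coord, ca, cb = line.rstrip("\n").split("\t")
                truth.chimera_junctions.append((layer, contig, int(coord), (ca, cb)))
        with open(os.path.join(directory, "reads.fastq")) as fh:
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline(); fh.readline()
                truth.reads[header[1:].strip()] = seq
        with open(os.path.join(directory, "read_origins.tsv")) as fh:
            next(fh)
            for line in fh:
                rid, chrom, start, end, strand = line.rstrip("\n").split("\t")
                truth.read_origins[rid] = OriginSegment(
                    chrom, int(start), int(end), strand, 0
                )
        with open(os.path.join(directory, "repeats.tsv")) as fh:
            next(fh)
            for line in fh:
                chrom, start, end, family = line.rstrip("\n").split("\t")
                truth.repeats.append((chrom, int(start), int(end), family))
        return truth


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def simulate_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc: float = 0.36,
    telomere_motif: str = "TTAGGC",
    telomere_copies: int = 300,
    repeat_spec: Mapping | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Simulate chromosomes: GC-biased i.i.d. background, telomeric repeat
    arrays at both ends, and optional interspersed diverged repeat copies.

    ``repeat_spec`` is ``{"length": bp, "copies": int, "divergence":
    fraction}``; each inserted copy carries i.i.d. point divergence from the
    family consensus and is recorded in ``truth.repeats``.  Deterministic per
    seed.  Defaults sketch a nematode-like genome (GC 0.36, motif TTAGGC).
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must list one size per chromosome")
    if min(lengths) <= 0:
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed=seed, telomere_motif=telomere_motif)
    tel = telomere_motif * telomere_copies
    for i, length in enumerate(lengths):
        if 2 * len(tel) >= length:
            raise ValueError(f"chromosome {i + 1} too short for telomere arrays")
        name = f"chr{i + 1}"
        body = _random_seq(rng, length - 2 * len(tel), gc)
        truth.chromosomes[name] = tel + body + tel
    if repeat_spec:
        rlen = int(repeat_spec["length"])
        copies = int(repeat_spec["copies"])
        div = float(repeat_spec["divergence"])
        if rlen >= min(lengths) - 2 * len(tel):
            raise ValueError("repeat longer than available chromosome interior")
        consensus = _random_seq(rng, rlen, gc)
        names = list(truth.chromosomes)
        weights = np.array([len(truth.chromosomes[n]) for n in names], dtype=float)
        weights /= weights.sum()
        for k in range(copies):
            chrom = rng.choice(names, p=weights)
            seq = truth.chromosomes[chrom]
            # keep copies disjoint so annotations stay exact
            for _ in range(200):
                pos = int(rng.integers(len(tel), len(seq) - len(tel) - rlen))
                if all(
                    c != chrom or pos + rlen <= s or pos >= e
                    for c, s, e, _f in truth.repeats
                ):
                    break
            else:
                raise ValueError("could not place repeat copies without overlap")
            copy = np.array(list(consensus))
            n_mut = rng.binomial(rlen, div)
            sites = rng.choice(rlen, size=n_mut, replace=False)
            for s in sites:
                copy[s] = rng.choice(_BASES[_BASES != copy[s]])
            truth.chromosomes[chrom] = seq[:pos] + "".join(copy) + seq[pos + rlen:]
            truth.repeats.append((chrom, pos, pos + rlen, "rep1"))
    return truth


def fragment_layer(
    truth: SyntheticTruth,
    layer_name: str,
    n50_target: int,
    overlap: int = 20_000,
    seed: int = 0,
    rc_prob: float = 0.0,
) -> dict[str, list[OriginSegment]]:
    """Cut each chromosome into overlapping fragments, emulating one draft
    assembly's contigs.

    Fragment lengths spread uniformly around ``n50_target``; adjacent
    fragments share ``overlap`` bp (the assemblable redundancy end-merging
    relies on), and breakpoints are layer-specific.  ``rc_prob`` flips
    individual fragments to the reverse strand.
    """
    rng = np.random.default_rng(seed)
    if overlap >= 0.5 * n50_target:
        raise ValueError("overlap must be small relative to fragment length")
    contigs: dict[str, list[OriginSegment]] = {}
    for chrom, seq in truth.chromosomes.items():
        L = len(seq)
        breaks = [0]
        while breaks[-1] < L:
            step = int(n50_target * rng.uniform(0.7, 1.3))
            nxt = min(breaks[-1] + step, L)
            if L - nxt < 0.35 * n50_target:
                nxt = L
            breaks.append(nxt)
        for i in range(len(breaks) - 1):
            start = breaks[i] - (overlap if i > 0 else 0)
            end = breaks[i + 1]
            strand = "-" if rng.random() < rc_prob else "+"
            name = f"{layer_name}_{chrom}_f{i}"
            contigs[name] = [OriginSegment(chrom, start, end, strand, 0)]
    truth.layers[layer_name] = contigs
    return contigs


def inject_chimeras(
    truth: SyntheticTruth,
    layer_name: str,
    plan: Sequence[tuple[str, int, str, int]],
) -> None:
    """Join fragments across chromosomes at stated coordinates.

    Each plan entry ``(chrom A, pos A, chrom B, pos B)`` truncates the
    forward fragment of A containing pos A at that coordinate and concatenates
    the suffix (from pos B) of the fragment of B containing pos B.  The
    junction coordinate on the new contig is recorded in the truth.
    """
    contigs = truth.layers[layer_name]
    for k, (chrom_a, pos_a, chrom_b, pos_b) in enumerate(plan):
        def _find(chrom, pos):
            for name, segs in contigs.items():
                if len(segs) != 1 or segs[0].strand != "+":
                    continue
                s = segs[0]
                if s.chrom == chrom and s.start < pos < s.end:
                    return name, s
            raise KeyError(
                f"no forward fragment of {chrom} containing position {pos} "
                f"in layer {layer_name}"
            )

        name_a, seg_a = _find(chrom_a, pos_a)
        name_b, seg_b = _find(chrom_b, pos_b)
        if name_a == name_b:
            raise ValueError("chimera plan points twice into the same fragment")
        junction = pos_a - seg_a.start
        chimera = f"{layer_name}_chimera{k + 1}"
        contigs.pop(name_a)
        contigs.pop(name_b)
        contigs[chimera] = [
            OriginSegment(chrom_a, seg_a.start, pos_a, "+", 0),
            OriginSegment(chrom_b, pos_b, seg_b.end, "+", junction),
        ]
        truth.chimera_junctions.append(
            (layer_name, chimera, junction, (chrom_a, chrom_b))
        )


def sample_reads(
    truth: SyntheticTruth,
    coverage: float,
    length_mean: int = 15_000,
    error_rate: float = 0.0,
    seed: int = 0,
    min_len: int = 1_000,
) -> dict[str, str]:
    """Draw reads uniformly from the genome to a target coverage.

    Lengths are exponential with mean ``length_mean`` (floored at
    ``min_len``), strands random, optional uniform point errors.  Total bases
    land within a few percent of ``coverage x genome size``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    names = list(truth.chromosomes)
    lens = np.array([len(truth.chromosomes[n]) for n in names], dtype=float)
    weights = lens / lens.sum()
    target = coverage * truth.genome_size()
    total = 0
    i = 0
    while total < target:
        chrom = names[int(rng.choice(len(names), p=weights))]
        seq = truth.chromosomes[chrom]
        length = min(max(int(rng.exponential(length_mean)), min_len), len(seq))
        start = int(rng.integers(0, len(seq) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        read = seq[start:start + length]
        if strand == "-":
            read = reverse_complement(read)
        if error_rate > 0:
            arr = np.array(list(read))
            n_err = rng.binomial(length, error_rate)
            sites = rng.choice(length, size=n_err, replace=False)
            for s in sites:
                arr[s] = rng.choice(_BASES[_BASES != arr[s]])
            read = "".join(arr)
        rid = f"read{i:06d}"
        truth.reads[rid] = read
        truth.read_origins[rid] = OriginSegment(chrom, start, start + length, strand, 0)
        total += length
        i += 1
    return truth.reads


class _SegmentIndex:
    """Per-chromosome sorted origin segments of one layer, for overlap query."""

    def __init__(self, contigs: Mapping[str, list[OriginSegment]]):
        self.by_chrom: dict[str, list[tuple[int, int, str, OriginSegment]]] = {}
        for contig, segs in contigs.items():
            for s in segs:
                self.by_chrom.setdefault(s.chrom, []).append((s.start, s.end, contig, s))
        for lst in self.by_chrom.values():
            lst.sort()

    def overlapping(self, chrom: str, lo: int, hi: int):
        for start, end, contig, seg in self.by_chrom.get(chrom, []):
            if start >= hi:
                break
            if end > lo:
                yield contig, seg


def _repeat_overlap(truth: SyntheticTruth, chrom: str, lo: int, hi: int) -> int:
    ov = 0
    for rchrom, rs, re_, _ in truth.repeats:
        if rchrom == chrom:
            ov += max(0, min(hi, re_) - max(lo, rs))
    return ov


def _pair_records(
    truth: SyntheticTruth,
    q_contigs: Mapping[str, list[OriginSegment]],
    q_lengths: Mapping[str, int],
    t_index: "_SegmentIndex",
    t_lengths: Mapping[str, int],
    min_block: int,
    identity: float,
    same_set: bool,
) -> list[AlignmentRecord]:
    records = []
    for qname, qsegs in q_contigs.items():
        for qs in qsegs:
            for tname, ts in t_index.overlapping(qs.chrom, qs.start, qs.end):
                if same_set and tname == qname:
                    continue
                lo, hi = max(qs.start, ts.start), min(qs.end, ts.end)
                if hi - lo < min_block:
                    continue
                q0, q1 = qs.to_local(lo, hi)
                t0, t1 = ts.to_local(lo, hi)
                strand = "+" if qs.strand == ts.strand else "-"
                block = hi - lo
                mapq = 60
                if _repeat_overlap(truth, qs.chrom, lo, hi) > 0.5 * block:
                    mapq = 0
                records.append(
                    AlignmentRecord(
                        query_name=qname,
                        query_len=q_lengths[qname],
                        query_start=q0,
                        query_end=q1,
                        strand=strand,
                        target_name=tname,
                        target_len=t_lengths[tname],
                        target_start=t0,
                        target_end=t1,
                        n_match=int(round(block * identity)),
                        block_len=block,
                        mapq=mapq,
                        identity=identity,
                    )
                )
    return records


def emit_truth_alignments(
    truth: SyntheticTruth,
    layer_pairs: Sequence[tuple[str, str]],
    min_block: int = 500,
) -> dict[tuple[str, str], list[AlignmentRecord]]:
    """Compute the alignments implied by shared chromosome intervals.

    For every requested ``(query layer, target layer)`` pair, any two contig
    origin segments sharing at least ``min_block`` bp of a chromosome yield
    one record with exact coordinates; mapq drops to 0 when the shared
    interval lies mostly in an annotated repeat.  A pair with equal names
    aligns a layer against itself (self-hits excluded) — the input for
    within-group overlap merging.
    """
    out: dict[tuple[str, str], list[AlignmentRecord]] = {}
    indices = {name: _SegmentIndex(truth.layers[name]) for name in truth.layers}
    lengths = {name: truth.layer_lengths(name) for name in truth.layers}
    for qlayer, tlayer in layer_pairs:
        out[(qlayer, tlayer)] = _pair_records(
            truth,
            truth.layers[qlayer],
            lengths[qlayer],
            indices[tlayer],
            lengths[tlayer],
            min_block,
            identity=1.0,
            same_set=qlayer == tlayer,
        )
    return out


def emit_read_alignments(
    truth: SyntheticTruth,
    anchor_layer: str,
    min_block: int = 500,
    error_rate: float = 0.0,
) -> list[AlignmentRecord]:
    """Read-vs-anchor-assembly alignments implied by the truth coordinates."""
    index = _SegmentIndex(truth.layers[anchor_layer])
    t_lengths = truth.layer_lengths(anchor_layer)
    q_contigs = {rid: [seg] for rid, seg in truth.read_origins.items()}
    q_lengths = {rid: len(seq) for rid, seq in truth.reads.items()}
    return _pair_records(
        truth, q_contigs, q_lengths, index, t_lengths, min_block,
        identity=1.0 - error_rate, same_set=False,
    )


def emit_hic_links(
    truth: SyntheticTruth,
    layer: str,
    cis_rate: float = 0.9,
    trans_rate: float = 0.1,
    n_pairs: int = 2_000,
    seed: int = 0,
) -> list[tuple[str, str, str, int]]:
    """Sample contact pairs with cis (same-chromosome) enrichment and
    aggregate them into a contig-pair link table for one layer."""
    if not (0 <= cis_rate <= 1 and 0 <= trans_rate <= 1) or cis_rate + trans_rate == 0:
        raise ValueError("rates must be in [0,1] and not both zero")
    rng = np.random.default_rng(seed)
    p_cis = cis_rate / (cis_rate + trans_rate)
    names = list(truth.chromosomes)
    lens = np.array([len(truth.chromosomes[n]) for n in names], dtype=float)
    weights = lens / lens.sum()
    index = _SegmentIndex(truth.layers[layer])

    def contig_at(chrom: str, pos: int):
        for contig, _seg in index.overlapping(chrom, pos, pos + 1):
            return contig
        return None

    counts: dict[tuple[str, str], int] = {}
    for _ in range(n_pairs):
        if rng.random() < p_cis:
            ci = int(rng.choice(len(names), p=weights))
            chrom_a = chrom_b = names[ci]
        else:
            ca, cb = rng.choice(len(names), size=2, replace=False, p=weights)
            chrom_a, chrom_b = names[int(ca)], names[int(cb)]
        pos_a = int(rng.integers(0, len(truth.chromosomes[chrom_a])))
        pos_b = int(rng.integers(0, len(truth.chromosomes[chrom_b])))
        a = contig_at(chrom_a, pos_a)
        b = contig_at(chrom_b, pos_b)
        if a is None or b is None or a == b:
            continue
        key = tuple(sorted((a, b)))
        counts[key] = counts.get(key, 0) + 1
    return [(a, b, "hic", c) for (a, b), c in sorted(counts.items())]


# ---------------------------------------------------------------------------
# integration preset: the end-to-end study conditions
# ---------------------------------------------------------------------------

#: 6 chromosomes spanning 0.5-2 Mb — minutes of work on one CPU while every
#: code path (splitting, clustering, partitioning, merging) is exercised.
INTEGRATION_CHROM_LENGTHS = (2_000_000, 1_600_000, 1_300_000, 1_000_000, 800_000, 500_000)
INTEGRATION_N50 = (400_000, 500_000, 600_000, 700_000, 800_000)
INTEGRATION_OVERLAP = 20_000
INTEGRATION_COVERAGE = 20.0


@dataclass
class IntegrationFixture:
    truth: SyntheticTruth
    layer_names: list[str]
    assemblies: dict[str, dict[str, int]]
    reciprocal_alignments: dict[tuple[str, str], list[AlignmentRecord]]
    read_alignments: list[AlignmentRecord]
    anchor_layer: str
    chimera_plan: list[tuple[str, str, int, str, int]]  # (layer, chrA, posA, chrB, posB)


def _mid_fragment_position(
    truth: SyntheticTruth, layer: str, chrom: str, margin: int = 150_000
) -> int:
    """A junction position deep inside some forward fragment of a chromosome."""
    candidates = [
        segs[0]
        for segs in truth.layers[layer].values()
        if len(segs) == 1 and segs[0].strand == "+" and segs[0].chrom == chrom
    ]
    seg = max(candidates, key=lambda s: s.length)
    if seg.length < 2 * margin:
        margin = seg.length // 4
    return seg.start + seg.length // 2 if seg.length // 2 >= margin else seg.start + margin


def integration_fixture(seed: int = 0, coverage: float = INTEGRATION_COVERAGE) -> IntegrationFixture:
    """The standard end-to-end scenario: 6 chromosomes, 5 assembly layers
    with layer-specific fragmentation, 3 chimeric contigs in 3 different
    layers (each joining a distinct chromosome pair), error-free reads at
    the given coverage, and all truth-derived alignments."""
    truth = simulate_genome(
        6, list(INTEGRATION_CHROM_LENGTHS), seed=seed,
    )
    layer_names = [f"L{i + 1}" for i in range(5)]
    for i, name in enumerate(layer_names):
        fragment_layer(
            truth, name, INTEGRATION_N50[i], INTEGRATION_OVERLAP,
            seed=seed * 101 + i + 1,
        )
    pairs = [("chr1", "chr2"), ("chr3", "chr4"), ("chr5", "chr6")]
    plan_log = []
    for i, (ca, cb) in enumerate(pairs):
        layer = layer_names[i]
        pos_a = _mid_fragment_position(truth, layer, ca)
        pos_b = _mid_fragment_position(truth, layer, cb)
        inject_chimeras(truth, layer, [(ca, pos_a, cb, pos_b)])
        plan_log.append((layer, ca, pos_a, cb, pos_b))

    assemblies = {name: truth.layer_lengths(name) for name in layer_names}
    directed = [(q, t) for q in layer_names for t in layer_names if q != t]
    recip = emit_truth_alignments(truth, directed, min_block=500)

    # anchor = largest-N50 layer (here simply the coarsest fragmentation)
    anchor = layer_names[-1]
    sample_reads(truth, coverage=coverage, seed=seed * 101 + 77)
    read_alns = emit_read_alignments(truth, anchor)
    return IntegrationFixture(
        truth=truth,
        layer_names=layer_names,
        assemblies=assemblies,
        reciprocal_alignments=recip,
        read_alignments=read_alns,
        anchor_layer=anchor,
        chimera_plan=plan_log,
    )
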