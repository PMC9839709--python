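"""Pairwise-alignment ingestion, filtering and merge-geometry classification.

Alignments between draft assemblies (and from raw reads to an assembly) arrive
as PAF (minimap2's native output) or SAM.  Both are normalised into
:class:`AlignmentRecord`, with coordinates 0-based half-open on the forward
strand of each sequence — the PAF convention — regardless of input format.

The merge-geometry classifier decides, for one alignment, whether the two
sequences could be merged end-to-end: the query may be *contained* in the
target, *containing* it, form a *dovetail* (suffix-to-prefix overlap), or be
only partially mapped — an *internal conflict*, where an alignment terminus
ends in the interior of both sequences.  Internal conflicts are the raw
signal for mis-assembly detection: a chimeric contig forces the alignments of
its true-locus partners to stop dead in its interior.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "AlignmentRecord",
    "FilterThresholds",
    "MergeClass",
    "ParseError",
    "parse_paf",
    "write_paf",
    "parse_sam",
    "filter_alignments",
    "classify_merge",
    "default_tolerance",
]


class ParseError(ValueError):
    """Raised for malformed alignment input; message names the offending line."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One pairwise alignment, PAF-style.

    Coordinates are 0-based half-open on the forward strand of each sequence.
    ``identity`` is the per-base agreement over the alignment block, taken
    from a divergence tag when the aligner provides one, otherwise
    ``n_match / block_len``.
    """

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    block_len: int
    mapq: int
    identity: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"bad query interval {self.query_start}-{self.query_end} "
                f"(len {self.query_len}) for {self.query_name}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"bad target interval {self.target_start}-{self.target_end} "
                f"(len {self.target_len}) for {self.target_name}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.n_match > self.block_len:
            raise ValueError("n_match exceeds block_len")
        if self.identity < 0:
            object.__setattr__(
                self, "identity", self.n_match / self.block_len if self.block_len else 0.0
            )

    def swapped(self) -> "AlignmentRecord":
        """The same alignment with query and target exchanged.

        For a reverse-strand alignment the partner's interval already refers
        to its forward strand, so coordinates carry over unchanged; only the
        roles flip.
        """
        return replace(
            self,
            query_name=self.target_name,
            query_len=self.target_len,
            query_start=self.target_start,
            query_end=self.target_end,
            target_name=self.query_name,
            target_len=self.query_len,
            target_start=self.query_start,
            target_end=self.query_end,
        )


@dataclass(frozen=True)
class FilterThresholds:
    """The four alignment-filtering criteria: mapping quality, sequence
    length, alignment block length, and sequence identity."""

    min_mapq: int = 20
    min_contig_len: int = 50_000
    min_block_len: int = 5_000
    min_identity: float = 0.90

    def __post_init__(self) -> None:
        if min(self.min_mapq, self.min_contig_len, self.min_block_len) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 <= self.min_identity <= 1):
            raise ValueError("min_identity must be in [0, 1]")


#: Filtering defaults for the raw-reads layer: reads are short relative to
#: contigs, so no length floor and a smaller block requirement.
READS_THRESHOLDS = FilterThresholds(min_mapq=20, min_contig_len=0, min_block_len=2_000)


@dataclass(frozen=True)
class MergeClass:
    """Merge geometry of one alignment.

    ``label`` is one of ``contained`` (query lies within the target, up to
    ``tol`` overhang), ``containing`` (target within query), ``dovetail``
    (end-to-end mergeable overlap) or ``internal_conflict`` (at least one
    alignment terminus ends in the interior of both sequences).
    ``conflict_breakpoints`` holds the target coordinates of the internal
    termini (0, 1 or 2 of them).
    """

    label: str
    conflict_breakpoints: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if (self.label == "internal_conflict") != bool(self.conflict_breakpoints):
            raise ValueError("internal_conflict iff breakpoints non-empty")


def default_tolerance(rec: AlignmentRecord) -> int:
    """Overhang slack for merge classification: max(500 bp, 2% of the
    shorter sequence). Absorbs aligner end-trimming on noisy reads."""
    return max(500, int(0.02 * min(rec.query_len, rec.target_len)))


_PAF_TAG = re.compile(r"^([A-Za-z][A-Za-z0-9]):([AifZHB]):(.*)$")


def _parse_paf_line(line: str, lineno: int) -> AlignmentRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ParseError(f"line {lineno}: expected >=12 PAF columns, got {len(cols)}")
    try:
        qn, ql, qs, qe, strand, tn, tl, ts, te, nm, bl, mq = cols[:12]
        rec_kwargs = dict(
            query_name=qn,
            query_len=int(ql),
            query_start=int(qs),
            query_end=int(qe),
            strand=strand,
            target_name=tn,
            target_len=int(tl),
            target_start=int(ts),
            target_end=int(te),
            n_match=int(nm),
            block_len=int(bl),
            mapq=int(mq),
        )
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric PAF field ({exc})") from None
    identity = -1.0
    for tag in cols[12:]:
        m = _PAF_TAG.match(tag)
        if m and m.group(1) in ("de", "dv") and m.group(2) == "f":
            identity = 1.0 - float(m.group(3))
            break
    try:
        return AlignmentRecord(identity=identity, **rec_kwargs)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def parse_paf(path) -> list[AlignmentRecord]:
    """Read a PAF file into records.

    Honors ``de:f``/``dv:f`` divergence tags for identity; otherwise
    identity = n_match / block_len.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            records.append(_parse_paf_line(line, lineno))
    return records


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    """Write the 12 mandatory PAF columns (re-parses bit-identically)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_name, r.query_len, r.query_start, r.query_end,
                        r.strand,
                        r.target_name, r.target_len, r.target_start, r.target_end,
                        r.n_match, r.block_len, r.mapq,
                    )
                )
                + "\n"
            )


def parse_sam(path) -> list[AlignmentRecord]:
    """Convert mapped primary + supplementary SAM records.

    Query start/end on the forward strand are recovered from the CIGAR
    clipping; target lengths come from the @SQ header. Secondary and
    unmapped records are skipped.
    """
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary:
                continue
            if aln.reference_name is None or aln.reference_length is None:
                raise ParseError(f"record {aln.query_name}: missing @SQ for reference")
            cig = aln.cigartuples or []
            for op, _ in cig:
                if op > 8:  # MIDNSHP=X are 0..8
                    raise ParseError(
                        f"record {aln.query_name}: unsupported CIGAR op code {op}"
                    )
            # clipped lengths at each end (S or H)
            lead = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            tail = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            qaln = sum(n for op, n in cig if op in (0, 1, 7, 8))
            qlen = lead + qaln + tail
            if aln.is_reverse:
                qstart, qend = tail, tail + qaln
            else:
                qstart, qend = lead, lead + qaln
            block = sum(n for op, n in cig if op in (0, 1, 2, 7, 8))
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            n_match = max(block - int(nm), 0)
            tlen = sam.get_reference_length(aln.reference_name)
            records.append(
                AlignmentRecord(
                    query_name=aln.query_name,
                    query_len=qlen,
                    query_start=qstart,
                    query_end=qend,
                    strand="-" if aln.is_reverse else "+",
                    target_name=aln.reference_name,
                    target_len=tlen,
                    target_start=aln.reference_start,
                    target_end=aln.reference_end,
                    n_match=n_match,
                    block_len=block,
                    mapq=aln.mapping_quality,
                )
            )
    return records


def filter_alignments(
    records: Sequence[AlignmentRecord],
    th: FilterThresholds,
    contig_lengths: Mapping[str, int],
) -> list[AlignmentRecord]:
    """Apply the four filtering criteria; order preserved.

    ``contig_lengths`` must cover every query and target name (lengths are
    checked against the *original* sequences, which may differ from the
    record's own fields after node splitting).
    """
    out = []
    for r in records:
        for name in (r.query_name, r.target_name):
            if name not in contig_lengths:
                raise KeyError(f"unknown sequence name in alignments: {name!r}")
        if (
            r.mapq >= th.min_mapq
            and contig_lengths[r.query_name] >= th.min_contig_len
            and contig_lengths[r.target_name] >= th.min_contig_len
            and r.block_len >= th.min_block_len
            and r.identity >= th.min_identity
        ):
            out.append(r)
    return out


def _terminus_overhangs(rec: AlignmentRecord) -> list[tuple[int, int, int]]:
    """Per alignment terminus: (query overhang, target overhang, target coord).

    The left terminus is the one at ``target_start``, the right at
    ``target_end``. The overhang is the unaligned tail beyond the terminus on
    that sequence; reverse-strand alignments mirror the query side so the
    pairing of ends is geometry-, not orientation-dependent.
    """
    q_left = rec.query_start
    q_right = rec.query_len - rec.query_end
    t_left = rec.target_start
    t_right = rec.target_len - rec.target_end
    if rec.strand == "+":
        return [(q_left, t_left, rec.target_start), (q_right, t_right, rec.target_end)]
    return [(q_right, t_left, rec.target_start), (q_left, t_right, rec.target_end)]


def classify_merge(rec: AlignmentRecord, tol: int | None = None) -> MergeClass:
    """Classify one alignment's merge geometry (see module docstring).

    A terminus is *internal* iff its distance to the sequence end it points
    at exceeds ``tol`` on both the query and the target.
    """
    if tol is None:
        tol = default_tolerance(rec)
    breakpoints = tuple(
        t_coord
        for q_over, t_over, t_coord in _terminus_overhangs(rec)
        if q_over > tol and t_over > tol
    )
    if breakpoints:
        return MergeClass("internal_conflict", breakpoints)
    if rec.query_start <= tol and rec.query_len - rec.query_end <= tol:
        return MergeClass("contained")
    if rec.target_start <= tol and rec.target_len - rec.target_end <= tol:
        return MergeClass("containing")
    return MergeClass("dovetail")
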