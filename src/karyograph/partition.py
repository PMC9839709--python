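"""Raw-read separation: assign each read to the scaffolding group that
absorbs most of its aligned bases, then export per-group read sets for
independent chromosome-by-chromosome assembly."""

from __future__ import annotations

import gzip
import os
import shlex
import subprocess
from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignio import AlignmentRecord
from .ccm import ScaffoldingGroup
from .mgraph import MultiLayerGraph

__all__ = [
    "UNPLACED",
    "AMBIGUOUS",
    "ReadAssignment",
    "assign_reads",
    "export_group_reads",
    "AssemblerJob",
    "assembler_hook",
]

UNPLACED = "UNPLACED"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class ReadAssignment:
    read: str
    group: int | str  # group id, UNPLACED or AMBIGUOUS
    best_bases: int = 0
    second_bases: int = 0
    #: for AMBIGUOUS reads: the group ids within the margin of the best one
    tied_groups: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.best_bases < self.second_bases:
            raise ValueError("best_bases must be >= second_bases")


def assign_reads(
    groups: Sequence[ScaffoldingGroup],
    read_alignments: Sequence[AlignmentRecord],
    margin: float = 0.2,
    g: MultiLayerGraph | None = None,
    warnings: list | None = None,
) -> list[ReadAssignment]:
    """Sum each read's aligned bases per group and pick a winner.

    The winning group must hold at least ``(1 + margin)`` times the bases of
    the runner-up, otherwise the read is AMBIGUOUS; reads with no surviving
    alignment into any group are UNPLACED.  When the graph ``g`` is given,
    alignments to split contigs are resolved to the fragment holding the
    majority of the target interval; otherwise contig names resolve directly.
    """
    contig_group: dict[str, list[tuple[ScaffoldingGroup, object]]] = {}
    for grp in groups:
        for node in grp.members:
            contig_group.setdefault(node.name, []).append((grp, node))

    per_read: dict[str, dict[int, int]] = {}
    seen: set[str] = set()
    stray = 0
    for rec in read_alignments:
        seen.add(rec.query_name)
        candidates = contig_group.get(rec.target_name)
        if not candidates:
            stray += 1
            continue
        if len(candidates) == 1 or g is None:
            grp = candidates[0][0]
        else:
            node = g.node_for_interval(
                candidates[0][1].layer, rec.target_name, rec.target_start, rec.target_end
            )
            grp = next(
                (gr for gr, n in candidates if n.node_id == node.node_id),
                candidates[0][0],
            )
        acc = per_read.setdefault(rec.query_name, {})
        acc[grp.id] = acc.get(grp.id, 0) + (rec.query_end - rec.query_start)

    if stray and warnings is not None:
        warnings.append(f"{stray} read alignments to contigs outside any group")

    out = []
    for read in sorted(seen):
        acc = per_read.get(read)
        if not acc:
            out.append(ReadAssignment(read, UNPLACED))
            continue
        ranked = sorted(acc.items(), key=lambda kv: (-kv[1], kv[0]))
        best_gid, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0
        if best >= (1 + margin) * second and best > 0:
            out.append(ReadAssignment(read, best_gid, best, second))
        else:
            tied = tuple(gid for gid, bases in ranked if bases * (1 + margin) > best)
            out.append(ReadAssignment(read, AMBIGUOUS, best, second, tied))
    return out


def _open_maybe_gz(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def _iter_fastx(path):
    """Yield (read id, verbatim record text) from FASTA or FASTQ."""
    with _open_maybe_gz(path) as fh:
        first = fh.read(1)
        if not first:
            return
        if first == "@":  # FASTQ: 4-line records
            line = first + fh.readline()
            while line:
                rid = line[1:].split()[0].strip()
                rec = line + fh.readline() + fh.readline() + fh.readline()
                yield rid, rec
                line = fh.readline()
        elif first == ">":
            line = first + fh.readline()
            rid, buf = line[1:].split()[0].strip(), [line]
            for line in fh:
                if line.startswith(">"):
                    yield rid, "".join(buf)
                    rid, buf = line[1:].split()[0].strip(), [line]
                else:
                    buf.append(line)
            yield rid, "".join(buf)
        else:
            raise ValueError(f"{path}: not FASTA/FASTQ (starts with {first!r})")


def export_group_reads(
    assignments: Sequence[ReadAssignment],
    reads_path,
    outdir,
    policy: str = "strict",
    near_tie_margin: float = 0.2,
) -> dict:
    """Write one FASTQ/FASTA per group, records byte-identical to the input.

    ``strict`` drops AMBIGUOUS reads; ``duplicate_ambiguous`` writes each
    ambiguous read to every group within ``near_tie_margin`` of its best
    group — useful for shared repeats, at the cost of inflated coverage.
    Returns a summary {group: {"reads": n, "bases": bp}} also written as TSV.
    """
    if policy not in ("strict", "duplicate_ambiguous"):
        raise ValueError(f"unknown policy {policy!r}")
    want: dict[str, list] = {}
    ambiguous_pool: dict[str, ReadAssignment] = {}
    for a in assignments:
        if isinstance(a.group, int):
            want.setdefault(a.read, []).append(a.group)
        elif a.group == AMBIGUOUS and policy == "duplicate_ambiguous":
            ambiguous_pool[a.read] = a

    os.makedirs(outdir, exist_ok=True)
    ext = ".fastq" if _sniff_fastq(reads_path) else ".fasta"
    handles: dict[int, object] = {}
    summary: dict[int, dict[str, int]] = {}
    missing = {a.read for a in assignments if isinstance(a.group, int)}

    try:
        for rid, rec in _iter_fastx(reads_path):
            missing.discard(rid)
            targets = list(want.get(rid, []))
            if rid in ambiguous_pool:
                targets.extend(ambiguous_pool[rid].tied_groups)
            for gid in targets:
                if gid not in handles:
                    handles[gid] = open(
                        os.path.join(outdir, f"group_{gid}{ext}"), "w"
                    )
                    summary[gid] = {"reads": 0, "bases": 0}
                handles[gid].write(rec)
                summary[gid]["reads"] += 1
                summary[gid]["bases"] += _record_bases(rec)
    finally:
        for fh in handles.values():
            fh.close()
    if missing:
        raise KeyError(
            f"{len(missing)} assigned reads missing from {reads_path}: "
            + ",".join(sorted(missing)[:10])
        )
    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write("group\treads\tbases\n")
        for gid in sorted(summary):
            fh.write(f"{gid}\t{summary[gid]['reads']}\t{summary[gid]['bases']}\n")
    return summary


def _sniff_fastq(path) -> bool:
    with _open_maybe_gz(path) as fh:
        c = fh.read(1)
    return c == "@"


def _record_bases(rec: str) -> int:
    lines = rec.splitlines()
    if lines[0].startswith("@"):
        return len(lines[1])
    return sum(len(l) for l in lines[1:])


@dataclass(frozen=True)
class AssemblerJob:
    group: object
    command: str
    returncode: int | None = None


def assembler_hook(
    group_reads: Mapping, command_template: str, dry_run: bool = True
) -> list[AssemblerJob]:
    """Render (and optionally launch) an external assembler per group.

    ``command_template`` must contain an ``{input}`` placeholder and may use
    ``{outdir}`` and ``{group}``.  With ``dry_run`` the commands are only
    rendered.  Non-zero exits are recorded; remaining groups still run.
    """
    if "{input}" not in command_template:
        raise ValueError("command template must contain an {input} placeholder")
    jobs = []
    for gid, reads_file in sorted(group_reads.items(), key=lambda kv: str(kv[0])):
        outdir = os.path.join(os.path.dirname(str(reads_file)) or ".", f"asm_group_{gid}")
        cmd = command_template.format(input=reads_file, outdir=outdir, group=gid)
        rc = None
        if not dry_run:
            rc = subprocess.run(shlex.split(cmd)).returncode
        jobs.append(AssemblerJob(group=gid, command=cmd, returncode=rc))
    return jobs
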