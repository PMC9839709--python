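"""Depth-of-coverage QC.

Read depth along an assembly is a cheap, assembler-independent error signal:
regions whose depth exceeds a multiple of the average (default double) are
*collapsed* — repeat copies merged into one locus — while internal zero-depth
holes point at joins unsupported by any read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alignio import AlignmentRecord

__all__ = [
    "DepthProfile",
    "CollapsedRegion",
    "depth_from_alignments",
    "collapsed_regions",
    "windowed_means",
    "write_collapsed_bed",
    "write_window_means",
]


@dataclass
class DepthProfile:
    sequence: str
    depth: np.ndarray  # int per-base coverage

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0


@dataclass(frozen=True)
class CollapsedRegion:
    sequence: str
    start: int
    end: int
    mean_region_depth: float


def depth_from_alignments(
    alignments: Sequence[AlignmentRecord], seq_lengths: Mapping[str, int]
) -> list[DepthProfile]:
    """Per-base depth per target sequence by difference-array accumulation.

    depth[p] counts the alignment blocks covering position p, so the total
    depth equals the total aligned block length on that sequence.
    """
    diffs = {name: np.zeros(length + 1, dtype=np.int64) for name, length in seq_lengths.items()}
    for rec in alignments:
        if rec.target_name not in diffs:
            raise KeyError(f"alignment targets unknown sequence {rec.target_name!r}")
        if rec.target_end > seq_lengths[rec.target_name]:
            raise ValueError(
                f"alignment exceeds length of {rec.target_name!r}: "
                f"{rec.target_end} > {seq_lengths[rec.target_name]}"
            )
        diffs[rec.target_name][rec.target_start] += 1
        diffs[rec.target_name][rec.target_end] -= 1
    return [
        DepthProfile(name, np.cumsum(d[:-1])) for name, d in diffs.items()
    ]


def collapsed_regions(
    profile: DepthProfile,
    multiplier: float = 2.0,
    min_len: int = 1_000,
    merge_gap: int = 0,
    mean_depth: float | None = None,
) -> list[CollapsedRegion]:
    """Maximal runs of positions with depth > multiplier x mean depth.

    With the default ``merge_gap=0`` every reported position satisfies the
    threshold pointwise; a positive ``merge_gap`` joins runs separated by
    fewer than that many sub-threshold positions (at the cost of the
    pointwise guarantee).  ``mean_depth`` may be supplied to use a
    genome-wide rather than per-sequence average.  Runs shorter than
    ``min_len`` are dropped after merging.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if len(profile.depth) == 0:
        return []
    mean = profile.mean_depth if mean_depth is None else mean_depth
    mask = profile.depth > multiplier * mean
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2]))
    if merge_gap > 0:
        joined = [list(runs[0])]
        for s, e in runs[1:]:
            if s - joined[-1][1] < merge_gap:
                joined[-1][1] = e
            else:
                joined.append([s, e])
        runs = [tuple(r) for r in joined]
    return [
        CollapsedRegion(
            profile.sequence, int(s), int(e), float(profile.depth[s:e].mean())
        )
        for s, e in runs
        if e - s >= min_len
    ]


def windowed_means(profile: DepthProfile, window: int = 5_000) -> list[tuple[int, float]]:
    """Mean depth in consecutive non-overlapping windows; the trailing partial
    window is averaged over its true length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    depth = profile.depth
    out = []
    for start in range(0, len(depth), window):
        chunk = depth[start: start + window]
        out.append((start, float(chunk.mean())))
    return out


def write_collapsed_bed(regions: Sequence[CollapsedRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.sequence}\t{r.start}\t{r.end}\t{r.mean_region_depth:.2f}\n")


def write_window_means(
    profiles: Sequence[DepthProfile], path, window: int = 5_000
) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\twindow_start\tmean_depth\n")
        for prof in profiles:
            for start, mean in windowed_means(prof, window):
                fh.write(f"{prof.sequence}\t{start}\t{mean:.4f}\n")
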