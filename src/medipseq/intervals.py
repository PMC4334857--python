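"""Genomic interval primitives shared by every stage of the pipeline.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
1-based inputs (GTF) are converted at parse time so that no other module
ever has to think about the off-by-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}; "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> List[GenomicInterval]:
    """Coalesce intervals whose gap is <= ``gap`` bp into their union.

    The result is coordinate-sorted and pairwise separated by more than
    ``gap`` bp; strand information is dropped (merged intervals are
    unstranded).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end + gap:
                cur_end = max(cur_end, end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


class IntervalIndex:
    """Per-chromosome interval tree for fast overlap queries.

    Payloads are arbitrary objects attached to each interval.
    """

    def __init__(self) -> None:
        self._trees: Dict[str, IntervalTree] = {}

    def add(self, iv: GenomicInterval, payload=None) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end, payload
        )

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[GenomicInterval], payloads: Sequence = None
    ) -> "IntervalIndex":
        idx = cls()
        for i, iv in enumerate(intervals):
            idx.add(iv, payloads[i] if payloads is not None else iv)
        return idx

    def query(self, chrom: str, start: int, end: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def query_hits(self, chrom: str, start: int, end: int) -> list:
        """Return ``(start, end, payload)`` triples of overlapping intervals."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [(hit.begin, hit.end, hit.data) for hit in tree.overlap(start, end)]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))


@dataclass
class AlignedReadSet:
    """One sample's uniquely aligned read intervals.

    ``reads`` maps chromosome name to an ``(N, 2)`` int array of
    ``[start, end)`` pairs sorted by start.  ``urc`` is the unique mapped
    read count, the normalization denominator used throughout.
    """

    sample_id: str
    reads: Dict[str, np.ndarray] = field(default_factory=dict)
    urc: int = 0

    def __post_init__(self) -> None:
        total = 0
        for chrom, arr in self.reads.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            order = np.argsort(arr[:, 0], kind="stable")
            self.reads[chrom] = arr[order]
            total += len(arr)
        if self.urc == 0:
            self.urc = total

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted fragment midpoints on ``chrom`` (empty array if none)."""
        cache = getattr(self, "_mid_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_mid_cache", cache)
        if chrom not in cache:
            arr = self.reads.get(chrom)
            if arr is None or len(arr) == 0:
                cache[chrom] = np.empty(0, dtype=np.int64)
            else:
                cache[chrom] = np.sort((arr[:, 0] + arr[:, 1]) // 2)
        return cache[chrom]

    def n_reads(self, chrom: str = None) -> int:
        if chrom is not None:
            arr = self.reads.get(chrom)
            return 0 if arr is None else len(arr)
        return sum(len(a) for a in self.reads.values())

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of reads whose midpoint falls in ``[start, end)``."""
        mids = self.midpoints(chrom)
        return int(np.searchsorted(mids, end) - np.searchsorted(mids, start))


def read_bed_reads(path, sample_id: str = None) -> AlignedReadSet:
    """Load one sample's aligned reads from a BED3+ file."""
    by_chrom: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            by_chrom.setdefault(fields[0], []).append((start, end))
    reads = {c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()}
    sid = sample_id if sample_id is not None else str(path)
    return AlignedReadSet(sample_id=sid, reads=reads)


def write_bed_reads(readset: AlignedReadSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(readset.reads):
            for start, end in readset.reads[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")
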