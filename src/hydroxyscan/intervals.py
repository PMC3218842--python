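"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Intervals are the universal currency between pipeline stages: reads after
fragment extension, candidate islands, consensus 5hmC regions, gene bodies,
enhancers, TFBS and histone-mark regions are all ``GenomicInterval`` lists.

The set-algebra helpers below (merge, intersect, overlap queries) operate on
plain python lists of intervals but vectorise internally with numpy
``searchsorted`` against per-chromosome sorted boundary arrays, so they stay
fast on the tens of thousands of intervals a genome-wide run produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "group_by_chrom",
    "sort_intervals",
    "merge_intervals",
    "intersect_intervals",
    "overlaps_any",
    "total_length",
    "midpoints",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); ``name`` and
    ``score`` carry BED columns 4-5 when present.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def group_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> Dict[str, List[GenomicInterval]]:
    out: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def sort_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def _chrom_arrays(
    intervals: Sequence[GenomicInterval],
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (starts, ends) arrays of *merged* intervals, sorted."""
    out = {}
    for chrom, ivs in group_by_chrom(merge_intervals(intervals)).items():
        out[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    return out


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> List[GenomicInterval]:
    """Union of intervals; intervals closer than ``gap`` bp are also joined.

    ``gap=0`` merges overlapping or book-ended intervals only. Strand, name
    and score are dropped (the union is unstranded).
    """
    merged: List[GenomicInterval] = []
    for chrom, ivs in sorted(group_by_chrom(intervals).items()):
        ivs = sorted(ivs, key=lambda iv: iv.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Base-pair-wise intersection ``A ∩ B`` as a merged interval list."""
    out: List[GenomicInterval] = []
    b_by_chrom = _chrom_arrays(b)
    for iv in merge_intervals(a):
        arrs = b_by_chrom.get(iv.chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        for j in range(lo, hi):
            s = max(iv.start, int(starts[j]))
            e = min(iv.end, int(ends[j]))
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e))
    return sort_intervals(out)


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean array: does each query share >= 1 bp with any subject?"""
    if len(subjects) == 0 or len(queries) == 0:
        return np.zeros(len(queries), dtype=bool)
    subj = _chrom_arrays(subjects)
    hit = np.zeros(len(queries), dtype=bool)
    q_idx: Dict[str, List[int]] = {}
    for i, iv in enumerate(queries):
        q_idx.setdefault(iv.chrom, []).append(i)
    for chrom, idx in q_idx.items():
        arrs = subj.get(chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        q_start = np.array([queries[i].start for i in idx])
        q_end = np.array([queries[i].end for i in idx])
        # last merged subject with start < q.end; overlaps iff its end > q.start
        j = np.searchsorted(starts, q_end, side="left") - 1
        ok = j >= 0
        ok[ok] = ends[j[ok]] > q_start[ok]
        hit[np.asarray(idx)] = ok
    return hit


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    """Total number of distinct bases covered (union length)."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def midpoints(intervals: Sequence[GenomicInterval]) -> List[Tuple[str, int]]:
    return [(iv.chrom, iv.midpoint) for iv in intervals]


def covered_length_in(
    window_chrom: str,
    window_start: float,
    window_end: float,
    merged_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]],
) -> float:
    """Length of ``[window_start, window_end)`` covered by merged intervals.

    Boundaries may be fractional (used by length-normalised metagene bins).
    """
    arrs = merged_by_chrom.get(window_chrom)
    if arrs is None or window_end <= window_start:
        return 0.0
    starts, ends = arrs
    lo = int(np.searchsorted(ends, window_start, side="right"))
    hi = int(np.searchsorted(starts, window_end, side="left"))
    if hi <= lo:
        return 0.0
    s = np.maximum(starts[lo:hi], window_start)
    e = np.minimum(ends[lo:hi], window_end)
    return float(np.clip(e - s, 0, None).sum())


def coverage_index(
    intervals: Sequence[GenomicInterval],
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Precomputed merged per-chromosome arrays for ``covered_length_in``."""
    return _chrom_arrays(intervals)
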