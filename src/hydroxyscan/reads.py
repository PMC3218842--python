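"""Post-alignment read hygiene and normalised density tracks.

Duplicate collapse, fragment extension and reads/bp/million coverage are the
preprocessing every immunoprecipitation library goes through before island
calling. Reads are sequenced fragment ends: a plus-strand read marks the 5'
end of its fragment, a minus-strand read the 3' end, so extension grows each
read to the library's average fragment size in the strand-appropriate
direction.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = ["deduplicate", "extend_reads", "density_track", "DensityTrack"]


def deduplicate(reads: Sequence[GenomicInterval], strand_aware: bool = True) -> List[GenomicInterval]:
    """Collapse identical reads to a single read.

    Identity is the (chrom, start, end, strand) tuple by default: a read at
    the same coordinates on the opposite strand marks the other end of a
    distinct fragment and is kept. ``strand_aware=False`` collapses on
    coordinates alone. The first occurrence is kept, and the result is
    independent of input order up to ordering (output is sorted).
    """
    seen = set()
    out: List[GenomicInterval] = []
    for r in reads:
        key = (r.chrom, r.start, r.end, r.strand if strand_aware else None)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return sorted(out, key=lambda r: (r.chrom, r.start, r.end, r.strand))


def extend_reads(
    reads: Sequence[GenomicInterval],
    fragment_size: int,
    chrom_sizes: Mapping[str, int],
) -> List[GenomicInterval]:
    """Extend each read to the average library fragment size.

    ``+`` strand ``[s, e)`` becomes ``[s, s+fragment_size)``; ``-`` strand
    becomes ``[e-fragment_size, e)``; results are clamped to the chromosome.
    Unstranded reads are treated as plus-strand.
    """
    if fragment_size <= 0:
        raise ValueError(f"fragment_size must be positive, got {fragment_size}")
    out: List[GenomicInterval] = []
    for r in reads:
        L = chrom_sizes[r.chrom]
        if r.strand == "-":
            s, e = r.end - fragment_size, r.end
        else:
            s, e = r.start, r.start + fragment_size
        s, e = max(0, s), min(L, e)
        out.append(GenomicInterval(r.chrom, s, e, r.strand))
    return out


class DensityTrack(dict):
    """Per-chromosome per-base density in reads/bp/million uniquely mapping reads.

    A thin dict subclass (chrom -> float array) that remembers the library
    size used for normalisation.
    """

    def __init__(self, values: Mapping[str, np.ndarray], library_size: int):
        super().__init__(values)
        self.library_size = library_size

    @property
    def total_mass(self) -> float:
        """Sum of density over all bases; equals total extended-fragment bp
        divided by library size in millions."""
        return float(sum(v.sum() for v in self.values()))


def density_track(
    extended: Sequence[GenomicInterval],
    library_size: int,
    chrom_sizes: Mapping[str, int],
) -> DensityTrack:
    """Per-base normalised coverage of extended fragments.

    value(b) = (# fragments covering b) / (library_size / 1e6). Computed with
    a difference-array cumsum, O(reads + genome).
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    scale = 1e6 / library_size
    diffs: Dict[str, np.ndarray] = {
        c: np.zeros(n + 1, dtype=np.float64) for c, n in chrom_sizes.items()
    }
    for iv in extended:
        d = diffs[iv.chrom]
        d[iv.start] += 1.0
        d[iv.end] -= 1.0
    values = {c: np.cumsum(d[:-1]) * scale for c, d in diffs.items()}
    return DensityTrack(values, library_size)
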