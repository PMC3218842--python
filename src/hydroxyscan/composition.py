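"""Watson-strand base composition and GC-skew around region anchors.

5hmC regions show a strand asymmetry: an excess of G over C on the Watson
strand near their 5' ends that flips to a C excess at the 3' ends. These
profiles pool base counts across regions at each offset from an anchor
(region start, end or centre) and report per-offset base frequencies plus a
sliding-window GC-skew |G-C|/(G+C). A signed variant (G-C)/(G+C) is exposed
for directional analyses. Also here: CpG-site counting used to sanity-check
dot-blot oligo designs, and a genic/enhancer/other region classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlaps_any
from .io import Genome
from .metaprofile import GeneModel

__all__ = [
    "SkewProfile",
    "base_composition_profile",
    "gc_skew",
    "signed_gc_skew",
    "count_cpg",
    "classify_regions",
    "DOT_BLOT_OLIGOS",
]

# Dot-blot control oligos named by their CpG-site count, primer arms
# included; used as worked examples for count_cpg.
_PRIMER_5 = "TACTCTATACTCTACTCATC"
_PRIMER_3 = "GAGATATGAGATGTGTATG"
DOT_BLOT_OLIGOS: Dict[int, str] = {
    12: _PRIMER_5 + "ATTACACGCGCGATATCGTTAACGATAATTCGCGCGATTACGATCGATAACGCGTTAATAT" + _PRIMER_3,
    6: _PRIMER_5 + "ATTACAATATATATATCGTTAACGATAATTCGCGCGATTACGATTTATAATTAATTAATAT" + _PRIMER_3,
    3: _PRIMER_5 + "ATTACAATATATATATAATTAATTATAATTCGCGAAATTACGATTTATAATTAATTAATAT" + _PRIMER_3,
    1: _PRIMER_5 + "ATTACAATATATATATAATTAATTATAATTAACGAAATTATAATTTATAATTAATTAATAT" + _PRIMER_3,
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SkewProfile:
    """Pooled per-offset base frequencies and sliding-window GC-skew."""

    anchor: str  # five_prime | three_prime | center
    offsets: np.ndarray  # bp relative to anchor, [-flank, +flank]
    frequencies: np.ndarray  # (n_offsets, 4) for A, C, G, T over counted bases
    n_counted: np.ndarray  # non-N bases pooled at each offset
    n_excluded: np.ndarray  # N (or off-genome) bases at each offset
    skew: np.ndarray  # |G-C|/(G+C) in sliding windows, 0-with-flag where G+C=0
    signed_skew: np.ndarray  # (G-C)/(G+C), same windows
    skew_undefined: np.ndarray  # bool: window had no G or C
    window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "offset": self.offsets,
                "fA": self.frequencies[:, 0],
                "fC": self.frequencies[:, 1],
                "fG": self.frequencies[:, 2],
                "fT": self.frequencies[:, 3],
                "skew": self.skew,
                "signed_skew": self.signed_skew,
                "n_counted": self.n_counted,
            }
        )


def gc_skew(g_count: float, c_count: float) -> Tuple[float, bool]:
    """|G-C|/(G+C); returns ``(0.0, True)`` when G+C = 0 (undefined)."""
    if g_count < 0 or c_count < 0:
        raise ValueError("counts must be >= 0")
    total = g_count + c_count
    if total == 0:
        return 0.0, True
    return abs(g_count - c_count) / total, False


def signed_gc_skew(g_count: float, c_count: float) -> Tuple[float, bool]:
    """(G-C)/(G+C), positive when G is in excess; ``(0.0, True)`` if G+C=0."""
    if g_count < 0 or c_count < 0:
        raise ValueError("counts must be >= 0")
    total = g_count + c_count
    if total == 0:
        return 0.0, True
    return (g_count - c_count) / total, False


def count_cpg(sequence: str) -> int:
    """Number of CG dinucleotides on the given strand."""
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A, C, G, T, N")
    return seq.count("CG")


def _anchor_position(region: GenomicInterval, anchor: str) -> int:
    if anchor == "five_prime":
        return region.start
    if anchor == "three_prime":
        return region.end - 1
    if anchor == "center":
        return region.midpoint
    raise ValueError(f"unknown anchor {anchor!r}")


def base_composition_profile(
    regions: Sequence[GenomicInterval],
    genome: Genome,
    anchor: str = "center",
    flank: int = 2000,
    window: int = 100,
) -> SkewProfile:
    """Watson-strand base frequencies around region anchors.

    At each offset in ``[-flank, +flank]`` the bases of all regions are
    pooled (regions whose anchor sits within ``flank`` of a chromosome edge
    contribute only their in-bounds offsets, tracked in the per-offset
    denominator). GC-skew is computed from pooled G and C counts in a
    centred sliding window of ``window`` bp, truncated at the profile ends.
    """
    if not regions:
        raise ValueError("no regions")
    offsets = np.arange(-flank, flank + 1)
    n_off = offsets.size
    counts = np.zeros((n_off, 4), dtype=np.int64)  # A C G T
    n_excl = np.zeros(n_off, dtype=np.int64)

    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i

    chrom_arrays: Dict[str, np.ndarray] = {}
    for region in regions:
        if region.chrom not in chrom_arrays:
            chrom_arrays[region.chrom] = lut[genome.array(region.chrom)]
        codes = chrom_arrays[region.chrom]
        pos = _anchor_position(region, anchor) + offsets
        valid = (pos >= 0) & (pos < codes.size)
        vcodes = codes[pos[valid]]
        known = vcodes >= 0
        rows = np.flatnonzero(valid)
        np.add.at(counts, (rows[known], vcodes[known]), 1)
        n_excl[~valid] += 1
        n_excl[rows[~known]] += 1

    n_counted = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n_counted[:, None] > 0, counts / n_counted[:, None], 0.0)

    half = window // 2
    skew = np.zeros(n_off)
    signed = np.zeros(n_off)
    undefined = np.zeros(n_off, dtype=bool)
    csum = np.vstack([np.zeros((1, 4)), np.cumsum(counts, axis=0)])
    for i in range(n_off):
        lo, hi = max(0, i - half), min(n_off, i + half + 1)
        g = csum[hi, 2] - csum[lo, 2]
        c = csum[hi, 1] - csum[lo, 1]
        signed[i], undefined[i] = signed_gc_skew(g, c)
        skew[i] = abs(signed[i])
    return SkewProfile(
        anchor=anchor,
        offsets=offsets,
        frequencies=freqs,
        n_counted=n_counted,
        n_excluded=n_excl,
        skew=skew,
        signed_skew=signed,
        skew_undefined=undefined,
        window=window,
    )


def classify_regions(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    enhancers: Sequence[GenomicInterval],
) -> List[str]:
    """Label each region ``genic`` / ``enhancer`` / ``other``.

    Priority order: a region overlapping a gene body (>= 1 bp) is genic even
    if it also overlaps an enhancer; else enhancer; else other.
    """
    bodies = [GenomicInterval(g.chrom, g.tx_start, g.tx_end) for g in genes]
    genic = overlaps_any(regions, bodies) if bodies else np.zeros(len(regions), bool)
    enh = overlaps_any(regions, enhancers) if len(enhancers) else np.zeros(len(regions), bool)
    return [
        "genic" if g else ("enhancer" if e else "other") for g, e in zip(genic, enh)
    ]
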