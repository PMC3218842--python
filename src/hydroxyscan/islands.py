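"""Window/island calling of 5hmC-enriched regions against two controls.

A simplified SICER-style caller: the genome is tiled into fixed windows,
read-rich windows are merged across small gaps into candidate islands, and
each island is scored against a background library with an upper-tail
Poisson test followed by Benjamini-Hochberg correction. A region enters the
final consensus only if it is significant against *both* the input and the
no-antibody control, in *both* antibody experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, intersect_intervals, merge_intervals

__all__ = [
    "CallerParams",
    "Island",
    "window_counts",
    "call_islands",
    "consensus_regions",
    "region_summary",
]


@dataclass
class CallerParams:
    """Island-caller tuning.

    ``window``/``gap`` default to the canonical SICER 200/600 bp; ``gap``
    must be a multiple of ``window``. ``min_reads_per_window`` is the
    eligibility threshold for a window to seed or extend an island.
    """

    window: int = 200
    gap: int = 600
    fdr: float = 0.05
    min_reads_per_window: int = 2

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.gap < 0 or self.gap % self.window != 0:
            raise ValueError("gap must be a non-negative multiple of window")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.min_reads_per_window < 0:
            raise ValueError("min_reads_per_window must be >= 0")


@dataclass
class Island:
    """A candidate enriched region scored against one control library."""

    interval: GenomicInterval
    ip_count: int
    control_count: int
    p_value: float
    q_value: float
    control_label: str = "control"


def window_counts(
    extended: Sequence[GenomicInterval],
    window: int,
    chrom_sizes: Mapping[str, int],
) -> Dict[str, np.ndarray]:
    """Count fragment midpoints per fixed genomic window.

    A fragment is assigned to exactly one window — the one containing its
    midpoint — so overlapping windows never double-count. The trailing
    partial window of each chromosome is kept.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    n_windows = {c: max(1, -(-L // window)) for c, L in chrom_sizes.items()}
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in n_windows.items()}
    by_chrom: Dict[str, List[int]] = {c: [] for c in chrom_sizes}
    for iv in extended:
        by_chrom[iv.chrom].append(iv.midpoint)
    for chrom, mids in by_chrom.items():
        if mids:
            idx = np.asarray(mids, dtype=np.int64) // window
            counts[chrom] += np.bincount(idx, minlength=n_windows[chrom])[: n_windows[chrom]]
    return counts


def _candidate_islands(
    ip_counts: Mapping[str, np.ndarray],
    params: CallerParams,
    chrom_sizes: Mapping[str, int],
) -> List[Tuple[str, int, int]]:
    """Merge eligible windows into candidate islands: (chrom, win_lo, win_hi]."""
    gap_windows = params.gap // params.window
    out: List[Tuple[str, int, int]] = []
    for chrom in sorted(ip_counts):
        eligible = np.flatnonzero(ip_counts[chrom] >= params.min_reads_per_window)
        if eligible.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(eligible) > gap_windows + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [eligible.size - 1]))
        for s, e in zip(starts, ends):
            out.append((chrom, int(eligible[s]), int(eligible[e]) + 1))
    return out


def call_islands(
    ip_counts: Mapping[str, np.ndarray],
    control_counts: Mapping[str, np.ndarray],
    library_sizes: Tuple[int, int],
    params: CallerParams,
    chrom_sizes: Mapping[str, int],
    control_label: str = "control",
) -> List[Island]:
    """Call islands for one IP/control library pair.

    Windows with at least ``min_reads_per_window`` IP fragments are merged
    into candidate islands when separated by at most ``gap`` bp. Each island
    is scored by the upper-tail Poisson probability of its IP fragment count
    given the control rate scaled by the library-size ratio. Because islands
    are *selected* for locally high IP counts, the observed control count
    alone underestimates the background over multi-window spans; the rate is
    therefore floored at the span's genome-wide expected control count (and
    at one read, avoiding zero-rate degeneracy), which keeps the island
    tests conservative under the null. BH correction runs across all
    islands of the run.
    """
    ip_lib, control_lib = library_sizes
    if control_lib <= 0:
        raise ValueError("empty control library rejected")
    for chrom in ip_counts:
        if len(ip_counts[chrom]) != len(control_counts[chrom]):
            raise ValueError(f"window grids differ on {chrom}")
    ratio = ip_lib / control_lib
    genome_bp = float(sum(chrom_sizes.values()))

    candidates = _candidate_islands(ip_counts, params, chrom_sizes)
    if not candidates:
        return []
    islands: List[Island] = []
    p_values = np.empty(len(candidates))
    for i, (chrom, lo, hi) in enumerate(candidates):
        ip_n = int(ip_counts[chrom][lo:hi].sum())
        ctl_n = int(control_counts[chrom][lo:hi].sum())
        span_bp = min(hi * params.window, chrom_sizes[chrom]) - lo * params.window
        expected_ctl = control_lib * span_bp / genome_bp
        lam = max(ctl_n, expected_ctl, 1.0) * ratio
        p = float(stats.poisson.sf(ip_n - 1, lam))
        p_values[i] = p
        interval = GenomicInterval(
            chrom, lo * params.window, min(hi * params.window, chrom_sizes[chrom])
        )
        islands.append(Island(interval, ip_n, ctl_n, p, q_value=1.0, control_label=control_label))
    _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    for isl, q in zip(islands, q_values):
        isl.q_value = float(q)
    return islands


def _passing(islands: Sequence[Island], fdr: float) -> List[GenomicInterval]:
    return [isl.interval for isl in islands if isl.q_value < fdr]


def consensus_regions(
    exp_a_vs_input: Sequence[Island],
    exp_a_vs_noab: Sequence[Island],
    exp_b_vs_input: Sequence[Island],
    exp_b_vs_noab: Sequence[Island],
    fdr: float = 0.05,
) -> List[GenomicInterval]:
    """Cross-control, cross-experiment consensus region set.

    Per experiment, the regions significant against both controls are the
    base-pair-wise intersection of the two passing island sets; the final
    set is the intersection of the two experiments' region sets, with
    book-ended pieces merged. Both steps are symmetric, so swapping the
    experiments (or the controls) leaves the result unchanged.
    """
    a = intersect_intervals(_passing(exp_a_vs_input, fdr), _passing(exp_a_vs_noab, fdr))
    b = intersect_intervals(_passing(exp_b_vs_input, fdr), _passing(exp_b_vs_noab, fdr))
    final = merge_intervals(intersect_intervals(a, b)) if a and b else []
    return [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=f"region_{i + 1:05d}")
        for i, iv in enumerate(final)
    ]


def region_summary(
    regions: Sequence[GenomicInterval],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Dict[str, object]:
    """Count, length statistics and per-chromosome region density (regions/bp)."""
    lengths = np.array([len(r) for r in regions], dtype=float)
    per_chrom: Dict[str, Dict[str, float]] = {}
    chroms = sorted(chrom_sizes) if chrom_sizes else sorted({r.chrom for r in regions})
    for chrom in chroms:
        n = sum(1 for r in regions if r.chrom == chrom)
        entry: Dict[str, float] = {"count": float(n)}
        if chrom_sizes:
            entry["density_per_bp"] = n / chrom_sizes[chrom]
        per_chrom[chrom] = entry
    return {
        "n": len(regions),
        "mean_length": float(lengths.mean()) if len(regions) else 0.0,
        "median_length": float(np.median(lengths)) if len(regions) else 0.0,
        "total_bp": float(lengths.sum()),
        "per_chromosome": per_chrom,
    }
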