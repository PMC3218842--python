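"""Metagene and feature-centred density profiles.

Aggregates a region set (e.g. consensus 5hmC regions) over many anchors on a
common coordinate frame: scaled gene bodies with fixed flanks, stratified by
expression; or fixed windows around feature centres (enhancers, TFBS). The
per-bin statistic is the mean fraction of bin bases covered by at least one
region — a "peak density" that is bounded in [0, 1] and invariant to how the
region list is split or ordered. A midpoint-count estimator is available as
an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, coverage_index, covered_length_in

__all__ = [
    "GeneModel",
    "MetaProfile",
    "smooth_profile",
    "gene_metaprofile",
    "stratify_by_expression",
    "point_metaprofile",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene body ``chrom:[tx_start, tx_end)`` with strand and id.

    The TSS is ``tx_start`` on the plus strand and ``tx_end - 1`` on the
    minus strand (the last covered base, in 0-based half-open coordinates).
    """

    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"empty gene body for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id} needs a strand")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class MetaProfile:
    """Binned mean-coverage profile, one value vector per stratum."""

    values: Dict[str, np.ndarray]
    n_features: Dict[str, int]
    bin_labels: List[str]
    bin_size: int
    kind: str  # "gene" or "point"
    smoothed: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stratum, vals in self.values.items():
            for i, (label, v) in enumerate(zip(self.bin_labels, vals)):
                rows.append(
                    {
                        "bin_index": i,
                        "bin_label": label,
                        "stratum": stratum,
                        "value": v,
                        "n": self.n_features[stratum],
                    }
                )
        return pd.DataFrame(rows)


@lru_cache(maxsize=32)
def _smoothing_matrix(n: int, half_window: int) -> np.ndarray:
    """Doubly stochastic ±half_window moving-average matrix.

    The banded all-ones matrix is Sinkhorn-balanced so that every row and
    every column sums to one: interior rows are the plain five-point moving
    average, and the few end rows get rebalanced weights. Row-stochasticity
    preserves constant profiles; column-stochasticity preserves the profile
    mean exactly.
    """
    idx = np.arange(n)
    M = (np.abs(idx[:, None] - idx[None, :]) <= half_window).astype(float)
    for _ in range(10_000):
        M /= M.sum(axis=1, keepdims=True)
        M /= M.sum(axis=0, keepdims=True)
        if max(
            np.abs(M.sum(axis=1) - 1).max(), np.abs(M.sum(axis=0) - 1).max()
        ) < 1e-13:
            break
    M /= M.sum(axis=1, keepdims=True)
    return M


def smooth_profile(values: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Moving average over ±half_window bins, mass-conserving at the ends."""
    values = np.asarray(values, dtype=float)
    if values.size <= 1 or half_window == 0:
        return values.copy()
    return _smoothing_matrix(values.size, half_window) @ values


def _bin_values(
    cov: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    chrom: str,
    edges: np.ndarray,
) -> np.ndarray:
    """Covered fraction for consecutive bins given by float edge positions."""
    out = np.empty(edges.size - 1)
    for i in range(edges.size - 1):
        lo, hi = edges[i], edges[i + 1]
        width = hi - lo
        out[i] = covered_length_in(chrom, lo, hi, cov) / width if width > 0 else 0.0
    return out


def _region_midpoint_index(regions: Sequence[GenomicInterval]) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, List[int]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r.midpoint)
    return {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}


def _bin_midpoint_counts(
    mids: Mapping[str, np.ndarray], chrom: str, edges: np.ndarray
) -> np.ndarray:
    pos = mids.get(chrom)
    if pos is None:
        return np.zeros(edges.size - 1)
    counts = np.searchsorted(pos, edges[1:]) - np.searchsorted(pos, edges[:-1])
    widths = np.diff(edges)
    return np.where(widths > 0, counts / widths, 0.0)


def gene_metaprofile(
    regions: Sequence[GenomicInterval],
    genes: Union[Sequence[GeneModel], Mapping[str, Sequence[GeneModel]]],
    bin_size: int = 300,
    flank: int = 15_000,
    n_body_bins: int = 50,
    smooth: bool = True,
    estimator: str = "coverage",
) -> MetaProfile:
    """Region density over scaled gene models with fixed flanks.

    Flanks are tiled in fixed ``bin_size`` bins; each gene body is rescaled
    into ``n_body_bins`` equal (possibly fractional) bins. Minus-strand
    genes are flipped so the TSS is always on the left. Per bin the fraction
    of bases covered by >= 1 region is averaged over the stratum's genes
    (``estimator="midpoints"`` counts region midpoints per bp instead).
    Bins beyond a chromosome end count as uncovered. Smoothing is a ±2-bin
    moving average.

    ``genes`` may be a list (single stratum ``"all"``) or a mapping of
    stratum label to gene list, e.g. from :func:`stratify_by_expression`.
    """
    if not isinstance(genes, Mapping):
        genes = {"all": list(genes)}
    if all(len(g) == 0 for g in genes.values()):
        raise ValueError("no genes to profile")
    if estimator not in ("coverage", "midpoints"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n_flank = flank // bin_size
    cov = coverage_index(regions)
    mids = _region_midpoint_index(regions) if estimator == "midpoints" else None

    labels = (
        [f"up_{(n_flank - i) * bin_size}" for i in range(n_flank)]
        + [f"body_{j + 1}" for j in range(n_body_bins)]
        + [f"down_{(i + 1) * bin_size}" for i in range(n_flank)]
    )
    values: Dict[str, np.ndarray] = {}
    n_features: Dict[str, int] = {}
    for stratum, gene_list in genes.items():
        acc = np.zeros(2 * n_flank + n_body_bins)
        for gene in gene_list:
            if gene.strand == "+":
                up = gene.tx_start - n_flank * bin_size + bin_size * np.arange(n_flank + 1.0)
                body = gene.tx_start + gene.length * np.arange(n_body_bins + 1.0) / n_body_bins
                down = gene.tx_end + bin_size * np.arange(n_flank + 1.0)
                edges = np.concatenate([up, body[1:], down[1:]])
            else:
                # build left-to-right in genomic coordinates, then flip
                up = gene.tx_end + bin_size * np.arange(n_flank + 1.0)
                body = gene.tx_start + gene.length * np.arange(n_body_bins + 1.0) / n_body_bins
                down = gene.tx_start - n_flank * bin_size + bin_size * np.arange(n_flank + 1.0)
                edges = np.concatenate([down, body[1:], up[1:]])
            if estimator == "coverage":
                vals = _bin_values(cov, gene.chrom, edges)
            else:
                assert mids is not None
                vals = _bin_midpoint_counts(mids, gene.chrom, edges)
            if gene.strand == "-":
                vals = vals[::-1]
            acc += vals
        profile = acc / len(gene_list) if gene_list else acc
        values[stratum] = smooth_profile(profile) if smooth else profile
        n_features[stratum] = len(gene_list)
    return MetaProfile(values, n_features, labels, bin_size, kind="gene", smoothed=smooth)


def stratify_by_expression(
    genes: Sequence[GeneModel],
    expression: Union[pd.DataFrame, Mapping[str, float]],
    n_strata: int = 5,
    rpkm_column: str = "rpkm_hesc",
) -> Tuple[Dict[str, List[GeneModel]], int]:
    """Split genes into near-equal expression strata, highest first.

    Genes are ranked by RPKM descending with ties broken by gene id; genes
    absent from the table are dropped and their count returned. Stratum
    labels run ``q1`` (highest) to ``q<n>``.
    """
    if isinstance(expression, pd.DataFrame):
        table = dict(zip(expression["gene_id"], expression[rpkm_column]))
    else:
        table = dict(expression)
    kept = [g for g in genes if g.gene_id in table]
    dropped = len(genes) - len(kept)
    if n_strata > len(kept):
        raise ValueError(f"n_strata={n_strata} exceeds {len(kept)} genes with expression")
    ranked = sorted(kept, key=lambda g: (-table[g.gene_id], g.gene_id))
    strata: Dict[str, List[GeneModel]] = {}
    for i, chunk in enumerate(np.array_split(np.arange(len(ranked)), n_strata)):
        strata[f"q{i + 1}"] = [ranked[j] for j in chunk]
    return strata, dropped


def point_metaprofile(
    regions: Sequence[GenomicInterval],
    centers: Sequence[GenomicInterval],
    span: int = 2000,
    window: int = 100,
    smooth: bool = False,
    estimator: str = "coverage",
) -> MetaProfile:
    """Region density in fixed windows around feature midpoints (± span)."""
    if len(centers) == 0:
        raise ValueError("empty centers rejected")
    if span % window != 0:
        raise ValueError("span must be a multiple of window")
    if estimator not in ("coverage", "midpoints"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n_bins = 2 * span // window
    cov = coverage_index(regions)
    mids = _region_midpoint_index(regions) if estimator == "midpoints" else None
    acc = np.zeros(n_bins)
    for feat in centers:
        m = feat.midpoint
        edges = m - span + window * np.arange(n_bins + 1.0)
        if estimator == "coverage":
            acc += _bin_values(cov, feat.chrom, edges)
        else:
            assert mids is not None
            acc += _bin_midpoint_counts(mids, feat.chrom, edges)
    profile = acc / len(centers)
    labels = [str(-span + window * i) for i in range(n_bins)]
    values = {"all": smooth_profile(profile) if smooth else profile}
    return MetaProfile(
        values, {"all": len(centers)}, labels, window, kind="point", smoothed=smooth
    )
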