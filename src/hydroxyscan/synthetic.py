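"""Synthetic hmeDIP-seq dataset generator.

Builds a toy multi-chromosome genome with planted GC-skewed segments, plants
"true" 5hmC regions preferentially inside those segments (and under
enhancers), and simulates already-aligned sequencing libraries: two
antibody-IP libraries enriched over the planted regions, plus matched input
and no-antibody controls drawn uniformly. Gene models, enhancers, TFBS and
histone-mark annotations, an expression table with a configurable
hESC-specific subset, and a glucosylation/MspI/HpaII qPCR copy-number table
with known modification fractions round out the dataset, so every analysis
stage has a ground truth to be scored against.

Reads are emitted as aligned intervals (BED-like), not FASTQ: alignment is
upstream of this pipeline, which consumes uniquely-mapping reads.

All randomness flows from ``SyntheticConfig.seed`` through named child
streams, so each generator is individually deterministic and the full
dataset is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals, overlaps_any, sort_intervals
from .io import Genome, write_bed, write_chrom_sizes, write_expression, write_fasta, write_qpcr
from .metaprofile import GeneModel

__all__ = [
    "SyntheticConfig",
    "TruthSet",
    "SyntheticDataset",
    "generate_genome",
    "generate_truth",
    "simulate_libraries",
    "simulate_qpcr",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# child-stream tags, one per generator, so ops are independently reproducible
_STREAM_GENOME = 1
_STREAM_TRUTH = 2
_STREAM_LIB_IP_A = 3
_STREAM_LIB_IP_B = 4
_STREAM_LIB_INPUT = 5
_STREAM_LIB_NOAB = 6
_STREAM_QPCR = 7


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults describe the standard conditions used throughout the test
    suite: a 50-Mb five-chromosome genome, 60 planted 5hmC regions of mean
    length 1.5 kb, IP libraries of 2x10^5 reads at 8-fold enrichment over
    the planted regions, 200-bp fragments from 50-b reads.
    """

    n_chroms: int = 5
    chrom_length: int = 10_000_000
    n_true_regions: int = 60
    region_length_mean: float = 1500.0
    region_length_sd: float = 300.0
    skew_segment_fraction: float = 0.012
    skew_segment_length: int = 6000
    skew_bias: float = 0.2
    ip_enrichment: float = 8.0
    depth: int = 200_000
    fragment_size: int = 200
    read_length: int = 50
    n_genes: int = 500
    n_enhancers: int = 200
    n_tfbs: int = 120
    n_histone_marks: int = 150
    specific_gene_fraction: float = 0.15
    region_at_skew_fraction: float = 0.7
    enhancer_at_region_fraction: float = 0.15
    n_qpcr_loci: int = 6
    qpcr_baseline_copies: float = 1000.0
    qpcr_background_rate: float = 0.05
    qpcr_noise_cv: float = 0.1
    qpcr_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_chroms": self.n_chroms,
            "n_true_regions": self.n_true_regions,
            "depth": self.depth,
            "n_genes": self.n_genes,
            "n_enhancers": self.n_enhancers,
            "n_tfbs": self.n_tfbs,
            "n_histone_marks": self.n_histone_marks,
            "n_qpcr_loci": self.n_qpcr_loci,
            "qpcr_replicates": self.qpcr_replicates,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        fractions = {
            "skew_segment_fraction": self.skew_segment_fraction,
            "specific_gene_fraction": self.specific_gene_fraction,
            "region_at_skew_fraction": self.region_at_skew_fraction,
            "enhancer_at_region_fraction": self.enhancer_at_region_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_chroms > 0 and self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive (zero-length chromosomes rejected)")
        if self.fragment_size < self.read_length:
            raise ValueError("fragment_size must be >= read_length")
        if self.region_length_mean <= 0:
            raise ValueError("region_length_mean must be > 0")
        if not 0.0 <= self.skew_bias <= 1.0:
            raise ValueError("skew_bias must be in [0, 1]")
        if self.qpcr_noise_cv < 0:
            raise ValueError("qpcr_noise_cv must be >= 0")
        if self.qpcr_baseline_copies < 0:
            raise ValueError("negative qPCR baseline rejected")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class TruthSet:
    """Ground truth behind a synthetic dataset."""

    regions: List[GenomicInterval]
    skew_segments: List[GenomicInterval]
    gene_models: List[GeneModel]
    enhancers: List[GenomicInterval]
    tfbs: List[GenomicInterval]
    histone_marks: List[GenomicInterval]
    expression: pd.DataFrame
    locus_fractions: pd.DataFrame  # columns: locus, hmc, mc


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: Genome
    truth: TruthSet
    libraries: Dict[str, List[GenomicInterval]]  # ip_a, ip_b, input, noab
    qpcr: pd.DataFrame


def _sample_bases(rng: np.random.Generator, n: int, p: Sequence[float]) -> np.ndarray:
    cum = np.cumsum(p)
    cum[-1] = 1.0
    return _BASES[np.searchsorted(cum, rng.random(n), side="right")]


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: Sequence[int],
    chrom_sizes: Mapping[str, int],
    occupied: Optional[List[GenomicInterval]] = None,
    pad: int = 0,
    max_tries: int = 200,
) -> List[GenomicInterval]:
    """Place intervals uniformly (chromosome ∝ length) avoiding prior placements."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: List[GenomicInterval] = []
    taken = list(occupied or [])
    for L in lengths:
        fit = sizes >= L
        if not fit.any():
            raise ValueError(f"no chromosome can fit an interval of length {L}")
        p = np.where(fit, sizes, 0.0)
        p /= p.sum()
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=p))
            start = int(rng.integers(0, chrom_sizes[chroms[ci]] - L + 1))
            cand = GenomicInterval(chroms[ci], start, start + L)
            padded = GenomicInterval(cand.chrom, max(0, cand.start - pad), cand.end + pad)
            if not overlaps_any([padded], taken)[0]:
                placed.append(cand)
                taken.append(cand)
                break
        else:
            raise RuntimeError("could not place interval without overlap; genome too full")
    return placed


def generate_genome(
    config: SyntheticConfig,
) -> Tuple[Dict[str, str], Dict[str, int], List[GenomicInterval]]:
    """Generate the toy genome and its planted GC-skew segments.

    Outside skew segments all four bases are equiprobable. Inside a segment
    the Watson strand carries a G-over-C excess on the 5' half and the
    mirror-image C-over-G excess on the 3' half: with bias ``b`` the G and C
    probabilities become ``0.25*(1±b)`` so the expected per-base signed skew
    (G-C)/(G+C) equals ``±b``. The sign flips at the segment midpoint,
    modelling regions whose 5' ends are G-rich and 3' ends C-rich.

    Returns ``(sequences, chrom_sizes, skew_segments)``.
    """
    if config.n_chroms > 0 and config.chrom_length <= 0:
        raise ValueError("zero-length chromosomes rejected")
    rng = config.rng(_STREAM_GENOME)
    sizes = config.chrom_sizes()
    b = config.skew_bias
    uniform = (0.25, 0.25, 0.25, 0.25)  # A C G T
    g_rich = (0.25, 0.25 * (1 - b), 0.25 * (1 + b), 0.25)
    c_rich = (0.25, 0.25 * (1 + b), 0.25 * (1 - b), 0.25)

    genome_len = sum(sizes.values())
    n_segments = int(round(config.skew_segment_fraction * genome_len / config.skew_segment_length))
    segments: List[GenomicInterval] = []
    if n_segments > 0 and config.skew_segment_fraction > 0:
        segments = _place_nonoverlapping(
            rng, [config.skew_segment_length] * n_segments, sizes, pad=4 * config.fragment_size
        )
        segments = sort_intervals(
            [
                GenomicInterval(s.chrom, s.start, s.end, name=f"skew_{i:04d}")
                for i, s in enumerate(sort_intervals(segments))
            ]
        )

    arrays = {c: _sample_bases(rng, n, uniform) for c, n in sizes.items()}
    for seg in segments:
        mid = (seg.start + seg.end) // 2
        arrays[seg.chrom][seg.start : mid] = _sample_bases(rng, mid - seg.start, g_rich)
        arrays[seg.chrom][mid : seg.end] = _sample_bases(rng, seg.end - mid, c_rich)

    sequences = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    return sequences, sizes, segments


def generate_truth(
    config: SyntheticConfig, skew_segments: Sequence[GenomicInterval]
) -> TruthSet:
    """Plant true 5hmC regions and generate annotations and expression.

    A ``region_at_skew_fraction`` share of the planted regions is centred on
    skew-segment midpoints (so each spans the segment's G-rich-to-C-rich
    sign flip); the rest land uniformly. Enhancers are partly centred on
    planted regions, histone marks partly on enhancers, TFBS partly on
    regions — giving downstream enrichment analyses real signal to find.
    hESC-specific genes are drawn preferentially among genes whose bodies
    overlap planted regions.
    """
    rng = config.rng(_STREAM_TRUTH)
    sizes = config.chrom_sizes()

    lengths = rng.normal(config.region_length_mean, config.region_length_sd, config.n_true_regions)
    lengths = np.maximum(lengths.round().astype(int), 200)
    n_at_skew = min(
        int(round(config.region_at_skew_fraction * config.n_true_regions)), len(skew_segments)
    )
    seg_idx = rng.choice(len(skew_segments), size=n_at_skew, replace=False) if n_at_skew else []
    regions: List[GenomicInterval] = []
    for i, si in enumerate(seg_idx):
        seg = skew_segments[int(si)]
        L = int(lengths[i])
        mid = (seg.start + seg.end) // 2
        start = max(0, mid - L // 2)
        regions.append(GenomicInterval(seg.chrom, start, min(start + L, sizes[seg.chrom])))
    free = _place_nonoverlapping(
        rng,
        [int(L) for L in lengths[n_at_skew:]],
        sizes,
        occupied=regions + list(skew_segments),
        pad=2 * config.fragment_size,
    )
    regions = sort_intervals(regions + free)
    regions = [
        GenomicInterval(r.chrom, r.start, r.end, name=f"true_{i:04d}")
        for i, r in enumerate(regions)
    ]

    gene_lengths = rng.integers(5_000, 30_001, config.n_genes)
    gene_ivs = _place_nonoverlapping(rng, [int(L) for L in gene_lengths], sizes, pad=500)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes = [
        GeneModel(iv.chrom, iv.start, iv.end, str(strand), f"gene_{i:04d}")
        for i, (iv, strand) in enumerate(zip(sort_intervals(gene_ivs), strands))
    ]

    def _at_regions(n_total: int, at_fraction: float, length: int, anchors: Sequence[GenomicInterval]) -> List[GenomicInterval]:
        n_at = min(int(round(at_fraction * n_total)), len(anchors)) if anchors else 0
        idx = rng.choice(len(anchors), size=n_at, replace=False) if n_at else []
        out = []
        for ai in idx:
            a = anchors[int(ai)]
            start = max(0, a.midpoint - length // 2)
            out.append(GenomicInterval(a.chrom, start, min(start + length, sizes[a.chrom])))
        out += _place_nonoverlapping(rng, [length] * (n_total - len(out)), sizes, occupied=out)
        return sort_intervals(out)

    enhancers = _at_regions(config.n_enhancers, config.enhancer_at_region_fraction, 1000, regions)
    enhancers = [
        GenomicInterval(e.chrom, e.start, e.end, name=f"enh_{i:04d}") for i, e in enumerate(enhancers)
    ]
    tfbs = _at_regions(config.n_tfbs, 0.3, 200, regions)
    tfbs = [GenomicInterval(t.chrom, t.start, t.end, name=f"tfbs_{i:04d}") for i, t in enumerate(tfbs)]
    marks = _at_regions(config.n_histone_marks, 0.6, 2000, enhancers)
    marks = [
        GenomicInterval(m.chrom, m.start, m.end, name=f"mark_{i:04d}") for i, m in enumerate(marks)
    ]

    gene_ivs_sorted = [GenomicInterval(g.chrom, g.tx_start, g.tx_end, g.strand, g.gene_id) for g in genes]
    overlaps = overlaps_any(gene_ivs_sorted, regions)
    n_specific = int(round(config.specific_gene_fraction * config.n_genes))
    weights = np.where(overlaps, 6.0, 1.0)
    if config.n_genes:
        weights /= weights.sum()
        specific_idx = rng.choice(config.n_genes, size=n_specific, replace=False, p=weights)
    else:
        specific_idx = np.array([], dtype=int)
    specific = np.zeros(config.n_genes, dtype=bool)
    specific[specific_idx] = True
    rpkm_hesc = np.where(
        specific,
        np.maximum(rng.lognormal(1.0, 1.0, config.n_genes), 0.5),
        rng.lognormal(0.5, 1.5, config.n_genes),
    )
    rpkm_imr90 = np.where(specific, 0.0, rng.lognormal(0.5, 1.5, config.n_genes))
    # a share of non-specific genes is silent in both lines
    silent = (~specific) & (rng.random(config.n_genes) < 0.15)
    rpkm_hesc = np.where(silent, 0.0, rpkm_hesc)
    rpkm_imr90 = np.where(silent, 0.0, rpkm_imr90)
    expression = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "rpkm_hesc": np.round(rpkm_hesc, 4),
            "rpkm_imr90": np.round(rpkm_imr90, 4),
            "hesc_specific": specific,
        }
    )

    # qPCR truth: a few "peak" loci with substantial 5hmC plus low-level controls
    n_loci = config.n_qpcr_loci
    n_peak = max(n_loci - 2, 1) if n_loci else 0
    hmc = np.concatenate(
        [rng.uniform(0.10, 0.35, n_peak), rng.uniform(0.005, 0.03, n_loci - n_peak)]
    ) if n_loci else np.array([])
    mc = rng.uniform(0.1, 0.4, n_loci) if n_loci else np.array([])
    mc = np.minimum(mc, 1.0 - hmc)  # fractions must sum <= 1
    locus_fractions = pd.DataFrame(
        {
            "locus": [f"locus_{i:02d}" for i in range(n_loci)],
            "hmc": np.round(hmc, 4),
            "mc": np.round(mc, 4),
        }
    )

    return TruthSet(
        regions=regions,
        skew_segments=list(skew_segments),
        gene_models=genes,
        enhancers=enhancers,
        tfbs=tfbs,
        histone_marks=marks,
        expression=expression,
        locus_fractions=locus_fractions,
    )


def simulate_libraries(
    config: SyntheticConfig,
    truth: TruthSet,
    streams: Tuple[int, int, int] = (_STREAM_LIB_IP_A, _STREAM_LIB_INPUT, _STREAM_LIB_NOAB),
) -> Tuple[List[GenomicInterval], List[GenomicInterval], List[GenomicInterval]]:
    """Simulate (IP, input, no-antibody) aligned-read libraries.

    IP fragment midpoints fall with density proportional to ``ip_enrichment``
    inside planted regions and uniform density elsewhere; control libraries
    are uniform everywhere. Each library contains exactly ``depth`` reads of
    ``read_length`` bp with random strand; a read marks the appropriate end
    of its ``fragment_size``-bp fragment so downstream extension recovers it.
    """
    if config.ip_enrichment < 1:
        raise ValueError("ip_enrichment < 1 rejected (IP cannot deplete the mark)")
    sizes = config.chrom_sizes()
    ip = _sample_library(config.rng(streams[0]), config, sizes, truth.regions, config.ip_enrichment)
    inp = _sample_library(config.rng(streams[1]), config, sizes, [], 1.0)
    noab = _sample_library(config.rng(streams[2]), config, sizes, [], 1.0)
    return ip, inp, noab


def _sample_library(
    rng: np.random.Generator,
    config: SyntheticConfig,
    sizes: Mapping[str, int],
    regions: Sequence[GenomicInterval],
    enrichment: float,
) -> List[GenomicInterval]:
    depth = config.depth
    if depth == 0:
        return []
    merged = merge_intervals(regions) if regions else []
    genome_len = sum(sizes.values())
    region_len = sum(len(r) for r in merged)

    # background = complement of the regions, sampled ∝ length at weight 1;
    # regions sampled at weight `enrichment` per bp
    background: List[GenomicInterval] = []
    by_chrom: Dict[str, List[GenomicInterval]] = {c: [] for c in sizes}
    for r in merged:
        by_chrom[r.chrom].append(r)
    for chrom, L in sizes.items():
        pos = 0
        for r in by_chrom[chrom]:
            if r.start > pos:
                background.append(GenomicInterval(chrom, pos, r.start))
            pos = r.end
        if pos < L:
            background.append(GenomicInterval(chrom, pos, L))

    pieces = list(merged) + background
    weights = np.array(
        [enrichment * len(p) for p in merged] + [float(len(p)) for p in background]
    )
    weights /= weights.sum()
    counts = rng.multinomial(depth, weights)

    chroms: List[str] = []
    mids: List[np.ndarray] = []
    for piece, n in zip(pieces, counts):
        if n == 0:
            continue
        chroms.extend([piece.chrom] * int(n))
        mids.append(rng.integers(piece.start, piece.end, int(n)))
    mid = np.concatenate(mids) if mids else np.array([], dtype=int)
    strand = rng.choice(np.array(["+", "-"]), size=depth)

    half = config.fragment_size // 2
    reads: List[GenomicInterval] = []
    for chrom, m, s in zip(chroms, mid, strand):
        L = sizes[chrom]
        fs = int(m) - half
        fe = fs + config.fragment_size
        if s == "+":
            rs = fs
        else:
            rs = fe - config.read_length
        rs = max(0, min(rs, L - config.read_length))
        reads.append(GenomicInterval(chrom, rs, rs + config.read_length, str(s)))
    return reads


def simulate_qpcr(
    locus_fractions: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Simulate EpiMark-style qPCR copy numbers from known fractions.

    Generative model per locus with baseline copies ``N``, background un-cut
    residue ``b``, and true fractions ``hmc``/``mc``:

    ==================  =========================
    condition            expected copies
    ==================  =========================
    (BGT, none)          N * (1 + b)
    (mock, none)         N * (1 + b)
    (BGT, MspI)          N * (hmc + b)
    (mock, MspI)         N * b
    (BGT|mock, HpaII)    N * (hmc + mc + b)
    ==================  =========================

    The background ``b`` is an additive un-cut/non-specific amplification
    residue present in every reaction — undigested ones included, which is
    what makes the standard background-subtract-and-normalise estimator
    invert this model exactly at zero noise:
    ``(N*(hmc+b) - N*b) / (N*(1+b) - N*b) = hmc``. Each measurement is
    multiplied by lognormal noise with coefficient of variation
    ``qpcr_noise_cv``.
    """
    if config.qpcr_baseline_copies < 0:
        raise ValueError("negative baseline rejected")
    rng = config.rng(_STREAM_QPCR)
    N = config.qpcr_baseline_copies
    b = config.qpcr_background_rate
    cv = config.qpcr_noise_cv
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv**2)))
        mu = -0.5 * sigma**2
    rows = []
    for _, locus in locus_fractions.iterrows():
        hmc, mc = float(locus["hmc"]), float(locus["mc"])
        if not (0 <= hmc <= 1 and 0 <= mc <= 1 and hmc + mc <= 1):
            raise ValueError(f"invalid fractions for {locus['locus']}: hmc={hmc} mc={mc}")
        expected = {
            ("BGT", "none"): N * (1 + b),
            ("mock", "none"): N * (1 + b),
            ("BGT", "MspI"): N * (hmc + b),
            ("mock", "MspI"): N * b,
            ("BGT", "HpaII"): N * (hmc + mc + b),
            ("mock", "HpaII"): N * (hmc + mc + b),
        }
        for (treatment, digestion), mean in expected.items():
            for rep in range(config.qpcr_replicates):
                noise = float(rng.lognormal(mu, sigma)) if cv > 0 else 1.0
                rows.append(
                    {
                        "locus": locus["locus"],
                        "treatment": treatment,
                        "digestion": digestion,
                        "replicate": rep,
                        "copies": mean * noise,
                    }
                )
    return pd.DataFrame(rows, columns=["locus", "treatment", "digestion", "replicate", "copies"])


def simulate_dataset(config: Optional[SyntheticConfig] = None) -> SyntheticDataset:
    """Generate the full synthetic study: genome, truth, 4 libraries, qPCR.

    The two IP libraries (``ip_a``, ``ip_b``) model the two independent
    antibody experiments and share one input and one no-antibody control,
    matching the sequencing design the caller consumes.
    """
    config = config or SyntheticConfig()
    sequences, sizes, segments = generate_genome(config)
    truth = generate_truth(config, segments)
    ip_a, inp, noab = simulate_libraries(config, truth)
    ip_b, _, _ = simulate_libraries(
        config, truth, streams=(_STREAM_LIB_IP_B, _STREAM_LIB_INPUT, _STREAM_LIB_NOAB)
    )
    qpcr = simulate_qpcr(truth.locus_fractions, config)
    return SyntheticDataset(
        config=config,
        genome=Genome(sequences=sequences),
        truth=truth,
        libraries={"ip_a": ip_a, "ip_b": ip_b, "input": inp, "noab": noab},
        qpcr=qpcr,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> Dict[str, Path]:
    """Write the dataset as plain-text files (FASTA, BED, TSV) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    tag = f"hydroxyscan simulate seed={cfg.seed}"
    paths: Dict[str, Path] = {}

    sequences = {c: dataset.genome.fetch(c, 0, n) for c, n in dataset.genome.chrom_sizes.items()}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(sequences, paths["genome"])
    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    write_chrom_sizes(dataset.genome.chrom_sizes, paths["chrom_sizes"])

    truth = dataset.truth
    bed_sets = {
        "true_regions": truth.regions,
        "skew_segments": truth.skew_segments,
        "enhancers": truth.enhancers,
        "tfbs": truth.tfbs,
        "histone_marks": truth.histone_marks,
    }
    for name, ivs in bed_sets.items():
        paths[name] = outdir / f"{name}.bed"
        write_bed(ivs, paths[name], comment=tag)
    genes_bed = [
        GenomicInterval(g.chrom, g.tx_start, g.tx_end, g.strand, g.gene_id)
        for g in truth.gene_models
    ]
    paths["genes"] = outdir / "genes.bed"
    write_bed(genes_bed, paths["genes"], comment=tag)

    for lib, reads in dataset.libraries.items():
        paths[lib] = outdir / f"reads_{lib}.bed"
        write_bed(reads, paths[lib], comment=tag)

    paths["expression"] = outdir / "expression.tsv"
    write_expression(
        truth.expression[["gene_id", "rpkm_hesc", "rpkm_imr90"]], paths["expression"], comment=tag
    )
    paths["qpcr"] = outdir / "qpcr.tsv"
    write_qpcr(dataset.qpcr, paths["qpcr"], comment=tag)
    paths["locus_fractions"] = outdir / "locus_fractions.tsv"
    truth.locus_fractions.to_csv(paths["locus_fractions"], sep="\t", index=False)
    return paths
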