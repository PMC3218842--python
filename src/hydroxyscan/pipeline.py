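"""End-to-end orchestration: reads in, consensus regions and analyses out.

``run_pipeline`` wires the stages in their natural order — deduplicate and
extend the four libraries, call islands for each IP against each control,
intersect to the consensus region set, then run whichever downstream
analyses the provided annotations allow (metaprofiles, permutation
enrichment, closest genes, specific-gene test, GC-skew, EpiMark) — and
writes plain TSV/BED outputs plus a JSON manifest of inputs, parameters,
seeds and per-stage counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import composition, enrichment, epimark, metaprofile
from .intervals import GenomicInterval
from .io import (
    Genome,
    config_hash,
    read_bed,
    read_chrom_sizes,
    read_expression,
    read_fasta,
    read_qpcr,
    write_bed,
    write_bedgraph,
)
from .islands import CallerParams, call_islands, consensus_regions, region_summary, window_counts
from .metaprofile import GeneModel
from .reads import deduplicate, density_track, extend_reads

logger = logging.getLogger("hydroxyscan")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run. Optional inputs switch their
    downstream stages on."""

    outdir: str
    reads_ip_a: str
    reads_ip_b: str
    reads_input: str
    reads_noab: str
    chrom_sizes: Optional[str] = None
    genome_fasta: Optional[str] = None
    genes_bed: Optional[str] = None
    enhancers_bed: Optional[str] = None
    tfbs_bed: Optional[str] = None
    histone_bed: Optional[str] = None
    expression_tsv: Optional[str] = None
    qpcr_tsv: Optional[str] = None
    fragment_size: int = 200
    caller: CallerParams = field(default_factory=CallerParams)
    n_strata: int = 5
    n_perm: int = 100
    skew_flank: int = 2000
    skew_window: int = 100
    seed: int = 0
    write_tracks: bool = False
    strand_aware_dedup: bool = True

    def input_paths(self) -> Dict[str, str]:
        paths = {
            "reads_ip_a": self.reads_ip_a,
            "reads_ip_b": self.reads_ip_b,
            "reads_input": self.reads_input,
            "reads_noab": self.reads_noab,
        }
        for name in (
            "chrom_sizes",
            "genome_fasta",
            "genes_bed",
            "enhancers_bed",
            "tfbs_bed",
            "histone_bed",
            "expression_tsv",
            "qpcr_tsv",
        ):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        return paths


def _read_genes(path: str, chrom_sizes: Dict[str, int]) -> List[GeneModel]:
    ivs, errors = read_bed(path, chrom_sizes=chrom_sizes)
    if errors:
        logger.warning("%s: %d malformed lines skipped", path, len(errors))
    genes = []
    for i, iv in enumerate(ivs):
        strand = iv.strand if iv.strand in "+-" else "+"
        name = iv.name if iv.name != "." else f"gene_{i:05d}"
        genes.append(GeneModel(iv.chrom, iv.start, iv.end, strand, name))
    return genes


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run all configured stages; returns the manifest dict.

    Fails fast: every referenced input path is checked before any output is
    written. Deterministic given ``config.seed``.
    """
    t0 = time.time()
    missing = [f"{k}: {v}" for k, v in config.input_paths().items() if not Path(v).exists()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))
    if config.chrom_sizes is None and config.genome_fasta is None:
        raise ValueError("need chrom_sizes or genome_fasta to define the genome")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hashed = asdict(config)
    hashed.pop("outdir")  # identical analyses hash alike wherever they land
    cfg_hash = config_hash(hashed)
    tag = f"hydroxyscan run seed={config.seed} config={cfg_hash}"
    manifest: Dict[str, object] = {
        "inputs": config.input_paths(),
        "params": asdict(config),
        "seed": config.seed,
        "config_hash": cfg_hash,
        "stages": {},
    }
    stages: Dict[str, object] = manifest["stages"]  # type: ignore[assignment]

    genome = read_fasta(config.genome_fasta) if config.genome_fasta else None
    chrom_sizes = (
        read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else genome.chrom_sizes  # type: ignore[union-attr]
    )

    # --- read processing -------------------------------------------------
    libraries: Dict[str, List[GenomicInterval]] = {}
    library_sizes: Dict[str, int] = {}
    counts: Dict[str, Dict[str, np.ndarray]] = {}
    for label, path in (
        ("ip_a", config.reads_ip_a),
        ("ip_b", config.reads_ip_b),
        ("input", config.reads_input),
        ("noab", config.reads_noab),
    ):
        t = time.time()
        raw, errors = read_bed(path, chrom_sizes=chrom_sizes)
        deduped = deduplicate(raw, strand_aware=config.strand_aware_dedup)
        extended = extend_reads(deduped, config.fragment_size, chrom_sizes)
        libraries[label] = extended
        library_sizes[label] = len(deduped)
        counts[label] = window_counts(extended, config.caller.window, chrom_sizes)
        if config.write_tracks:
            track = density_track(extended, len(deduped), chrom_sizes)
            write_bedgraph(track, outdir / f"track_{label}.bedgraph", comment=tag)
            del track
        stages[f"reads_{label}"] = {
            "raw": len(raw),
            "bad_lines": len(errors),
            "deduplicated": len(deduped),
            "seconds": round(time.time() - t, 2),
        }
        logger.info("library %s: %d reads -> %d after dedup", label, len(raw), len(deduped))

    # --- island calling and consensus ------------------------------------
    t = time.time()
    island_sets = {}
    for exp in ("ip_a", "ip_b"):
        for ctl in ("input", "noab"):
            island_sets[(exp, ctl)] = call_islands(
                counts[exp],
                counts[ctl],
                (library_sizes[exp], library_sizes[ctl]),
                config.caller,
                chrom_sizes,
                control_label=ctl,
            )
    regions = consensus_regions(
        island_sets[("ip_a", "input")],
        island_sets[("ip_a", "noab")],
        island_sets[("ip_b", "input")],
        island_sets[("ip_b", "noab")],
        fdr=config.caller.fdr,
    )
    write_bed(regions, outdir / "consensus_regions.bed", comment=tag)
    summary = region_summary(regions, chrom_sizes)
    (outdir / "region_summary.json").write_text(json.dumps(summary, indent=2))
    stages["region_calling"] = {
        "islands_per_run": {f"{e}_vs_{c}": len(v) for (e, c), v in island_sets.items()},
        "consensus_regions": len(regions),
        "mean_length": summary["mean_length"],
        "seconds": round(time.time() - t, 2),
    }

    # --- annotation-dependent analyses ------------------------------------
    genes = _read_genes(config.genes_bed, chrom_sizes) if config.genes_bed else None
    enhancers = None
    if config.enhancers_bed:
        enhancers, _ = read_bed(config.enhancers_bed, chrom_sizes=chrom_sizes)

    if genes and regions:
        expr = read_expression(config.expression_tsv) if config.expression_tsv else None
        if expr is not None:
            strata, dropped = metaprofile.stratify_by_expression(genes, expr, config.n_strata)
            profile = metaprofile.gene_metaprofile(regions, strata)
            stages["gene_metaprofile"] = {"strata": len(strata), "genes_dropped": dropped}
        else:
            profile = metaprofile.gene_metaprofile(regions, genes)
            stages["gene_metaprofile"] = {"strata": 1, "genes_dropped": 0}
        profile.to_frame().to_csv(outdir / "gene_metaprofile.tsv", sep="\t", index=False)

        assignments = enrichment.closest_gene(regions, genes)
        pd.DataFrame(
            [
                {"region": a.region_name, "gene_id": a.gene_id or "", "tss_distance": a.tss_distance}
                for a in assignments
            ]
        ).to_csv(outdir / "closest_genes.tsv", sep="\t", index=False)
        stages["closest_gene"] = {
            "assigned": sum(a.gene_id is not None for a in assignments),
            "unassigned": sum(a.gene_id is None for a in assignments),
        }

        if expr is not None:
            special, n_missing = enrichment.specific_gene_set(
                dict(zip(expr["gene_id"], expr["rpkm_hesc"])),
                dict(zip(expr["gene_id"], expr["rpkm_imr90"])),
            )
            test = enrichment.gene_set_overlap_test(special, genes, regions)
            stages["specific_genes"] = {
                "n_specific": len(special),
                "missing_expression": n_missing,
                "special_overlap_pct": test.special_overlap_pct,
                "all_overlap_pct": test.all_overlap_pct,
                "fisher_p": test.p_value,
            }

    feature_sets = {}
    if enhancers:
        feature_sets["enhancers"] = enhancers
    if config.histone_bed:
        feature_sets["histone_marks"], _ = read_bed(config.histone_bed, chrom_sizes=chrom_sizes)
    if feature_sets and regions:
        rows = []
        for name, features in feature_sets.items():
            res = enrichment.permutation_enrichment(
                regions, features, chrom_sizes, n_perm=config.n_perm, seed=config.seed
            )
            rows.append(
                {
                    "feature_set": name,
                    "observed": res.observed_overlap,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "z": res.z_score,
                    "p": res.empirical_p,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        stages["enrichment"] = {r["feature_set"]: round(r["z"], 2) for r in rows}

    if config.tfbs_bed and regions:
        tfbs, _ = read_bed(config.tfbs_bed, chrom_sizes=chrom_sizes)
        if tfbs:
            prof = metaprofile.point_metaprofile(regions, tfbs)
            prof.to_frame().to_csv(outdir / "tfbs_metaprofile.tsv", sep="\t", index=False)
            stages["tfbs_metaprofile"] = {"n_sites": len(tfbs)}
    if enhancers and regions:
        prof = metaprofile.point_metaprofile(regions, enhancers)
        prof.to_frame().to_csv(outdir / "enhancer_metaprofile.tsv", sep="\t", index=False)

    if genome is not None and regions:
        frames = []
        for anchor in ("five_prime", "three_prime", "center"):
            prof = composition.base_composition_profile(
                regions, genome, anchor=anchor, flank=config.skew_flank, window=config.skew_window
            )
            frames.append(prof.to_frame())
        pd.concat(frames).to_csv(outdir / "skew_profiles.tsv", sep="\t", index=False)
        if genes is not None and enhancers is not None:
            labels = composition.classify_regions(regions, genes, enhancers)
            stages["region_classes"] = {
                label: labels.count(label) for label in ("genic", "enhancer", "other")
            }
        stages["skew"] = {"anchors": 3, "flank": config.skew_flank}

    if config.qpcr_tsv:
        qpcr = read_qpcr(config.qpcr_tsv)
        table = epimark.modification_table(qpcr)
        table.to_csv(outdir / "modification_fractions.tsv", sep="\t", index=False)
        stages["epimark"] = {
            "loci": len(table),
            "hmc_range": [float(table["hmc_fraction"].min()), float(table["hmc_fraction"].max())]
            if len(table)
            else None,
        }

    manifest["total_seconds"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
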