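"""Readers and writers for the plain-text formats the pipeline speaks.

BED (0-based half-open) is the sole interval dialect; every writer emits a
``#`` header line recording the producing command, seed and a config hash so
outputs are self-describing. FASTA access goes through :class:`Genome`, which
wraps either a pyfaidx-indexed file or an in-memory dict of sequences behind
one slicing interface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_expression",
    "write_expression",
    "read_qpcr",
    "write_qpcr",
    "write_bedgraph",
]

_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass
class BedParseError:
    line_number: int
    line: str
    reason: str


def read_bed(
    path: Union[str, Path],
    chrom_sizes: Optional[Mapping[str, int]] = None,
    strict: bool = False,
) -> Tuple[List[GenomicInterval], List[BedParseError]]:
    """Parse a 3-6 column BED file into intervals.

    Invalid lines (too few columns, non-integer or inverted coordinates) are
    collected as :class:`BedParseError` with their 1-based line numbers rather
    than aborting the whole file. If ``chrom_sizes`` is given, intervals on
    unknown chromosomes are an error under ``strict`` and a collected warning
    otherwise.

    Returns ``(intervals, errors)``.
    """
    intervals: List[GenomicInterval] = []
    errors: List[BedParseError] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append(BedParseError(lineno, line, "fewer than 3 columns"))
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append(BedParseError(lineno, line, "non-integer coordinates"))
                continue
            if start < 0 or start >= end:
                errors.append(
                    BedParseError(lineno, line, f"empty/inverted interval {start}-{end}")
                )
                continue
            if chrom_sizes is not None and chrom not in chrom_sizes:
                err = BedParseError(lineno, line, f"unknown chromosome {chrom!r}")
                if strict:
                    raise ValueError(f"line {lineno}: {err.reason}")
                errors.append(err)
                continue
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError:
                score = 0.0
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name, score))
    return intervals, errors


def _header(comment: Optional[str]) -> List[str]:
    return [f"# {comment}"] if comment else []


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: Union[str, Path],
    comment: Optional[str] = None,
) -> None:
    """Write BED6. A ``comment`` becomes a leading ``#`` header line."""
    lines = _header(comment)
    for iv in intervals:
        score = f"{iv.score:g}"
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}")
    Path(path).write_text("\n".join(lines) + "\n")


class Genome:
    """Random-access genome sequence, uppercase, 0-based half-open slicing.

    Backed either by an in-memory ``{chrom: sequence}`` dict or by a
    pyfaidx-indexed FASTA file. Out-of-range slices raise ``IndexError``.
    """

    def __init__(self, sequences: Optional[Mapping[str, str]] = None, fasta: Optional[Fasta] = None):
        if (sequences is None) == (fasta is None):
            raise ValueError("provide exactly one of sequences or fasta")
        self._seqs = {c: s.upper() for c, s in sequences.items()} if sequences else None
        self._fasta = fasta
        if self._seqs is not None:
            self.chrom_sizes: Dict[str, int] = {c: len(s) for c, s in self._seqs.items()}
        else:
            assert fasta is not None
            self.chrom_sizes = {name: len(rec) for name, rec in fasta.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        if start < 0 or end > size or start > end:
            raise IndexError(f"slice {chrom}:{start}-{end} outside [0, {size}]")
        if start == end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        assert self._fasta is not None
        return str(self._fasta[chrom][start:end]).upper()

    def array(self, chrom: str) -> np.ndarray:
        """Whole chromosome as a uint8 byte array (fast composition counting)."""
        seq = self.fetch(chrom, 0, self.chrom_sizes[chrom])
        return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def read_fasta(path: Union[str, Path]) -> Genome:
    """Open an indexable FASTA. Duplicate headers are rejected by pyfaidx."""
    return Genome(fasta=Fasta(str(path), duplicate_action="stop", sequence_always_upper=True))


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: Union[str, Path]) -> Dict[str, int]:
    out: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, size = line.split("\t")[:2]
            out[chrom] = int(size)
    return out


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: Union[str, Path]) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{s}\n" for c, s in chrom_sizes.items())
    )


def read_expression(path: Union[str, Path]) -> pd.DataFrame:
    """Expression table: gene_id, rpkm_hesc, rpkm_imr90 (TSV with header)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "rpkm_hesc", "rpkm_imr90"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df


def write_expression(df: pd.DataFrame, path: Union[str, Path], comment: Optional[str] = None) -> None:
    _write_tsv(df, path, comment)


def read_qpcr(path: Union[str, Path]) -> pd.DataFrame:
    """qPCR copy table: locus, treatment(BGT|mock), digestion(none|MspI|HpaII), replicate, copies."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"locus", "treatment", "digestion", "replicate", "copies"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return df


def write_qpcr(df: pd.DataFrame, path: Union[str, Path], comment: Optional[str] = None) -> None:
    _write_tsv(df, path, comment)


def _write_tsv(df: pd.DataFrame, path: Union[str, Path], comment: Optional[str]) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_bedgraph(
    track: Mapping[str, np.ndarray],
    path: Union[str, Path],
    track_header: bool = False,
    comment: Optional[str] = None,
) -> None:
    """Write per-base values as bedGraph with equal-value runs merged.

    Zero-valued runs are written too, so the file tiles each chromosome; this
    keeps read-back trivially exact.
    """
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        if track_header:
            fh.write("track type=bedGraph\n")
        for chrom, values in track.items():
            values = np.asarray(values)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:g}\n")


def config_hash(obj) -> str:
    """Short stable hash of a configuration object for output headers."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
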