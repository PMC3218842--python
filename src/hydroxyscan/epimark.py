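"""Per-locus 5hmC / 5mC / unmodified fractions from glucosylation qPCR.

The assay: genomic DNA is either glucosylated with beta-glucosyltransferase
(BGT) + UDP-glucose or mock treated, then split and left undigested,
digested with MspI, or with HpaII. MspI cuts CCGG regardless of CpG
methylation but cannot cut glucosyl-5hmC, so the surviving (amplifiable)
copies in the BGT+MspI reaction report the 5hmC fraction. HpaII cuts only
fully unmodified CCGG, so its surviving copies report 5hmC + 5mC. Copy
numbers are background-subtracted (the mock+MspI reaction, where everything
is cuttable, defines background) and normalised to the undigested
glucosylated sample:

    hmc       = (copies[BGT, MspI] - B) / (copies[BGT, none] - B)
    resistant = (copies[*, HpaII]  - B) / (copies[*, none]  - B)
    mc        = resistant - hmc
    unmod     = 1 - resistant          with B = mean copies[mock, MspI]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["QpcrMeasurement", "ModificationEstimate", "modification_fractions", "modification_table"]

_TREATMENTS = {"BGT", "mock"}
_DIGESTIONS = {"none", "MspI", "HpaII"}


@dataclass(frozen=True)
class QpcrMeasurement:
    locus: str
    treatment: str  # BGT | mock
    digestion: str  # none | MspI | HpaII
    replicate: int
    copies: float

    def __post_init__(self) -> None:
        if self.treatment not in _TREATMENTS:
            raise ValueError(f"treatment must be one of {sorted(_TREATMENTS)}")
        if self.digestion not in _DIGESTIONS:
            raise ValueError(f"digestion must be one of {sorted(_DIGESTIONS)}")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


@dataclass
class ModificationEstimate:
    locus: str
    hmc_fraction: float
    mc_fraction: float
    unmodified_fraction: float
    hmc_sd: float = float("nan")
    mc_sd: float = float("nan")
    unmodified_sd: float = float("nan")
    clamped: bool = False
    negative_input: bool = False


def _mean(measurements: Sequence[QpcrMeasurement], treatment: Optional[str], digestion: str) -> Optional[float]:
    vals = [
        m.copies
        for m in measurements
        if m.digestion == digestion and (treatment is None or m.treatment == treatment)
    ]
    return float(np.mean(vals)) if vals else None


def _fractions(undig: float, bgt_mspi: float, hpaii: float, background: float):
    denom = undig - background
    if denom <= 0:
        raise ValueError(
            f"assay failure: undigested signal ({undig:g}) does not exceed background ({background:g})"
        )
    hmc = (bgt_mspi - background) / denom
    resistant = (hpaii - background) / denom
    mc = resistant - hmc
    unmod = 1.0 - resistant
    return hmc, mc, unmod


def modification_fractions(
    measurements: Sequence[QpcrMeasurement],
    background: Optional[float] = None,
) -> ModificationEstimate:
    """Estimate (5hmC, 5mC, unmodified) fractions for one locus.

    Replicates are averaged before the point estimate; per-fraction standard
    deviations come from recomputing the fractions replicate-by-replicate.
    Background defaults to the mean (mock, MspI) signal but may be supplied
    as a constant. Negative intermediate fractions are clamped to zero with
    a flag (visible assay failure, not silent truncation) and the three
    fractions renormalised to sum to one. HpaII copies are averaged over
    whichever treatments are present — glucosylation does not affect HpaII
    in this model.

    Raises ``ValueError`` when a required condition is missing or the
    background reaches the undigested signal (assay failure).
    """
    loci = {m.locus for m in measurements}
    if len(loci) != 1:
        raise ValueError(f"measurements must come from one locus, got {sorted(loci)}")
    locus = loci.pop()

    undig = _mean(measurements, "BGT", "none")
    bgt_mspi = _mean(measurements, "BGT", "MspI")
    mock_mspi = _mean(measurements, "mock", "MspI")
    hpaii = _mean(measurements, None, "HpaII")
    required = {
        "(BGT, none)": undig,
        "(BGT, MspI)": bgt_mspi,
        "(any, HpaII)": hpaii,
    }
    if background is None:
        required["(mock, MspI)"] = mock_mspi
    missing = [name for name, v in required.items() if v is None]
    if missing:
        raise ValueError(f"locus {locus}: missing required condition(s) {missing}")
    B = background if background is not None else mock_mspi
    assert B is not None

    hmc, mc, unmod = _fractions(undig, bgt_mspi, hpaii, B)
    negative = hmc < 0 or mc < 0 or unmod < 0
    clipped = np.clip([hmc, mc, unmod], 0.0, 1.0)
    total = clipped.sum()
    if total > 0:
        clipped = clipped / total
    hmc_c, mc_c, unmod_c = (float(v) for v in clipped)

    # replicate-wise recomputation for sds, skipping failed replicates
    reps = sorted({m.replicate for m in measurements})
    per_rep: List[np.ndarray] = []
    for rep in reps:
        sub = [m for m in measurements if m.replicate == rep]
        try:
            u = _mean(sub, "BGT", "none")
            g = _mean(sub, "BGT", "MspI")
            h = _mean(sub, None, "HpaII")
            b_rep = B if background is not None else _mean(sub, "mock", "MspI")
            if None in (u, g, h, b_rep):
                continue
            per_rep.append(np.array(_fractions(u, g, h, b_rep)))
        except ValueError:
            continue
    if len(per_rep) >= 2:
        sds = np.std(np.vstack(per_rep), axis=0, ddof=1)
    else:
        sds = np.full(3, np.nan)

    return ModificationEstimate(
        locus=locus,
        hmc_fraction=hmc_c,
        mc_fraction=mc_c,
        unmodified_fraction=unmod_c,
        hmc_sd=float(sds[0]),
        mc_sd=float(sds[1]),
        unmodified_sd=float(sds[2]),
        clamped=bool(negative),
        negative_input=bool(negative),
    )


def modification_table(qpcr: pd.DataFrame, background: Optional[float] = None) -> pd.DataFrame:
    """Run :func:`modification_fractions` per locus of a qPCR table."""
    rows = []
    for locus, sub in qpcr.groupby("locus", sort=True):
        ms = [
            QpcrMeasurement(
                str(r.locus), str(r.treatment), str(r.digestion), int(r.replicate), float(r.copies)
            )
            for r in sub.itertuples()
        ]
        est = modification_fractions(ms, background=background)
        rows.append(
            {
                "locus": est.locus,
                "hmc_fraction": est.hmc_fraction,
                "mc_fraction": est.mc_fraction,
                "unmodified_fraction": est.unmodified_fraction,
                "hmc_sd": est.hmc_sd,
                "mc_sd": est.mc_sd,
                "unmodified_sd": est.unmodified_sd,
                "clamped": est.clamped,
            }
        )
    return pd.DataFrame(rows)
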