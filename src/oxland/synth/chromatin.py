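"""Planted chromatin-loop anchors and their histone/cohesin tracks.

Each planted anchor carries a ground-truth insulation label. The simulator
emits CTCF/RAD21/SMC3 peaks overlapping the anchor motif and step-shaped
H3K36me3/H3K27me3 coverage over the 10-kb windows on either side consistent
with the label, plus optional multiplicative log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from ..genome import Genome
from ..tracks import BinnedTrack, n_bins

LABELS = ("swap_on", "swap_off", "on", "off")

ACTIVE = 8.0    # H3K36me3 coverage in active chromatin
INACTIVE = 1.0  # H3K36me3 coverage in inactive chromatin (marks swap roles)
BACKGROUND = 1.0


@dataclass
class ChromatinTracks:
    ctcf_peaks: pd.DataFrame
    rad21_peaks: pd.DataFrame
    smc3_peaks: pd.DataFrame
    motifs: pd.DataFrame
    h3k36: BinnedTrack
    h3k27: BinnedTrack


def plant_anchors(genome: Genome, n_per_chrom: int = 30, window: int = 10_000,
                  seed: int = 0, avoid=None) -> pd.DataFrame:
    """Evenly spaced anchors with cycling ground-truth labels.

    Spacing guarantees that the +/-window histone steps of neighbouring
    anchors never overlap; windows avoid undefined sequence and, when an
    ``avoid`` interval frame is given, those regions too (anchors are
    intergenic: their chromatin-state steps should not cut through gene
    territories). Returns chrom, center, strand, true_class.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in genome:
        L = genome.length(chrom)
        defined = genome.defined_mask(chrom).copy()
        if avoid is not None and len(avoid):
            from ..features import interval_mask

            sub = avoid[avoid["chrom"] == chrom]
            defined &= ~interval_mask(L, sub["start"].to_numpy(),
                                      sub["end"].to_numpy())
        margin = 2 * window + 1000
        slot = (L - 2 * margin) // n_per_chrom
        if slot < 2 * window + 1000:
            raise ValueError("chromosome too short for the requested anchors")
        for k in range(n_per_chrom):
            centre = None
            for _ in range(50):  # avoid windows touching undefined sequence
                cand = margin + k * slot + int(rng.integers(0, slot - 2 * window))
                if defined[cand - window:cand + window].all():
                    centre = cand
                    break
            if centre is None:
                continue
            rows.append({
                "chrom": chrom, "center": centre,
                "strand": "+" if rng.random() < 0.5 else "-",
                "true_class": LABELS[k % len(LABELS)],
            })
    return pd.DataFrame(rows)


def _label_levels(label: str) -> Dict[str, float]:
    """(out, in) H3K36me3/H3K27me3 levels implied by a ground-truth label."""
    if label == "swap_on":    # outside inactive, inside active
        return {"k36_out": INACTIVE, "k27_out": ACTIVE,
                "k36_in": ACTIVE, "k27_in": INACTIVE}
    if label == "swap_off":
        return {"k36_out": ACTIVE, "k27_out": INACTIVE,
                "k36_in": INACTIVE, "k27_in": ACTIVE}
    if label == "on":
        return {"k36_out": ACTIVE, "k27_out": INACTIVE,
                "k36_in": ACTIVE, "k27_in": INACTIVE}
    if label == "off":
        return {"k36_out": INACTIVE, "k27_out": ACTIVE,
                "k36_in": INACTIVE, "k27_in": ACTIVE}
    raise ValueError(f"unknown anchor label {label!r}")


def simulate_chromatin(genome: Genome, anchors: pd.DataFrame,
                       window: int = 10_000, bin_size: int = 100,
                       peak_halfwidth: int = 150, noise_sd: float = 0.0,
                       seed: int = 0) -> ChromatinTracks:
    """Peaks and histone coverage consistent with the planted anchor labels.

    ``noise_sd`` is the sigma of multiplicative log-normal noise per coverage
    bin; zero gives the noiseless limit in which the insulation classifier
    must recover every label.
    """
    rng = np.random.default_rng(seed)
    k36 = {}
    k27 = {}
    for chrom in genome:
        nb = n_bins(genome.length(chrom), bin_size)
        k36[chrom] = np.full(nb, BACKGROUND, dtype=np.float64)
        k27[chrom] = np.full(nb, BACKGROUND, dtype=np.float64)
    peaks: Dict[str, List[dict]] = {"ctcf": [], "rad21": [], "smc3": []}
    motif_rows = []
    for r in anchors.itertuples(index=False):
        c = int(r.center)
        upstream = (c - window, c)
        downstream = (c, c + window)
        out_win, in_win = ((upstream, downstream) if r.strand != "-"
                           else (downstream, upstream))
        levels = _label_levels(r.true_class)
        for (lo, hi), suffix in ((out_win, "out"), (in_win, "in")):
            b_lo, b_hi = lo // bin_size, -(-hi // bin_size)
            k36[r.chrom][b_lo:b_hi] = levels[f"k36_{suffix}"]
            k27[r.chrom][b_lo:b_hi] = levels[f"k27_{suffix}"]
        motif_rows.append({"chrom": r.chrom, "start": c - 9, "end": c + 10,
                           "name": "ctcf_motif", "score": 0, "strand": r.strand,
                           "feature_class": "ctcf_motif"})
        for mark in peaks:
            peaks[mark].append({
                "chrom": r.chrom, "start": c - peak_halfwidth,
                "end": c + peak_halfwidth,
                "name": mark, "score": float(rng.uniform(5, 15)),
                "strand": ".", "feature_class": f"{mark}_peak"})
    if noise_sd > 0:
        for chrom in k36:
            k36[chrom] *= rng.lognormal(0.0, noise_sd, size=len(k36[chrom]))
            k27[chrom] *= rng.lognormal(0.0, noise_sd, size=len(k27[chrom]))
    return ChromatinTracks(
        ctcf_peaks=pd.DataFrame(peaks["ctcf"]),
        rad21_peaks=pd.DataFrame(peaks["rad21"]),
        smc3_peaks=pd.DataFrame(peaks["smc3"]),
        motifs=pd.DataFrame(motif_rows),
        h3k36=BinnedTrack(bin_size, k36),
        h3k27=BinnedTrack(bin_size, k27),
    )
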