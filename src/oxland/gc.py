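"""GC-content tracks, trinucleotide spectra, and sequence-based expectations.

GC content is computed in 1-kb bins over defined bases only, rounded
half-away-from-zero to integer percent; bins with more than 10% undefined
sequence are censored and excluded from every GC-stratified statistic
downstream. Trinucleotides are folded with their reverse complements into 32
strand-agnostic classes (no odd-length trinucleotide is self-complementary,
so the 64 sequences collapse exactly to 64/2 = 32).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .genome import CODE_A, CODE_C, CODE_G, CODE_T, Genome, revcomp
from .smoothing import gaussian_smooth
from .tracks import BinnedTrack, EnrichmentTrack, n_bins

BASES = "ACGT"
TRINUCS = [a + b + c for a in BASES for b in BASES for c in BASES]

#: The 32 reverse-complement-collapsed trinucleotide classes, sorted.
CLASSES: List[str] = sorted({min(t, revcomp(t)) for t in TRINUCS})
CLASS_INDEX: Dict[str, int] = {t: i for i, t in enumerate(CLASSES)}

#: 64-entry lookup: lexicographic trinucleotide index -> folded class index.
FOLD_TABLE = np.array(
    [CLASS_INDEX[min(t, revcomp(t))] for t in TRINUCS], dtype=np.uint8
)

INVALID = np.uint8(255)

_BASE2BIT = np.full(256, INVALID, dtype=np.uint8)
for _code, _bit in ((CODE_A, 0), (CODE_C, 1), (CODE_G, 2), (CODE_T, 3)):
    _BASE2BIT[_code] = _bit


def fold_trinuc(trinuc: str) -> str:
    """Canonical (reverse-complement-collapsed) representative of a trinucleotide."""
    return min(trinuc, revcomp(trinuc))


def central_pair(class_index: int) -> str:
    """Central-base pair of a folded class: 'CG' or 'AT'."""
    centre = CLASSES[class_index][1]
    return "CG" if centre in "CG" else "AT"


#: Folded classes whose central base pair matches each mutation type.
CG_CLASSES = np.array([i for i in range(32) if central_pair(i) == "CG"])
AT_CLASSES = np.array([i for i in range(32) if central_pair(i) == "AT"])


def classes_for_mutation_type(mutation_type: str) -> np.ndarray:
    """Valid context classes for a folded mutation type (C>A, C>T: CG; T>G: AT)."""
    ref = mutation_type.split(">")[0]
    return CG_CLASSES if ref in "CG" else AT_CLASSES


def trinuc_class_codes(genome: Genome, chrom: str) -> np.ndarray:
    """Folded class code of the trinucleotide centred at each position.

    Positions where the window leaves the chromosome or touches undefined
    sequence carry the INVALID code.
    """
    bits = _BASE2BIT[genome.codes(chrom)]
    length = len(bits)
    out = np.full(length, INVALID, dtype=np.uint8)
    if length < 3:
        return out
    b0, b1, b2 = bits[:-2], bits[1:-1], bits[2:]
    valid = (b0 != INVALID) & (b1 != INVALID) & (b2 != INVALID)
    idx = (b0.astype(np.int32) * 16 + b1 * 4 + b2)[valid]
    centre = np.arange(1, length - 1)[valid]
    out[centre] = FOLD_TABLE[idx]
    return out


@dataclass
class GcTrack:
    """Integer-percent GC per bin, with the 10%-undefined censoring rule."""

    bin_size: int
    gc_percent: Dict[str, np.ndarray]  # float arrays holding integer percents
    defined_fraction: Dict[str, np.ndarray]
    censored: Dict[str, np.ndarray]

    @property
    def chroms(self) -> List[str]:
        return list(self.gc_percent)

    def rich_mask(self, chrom: str, cutoff: int = 50) -> np.ndarray:
        """Uncensored bins with GC at or above the cutoff (GC-rich)."""
        gc = self.gc_percent[chrom]
        return (~self.censored[chrom]) & np.greater_equal(
            np.nan_to_num(gc, nan=-1.0), cutoff
        )

    def bin_of(self, chrom: str, positions) -> np.ndarray:
        return np.asarray(positions, dtype=np.int64) // self.bin_size


def gc_per_bin(genome: Genome, bin_size: int = 1000,
               max_undefined: float = 0.10) -> GcTrack:
    """GC percent per bin over defined bases, with censoring.

    Rounding is half-away-from-zero to the closest integer percent; a bin is
    censored when its undefined-sequence fraction exceeds ``max_undefined``
    (strictly more than 10% by default).
    """
    gc_percent, defined_fraction, censored = {}, {}, {}
    for chrom in genome:
        length = genome.length(chrom)
        nb = n_bins(length, bin_size)
        bin_idx = np.arange(length) // bin_size
        gc_sum = np.bincount(bin_idx, weights=genome.gc_mask(chrom), minlength=nb)
        def_sum = np.bincount(bin_idx, weights=genome.defined_mask(chrom), minlength=nb)
        widths = (np.minimum((np.arange(nb) + 1) * bin_size, length)
                  - np.arange(nb) * bin_size)
        def_frac = def_sum / widths
        with np.errstate(invalid="ignore", divide="ignore"):
            gc = np.floor(gc_sum / def_sum * 100.0 + 0.5)
        gc[def_sum == 0] = np.nan
        cens = (1.0 - def_frac) > max_undefined
        gc_percent[chrom] = gc
        defined_fraction[chrom] = def_frac
        censored[chrom] = cens
    return GcTrack(bin_size, gc_percent, defined_fraction, censored)


def enrichment_by_gc(re: EnrichmentTrack, gc: GcTrack,
                     smooth_window: Optional[int] = None) -> pd.DataFrame:
    """Mean Relative Enrichment per GC percent category.

    Per category, each replicate's RE is averaged over the member bins
    (censored bins excluded), then mean and SEM are taken across replicates;
    averaging within categories accounts for the low bin counts at extreme
    GC. The optional Gaussian smoothing (window in percent categories,
    display only) is returned as an extra column.
    """
    if re.bin_size != gc.bin_size:
        raise ValueError("enrichment and GC tracks must share the bin size")
    cats = np.concatenate([
        np.where(gc.censored[c], np.nan, gc.gc_percent[c]) for c in re.chroms
    ])
    reps = np.concatenate([re.replicates[c] for c in re.chroms], axis=1)
    rows = []
    for percent in np.unique(cats[np.isfinite(cats)]):
        member = cats == percent
        vals = reps[:, member]
        per_rep = np.array([
            np.nanmean(row) if np.isfinite(row).any() else np.nan for row in vals
        ])
        if not np.isfinite(per_rep).any():
            continue
        mean = float(np.nanmean(per_rep))
        n_rep = int(np.isfinite(per_rep).sum())
        sem = (float(np.nanstd(per_rep, ddof=1) / np.sqrt(n_rep))
               if n_rep >= 2 else np.nan)
        rows.append({"gc_percent": int(percent), "mean": mean, "sem": sem,
                     "n_bins": int(member.sum())})
    curve = pd.DataFrame(rows)
    if smooth_window is not None and len(curve):
        curve["smoothed"] = gaussian_smooth(curve["mean"].to_numpy(), smooth_window)
    return curve


@dataclass
class TrinucSpectrum:
    """Per-GC-category proportions over the 32 folded trinucleotide classes."""

    counts: np.ndarray  # shape (101, 32): GC percent category x class
    classes: List[str]

    def category_proportions(self, percent: int) -> np.ndarray:
        row = self.counts[percent]
        total = row.sum()
        if total == 0:
            raise ValueError(f"GC category {percent}% is empty")
        return row / total

    def occupied_categories(self) -> np.ndarray:
        return np.flatnonzero(self.counts.sum(axis=1) > 0)

    def genome_share(self) -> np.ndarray:
        """Share of all genomic trinucleotides in each GC category."""
        totals = self.counts.sum(axis=1)
        return totals / totals.sum()

    def rich_share(self, cutoff: int = 50) -> float:
        """Pooled genome share of categories at or above the cutoff."""
        totals = self.counts.sum(axis=1)
        return float(totals[cutoff:].sum() / totals.sum())

    def rich_proportions(self, cutoff: int = 50) -> np.ndarray:
        pooled = self.counts[cutoff:].sum(axis=0)
        return pooled / pooled.sum()


def trinucleotide_spectrum(genome: Genome, gc: GcTrack) -> TrinucSpectrum:
    """Count folded trinucleotides per GC category over uncensored bins.

    Trinucleotide windows step 1 bp; a window is assigned to the bin of its
    central base, and any window touching undefined sequence is skipped.
    """
    counts = np.zeros((101, 32), dtype=np.int64)
    for chrom in genome:
        codes = trinuc_class_codes(genome, chrom)
        valid = codes != INVALID
        if not valid.any():
            continue
        pos = np.flatnonzero(valid)
        bins = pos // gc.bin_size
        cens = gc.censored[chrom][bins]
        gcp = gc.gc_percent[chrom][bins]
        keep = ~cens & np.isfinite(gcp)
        if not keep.any():
            continue
        cat = gcp[keep].astype(np.int64)
        cls = codes[pos[keep]].astype(np.int64)
        np.add.at(counts, (cat, cls), 1)
    return TrinucSpectrum(counts, CLASSES)


def expected_gc_rich_fraction(spectrum: TrinucSpectrum,
                              profile: Optional[np.ndarray] = None,
                              mutation_type: str = "C>A",
                              cutoff: int = 50) -> float:
    """Expected fraction of mutations falling in GC-rich categories.

    With a signature profile (32 class weights), mutation opportunity at each
    genomic trinucleotide occurrence is proportional to its class weight.
    Without one, the uniform-by-base expectation weights every occurrence of
    the mutation type's central-base pair equally (C:G for C>A and C>T, T:A
    for T>G), i.e. "equal distribution dependent exclusively on base content".
    """
    valid = classes_for_mutation_type(mutation_type)
    weights = np.zeros(32)
    if profile is None:
        weights[valid] = 1.0
    else:
        profile = np.asarray(profile, dtype=float)
        if profile.shape != (32,):
            raise ValueError("profile must have 32 class weights")
        off_support = np.setdiff1d(np.arange(32), valid)
        if profile[off_support].sum() > 1e-9:
            raise ValueError("profile has weight on classes whose central base "
                             f"does not match mutation type {mutation_type}")
        weights = profile
    weighted = spectrum.counts * weights[np.newaxis, :]
    total = weighted.sum()
    if total == 0:
        raise ValueError("no opportunity sites for this profile in the genome")
    return float(weighted[cutoff:].sum() / total)
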