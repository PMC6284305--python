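"""Binned genome tracks and replicate-resolved enrichment tracks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import TrackError


def n_bins(length: int, bin_size: int) -> int:
    return -(-length // bin_size)


@dataclass
class BinnedTrack:
    """Per-bin numeric values over a contiguous genome tiling.

    ``values[chrom]`` is a float array, NaN marks missing bins. The optional
    ``n_fraction`` holds the undefined-sequence fraction per bin.
    """

    bin_size: int
    values: Dict[str, np.ndarray]
    n_fraction: Optional[Dict[str, np.ndarray]] = None

    @property
    def chroms(self) -> List[str]:
        return list(self.values)

    def flat(self, chromosomes: Optional[Sequence[str]] = None) -> np.ndarray:
        chroms = list(chromosomes) if chromosomes is not None else self.chroms
        return np.concatenate([self.values[c] for c in chroms])

    def value_at(self, chrom: str, positions) -> np.ndarray:
        """Per-bp lookup: track value of the bin containing each position."""
        idx = np.asarray(positions, dtype=np.int64) // self.bin_size
        return self.values[chrom][idx]

    def same_tiling(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )

    def copy_with(self, values: Dict[str, np.ndarray]) -> "BinnedTrack":
        return BinnedTrack(self.bin_size, values, self.n_fraction)


def require_same_tiling(*tracks: BinnedTrack) -> None:
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_tiling(t):
            raise TrackError("tracks are not on the same tiling")


@dataclass
class EnrichmentTrack:
    """Relative Enrichment per bin, replicate-resolved.

    ``replicates[chrom]`` has shape (n_replicates, n_bins) in log2 units.
    Mean/SEM are taken across replicates; a bin missing (NaN) in any
    replicate is missing in the aggregate.
    """

    bin_size: int
    replicates: Dict[str, np.ndarray]
    sem_available: bool = True

    def __post_init__(self):
        for c, arr in self.replicates.items():
            if arr.ndim != 2:
                raise TrackError(f"replicate array for {c} must be 2-D")

    @property
    def chroms(self) -> List[str]:
        return list(self.replicates)

    @property
    def n_replicates(self) -> int:
        first = next(iter(self.replicates.values()))
        return first.shape[0]

    def mean(self, chrom: str) -> np.ndarray:
        return np.mean(self.replicates[chrom], axis=0)

    def sem(self, chrom: str) -> np.ndarray:
        arr = self.replicates[chrom]
        if arr.shape[0] < 2:
            return np.full(arr.shape[1], np.nan)
        return np.std(arr, axis=0, ddof=1) / np.sqrt(arr.shape[0])

    def values_at(self, chrom: str, positions) -> np.ndarray:
        """Per-bp lookup, shape (n_replicates, len(positions))."""
        idx = np.asarray(positions, dtype=np.int64) // self.bin_size
        return self.replicates[chrom][:, idx]

    def flat_mean(self, chromosomes: Optional[Sequence[str]] = None) -> np.ndarray:
        chroms = list(chromosomes) if chromosomes is not None else self.chroms
        return np.concatenate([self.mean(c) for c in chroms])

    def as_binned(self) -> BinnedTrack:
        """Replicate-mean as a plain BinnedTrack."""
        return BinnedTrack(self.bin_size, {c: self.mean(c) for c in self.chroms})


def genome_n_fraction(genome, bin_size: int) -> Dict[str, np.ndarray]:
    """Undefined-sequence fraction per bin for every chromosome."""
    out = {}
    for chrom in genome:
        length = genome.length(chrom)
        nb = n_bins(length, bin_size)
        undef = ~genome.defined_mask(chrom)
        sums = np.zeros(nb, dtype=np.float64)
        np.add.at(sums, np.arange(length) // bin_size, undef.astype(np.float64))
        widths = np.minimum((np.arange(nb) + 1) * bin_size, length) - np.arange(nb) * bin_size
        out[chrom] = sums / widths
    return out
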