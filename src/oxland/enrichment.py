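"""From fragment libraries to Relative Enrichment tracks.

The central statistic is the Relative Enrichment (RE): the log2 fold change
of inter-library-normalised pulldown coverage over input coverage per genomic
bin. Libraries are normalised with a global scaling factor computed over a
low-damage subset of 100-kb bins (the lowest decile by mean coverage across
all libraries), so that damage-dependent library-size differences cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .errors import TrackError
from .genome import Genome
from .tracks import BinnedTrack, EnrichmentTrack, genome_n_fraction, n_bins, require_same_tiling

MAX_FRAGMENT_SPAN = 1000  # bp; read pairs mapping further apart are discarded


@dataclass(frozen=True)
class SampleMetadata:
    """Unique library key: (treatment, processing, role, replicate)."""

    treatment: str  # "untreated" | "xray"
    processing: str  # "AP" | "OGG1-AP"
    role: str  # "pulldown" | "input"
    replicate: int


@dataclass
class FilterReport:
    kept: int = 0
    dropped_span: int = 0
    dropped_cross_chrom: int = 0
    dropped_malformed: int = 0

    @property
    def dropped(self) -> int:
        return self.dropped_span + self.dropped_cross_chrom + self.dropped_malformed


def filter_fragment_pairs(pairs: pd.DataFrame,
                          max_span: int = MAX_FRAGMENT_SPAN) -> Tuple[pd.DataFrame, FilterReport]:
    """Reduce raw read pairs to fragment intervals, dropping wide/invalid pairs.

    Accepts either BEDPE-style mate columns (chrom1, start1, end1, chrom2,
    start2, end2) or already-joined fragments (chrom, start, end). A fragment
    is the full interval between the outermost mate coordinates; pairs
    spanning more than ``max_span`` bp or mapping to different chromosomes
    are discarded and counted.
    """
    report = FilterReport()
    if {"chrom1", "chrom2"}.issubset(pairs.columns):
        same = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
        report.dropped_cross_chrom = int((~same).sum())
        sub = pairs[same]
        start = np.minimum(sub["start1"].to_numpy(), sub["start2"].to_numpy())
        end = np.maximum(sub["end1"].to_numpy(), sub["end2"].to_numpy())
        frag = pd.DataFrame({"chrom": sub["chrom1"].to_numpy(), "start": start, "end": end})
    else:
        frag = pairs[["chrom", "start", "end"]].copy()
    wellformed = (frag["end"] > frag["start"]).to_numpy()
    report.dropped_malformed = int((~wellformed).sum())
    frag = frag[wellformed]
    span_ok = (frag["end"] - frag["start"] <= max_span).to_numpy()
    report.dropped_span = int((~span_ok).sum())
    frag = frag[span_ok].reset_index(drop=True)
    report.kept = len(frag)
    return frag, report


def bin_coverage(fragments: pd.DataFrame, genome: Genome, bin_size: int) -> BinnedTrack:
    """Mean per-bp fragment coverage per bin.

    A fragment contributes to every bin it overlaps, proportional to the
    overlap length, so total coverage mass is conserved across bin borders.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    values: Dict[str, np.ndarray] = {}
    for chrom in genome:
        length = genome.length(chrom)
        nb = n_bins(length, bin_size)
        acc = np.zeros(nb, dtype=np.float64)
        sub = fragments[fragments["chrom"] == chrom]
        if len(sub):
            starts = np.clip(sub["start"].to_numpy(np.int64), 0, length)
            ends = np.clip(sub["end"].to_numpy(np.int64), 0, length)
            first = starts // bin_size
            span = (ends - 1) // bin_size - first + 1
            for k in range(int(span.max())):
                sel = span > k
                j = first[sel] + k
                ov = (np.minimum(ends[sel], (j + 1) * bin_size)
                      - np.maximum(starts[sel], j * bin_size))
                np.add.at(acc, j, ov)
        widths = (np.minimum((np.arange(nb) + 1) * bin_size, length)
                  - np.arange(nb) * bin_size)
        values[chrom] = acc / widths
    return BinnedTrack(bin_size, values, genome_n_fraction(genome, bin_size))


@dataclass
class ScalingFactors:
    """Per-library global scaling factors over the low-damage bin subset."""

    factors: Dict[str, float]
    low_damage_bins: np.ndarray  # flat indices into the concatenated tiling
    chromosomes: List[str]

    def __getitem__(self, key: str) -> float:
        return self.factors[key]


def low_damage_scaling(tracks: Mapping[str, BinnedTrack],
                       fraction: float = 0.1) -> ScalingFactors:
    """Scaling factors from the lowest-coverage decile of bins.

    Bins are ranked by their mean coverage across all libraries; the lowest
    ``fraction`` (ties broken stably by bin index) defines the low-damage
    subset, and each library's factor is its mean coverage over that subset.
    """
    names = list(tracks)
    if not names:
        raise ValueError("no libraries given")
    first = tracks[names[0]]
    require_same_tiling(*[tracks[n] for n in names])
    flat = np.stack([tracks[n].flat() for n in names])
    usable = np.all(np.isfinite(flat), axis=0)
    n_usable = int(usable.sum())
    k = int(np.floor(fraction * n_usable))
    if k < 1:
        raise ValueError("too few usable bins to select a low-damage subset")
    mean_cov = flat.mean(axis=0)
    usable_idx = np.flatnonzero(usable)
    order = np.lexsort((usable_idx, mean_cov[usable]))
    selected = usable_idx[order[:k]]
    factors = {}
    for i, name in enumerate(names):
        f = float(flat[i, selected].mean())
        if f <= 0:
            raise ValueError(f"library {name!r} has zero coverage in the "
                             "low-damage subset; cannot derive a scaling factor")
        factors[name] = f
    return ScalingFactors(factors, selected, first.chroms)


def relative_enrichment(pulldown: BinnedTrack, input_: BinnedTrack,
                        factor_pulldown: float, factor_input: float,
                        pseudocount: Optional[float] = None,
                        max_n_fraction: float = 0.1,
                        chromosomes: Optional[Sequence[str]] = None) -> EnrichmentTrack:
    """Relative Enrichment for one replicate.

    RE(bin) = log2((pulldown/f_p + eps) / (input/f_i + eps)). The pseudocount
    eps defaults to half a fragment-bp per bin on the scaled-coverage scale
    (0.5 / bin_size), which keeps RE finite on empty bins, vanishes at high
    coverage, and leaves RE exactly invariant to rescaling any raw library by
    a positive constant (the scaling factor absorbs it). Bins whose undefined
    sequence fraction exceeds ``max_n_fraction`` are flagged missing.
    """
    require_same_tiling(pulldown, input_)
    if factor_pulldown <= 0 or factor_input <= 0:
        raise ValueError("scaling factors must be positive")
    eps = 0.5 / pulldown.bin_size if pseudocount is None else pseudocount
    chroms = list(chromosomes) if chromosomes is not None else pulldown.chroms
    replicates: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        p = pulldown.values[chrom] / factor_pulldown
        i = input_.values[chrom] / factor_input
        re = np.log2((p + eps) / (i + eps))
        if pulldown.n_fraction is not None:
            re = np.where(pulldown.n_fraction[chrom] > max_n_fraction, np.nan, re)
        replicates[chrom] = re[np.newaxis, :]
    return EnrichmentTrack(pulldown.bin_size, replicates)


def feature_relative_enrichment(pulldown: BinnedTrack, input_: BinnedTrack,
                                intervals: pd.DataFrame,
                                factor_pulldown: float, factor_input: float,
                                pseudocount: Optional[float] = None,
                                edge_trim: int = 0) -> np.ndarray:
    """Per-element Relative Enrichment for one replicate.

    Coverage of both libraries is averaged over each element *before* the
    log ratio is taken. At sparse per-bin coverage the mean of per-bin log
    ratios is biased downward by Jensen's inequality; aggregating to the
    element first makes feature-level quantification unbiased down to a few
    fragments per element. ``edge_trim`` shrinks each element by that many
    bp per side (capped so at least a small core remains): coverage closer
    than half a fragment span to the border mixes in flanking signal, so
    trimming by half the median fragment length removes boundary smearing.
    The default pseudocount is half a fragment-bp over the trimmed element
    width - sized to the aggregated quantity, so it vanishes for any element
    with appreciable coverage. Returns one log2 value per element (NaN where
    an element has no defined bins).
    """
    require_same_tiling(pulldown, input_)
    out = np.full(len(intervals), np.nan)
    for i, row in enumerate(intervals.itertuples(index=False)):
        limit = len(pulldown.values[row.chrom]) * pulldown.bin_size
        start, end = max(int(row.start), 0), min(int(row.end), limit)
        if end <= start:
            continue
        trim = min(edge_trim, max((end - start - 10) // 2, 0))
        start, end = start + trim, end - trim
        eps = 0.5 / (end - start) if pseudocount is None else pseudocount
        pos = np.arange(start, end)
        p = np.nanmean(pulldown.value_at(row.chrom, pos)) / factor_pulldown
        q = np.nanmean(input_.value_at(row.chrom, pos)) / factor_input
        if np.isfinite(p) and np.isfinite(q):
            out[i] = np.log2((p + eps) / (q + eps))
    return out


def aggregate_replicates(tracks: Sequence[EnrichmentTrack]) -> EnrichmentTrack:
    """Stack per-replicate RE tracks; mean and SEM are taken across replicates.

    A single replicate is allowed but flagged: its SEM is unavailable (NaN),
    never reported as zero.
    """
    if not tracks:
        raise ValueError("no replicate tracks given")
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or t.chroms != first.chroms:
            raise TrackError("replicate tracks are not on the same tiling")
    replicates = {
        c: np.concatenate([t.replicates[c] for t in tracks], axis=0)
        for c in first.chroms
    }
    total = sum(t.n_replicates for t in tracks)
    return EnrichmentTrack(first.bin_size, replicates, sem_available=total >= 2)


@dataclass
class CorrelationResult:
    coefficient: float
    n: int


def correlate_tracks(a: BinnedTrack, b: BinnedTrack,
                     method: str = "spearman") -> CorrelationResult:
    """Correlation over pairwise-complete bins of two tracks on one tiling."""
    require_same_tiling(a, b)
    x = a.flat()
    y = b.flat()
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("fewer than 3 pairwise-complete bins")
    if method == "spearman":
        rho = sps.spearmanr(x[ok], y[ok]).statistic
    elif method == "pearson":
        rho = sps.pearsonr(x[ok], y[ok]).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(rho), n)


@dataclass
class FeatureClustering:
    correlation: pd.DataFrame
    linkage: np.ndarray
    order: List[str]
    excluded: List[str] = field(default_factory=list)


def cluster_features(tracks: Mapping[str, BinnedTrack]) -> FeatureClustering:
    """Hierarchical clustering (average linkage) on 1 - Spearman's rho.

    Constant tracks have undefined rank correlations and are excluded with a
    warning.
    """
    names = list(tracks)
    if len(names) < 2:
        raise ValueError("need at least two feature tracks")
    require_same_tiling(*[tracks[n] for n in names])
    excluded = []
    kept = []
    for name in names:
        vals = tracks[name].flat()
        finite = vals[np.isfinite(vals)]
        if finite.size == 0 or np.all(finite == finite[0]):
            excluded.append(name)
        else:
            kept.append(name)
    if excluded:
        warnings.warn(f"constant tracks excluded from clustering: {excluded}")
    if len(kept) < 2:
        raise ValueError("fewer than two non-constant tracks")
    data = pd.DataFrame({n: tracks[n].flat() for n in kept})
    corr = data.corr(method="spearman")
    dist = 1.0 - corr.to_numpy()
    condensed = dist[np.triu_indices(len(kept), k=1)]
    link = hierarchy.linkage(condensed, method="average")
    order = [kept[i] for i in hierarchy.leaves_list(link)]
    return FeatureClustering(corr, link, order, excluded)


@dataclass
class RecoveryResult:
    recovery: float
    fold: Optional[float]


def recovery_fold(recovery: float, control_recovery: float) -> float:
    """Fold enrichment of a measured recovery over the control recovery."""
    if control_recovery == 0:
        raise ValueError("control recovery must be non-zero")
    return recovery / control_recovery


def qpcr_recovery(ct_pulldown: float, ct_input: float,
                  template_fraction_pulldown: float = 0.02,
                  template_fraction_input: float = 0.01,
                  control_recovery: Optional[float] = None) -> RecoveryResult:
    """Pulldown recovery of input from qPCR cycle thresholds.

    Recovery = 2^-(CT_pulldown - CT_input), corrected for unequal template
    fractions used in the two qPCR reactions (by default 2% of the pulldown
    and 1% of the input). If a control recovery (e.g. the undamaged-oligo
    background) is given, the fold enrichment over it is reported too.
    """
    if not (np.isfinite(ct_pulldown) and np.isfinite(ct_input)):
        raise ValueError("CT values must be finite")
    for frac in (template_fraction_pulldown, template_fraction_input):
        if not (0 < frac <= 1):
            raise ValueError("template fractions must be in (0, 1]")
    recovery = (2.0 ** -(ct_pulldown - ct_input)
                * template_fraction_input / template_fraction_pulldown)
    fold = None
    if control_recovery is not None:
        fold = recovery_fold(recovery, control_recovery)
    return RecoveryResult(recovery, fold)
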