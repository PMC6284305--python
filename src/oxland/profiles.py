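"""Feature-anchored and element-scaled damage metaprofiles.

Two summarisation modes mirror how variable-size genomic elements are
handled: point-anchored features get per-base-pair profiles (minus-strand
features are reversed so the axis always runs 5'->3'), while variable-size
elements (UTRs, exons, introns, intergenic regions) are summarised by their
mean track value with every element weighted equally regardless of length.
SEM is always taken across replicates, not across features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .features import class_subset, overlaps_any
from .genome import Genome, revcomp
from .smoothing import gaussian_smooth
from .tracks import BinnedTrack, EnrichmentTrack

Track = Union[BinnedTrack, EnrichmentTrack]

__all__ = [
    "Metaprofile", "ProfileSegment", "GeneBodyProfile",
    "centered_profile", "centered_gc_profile", "scaled_element_mean",
    "gene_body_profile", "stratify_by_deciles", "select_features",
    "canonical_repeat_unit", "microsatellite_summary", "gaussian_smooth",
]


def _replicate_values(track: Track, chrom: str, idx: np.ndarray) -> np.ndarray:
    """Track values at (arbitrary-shape) per-bp indices, replicate-major."""
    bins = idx // track.bin_size
    if isinstance(track, EnrichmentTrack):
        return track.replicates[chrom][:, bins]
    return track.values[chrom][bins][np.newaxis, ...]


def _chrom_limit(track: Track, chrom: str) -> int:
    arr = (track.replicates[chrom] if isinstance(track, EnrichmentTrack)
           else track.values[chrom])
    return arr.shape[-1] * track.bin_size


@dataclass
class Metaprofile:
    """Per-position mean +/- SEM relative to stranded anchors."""

    axis: np.ndarray  # bp relative to the anchor
    mean: np.ndarray
    sem: np.ndarray
    n_features: int
    per_replicate: np.ndarray  # (n_replicates, len(axis))
    n_dropped: int = 0


def centered_profile(track: Track, anchors: pd.DataFrame,
                     flank_5p: int, flank_3p: int) -> Metaprofile:
    """Per-bp mean profile around stranded anchor points.

    ``anchors`` needs columns chrom, pos, strand. The window covers
    [-flank_5p, flank_3p) on the feature's own 5'->3' axis. Anchors whose
    window leaves the chromosome are dropped and counted.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    axis = np.arange(-flank_5p, flank_3p)
    n_rep = track.n_replicates if isinstance(track, EnrichmentTrack) else 1
    total = np.zeros((n_rep, len(axis)))
    count = np.zeros((n_rep, len(axis)))
    n_kept = n_dropped = 0
    for chrom, sub in anchors.groupby("chrom", sort=False):
        limit = _chrom_limit(track, chrom)
        pos = sub["pos"].to_numpy(np.int64)
        minus = (sub["strand"] == "-").to_numpy()
        idx = np.where(minus[:, None], pos[:, None] - axis, pos[:, None] + axis)
        ok = (idx.min(axis=1) >= 0) & (idx.max(axis=1) < limit)
        n_dropped += int((~ok).sum())
        n_kept += int(ok.sum())
        if not ok.any():
            continue
        vals = _replicate_values(track, chrom, idx[ok])
        finite = np.isfinite(vals)
        total += np.where(finite, vals, 0.0).sum(axis=1)
        count += finite.sum(axis=1)
    if n_kept == 0:
        raise ValueError("no anchors fit within chromosome bounds")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_rep = total / count
    mean = np.mean(per_rep, axis=0)
    sem = (np.std(per_rep, axis=0, ddof=1) / np.sqrt(n_rep)
           if n_rep >= 2 else np.full(len(axis), np.nan))
    return Metaprofile(axis, mean, sem, n_kept, per_rep, n_dropped)


def centered_gc_profile(genome: Genome, anchors: pd.DataFrame,
                        flank_5p: int, flank_3p: int,
                        smooth_window: Optional[int] = 100) -> np.ndarray:
    """Mean GC fraction per position around anchors (display-smoothed)."""
    gc_tracks = BinnedTrack(1, {c: genome.gc_mask(c).astype(float) for c in genome})
    prof = centered_profile(gc_tracks, anchors, flank_5p, flank_3p)
    if smooth_window:
        return gaussian_smooth(prof.mean, smooth_window)
    return prof.mean


def scaled_element_mean(track: Track, intervals: pd.DataFrame
                        ) -> Tuple[np.ndarray, pd.DataFrame, int]:
    """One mean track value per element, elements weighted equally.

    Returns (values with shape (n_kept, n_replicates), the kept intervals,
    and the count of elements dropped because the track is fully missing
    over them).
    """
    if len(intervals) == 0:
        raise ValueError("empty interval set")
    rows = []
    keep = []
    n_rep = track.n_replicates if isinstance(track, EnrichmentTrack) else 1
    for i, row in enumerate(intervals.itertuples(index=False)):
        limit = _chrom_limit(track, row.chrom)
        start = max(int(row.start), 0)
        end = min(int(row.end), limit)
        if end <= start:
            continue
        vals = _replicate_values(track, row.chrom, np.arange(start, end))
        with np.errstate(invalid="ignore"):
            means = np.nanmean(vals, axis=-1) if np.isfinite(vals).any() else None
        if means is None or not np.isfinite(means).any():
            continue
        rows.append(means)
        keep.append(i)
    if not rows:
        raise ValueError("track is missing over every element")
    values = np.vstack(rows)
    kept = intervals.iloc[keep].reset_index(drop=True)
    return values, kept, len(intervals) - len(kept)


@dataclass
class ProfileSegment:
    name: str
    kind: str  # "centered" | "scaled"
    mean: np.ndarray  # per-position (centered) or per-replicate scalar mean
    sem: np.ndarray
    n_features: int
    axis: Optional[np.ndarray] = None
    gc: Optional[np.ndarray] = None


@dataclass
class GeneBodyProfile:
    segments: List[ProfileSegment]

    def segment(self, name: str) -> ProfileSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> List[str]:
        return [s.name for s in self.segments]


def _scaled_segment(track: Track, intervals: pd.DataFrame, name: str,
                    genome: Optional[Genome]) -> Optional[ProfileSegment]:
    if len(intervals) == 0:
        return None
    values, kept, _ = scaled_element_mean(track, intervals)
    per_rep = np.nanmean(values, axis=0)  # equal weight per element
    n_rep = len(per_rep)
    mean = np.array([np.mean(per_rep)])
    sem = (np.array([np.std(per_rep, ddof=1) / np.sqrt(n_rep)])
           if n_rep >= 2 else np.array([np.nan]))
    gc = None
    if genome is not None:
        fracs = [genome.gc_mask(r.chrom)[r.start:r.end].mean()
                 for r in kept.itertuples(index=False)]
        gc = np.array([float(np.mean(fracs))])
    return ProfileSegment(name, "scaled", mean, sem, len(kept), gc=gc)


def _centered_segment(track: Track, anchors: pd.DataFrame, name: str,
                      flank_5p: int, flank_3p: int,
                      genome: Optional[Genome]) -> Optional[ProfileSegment]:
    if len(anchors) == 0:
        return None
    prof = centered_profile(track, anchors, flank_5p, flank_3p)
    gc = None
    if genome is not None:
        gc = centered_gc_profile(genome, anchors, flank_5p, flank_3p)
    return ProfileSegment(name, "centered", prof.mean, prof.sem,
                          prof.n_features, axis=prof.axis, gc=gc)


def _element_anchors(elements: pd.DataFrame, end_kind: str) -> pd.DataFrame:
    """Stranded 5' or 3' end points of intervals."""
    plus = elements["strand"] != "-"
    if end_kind == "5p":
        pos = np.where(plus, elements["start"], elements["end"] - 1)
    else:
        pos = np.where(plus, elements["end"] - 1, elements["start"])
    return pd.DataFrame({"chrom": elements["chrom"].to_numpy(),
                         "pos": pos.astype(np.int64),
                         "strand": elements["strand"].to_numpy()})


def point_anchors(features: pd.DataFrame) -> pd.DataFrame:
    """Anchor frame (chrom, pos, strand) at interval centres."""
    centre = (features["start"].to_numpy() + features["end"].to_numpy()) // 2
    return pd.DataFrame({"chrom": features["chrom"].to_numpy(),
                         "pos": centre.astype(np.int64),
                         "strand": features.get("strand", ".").to_numpy()
                         if "strand" in features else "."})


def derive_intergenic(annotation: pd.DataFrame, lengths: Mapping[str, int]
                      ) -> pd.DataFrame:
    """Complement of transcript spans (plus annotated promoters/terminators)."""
    spanned_classes = {"transcript", "promoter", "termination_site"}
    spans = annotation[annotation["feature_class"].isin(spanned_classes)]
    rows = []
    for chrom, length in lengths.items():
        sub = spans[spans["chrom"] == chrom].sort_values("start")
        cursor = 0
        for r in sub.itertuples(index=False):
            if r.start > cursor:
                rows.append({"chrom": chrom, "start": cursor, "end": int(r.start),
                             "name": "intergenic", "score": 0, "strand": ".",
                             "feature_class": "intergenic"})
            cursor = max(cursor, int(r.end))
        if cursor < length:
            rows.append({"chrom": chrom, "start": cursor, "end": length,
                         "name": "intergenic", "score": 0, "strand": ".",
                         "feature_class": "intergenic"})
    return pd.DataFrame(rows)


def gene_body_profile(track: Track, annotation: pd.DataFrame,
                      genome: Optional[Genome] = None,
                      intergenic: Optional[pd.DataFrame] = None,
                      junction_flank: int = 250) -> GeneBodyProfile:
    """Composite metaprofile over the ordered elements of protein-coding genes.

    Order: promoter (TSS -1 kb/+500 bp, per-bp) -> 5'UTR (scaled) ->
    exon 5' junction (+/-250 bp) -> exon (scaled) -> exon 3' junction ->
    intron (scaled) -> 3'UTR (scaled) -> termination site (TES -500 bp/+1 kb,
    per-bp) -> intergenic (scaled). Transcripts lacking an element simply do
    not contribute to that segment. With a genome, each segment carries a GC
    companion (centered segments smoothed over 100 bp).
    """
    tss = class_subset(annotation, "tss")
    tes = class_subset(annotation, "tes")
    exons = class_subset(annotation, "exon")
    segs: List[Optional[ProfileSegment]] = []
    if len(tss):
        segs.append(_centered_segment(
            track, point_anchors(tss), "promoter", 1000, 500, genome))
    segs.append(_scaled_segment(track, class_subset(annotation, "five_utr"),
                                "five_utr", genome))
    if len(exons):
        segs.append(_centered_segment(
            track, _element_anchors(exons, "5p"), "exon_5p_junction",
            junction_flank, junction_flank, genome))
    segs.append(_scaled_segment(track, exons, "exon", genome))
    if len(exons):
        segs.append(_centered_segment(
            track, _element_anchors(exons, "3p"), "exon_3p_junction",
            junction_flank, junction_flank, genome))
    segs.append(_scaled_segment(track, class_subset(annotation, "intron"),
                                "intron", genome))
    segs.append(_scaled_segment(track, class_subset(annotation, "three_utr"),
                                "three_utr", genome))
    if len(tes):
        segs.append(_centered_segment(
            track, point_anchors(tes), "termination_site", 500, 1000, genome))
    if intergenic is None and genome is not None:
        intergenic = derive_intergenic(annotation, genome.lengths)
    if intergenic is not None and len(intergenic):
        segs.append(_scaled_segment(track, intergenic, "intergenic", genome))
    return GeneBodyProfile([s for s in segs if s is not None])


def stratify_by_deciles(values: pd.Series, covariate: pd.Series,
                        silent_value: float = 0.0
                        ) -> Tuple[pd.Series, pd.DataFrame]:
    """Split features into a silent group plus 10 covariate deciles.

    Features with covariate equal to ``silent_value`` form the "silent"
    group; the rest are ranked (stable on (covariate, feature id)) and cut
    into 10 groups whose sizes differ by at most one. Returns per-feature
    labels and a summary table (n, median, quartiles of ``values``).
    """
    values, covariate = values.align(covariate, join="inner")
    silent = covariate == silent_value
    active_ids = covariate.index[~silent]
    if len(active_ids) and len(active_ids) < 10:
        raise ValueError("fewer than 10 non-silent features")
    labels = pd.Series(index=covariate.index, dtype=object)
    labels[silent] = "silent"
    if len(active_ids):
        cov = covariate[~silent]
        order = np.lexsort((np.asarray(cov.index, dtype=object), cov.to_numpy()))
        for d, chunk in enumerate(np.array_split(order, 10), start=1):
            labels[cov.index[chunk]] = f"decile_{d}"
    rows = []
    group_names = ["silent"] + [f"decile_{d}" for d in range(1, 11)]
    for g in group_names:
        member = values[labels == g]
        rows.append({
            "group": g, "n": len(member),
            "median": float(member.median()) if len(member) else np.nan,
            "q1": float(member.quantile(0.25)) if len(member) else np.nan,
            "q3": float(member.quantile(0.75)) if len(member) else np.nan,
        })
    return labels, pd.DataFrame(rows)


def select_features(features: pd.DataFrame, rules: Sequence[tuple]
                    ) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply explicit selection rules, reporting per-rule exclusion counts.

    Supported rules:
      ("size_range", lo, hi)            keep closed-interval sizes [lo, hi]
      ("exclude_near_center", df, d)    drop features whose centre lies
                                        within d bp of any centre in df
      ("require_overlap", df)           keep only features overlapping df
      ("exclude_overlap", df)           drop features overlapping df
      ("intragenic", transcripts_df)    keep features overlapping a transcript
      ("name_in", allowed)              keep features whose name is allowed
    """
    kept = features.reset_index(drop=True)
    counts: Dict[str, int] = {}
    for rule in rules:
        kind = rule[0]
        before = len(kept)
        if kind == "size_range":
            _, lo, hi = rule
            size = kept["end"] - kept["start"]
            kept = kept[(size >= lo) & (size <= hi)]
        elif kind == "exclude_near_center":
            _, other, dist = rule
            centres = (kept["start"] + kept["end"]) // 2
            keep_mask = np.ones(len(kept), dtype=bool)
            other_centres = ((other["start"] + other["end"]) // 2).to_numpy()
            for chrom, sub in kept.groupby("chrom", sort=False):
                oc = np.sort(other_centres[(other["chrom"] == chrom).to_numpy()])
                if len(oc) == 0:
                    continue
                c = centres[sub.index].to_numpy()
                j = np.searchsorted(oc, c)
                left = np.where(j > 0, np.abs(c - oc[np.maximum(j - 1, 0)]), np.inf)
                right = np.where(j < len(oc), np.abs(oc[np.minimum(j, len(oc) - 1)] - c), np.inf)
                near = np.minimum(left, right) <= dist
                keep_mask[sub.index.to_numpy()] = ~near
            kept = kept[keep_mask]
        elif kind in ("require_overlap", "exclude_overlap", "intragenic"):
            clean = kept.reset_index(drop=True)
            hits = overlaps_any(clean, rule[1])
            if kind == "exclude_overlap":
                hits = ~hits
            kept = clean[hits]
        elif kind == "name_in":
            _, allowed = rule
            kept = kept[kept["name"].isin(set(allowed))]
        else:
            raise ValueError(f"unknown selection rule {kind!r}")
        counts[kind] = before - len(kept)
        kept = kept.reset_index(drop=True)
    return kept.reset_index(drop=True), counts


def _min_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def canonical_repeat_unit(unit: str) -> str:
    """Canonical microsatellite class label.

    The unit is reduced to its lexicographically minimal rotation, then
    pooled with its reverse complement by taking the alphabetically first of
    the two representatives, so e.g. GAA, AAG, AGA, TTC, TCT and CTT all
    share one class.
    """
    a = _min_rotation(unit.upper())
    b = _min_rotation(revcomp(unit.upper()))
    return min(a, b)


def microsatellite_summary(tracks: Mapping[str, Track], repeats: pd.DataFrame,
                           min_genome_count: int = 1000) -> pd.DataFrame:
    """Median per-type Relative Enrichment per condition.

    ``repeats`` carries the repeat unit in its name column. Types are pooled
    by canonical unit; types represented at most ``min_genome_count`` times
    in the genome (strict >) are dropped. The per-repeat statistic is the
    replicate-mean RE over the repeat; types are summarised by the median.
    """
    reps = repeats.copy()
    reps["repeat_type"] = reps["name"].map(canonical_repeat_unit)
    type_counts = reps["repeat_type"].value_counts()
    keep_types = type_counts[type_counts > min_genome_count].index
    reps = reps[reps["repeat_type"].isin(keep_types)]
    rows = []
    for rtype, sub in reps.groupby("repeat_type"):
        row = {"repeat_type": rtype, "n_repeats": len(sub)}
        for cond, track in tracks.items():
            values, _, _ = scaled_element_mean(track, sub.reset_index(drop=True))
            row[cond] = float(np.median(values.mean(axis=1)))
        rows.append(row)
    return pd.DataFrame(rows)
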