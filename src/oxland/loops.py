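"""Chromatin-loop anchors: calling, insulation classification, damage asymmetry.

Anchors are a peak-overlap proxy for loop boundaries: a CTCF peak qualifies
only when it overlaps a canonical CTCF motif plus RAD21 and SMC3 cohesin
peaks. The anchor sits at the motif centre and is oriented by the motif
strand; orientation defines the loop interior as the downstream (+) side of
the oriented motif, so "outside" is the 10-kb window upstream of the motif
and "inside" the 10-kb window downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .features import overlaps_any
from .stats import rank_sum_test
from .tracks import BinnedTrack, EnrichmentTrack

ANCHOR_CLASSES = ("swap_on", "swap_off", "on", "off", "unclassified")


def call_anchors(ctcf_peaks: pd.DataFrame, rad21_peaks: pd.DataFrame,
                 smc3_peaks: pd.DataFrame, motifs: pd.DataFrame,
                 merge_distance: int = 500) -> pd.DataFrame:
    """Oriented loop anchors from the CTCF/RAD21/SMC3 triple overlap.

    CTCF peaks are kept only when they overlap at least one canonical CTCF
    motif AND one RAD21 peak AND one SMC3 peak. Each qualifying motif centre
    becomes an anchor oriented by the motif strand; anchors closer than
    ``merge_distance`` are merged and recentred at their midpoint, taking the
    orientation of the anchor backed by the stronger CTCF peak (leftmost on
    ties). Returns columns chrom, center, strand, ctcf_score.
    """
    for name, peaks in (("ctcf", ctcf_peaks), ("rad21", rad21_peaks),
                        ("smc3", smc3_peaks)):
        if len(peaks) == 0:
            warnings.warn(f"empty {name} peak set; no anchors can be called")
            return pd.DataFrame(columns=["chrom", "center", "strand", "ctcf_score"])
    ctcf = ctcf_peaks.reset_index(drop=True)
    qualifies = (overlaps_any(ctcf, motifs)
                 & overlaps_any(ctcf, rad21_peaks)
                 & overlaps_any(ctcf, smc3_peaks))
    ctcf = ctcf[qualifies].reset_index(drop=True)
    if len(ctcf) == 0:
        return pd.DataFrame(columns=["chrom", "center", "strand", "ctcf_score"])
    # anchor = centre of each motif that overlaps a qualifying CTCF peak
    motif_hit = overlaps_any(motifs.reset_index(drop=True), ctcf)
    hits = motifs.reset_index(drop=True)[motif_hit]
    rows = []
    for r in hits.itertuples(index=False):
        centre = (int(r.start) + int(r.end)) // 2
        peak_scores = ctcf[(ctcf["chrom"] == r.chrom)
                           & (ctcf["start"] < r.end) & (ctcf["end"] > r.start)]
        score = float(peak_scores["score"].max()) if len(peak_scores) else 0.0
        rows.append({"chrom": r.chrom, "center": centre, "strand": r.strand,
                     "ctcf_score": score})
    anchors = pd.DataFrame(rows).sort_values(["chrom", "center"]).reset_index(drop=True)
    return merge_anchors(anchors, merge_distance)


def merge_anchors(anchors: pd.DataFrame, merge_distance: int = 500) -> pd.DataFrame:
    """Merge anchors closer than ``merge_distance``, recentring at the midpoint.

    Chained merging (a-b close, b-c close => one cluster); idempotent once
    the surviving anchors are all at least ``merge_distance`` apart.
    """
    out = []
    for chrom, sub in anchors.groupby("chrom", sort=False):
        sub = sub.sort_values(["center", "chrom"]).reset_index(drop=True)
        centres = sub["center"].to_numpy()
        cluster_start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or centres[i] - centres[i - 1] >= merge_distance:
                block = sub.iloc[cluster_start:i]
                centre = int(round(block["center"].mean()))
                best = block.sort_values(
                    ["ctcf_score", "center"], ascending=[False, True]).iloc[0]
                out.append({"chrom": chrom, "center": centre,
                            "strand": best["strand"],
                            "ctcf_score": float(block["ctcf_score"].max())})
                cluster_start = i
    return pd.DataFrame(out, columns=["chrom", "center", "strand", "ctcf_score"])


def _window_mean(track: BinnedTrack, chrom: str, start: int, end: int) -> float:
    limit = len(track.values[chrom]) * track.bin_size
    start, end = max(start, 0), min(end, limit)
    if end <= start:
        return np.nan
    return float(np.mean(track.value_at(chrom, np.arange(start, end))))


def classify_insulation(anchors: pd.DataFrame, h3k36: BinnedTrack,
                        h3k27: BinnedTrack, window: int = 10_000,
                        swap_cutoff: float = 1.2, off_cutoff: float = 2.0,
                        pseudocount: Optional[float] = None) -> pd.DataFrame:
    """Classify anchor insulation from H3K36me3:H3K27me3 coverage ratios.

    For each oriented anchor, mean raw coverage of both marks is taken over
    the 10-kb windows outside (upstream of the oriented motif) and inside
    (downstream). The insulation differential is

        d = log2(K36/K27)_inside - log2(K36/K27)_outside

    so crossing into the loop from inactive into active chromatin gives
    d > +swap_cutoff ("swap_on") and the reverse gives d < -swap_cutoff
    ("swap_off"). Otherwise the anchor is "off" when the mean
    log2(H3K27me3/H3K36me3) over the full +/-window exceeds ``off_cutoff``,
    else "on". Anchors with zero coverage of both marks in a window stay
    "unclassified". The pseudocount (default one coverage unit per window)
    keeps ratios finite over sparse marks.
    """
    eps = (1.0 / window) if pseudocount is None else pseudocount
    rows = []
    for r in anchors.itertuples(index=False):
        c = int(r.center)
        upstream = (c - window, c)
        downstream = (c, c + window)
        out_win, in_win = ((upstream, downstream) if r.strand != "-"
                           else (downstream, upstream))
        k36_out = _window_mean(h3k36, r.chrom, *out_win)
        k36_in = _window_mean(h3k36, r.chrom, *in_win)
        k27_out = _window_mean(h3k27, r.chrom, *out_win)
        k27_in = _window_mean(h3k27, r.chrom, *in_win)
        row = {"chrom": r.chrom, "center": c, "strand": r.strand,
               "h3k36_out": k36_out, "h3k36_in": k36_in,
               "h3k27_out": k27_out, "h3k27_in": k27_in}
        vals = np.array([k36_out, k36_in, k27_out, k27_in])
        if (not np.isfinite(vals).all()
                or (k36_out == 0 and k27_out == 0)
                or (k36_in == 0 and k27_in == 0)):
            row.update({"class": "unclassified", "differential": np.nan})
        else:
            ratio_in = np.log2((k36_in + eps) / (k27_in + eps))
            ratio_out = np.log2((k36_out + eps) / (k27_out + eps))
            d = ratio_in - ratio_out
            if d > swap_cutoff:
                cls = "swap_on"
            elif d < -swap_cutoff:
                cls = "swap_off"
            else:
                k27_mean = (k27_in + k27_out) / 2.0
                k36_mean = (k36_in + k36_out) / 2.0
                cls = ("off" if np.log2((k27_mean + eps) / (k36_mean + eps))
                       > off_cutoff else "on")
            row.update({"class": cls, "differential": d})
        rows.append(row)
    return pd.DataFrame(rows)


def anchor_damage(anchors: pd.DataFrame, re: EnrichmentTrack,
                  window: int = 10_000) -> Tuple[pd.DataFrame, int]:
    """Per-anchor mean RE (+/-window) and oriented differential (in minus out).

    Anchors whose window leaves the chromosome are dropped and counted.
    Differentials and means are first computed per replicate, then averaged.
    """
    rows = []
    dropped = 0
    for _, r in anchors.iterrows():
        c = int(r["center"])
        chrom = r["chrom"]
        limit = re.replicates[chrom].shape[1] * re.bin_size
        if c - window < 0 or c + window > limit:
            dropped += 1
            continue
        left = re.values_at(chrom, np.arange(c - window, c))
        right = re.values_at(chrom, np.arange(c, c + window))
        out_vals, in_vals = (left, right) if r["strand"] != "-" else (right, left)
        mean_rep = np.nanmean(np.concatenate([left, right], axis=1), axis=1)
        diff_rep = np.nanmean(in_vals, axis=1) - np.nanmean(out_vals, axis=1)
        row = r.to_dict()
        row.update({"mean_re": float(np.mean(mean_rep)),
                    "differential_re": float(np.mean(diff_rep))})
        rows.append(row)
    return pd.DataFrame(rows), dropped


def class_summary(damage: pd.DataFrame, class_column: str = "class") -> pd.DataFrame:
    """Per-class mean and SEM of the damage differential."""
    rows = []
    for cls, sub in damage.groupby(class_column):
        vals = sub["differential_re"].to_numpy()
        rows.append({"class": cls, "n": len(vals),
                     "mean_differential": float(np.mean(vals)),
                     "sem_differential": (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                                          if len(vals) >= 2 else np.nan)})
    return pd.DataFrame(rows)


def compare_anchor_classes(differentials: Dict[str, np.ndarray],
                           group_a: str, group_b: str) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two anchor classes."""
    a = np.asarray(differentials[group_a], dtype=float)
    b = np.asarray(differentials[group_b], dtype=float)
    return rank_sum_test(a, b)
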