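"""Typed, stranded genomic intervals as pandas DataFrames.

A feature frame carries BED6-like columns plus an explicit ``feature_class``:

    chrom, start, end, name, score, strand, feature_class

Coordinates are 0-based half-open. ``name`` holds a per-feature identifier
(transcript id, repeat unit, family name); ``feature_class`` the feature type
(``promoter``, ``exon``, ``alu`` ...).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "feature_class"]


def feature_frame(rows: Iterable[Mapping] = ()) -> pd.DataFrame:
    """Build an empty or populated feature frame with canonical columns."""
    df = pd.DataFrame(list(rows), columns=FEATURE_COLUMNS)
    df["start"] = df["start"].astype(np.int64) if len(df) else df["start"]
    df["end"] = df["end"].astype(np.int64) if len(df) else df["end"]
    return df


def class_subset(features: pd.DataFrame, feature_class: str) -> pd.DataFrame:
    return features[features["feature_class"] == feature_class].reset_index(drop=True)


def interval_mask(length: int, starts, ends) -> np.ndarray:
    """Boolean per-bp mask covered by any interval (vectorised diff trick)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    s = np.clip(np.asarray(starts, dtype=np.int64), 0, length)
    e = np.clip(np.asarray(ends, dtype=np.int64), 0, length)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    return np.cumsum(diff[:-1]) > 0


def class_mask(features: pd.DataFrame, chrom: str, length: int,
               feature_class: Optional[str] = None) -> np.ndarray:
    sub = features[features["chrom"] == chrom]
    if feature_class is not None:
        sub = sub[sub["feature_class"] == feature_class]
    return interval_mask(length, sub["start"].to_numpy(), sub["end"].to_numpy())


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per query row: does any subject interval overlap it?

    Sorted-sweep on (start, prefix-max end); exact for half-open intervals.
    """
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    for chrom, qsub in query.groupby("chrom", sort=False):
        ssub = subject[subject["chrom"] == chrom]
        if len(ssub) == 0:
            continue
        order = np.argsort(ssub["start"].to_numpy(), kind="stable")
        starts = ssub["start"].to_numpy()[order]
        maxend = np.maximum.accumulate(ssub["end"].to_numpy()[order])
        # subjects with start < q.end are candidates; overlap iff their
        # running max end exceeds q.start
        idx = np.searchsorted(starts, qsub["end"].to_numpy(), side="left")
        hit = (idx > 0) & (maxend[np.maximum(idx - 1, 0)] > qsub["start"].to_numpy())
        result[qsub.index.to_numpy()] = hit
    return result


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file; the name column is split as ``class`` or ``class:id``."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    parts = df["name"].astype(str).str.split(":", n=1)
    df["feature_class"] = parts.str[0]
    df["name"] = parts.str[1].fillna(parts.str[0])
    return df[FEATURE_COLUMNS]


def write_bed(features: pd.DataFrame, path) -> None:
    out = features.copy()
    joined = np.where(
        out["name"].astype(str) == out["feature_class"].astype(str),
        out["feature_class"].astype(str),
        out["feature_class"].astype(str) + ":" + out["name"].astype(str),
    )
    out = out.assign(name=joined)[["chrom", "start", "end", "name", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def mirror_features(features: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    """Mirror intervals through each chromosome (for strand-symmetry tests)."""
    out = features.copy()
    L = out["chrom"].map(lengths).to_numpy()
    start = out["start"].to_numpy().copy()
    end = out["end"].to_numpy().copy()
    out["start"] = L - end
    out["end"] = L - start
    out["strand"] = out["strand"].map({"+": "-", "-": "+", ".": "."})
    return out
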