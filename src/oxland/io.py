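"""Plain-text interchange: bedGraph, fragment BED/BEDPE, SNV and patient TSV."""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from .errors import TrackError
from .tracks import BinnedTrack, EnrichmentTrack


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a BinnedTrack as bedGraph (missing bins are skipped)."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            starts = np.arange(len(vals)) * track.bin_size
            for s, v in zip(starts, vals):
                if np.isfinite(v):
                    fh.write(f"{chrom}\t{s}\t{s + track.bin_size}\t{v:.6g}\n")


def read_bedgraph(path, bin_size: int) -> BinnedTrack:
    """Read a bedGraph written on a uniform tiling back into a BinnedTrack."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    if len(df) and ((df["end"] - df["start"]) != bin_size).any():
        raise TrackError("bedGraph intervals do not match the bin size")
    values: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        nb = int(sub["end"].max() // bin_size)
        arr = np.full(nb, np.nan)
        arr[(sub["start"] // bin_size).to_numpy()] = sub["value"].to_numpy()
        values[chrom] = arr
    return BinnedTrack(bin_size, values)


def write_enrichment_bedgraphs(track: EnrichmentTrack, prefix) -> None:
    """Write replicate-mean and SEM of an enrichment track as bedGraphs."""
    write_bedgraph(track.as_binned(), f"{prefix}.mean.bedgraph")
    sem = BinnedTrack(track.bin_size, {c: track.sem(c) for c in track.chroms})
    write_bedgraph(sem, f"{prefix}.sem.bedgraph")


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end"], dtype={0: str})


def write_snv_tsv(catalog, snv_path, patient_path) -> None:
    catalog.snvs.to_csv(snv_path, sep="\t", index=False)
    catalog.patients.to_csv(patient_path, sep="\t", index=False)


def read_snv_tsv(snv_path, patient_path):
    from .mutations import SnvCatalog

    snvs = pd.read_csv(snv_path, sep="\t", dtype={"chrom": str})
    patients = pd.read_csv(patient_path, sep="\t")
    return SnvCatalog(snvs, patients)
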