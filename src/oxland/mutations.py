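"""Patient-level SNV landscape analysis stratified by mutational signatures.

Mutation types are strand-folded (C>A includes G>T, T>G includes A>C, C>T
includes G>A); no analysis is strand-specific. Patients are censored for
hypermutator phenotype, coding mutations in base-excision-repair genes
(OGG1/APEX1/FEN1, precomputed flags), and documented smoking or prior
chemo/radiotherapy; polymerase-epsilon proofreading-deficient tumours are
instead *selected* by the hypermutator phenotype combined with prominent
Signature 10 exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gc import GcTrack
from .genome import Genome
from .smoothing import gaussian_smooth
from .stats import rank_sum_test
from .profiles import Metaprofile, centered_profile, centered_gc_profile
from .tracks import BinnedTrack

MUTATION_TYPES = ("C>A", "T>G", "C>T")

_FOLD = {("C", "A"): "C>A", ("G", "T"): "C>A",
         ("T", "G"): "T>G", ("A", "C"): "T>G",
         ("C", "T"): "C>T", ("G", "A"): "C>T"}

HYPERMUTATOR_THRESHOLD = 100_000  # C>A count above which a patient is a hypermutator


def fold_mutation_type(ref: str, alt: str) -> Optional[str]:
    """Folded mutation-type label, or None for types outside the analysis."""
    return _FOLD.get((ref.upper(), alt.upper()))


@dataclass
class SnvCatalog:
    """Per-patient SNVs plus the patient table.

    ``snvs`` columns: chrom, pos (1-based), ref, alt, patient, mutation_type.
    ``patients`` columns: patient, n_c_to_a, n_t_to_g, n_c_to_t, sig18,
    sig17, sig10, ber_coding, smoking_or_therapy (exposures are proportions
    of the respective mutation type attributed to the signature).
    """

    snvs: pd.DataFrame
    patients: pd.DataFrame

    def subset(self, patient_ids: Sequence[str]) -> "SnvCatalog":
        ids = set(patient_ids)
        return SnvCatalog(
            self.snvs[self.snvs["patient"].isin(ids)].reset_index(drop=True),
            self.patients[self.patients["patient"].isin(ids)].reset_index(drop=True),
        )

    def of_type(self, mutation_type: str) -> pd.DataFrame:
        return self.snvs[self.snvs["mutation_type"] == mutation_type]

    def complemented(self) -> "SnvCatalog":
        """Catalog with every ref/alt complemented (same folded types)."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        snvs = self.snvs.copy()
        snvs["ref"] = snvs["ref"].map(comp)
        snvs["alt"] = snvs["alt"].map(comp)
        snvs["mutation_type"] = [
            fold_mutation_type(r, a) for r, a in zip(snvs["ref"], snvs["alt"])
        ]
        return SnvCatalog(snvs, self.patients.copy())


@dataclass
class CensoringReport:
    hypermutator: List[str] = field(default_factory=list)
    ber_coding: List[str] = field(default_factory=list)
    smoking_or_therapy: List[str] = field(default_factory=list)
    missing_flags: List[str] = field(default_factory=list)

    @property
    def removed(self) -> List[str]:
        return sorted(set(self.hypermutator) | set(self.ber_coding)
                      | set(self.smoking_or_therapy))


def censor_patients(catalog: SnvCatalog,
                    hypermutator_threshold: int = HYPERMUTATOR_THRESHOLD,
                    exempt_pole: bool = True,
                    sig10_prominence: float = 0.2
                    ) -> Tuple[SnvCatalog, CensoringReport]:
    """Remove hypermutators, BER-gene-mutated and smoking/therapy patients.

    A hypermutator has strictly more than ``hypermutator_threshold`` C>A
    mutations. Patients qualifying as POLE proofreading-deficient (the same
    hypermutator phenotype with prominent Signature 10) are exempt from the
    hypermutator rule when ``exempt_pole`` - they are selected by it instead.
    Patients with missing flags are retained (never silently dropped) and
    listed in the report.
    """
    pats = catalog.patients
    report = CensoringReport()
    pole = (select_pole_deficient(catalog, hypermutator_threshold,
                                  sig10_prominence) if exempt_pole else [])
    for _, p in pats.iterrows():
        pid = p["patient"]
        if p["n_c_to_a"] > hypermutator_threshold and pid not in pole:
            report.hypermutator.append(pid)
        for flag, bucket in (("ber_coding", report.ber_coding),
                             ("smoking_or_therapy", report.smoking_or_therapy)):
            value = p.get(flag)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                report.missing_flags.append(pid)
            elif bool(value):
                bucket.append(pid)
    keep = [p for p in pats["patient"] if p not in set(report.removed)]
    return catalog.subset(keep), report


def select_pole_deficient(catalog: SnvCatalog,
                          hypermutator_threshold: int = HYPERMUTATOR_THRESHOLD,
                          sig10_prominence: float = 0.2) -> List[str]:
    """Patients with the hypermutator phenotype and prominent Signature 10."""
    pats = catalog.patients
    sel = (pats["n_c_to_a"] > hypermutator_threshold) & (pats["sig10"] > sig10_prominence)
    return list(pats.loc[sel, "patient"])


#: Half-open exposure bins (lower-closed; top bin closed above).
SIGNATURE_GROUPS = {
    "sig18": [(0.0, 0.1), (0.1, 0.4), (0.4, 0.6), (0.6, 1.0 + 1e-12)],
    "sig17": [(0.0, 0.1), (0.1, 0.25), (0.25, 0.5), (0.5, 1.0 + 1e-12)],
}


def group_label(bounds: Tuple[float, float], first: bool, last: bool) -> str:
    lo, hi = bounds
    if first:
        return f"<{lo + (hi - lo):g}" if lo == 0 else f"{lo:g}-{hi:g}"
    if last:
        return f">{lo:g}"
    return f"{lo:g}-{hi:g}"


def assign_signature_groups(catalog: SnvCatalog, variable: str) -> pd.Series:
    """Per-patient signature-exposure group labels.

    Bins are lower-closed/upper-open except the top bin, e.g. for Signature
    18: [0, 0.1) -> "<0.1", [0.1, 0.4) -> "0.1-0.4", [0.4, 0.6) ->
    "0.4-0.6", [0.6, 1] -> ">0.6".
    """
    if variable not in SIGNATURE_GROUPS:
        raise ValueError(f"unknown grouping variable {variable!r}")
    bins = SIGNATURE_GROUPS[variable]
    exposures = catalog.patients.set_index("patient")[variable]
    if ((exposures < 0) | (exposures > 1)).any():
        raise ValueError("exposures must lie in [0, 1]")
    labels = []
    for e in exposures:
        for k, (lo, hi) in enumerate(bins):
            if lo <= e < hi:
                labels.append(group_label((lo, hi), k == 0, k == len(bins) - 1))
                break
    return pd.Series(labels, index=exposures.index, name=f"{variable}_group")


def gc_rich_fraction(catalog: SnvCatalog, gc: GcTrack,
                     mutation_type: str = "C>A", cutoff: int = 50
                     ) -> Tuple[pd.Series, int]:
    """Per-patient fraction of SNVs (of one folded type) in GC-rich bins.

    SNVs falling in censored bins are excluded from numerator and
    denominator; patients left with zero retained SNVs are excluded and
    counted. GC-rich means rounded GC >= cutoff.
    """
    snvs = catalog.of_type(mutation_type)
    fractions = {}
    n_excluded = 0
    for pid, sub in snvs.groupby("patient"):
        rich_total = 0
        kept_total = 0
        for chrom, chrom_snvs in sub.groupby("chrom"):
            bins = (chrom_snvs["pos"].to_numpy(np.int64) - 1) // gc.bin_size
            cens = gc.censored[chrom][bins]
            rich = gc.rich_mask(chrom, cutoff)[bins]
            kept_total += int((~cens).sum())
            rich_total += int((rich & ~cens).sum())
        if kept_total == 0:
            n_excluded += 1
            continue
        fractions[pid] = rich_total / kept_total
    return pd.Series(fractions, name="gc_rich_fraction"), n_excluded


def group_fraction_stats(fractions: pd.Series, groups: pd.Series,
                         reference_group: str) -> pd.DataFrame:
    """Median/quartiles per group plus rank-sum p vs the reference group."""
    fractions, groups = fractions.align(groups, join="inner")
    ref = fractions[groups == reference_group]
    rows = []
    for g in pd.unique(groups):
        vals = fractions[groups == g]
        row = {"group": g, "n": len(vals), "median": float(vals.median()),
               "q1": float(vals.quantile(0.25)), "q3": float(vals.quantile(0.75))}
        if g != reference_group and len(ref) and len(vals):
            row["p_vs_reference"] = rank_sum_test(vals.to_numpy(), ref.to_numpy())
        else:
            row["p_vs_reference"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_replication_timing(catalog: SnvCatalog, timing: BinnedTrack,
                                   gc: GcTrack, mutation_type: str = "C>A",
                                   cutoff: int = 50) -> Dict[str, pd.Series]:
    """GC-rich SNV fractions computed separately within timing tertiles.

    Uncensored 1-kb bins are ranked by replication timing and split into
    three equal-count tertiles (stable on bin index; constant timing thus
    degrades to an index split, with a warning).
    """
    if timing.bin_size != gc.bin_size:
        raise ValueError("timing and GC tracks must share the bin size")
    flat_timing = timing.flat(gc.chroms)
    usable = np.isfinite(flat_timing) & ~np.concatenate(
        [gc.censored[c] for c in gc.chroms])
    idx = np.flatnonzero(usable)
    vals = flat_timing[idx]
    if np.all(vals == vals[0]):
        import warnings
        warnings.warn("constant replication timing; tertiles split by bin index")
    order = np.lexsort((idx, vals))
    tertile_of_flat = np.full(len(flat_timing), -1, dtype=np.int8)
    for t, chunk in enumerate(np.array_split(order, 3)):
        tertile_of_flat[idx[chunk]] = t
    # map flat indices back to (chrom, bin)
    offsets = {}
    off = 0
    for c in gc.chroms:
        offsets[c] = off
        off += len(gc.gc_percent[c])
    out = {}
    for t, name in enumerate(["early", "intermediate", "late"]):
        member = {c: tertile_of_flat[offsets[c]:offsets[c] + len(gc.gc_percent[c])] == t
                  for c in gc.chroms}
        masked_gc = GcTrack(
            gc.bin_size,
            gc.gc_percent,
            gc.defined_fraction,
            {c: gc.censored[c] | ~member[c] for c in gc.chroms},
        )
        fracs, _ = gc_rich_fraction(catalog, masked_gc, mutation_type, cutoff)
        out[name] = fracs
    return out


def snv_metaprofile(catalog: SnvCatalog, anchors: pd.DataFrame,
                    flank_5p: int, flank_3p: int, genome: Genome,
                    mutation_type: str = "C>A",
                    smooth_window: Optional[int] = 100,
                    genome_avg_gc: Optional[float] = None) -> Metaprofile:
    """GC-normalised SNV-rate metaprofile around stranded anchors.

    Per relative position, pooled SNV counts across features are scaled to
    1,000,000 mutations of the given type in the pooled group, then divided
    by the local GC content over the genome-average GC (computed from the
    genome, not hard-coded), and finally Gaussian-smoothed for display.
    """
    snvs = catalog.of_type(mutation_type)
    total = len(snvs)
    if total == 0:
        raise ValueError(f"no {mutation_type} mutations in the group")
    counts = {c: np.zeros(genome.length(c)) for c in genome}
    for chrom, sub in snvs.groupby("chrom"):
        np.add.at(counts[chrom], sub["pos"].to_numpy(np.int64) - 1, 1.0)
    count_track = BinnedTrack(1, counts)
    prof = centered_profile(count_track, anchors, flank_5p, flank_3p)
    density = prof.mean * (1_000_000.0 / total)
    avg_gc = genome.gc_fraction() if genome_avg_gc is None else genome_avg_gc
    local_gc = centered_gc_profile(genome, anchors, flank_5p, flank_3p,
                                   smooth_window=smooth_window)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalised = density / (local_gc / avg_gc)
    if smooth_window:
        normalised = gaussian_smooth(normalised, smooth_window)
    return Metaprofile(prof.axis, normalised, np.full_like(normalised, np.nan),
                       prof.n_features, normalised[np.newaxis, :], prof.n_dropped)
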