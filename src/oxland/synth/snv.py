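"""Trinucleotide-context-aware SNV catalog simulator.

SNV positions are sampled at genomic occurrences of the trinucleotide
classes drawn from each patient's signature mixture (strand-folded, so a
C>A mutation may land on a genomic C or G). A per-patient GC-rich weight
lets cohorts deplete (or enrich) mutations in GC-rich 1-kb bins, emulating
the damage-pattern-driven depletion seen in oxidative-signature and
POLE-proofreading-deficient tumours.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..errors import SimulationError
from ..gc import (CLASSES, INVALID, GcTrack, classes_for_mutation_type,
                  gc_per_bin, trinuc_class_codes)
from ..genome import Genome
from ..mutations import MUTATION_TYPES, SnvCatalog

_ALT = {("C>A", "C"): "A", ("C>A", "G"): "T",
        ("T>G", "T"): "G", ("T>G", "A"): "C",
        ("C>T", "C"): "T", ("C>T", "G"): "A"}


def _profile_vector(weights: Dict[str, float], mutation_type: str) -> np.ndarray:
    """32-vector from {trinucleotide: weight}, validated and normalised."""
    vec = np.zeros(32)
    valid = set(classes_for_mutation_type(mutation_type).tolist())
    for tri, w in weights.items():
        from ..gc import fold_trinuc, CLASS_INDEX
        idx = CLASS_INDEX[fold_trinuc(tri.upper())]
        if idx not in valid:
            raise ValueError(f"context {tri} incompatible with {mutation_type}")
        vec[idx] += w
    if vec.sum() <= 0:
        raise ValueError("profile weights must be positive")
    return vec / vec.sum()


@dataclass
class SignatureProfile:
    """Folded mutation type plus 32-class trinucleotide weights."""

    mutation_type: str
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mutation_type!r}")
        if self.weights.shape != (32,):
            raise ValueError("profile needs exactly 32 class weights")
        if (self.weights < 0).any() or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        valid = classes_for_mutation_type(self.mutation_type)
        off = np.setdiff1d(np.arange(32), valid)
        if self.weights[off].sum() > 1e-12:
            raise ValueError("weights on classes whose central base does not "
                             f"match {self.mutation_type}")

    @classmethod
    def uniform(cls, mutation_type: str) -> "SignatureProfile":
        valid = classes_for_mutation_type(mutation_type)
        w = np.zeros(32)
        w[valid] = 1.0 / len(valid)
        return cls(mutation_type, w)

    @classmethod
    def from_contexts(cls, mutation_type: str,
                      weights: Dict[str, float]) -> "SignatureProfile":
        return cls(mutation_type, _profile_vector(weights, mutation_type))


def default_profiles() -> Dict[str, SignatureProfile]:
    """Synthetic stand-ins for the oxidative-damage-linked COSMIC signatures.

    The context preferences are invented but qualitatively faithful:
    Signature 18 (genomic 8-oxoG) favours NCA/NCT contexts, Signature 17
    (oxidised dNTP incorporation) strongly favours CTT-type contexts, and
    Signature 10 (POLE proofreading loss) favours TCT contexts.
    """
    return {
        "sig18": SignatureProfile.from_contexts("C>A", {
            "ACA": 0.2, "CCA": 0.15, "GCA": 0.2, "TCA": 0.15,
            "ACT": 0.1, "GCT": 0.1, "TCT": 0.1}),
        "sig17": SignatureProfile.from_contexts("T>G", {
            "CTT": 0.6, "ATT": 0.15, "GTT": 0.15, "TTT": 0.1}),
        "sig10": SignatureProfile.from_contexts("C>A", {
            "TCT": 0.75, "TCA": 0.15, "CCT": 0.1}),
        "flat_ca": SignatureProfile.uniform("C>A"),
        "flat_tg": SignatureProfile.uniform("T>G"),
        "flat_ct": SignatureProfile.uniform("C>T"),
    }


@dataclass
class PatientSpec:
    """Design of one synthetic patient.

    ``exposures`` maps mutation type -> {profile name: proportion}; any
    remainder up to 1 is drawn from the flat profile of that type.
    ``gc_rich_weight`` multiplies the sampling weight of positions in
    GC-rich (>= 50%) 1-kb bins.
    """

    patient_id: str
    mutation_counts: Dict[str, int]
    exposures: Dict[str, Dict[str, float]] = dc_field(default_factory=dict)
    ber_coding: bool = False
    smoking_or_therapy: bool = False
    gc_rich_weight: float = 1.0


class _ContextIndex:
    """Genomic positions per folded trinucleotide class, split by GC-rich."""

    def __init__(self, genome: Genome, gc: GcTrack):
        self.positions: Dict[Tuple[str, int, bool], np.ndarray] = {}
        self.counts = np.zeros((2, 32), dtype=np.int64)  # [rich, class]
        self.chroms = list(genome)
        for chrom in genome:
            codes = trinuc_class_codes(genome, chrom)
            rich = gc.rich_mask(chrom)[np.arange(len(codes)) // gc.bin_size]
            order = np.argsort(codes, kind="stable")
            sorted_codes = codes[order]
            bounds = np.searchsorted(sorted_codes, np.arange(33))
            for cls in range(32):
                pos = order[bounds[cls]:bounds[cls + 1]]
                is_rich = rich[pos]
                self.positions[(chrom, cls, True)] = np.sort(pos[is_rich]).astype(np.int64)
                self.positions[(chrom, cls, False)] = np.sort(pos[~is_rich]).astype(np.int64)
                self.counts[1, cls] += int(is_rich.sum())
                self.counts[0, cls] += int((~is_rich).sum())

    def sample(self, rng, cls: int, k: int, gc_rich_weight: float
               ) -> List[Tuple[str, np.ndarray]]:
        n_rich = self.counts[1, cls]
        n_other = self.counts[0, cls]
        if n_rich + n_other == 0:
            raise SimulationError(
                f"requested context {CLASSES[cls]} absent from genome")
        w_rich = gc_rich_weight * n_rich
        k_rich = rng.binomial(k, w_rich / (w_rich + n_other)) if (w_rich + n_other) else 0
        out = []
        for rich, kk in ((True, k_rich), (False, k - k_rich)):
            if kk == 0:
                continue
            pools = [self.positions[(c, cls, rich)] for c in self.chroms]
            sizes = np.array([len(p) for p in pools], dtype=float)
            per_chrom = rng.multinomial(kk, sizes / sizes.sum())
            for chrom, pool, kc in zip(self.chroms, pools, per_chrom):
                if kc:
                    out.append((chrom, rng.choice(pool, size=int(kc), replace=True)))
        return out


def simulate_snv_catalog(genome: Genome,
                         patients: Sequence[PatientSpec],
                         profiles: Optional[Dict[str, SignatureProfile]] = None,
                         gc_track: Optional[GcTrack] = None,
                         seed: int = 0) -> SnvCatalog:
    """Sample per-patient SNV catalogs at matching trinucleotide contexts.

    Every emitted SNV's strand-folded reference trinucleotide matches its
    sampled class; per-patient signature exposures and flags are recorded in
    the patient table.
    """
    if profiles is None:
        profiles = default_profiles()
    if gc_track is None:
        gc_track = gc_per_bin(genome)
    rng = np.random.default_rng(seed)
    index = _ContextIndex(genome, gc_track)
    col_chrom: List[np.ndarray] = []
    col_pos: List[np.ndarray] = []
    col_ref: List[np.ndarray] = []
    col_alt: List[np.ndarray] = []
    col_patient: List[np.ndarray] = []
    col_type: List[np.ndarray] = []
    patient_rows = []
    for spec in patients:
        type_counts = {t: 0 for t in MUTATION_TYPES}
        for mtype in MUTATION_TYPES:
            n = int(spec.mutation_counts.get(mtype, 0))
            if n == 0:
                continue
            mix = np.zeros(32)
            total_exposure = 0.0
            for name, prop in spec.exposures.get(mtype, {}).items():
                prof = profiles[name]
                if prof.mutation_type != mtype:
                    raise ValueError(f"profile {name} is for {prof.mutation_type}, "
                                     f"not {mtype}")
                mix += prop * prof.weights
                total_exposure += prop
            if total_exposure > 1.0 + 1e-9:
                raise ValueError("exposures exceed 1 for one mutation type")
            mix += (1.0 - total_exposure) * SignatureProfile.uniform(mtype).weights
            class_counts = rng.multinomial(n, mix)
            alt_map = np.full(256, b"?"[0], dtype=np.uint8)
            for (t, ref), alt in _ALT.items():
                if t == mtype:
                    alt_map[ord(ref)] = ord(alt)
            for cls in np.flatnonzero(class_counts):
                for chrom, positions in index.sample(
                        rng, int(cls), int(class_counts[cls]),
                        spec.gc_rich_weight):
                    refs = genome.codes(chrom)[positions]
                    col_chrom.append(np.repeat(chrom, len(positions)))
                    col_pos.append(positions + 1)
                    col_ref.append(refs.view("S1").astype("U1"))
                    col_alt.append(alt_map[refs].view("S1").astype("U1"))
                    col_patient.append(np.repeat(spec.patient_id, len(positions)))
                    col_type.append(np.repeat(mtype, len(positions)))
            type_counts[mtype] = n
        exp = spec.exposures
        patient_rows.append({
            "patient": spec.patient_id,
            "n_c_to_a": type_counts["C>A"],
            "n_t_to_g": type_counts["T>G"],
            "n_c_to_t": type_counts["C>T"],
            "sig18": exp.get("C>A", {}).get("sig18", 0.0),
            "sig17": exp.get("T>G", {}).get("sig17", 0.0),
            "sig10": exp.get("C>A", {}).get("sig10", 0.0),
            "ber_coding": spec.ber_coding,
            "smoking_or_therapy": spec.smoking_or_therapy,
        })
    if col_chrom:
        snvs = pd.DataFrame({
            "chrom": np.concatenate(col_chrom),
            "pos": np.concatenate(col_pos).astype(np.int64),
            "ref": np.concatenate(col_ref),
            "alt": np.concatenate(col_alt),
            "patient": np.concatenate(col_patient),
            "mutation_type": np.concatenate(col_type),
        })
    else:
        snvs = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "patient",
                                     "mutation_type"])
    return SnvCatalog(snvs, pd.DataFrame(patient_rows,
                                         columns=["patient", "n_c_to_a",
                                                  "n_t_to_g", "n_c_to_t",
                                                  "sig18", "sig17", "sig10",
                                                  "ber_coding",
                                                  "smoking_or_therapy"]))
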