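"""Synthetic genome and annotation generator.

Emulates the annotation universe of a mammalian reference at desk scale:
non-overlapping gene models (promoter, UTRs, exons, introns, termination
site), Alu (270-330 bp) and LINE (5.9-6.1 kb) retrotransposons, CpG islands,
TF and CTCF binding motifs, microsatellite runs, G-quadruplex intervals, and
a contiguous centromere-like N-run. Promoters and CpG islands are GC-rich;
background GC varies smoothly in 10-kb blocks around the requested baseline
so that 1-kb bins spread over a realistic GC-percent range.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ..errors import SimulationError
from ..features import FEATURE_COLUMNS
from ..genome import Genome

DEFAULT_DENSITIES = {
    "gene": 8.0,          # per Mb
    "alu": 60.0,
    "line": 2.0,
    "cpg_island": 2.0,    # intergenic islands; promoter islands come for free
    "tfbs": 30.0,
    "ctcf_motif": 10.0,
    "microsatellite": 10.0,
    "g4": 10.0,
}

ALU_SIZE = (270, 330)
LINE_SIZE = (5900, 6100)
MICROSAT_UNITS = ["A", "AC", "AG", "AT", "GAA", "CA", "GGAA", "GAAA", "CCCA", "ATGGTG"]
LINE_FAMILIES = ["L1PA3", "L1PA4", "L1PA5", "L1PA6", "L1PA7", "L1PA8", "L1PA10"]


@dataclass
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    gc_baseline: float = 0.41
    feature_densities: Dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    n_run_fraction: float = 0.02
    gc_block: int = 10_000
    gc_sd: float = 0.055
    promoter_gc: float = 0.62
    cpg_island_gc: float = 0.68
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not (0.0 <= self.gc_baseline <= 1.0):
            raise ValueError("gc_baseline must lie in [0, 1]")
        if any(d < 0 for d in self.feature_densities.values()):
            raise ValueError("feature densities must be non-negative")
        if not (0.0 <= self.n_run_fraction < 1.0):
            raise ValueError("n_run_fraction must lie in [0, 1)")


def _count(spec: SyntheticGenomeSpec, cls: str) -> int:
    density = spec.feature_densities.get(cls, 0.0)
    return int(round(density * spec.chrom_length / 1e6))


def _place_in_slots(rng, lo: int, hi: int, lengths: List[int], cls: str,
                    lead: int = 0, trail: int = 0) -> List[int]:
    """Place len(lengths) non-overlapping intervals in [lo, hi).

    The region is divided into equal slots; each interval lands at a random
    offset inside its slot, leaving ``lead``/``trail`` bp of clearance. An
    interval that cannot fit raises with the offending feature class.
    """
    n = len(lengths)
    if n == 0:
        return []
    slot = (hi - lo) // n
    starts = []
    for i, length in enumerate(lengths):
        needed = length + lead + trail
        if slot < needed:
            raise SimulationError(
                f"chromosome too short to host requested features: {cls}")
        s_lo = lo + i * slot + lead
        s_hi = lo + i * slot + slot - length - trail
        starts.append(int(rng.integers(s_lo, s_hi + 1)))
    return starts


def _sample_free(rng, free: np.ndarray, length: int, cls: str,
                 max_tries: int = 200) -> int:
    """Uniform start position whose whole interval is unoccupied."""
    limit = len(free) - length
    if limit <= 0:
        raise SimulationError(
            f"chromosome too short to host requested features: {cls}")
    for _ in range(max_tries):
        s = int(rng.integers(0, limit))
        if free[s:s + length].all():
            return s
    raise SimulationError(
        f"chromosome too short to host requested features: {cls} "
        "(no free interval found)")


def _gene_rows(rng, chrom: str, start: int, strand: str, gene_id: str
               ) -> Tuple[List[dict], int]:
    """Element rows of one gene model laid out from its 5' end.

    Local coordinates run 0 (TSS) downstream; they are mapped onto the
    genome according to the strand. Returns (rows, transcript span length).
    """
    u5 = int(rng.integers(150, 301))
    u3 = int(rng.integers(200, 401))
    n_exons = int(rng.integers(4, 8))
    exon_lens = rng.integers(80, 201, size=n_exons)
    intron_lens = rng.integers(500, 2001, size=n_exons - 1)
    local: List[Tuple[str, int, int]] = [("five_utr", 0, u5)]
    cursor = u5
    for i in range(n_exons):
        local.append(("exon", cursor, cursor + int(exon_lens[i])))
        cursor += int(exon_lens[i])
        if i < n_exons - 1:
            local.append(("intron", cursor, cursor + int(intron_lens[i])))
            cursor += int(intron_lens[i])
    local.append(("three_utr", cursor, cursor + u3))
    cursor += u3
    span = cursor
    rows = []

    def to_genome(a: int, b: int) -> Tuple[int, int]:
        if strand == "+":
            return start + a, start + b
        end = start + span
        return end - b, end - a

    for cls, a, b in local:
        ga, gb = to_genome(a, b)
        rows.append({"chrom": chrom, "start": ga, "end": gb, "name": gene_id,
                     "score": 0, "strand": strand, "feature_class": cls})
    ta, tb = to_genome(0, span)
    rows.append({"chrom": chrom, "start": ta, "end": tb, "name": gene_id,
                 "score": 0, "strand": strand, "feature_class": "transcript"})
    tss = ta if strand == "+" else tb - 1
    tes = tb - 1 if strand == "+" else ta
    rows.append({"chrom": chrom, "start": tss, "end": tss + 1, "name": gene_id,
                 "score": 0, "strand": strand, "feature_class": "tss"})
    rows.append({"chrom": chrom, "start": tes, "end": tes + 1, "name": gene_id,
                 "score": 0, "strand": strand, "feature_class": "tes"})
    if strand == "+":
        prom = (ta - 1000, ta)
    else:
        prom = (tb, tb + 1000)
    rows.append({"chrom": chrom, "start": prom[0], "end": prom[1],
                 "name": gene_id, "score": 0, "strand": strand,
                 "feature_class": "promoter"})
    return rows, span


def simulate_genome(spec: SyntheticGenomeSpec) -> Tuple[Genome, pd.DataFrame]:
    """Generate a genome and its feature annotation from the spec.

    Identical specs (including seed) produce byte-identical sequences and
    annotation tables.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_length
    all_rows: List[dict] = []
    sequences: Dict[str, str] = {}
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        rows: List[dict] = []
        # centromere-like contiguous N-run in the chromosome middle
        n_len = int(round(spec.n_run_fraction * L))
        n_start = (L - n_len) // 2
        n_end = n_start + n_len
        occupied = np.zeros(L, dtype=bool)
        if n_len:
            occupied[max(0, n_start - 500):min(L, n_end + 500)] = True
            rows.append({"chrom": chrom, "start": n_start, "end": n_end,
                         "name": "n_run", "score": 0, "strand": ".",
                         "feature_class": "n_run"})

        # gene models: non-overlapping, half before and half after the N-run
        n_genes = _count(spec, "gene")
        if n_genes:
            halves = ([(0, n_start)] * (n_genes // 2)
                      + [(n_end, L)] * (n_genes - n_genes // 2))
            # regroup per half for slot placement
            per_half = {}
            for (lo, hi) in halves:
                per_half[(lo, hi)] = per_half.get((lo, hi), 0) + 1
            gi = 0
            for (lo, hi), count in per_half.items():
                max_span = 300 + 7 * 200 + 6 * 2000 + 400
                starts = _place_in_slots(
                    rng, lo, hi, [max_span] * count, "gene",
                    lead=1100, trail=1100)
                for s in starts:
                    gi += 1
                    strand = "+" if rng.random() < 0.5 else "-"
                    gene_id = f"{chrom}_t{gi:04d}"
                    grows, span = _gene_rows(rng, chrom, s, strand, gene_id)
                    rows.extend(grows)
                    occupied[max(0, s - 1100):min(L, s + span + 1100)] = True

        # microsatellites (literal repeat runs, written into the sequence)
        microsat = []
        for mi in range(_count(spec, "microsatellite")):
            unit = MICROSAT_UNITS[int(rng.integers(0, len(MICROSAT_UNITS)))]
            n_rep = int(rng.integers(10, 31))
            length = len(unit) * n_rep
            s = _sample_free(rng, ~occupied, length, "microsatellite")
            occupied[s:s + length] = True
            microsat.append((s, unit, n_rep))
            rows.append({"chrom": chrom, "start": s, "end": s + length,
                         "name": unit, "score": n_rep, "strand": "+",
                         "feature_class": "microsatellite"})

        # CpG islands: at half the promoters (overlapping the TSS) and intergenic
        prom_rows = [r for r in rows if r["feature_class"] == "tss"]
        for k, r in enumerate(prom_rows):
            if k % 2 == 0:
                s = max(0, r["start"] - 200)
                rows.append({"chrom": chrom, "start": s, "end": min(L, r["start"] + 300),
                             "name": f"cpg_{chrom}_{k}", "score": 0, "strand": ".",
                             "feature_class": "cpg_island"})
        for k in range(_count(spec, "cpg_island")):
            length = int(rng.integers(300, 801))
            s = _sample_free(rng, ~occupied, length, "cpg_island")
            occupied[s:s + length] = True
            rows.append({"chrom": chrom, "start": s, "end": s + length,
                         "name": f"cpg_ig_{chrom}_{k}", "score": 0, "strand": ".",
                         "feature_class": "cpg_island"})

        # G-quadruplex intervals: some promoter-proximal, the rest scattered
        n_g4 = _count(spec, "g4")
        for k in range(n_g4):
            length = int(rng.integers(25, 41))
            if k % 3 == 0 and prom_rows:
                r = prom_rows[k % len(prom_rows)]
                s = min(max(0, r["start"] + int(rng.integers(-400, 400))),
                        L - length)
            else:
                s = _sample_free(rng, ~occupied, length, "g4")
            rows.append({"chrom": chrom, "start": s, "end": s + length,
                         "name": f"g4_{chrom}_{k}", "score": 0,
                         "strand": "+" if rng.random() < 0.5 else "-",
                         "feature_class": "g4"})

        # stranded CTCF motifs, spaced so unintended merges cannot occur
        n_ctcf = _count(spec, "ctcf_motif")
        if n_ctcf:
            starts = _place_in_slots(rng, 0, n_start if n_len else L,
                                     [19] * n_ctcf, "ctcf_motif",
                                     lead=1000, trail=1000)
            for k, s in enumerate(starts):
                rows.append({"chrom": chrom, "start": s, "end": s + 19,
                             "name": f"ctcf_{chrom}_{k}", "score": 0,
                             "strand": "+" if rng.random() < 0.5 else "-",
                             "feature_class": "ctcf_motif"})

        # TF binding sites: anywhere in defined sequence
        for k in range(_count(spec, "tfbs")):
            s = _sample_free(rng, ~occupied, 10, "tfbs")
            rows.append({"chrom": chrom, "start": s, "end": s + 10,
                         "name": f"tf{k % 8}", "score": 0,
                         "strand": "+" if rng.random() < 0.5 else "-",
                         "feature_class": "tfbs"})

        # LINE elements: intergenic, family-labelled
        for k in range(_count(spec, "line")):
            length = int(rng.integers(LINE_SIZE[0], LINE_SIZE[1] + 1))
            s = _sample_free(rng, ~occupied, length, "line")
            occupied[s:s + length] = True
            family = LINE_FAMILIES[int(rng.integers(0, len(LINE_FAMILIES)))]
            rows.append({"chrom": chrom, "start": s, "end": s + length,
                         "name": family, "score": 0,
                         "strand": "+" if rng.random() < 0.5 else "-",
                         "feature_class": "line"})

        # Alu elements: intronic or intergenic, never in exons/promoters/UTRs
        hard = occupied.copy()
        frame_so_far = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
        for cls in ("exon", "five_utr", "three_utr", "promoter"):
            sub = frame_so_far[frame_so_far["feature_class"] == cls]
            for r in sub.itertuples(index=False):
                hard[r.start:r.end] = True
        intron_free = hard.copy()
        for r in frame_so_far[frame_so_far["feature_class"] == "intron"].itertuples(index=False):
            intron_free[r.start:r.end] = False  # introns may host Alus
        for k in range(_count(spec, "alu")):
            length = int(rng.integers(ALU_SIZE[0], ALU_SIZE[1] + 1))
            s = _sample_free(rng, ~intron_free, length, "alu")
            intron_free[s:s + length] = True
            rows.append({"chrom": chrom, "start": s, "end": s + length,
                         "name": f"alu_{chrom}_{k}", "score": 0,
                         "strand": "+" if rng.random() < 0.5 else "-",
                         "feature_class": "alu"})

        sequences[chrom] = _draw_sequence(rng, spec, L, rows, (n_start, n_end),
                                          microsat)
        all_rows.extend(rows)

    features = pd.DataFrame(all_rows, columns=FEATURE_COLUMNS)
    features = features.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    return Genome(sequences), features


def _draw_sequence(rng, spec: SyntheticGenomeSpec, L: int, rows: List[dict],
                   n_run: Tuple[int, int], microsat) -> str:
    """Draw bases from a per-bp GC probability field, then apply overrides."""
    n_blocks = -(-L // spec.gc_block)
    block_gc = np.clip(
        rng.normal(spec.gc_baseline, spec.gc_sd, size=n_blocks), 0.2, 0.75)
    p_gc = np.repeat(block_gc, spec.gc_block)[:L].copy()
    for r in rows:
        if r["feature_class"] == "promoter":
            p_gc[max(0, r["start"]):r["end"]] = spec.promoter_gc
        elif r["feature_class"] == "cpg_island":
            p_gc[max(0, r["start"]):r["end"]] = spec.cpg_island_gc
    u = rng.random(L)
    # [0, gc/2) -> G, [gc/2, gc) -> C, [gc, gc + at/2) -> A, rest -> T
    at = 1.0 - p_gc
    base = np.full(L, ord("T"), dtype=np.uint8)
    base[u < p_gc / 2] = ord("G")
    base[(u >= p_gc / 2) & (u < p_gc)] = ord("C")
    base[(u >= p_gc) & (u < p_gc + at / 2)] = ord("A")
    seq = bytearray(base.tobytes())
    for s, unit, n_rep in microsat:
        run = (unit * n_rep).encode("ascii")
        seq[s:s + len(run)] = run
    ns, ne = n_run
    if ne > ns:
        seq[ns:ne] = b"N" * (ne - ns)
    return seq.decode("ascii")
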