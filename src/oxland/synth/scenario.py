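"""Desk-scale study scenarios: the default end-to-end synthetic experiment.

The default scenario is 2 chromosomes x 5 Mb, three biological replicates,
5e5 fragments per library, with planted log2 damage effects of +2 in Alu
elements and -1.5 in promoters; it runs end-to-end in minutes on one CPU.
Treatment/processing conditions (untreated vs X-ray, AP vs OGG1-AP) reuse
the same genome with condition-specific damage models: untreated damage
effects are attenuated, and OGG1-AP processing adds extra intensity at
G-quadruplexes and microsatellites (unprocessed 8-oxoG).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from ..genome import Genome
from .chromatin import ChromatinTracks, plant_anchors, simulate_chromatin
from .damage import DamageField, DamageModel, simulate_damage_field
from .genome import SyntheticGenomeSpec, simulate_genome
from .libraries import ReplicatePair, simulate_libraries
from .snv import PatientSpec, simulate_snv_catalog

CONDITIONS = ("xray_AP", "xray_OGG1", "untreated_AP", "untreated_OGG1")

DEFAULT_SCENARIO = {
    "n_chromosomes": 2,
    "chrom_length": 5_000_000,
    "n_replicates": 3,
    "fragments_per_replicate": 500_000,
    "fragment_length": [60.0, 15.0],
    "anchors_per_chrom": 28,
    "anchor_noise_sd": 0.1,
}


@dataclass
class Scenario:
    genome_spec: SyntheticGenomeSpec
    damage_model: DamageModel
    n_replicates: int = 3
    fragments_per_replicate: int = 500_000
    fragment_length: Tuple[float, float] = (60.0, 15.0)
    anchors_per_chrom: int = 28
    anchor_noise_sd: float = 0.1
    #: log2 damage step across swap anchors (damage loads toward the
    #: inactive compartment; swap_on and swap_off get opposite signs)
    anchor_damage_step: float = 0.8
    anchor_window: int = 10_000


def default_scenario() -> Scenario:
    return Scenario(SyntheticGenomeSpec(), DamageModel())


def scenario_from_yaml(path) -> Scenario:
    """Scenario from a YAML mapping (keys as in DEFAULT_SCENARIO)."""
    with open(path) as fh:
        cfg = dict(DEFAULT_SCENARIO, **(yaml.safe_load(fh) or {}))
    spec = SyntheticGenomeSpec(
        n_chromosomes=int(cfg["n_chromosomes"]),
        chrom_length=int(cfg["chrom_length"]),
    )
    return Scenario(
        genome_spec=spec,
        damage_model=DamageModel(),
        n_replicates=int(cfg["n_replicates"]),
        fragments_per_replicate=int(cfg["fragments_per_replicate"]),
        fragment_length=tuple(cfg["fragment_length"]),
        anchors_per_chrom=int(cfg["anchors_per_chrom"]),
        anchor_noise_sd=float(cfg["anchor_noise_sd"]),
    )


def apply_anchor_damage_steps(field: DamageField, anchors: pd.DataFrame,
                              window: int = 10_000,
                              step_log2: float = 0.8) -> None:
    """Plant opposite damage steps across swap anchors (in place).

    Damage loads toward the inactive chromatin compartment: for a "swap_on"
    anchor the outside of the loop is inactive, so intensity rises outside
    and falls inside by half the step each; "swap_off" is mirrored. Neutral
    ("on"/"off") anchors receive no asymmetry.
    """
    half = 2.0 ** (step_log2 / 2.0)
    for r in anchors.itertuples(index=False):
        if r.true_class not in ("swap_on", "swap_off"):
            continue
        arr = field.intensities[r.chrom]
        c = int(r.center)
        upstream = slice(max(c - window, 0), c)
        downstream = slice(c, min(c + window, len(arr)))
        out_sl, in_sl = ((upstream, downstream) if r.strand != "-"
                         else (downstream, upstream))
        inactive_out = r.true_class == "swap_on"
        arr[out_sl] *= half if inactive_out else 1.0 / half
        arr[in_sl] *= 1.0 / half if inactive_out else half


def condition_model(base: DamageModel, condition: str) -> DamageModel:
    """Condition-specific damage model derived from the base model."""
    effects = dict(base.feature_effects)
    if condition.startswith("untreated"):
        effects = {k: v * 0.6 for k, v in effects.items()}
    if condition.endswith("OGG1"):
        effects = dict(effects)
        effects["g4"] = effects.get("g4", 0.0) + 1.0
        effects["microsatellite"] = effects.get("microsatellite", 0.0) + 0.5
    return replace(base, feature_effects=effects)


@dataclass
class StudyData:
    """Everything one synthetic study produces, ground truth included."""

    genome: Genome
    features: pd.DataFrame
    fields: Dict[str, DamageField]            # per condition
    libraries: Dict[str, List[ReplicatePair]]  # per condition
    anchors: pd.DataFrame                      # planted, with true_class
    chromatin: ChromatinTracks
    scenario: Scenario
    seed: int


def simulate_scenario(seed: int, scenario: Optional[Scenario] = None,
                      conditions: Sequence[str] = ("xray_AP",)) -> StudyData:
    """Run the full generator chain for the requested conditions."""
    scenario = scenario or default_scenario()
    seeds = np.random.SeedSequence(seed).spawn(4 + 2 * len(conditions))
    genome_seed = int(seeds[0].generate_state(1)[0] % (2 ** 31))
    spec = replace(scenario.genome_spec, seed=genome_seed)
    genome, features = simulate_genome(spec)
    gene_territory = features[features["feature_class"].isin(
        ["transcript", "promoter"])]
    anchors = plant_anchors(genome, scenario.anchors_per_chrom,
                            scenario.anchor_window,
                            seed=int(seeds[1].generate_state(1)[0] % (2 ** 31)),
                            avoid=gene_territory)
    chromatin = simulate_chromatin(
        genome, anchors, noise_sd=scenario.anchor_noise_sd,
        seed=int(seeds[2].generate_state(1)[0] % (2 ** 31)))
    fields = {}
    libraries = {}
    for i, cond in enumerate(conditions):
        model = condition_model(scenario.damage_model, cond)
        fields[cond] = simulate_damage_field(genome, features, model)
        apply_anchor_damage_steps(fields[cond], anchors,
                                  scenario.anchor_window,
                                  scenario.anchor_damage_step)
        libraries[cond] = simulate_libraries(
            fields[cond], genome, scenario.n_replicates,
            scenario.fragments_per_replicate, scenario.fragment_length,
            model, seed=int(seeds[4 + i].generate_state(1)[0] % (2 ** 31)))
    return StudyData(genome, features, fields, libraries, anchors, chromatin,
                     scenario, seed)


def simulate_cohort(genome: Genome, seed: int,
                    n_control: int = 50, n_depleted: int = 50,
                    snvs_per_patient: int = 2000,
                    depletion: float = 1.0 / 3.0,
                    n_pole: int = 0,
                    pole_c_to_a: int = 150_000):
    """Synthetic tumour cohort: control vs GC-rich-context-depleted patients.

    The depleted group samples GC-rich positions with weight ``depletion``
    (default threefold depletion), emulating the reduced GC-rich mutation
    load of oxidative-signature-high and POLE-deficient tumours. Optional
    ``n_pole`` patients carry a hypermutator C>A load with prominent
    Signature 10 (and the GC-rich depletion).

    Returns the catalog; group membership is recoverable from the patient
    table (sig18/sig10 exposures) and from the patient id prefix.
    """
    patients = []
    for i in range(n_control):
        patients.append(PatientSpec(
            patient_id=f"control_{i:03d}",
            mutation_counts={"C>A": snvs_per_patient, "T>G": snvs_per_patient},
            exposures={"C>A": {"sig18": 0.05}, "T>G": {"sig17": 0.05}},
        ))
    for i in range(n_depleted):
        patients.append(PatientSpec(
            patient_id=f"sig18high_{i:03d}",
            mutation_counts={"C>A": snvs_per_patient, "T>G": snvs_per_patient},
            exposures={"C>A": {"sig18": 0.7}, "T>G": {"sig17": 0.05}},
            gc_rich_weight=depletion,
        ))
    for i in range(n_pole):
        patients.append(PatientSpec(
            patient_id=f"pole_{i:03d}",
            mutation_counts={"C>A": pole_c_to_a},
            exposures={"C>A": {"sig10": 0.8}},
            gc_rich_weight=depletion,
        ))
    return simulate_snv_catalog(genome, patients, seed=seed)
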