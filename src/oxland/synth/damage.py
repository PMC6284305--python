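"""Ground-truth per-bp damage intensity fields.

The field is multiplicative: a baseline expected fragment rate per bp, a GC
response evaluated on the surrounding 1-kb sequence, and per-feature-class
log2 multipliers (retrotransposon hotspots, promoter/exon depletion).
Intensity is zero on undefined (N) sequence. The field is the latent truth
that the library simulator samples from and that recovery tests compare
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd

from ..features import class_mask
from ..genome import Genome

#: Default planted log2 effects (Alu hotspot, promoter/exon protection).
DEFAULT_FEATURE_EFFECTS = {
    "alu": 2.0,
    "promoter": -1.5,
    "exon": -1.0,
    "line": 1.0,
}


def gc_bump_response(low: float = 0.5, peak: float = 1.5, high: float = 0.4,
                     peak_gc: float = 47.0) -> Callable[[np.ndarray], np.ndarray]:
    """Rise-then-fall GC response: damage grows with GC then drops sharply.

    Piecewise linear in GC percent: ``low`` at 25%, ``peak`` at ``peak_gc``,
    ``high`` at 70%; clamped outside.
    """

    def response(gc_percent: np.ndarray) -> np.ndarray:
        g = np.asarray(gc_percent, dtype=float)
        up = low + (peak - low) * (g - 25.0) / (peak_gc - 25.0)
        down = peak + (high - peak) * (g - peak_gc) / (70.0 - peak_gc)
        return np.clip(np.where(g <= peak_gc, up, down), min(low, high), peak)

    return response


@dataclass
class DamageModel:
    baseline_intensity: float = 0.05  # expected fragments per bp (relative)
    feature_effects: Dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS))
    gc_response: Optional[Callable[[np.ndarray], np.ndarray]] = None
    pulldown_efficiency: float = 0.5
    noise_dispersion: float = 20.0  # gamma shape of the overdispersion mixing

    def __post_init__(self):
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if any(not np.isfinite(v) for v in self.feature_effects.values()):
            raise ValueError("feature effects must be finite")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be non-negative")


@dataclass
class DamageField:
    """Per-bp expected pulldown intensity (the generator's stored truth)."""

    intensities: Dict[str, np.ndarray]

    @property
    def chroms(self):
        return list(self.intensities)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.intensities.values()))

    def expected_log2_effect(self, features: pd.DataFrame, feature_class: str,
                             baseline_mask: Optional[Dict[str, np.ndarray]] = None
                             ) -> float:
        """Oracle: log2 of mean intensity inside a class over baseline mean.

        The baseline defaults to all defined positions not covered by the
        class itself.
        """
        inside, outside = [], []
        for chrom, arr in self.intensities.items():
            mask = class_mask(features, chrom, len(arr), feature_class)
            defined = arr > 0
            inside.append(arr[mask & defined])
            base = (baseline_mask[chrom] if baseline_mask is not None
                    else (~mask & defined))
            outside.append(arr[base])
        inside = np.concatenate(inside)
        outside = np.concatenate(outside)
        return float(np.log2(inside.mean() / outside.mean()))


def rolling_gc_percent(genome: Genome, chrom: str, window: int = 1000) -> np.ndarray:
    """GC percent of the ``window`` bp surrounding each position."""
    gc = genome.gc_mask(chrom).astype(np.float64)
    defined = genome.defined_mask(chrom).astype(np.float64)
    half = window // 2
    csum_gc = np.concatenate([[0.0], np.cumsum(gc)])
    csum_def = np.concatenate([[0.0], np.cumsum(defined)])
    L = len(gc)
    lo = np.clip(np.arange(L) - half, 0, L)
    hi = np.clip(np.arange(L) + half + 1, 0, L)
    gc_w = csum_gc[hi] - csum_gc[lo]
    def_w = csum_def[hi] - csum_def[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * gc_w / def_w
    out[def_w == 0] = np.nan
    return out


def simulate_damage_field(genome: Genome, features: pd.DataFrame,
                          model: DamageModel) -> DamageField:
    """Evaluate the multiplicative intensity model over the genome."""
    intensities: Dict[str, np.ndarray] = {}
    for chrom in genome:
        L = genome.length(chrom)
        sub = features[features["chrom"] == chrom]
        if len(sub) and ((sub["start"] < 0).any() or (sub["end"] > L).any()):
            raise ValueError(f"features exceed bounds of {chrom}")
        arr = np.full(L, model.baseline_intensity, dtype=np.float64)
        for cls, effect in model.feature_effects.items():
            if effect == 0.0:
                continue
            mask = class_mask(features, chrom, L, cls)
            arr[mask] *= 2.0 ** effect
        if model.gc_response is not None:
            gc_pct = rolling_gc_percent(genome, chrom)
            arr *= model.gc_response(np.nan_to_num(gc_pct, nan=50.0))
        arr[~genome.defined_mask(chrom)] = 0.0
        intensities[chrom] = arr
    return DamageField(intensities)
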