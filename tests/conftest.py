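import numpy as np
import pandas as pd
import pytest

from oxland.genome import Genome
from oxland.pipeline import run_enrichment
from oxland.synth import simulate_scenario
from oxland.synth.scenario import Scenario
from oxland.synth.genome import SyntheticGenomeSpec
from oxland.synth.damage import DamageModel

SESSION_SEED = 20250925


def make_features(rows):
    """Feature frame from (chrom, start, end, name, strand, feature_class)."""
    from oxland.features import FEATURE_COLUMNS

    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "name": n, "score": 0,
          "strand": st, "feature_class": f}
         for c, s, e, n, st, f in rows],
        columns=FEATURE_COLUMNS)


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return Genome({"chrT": seq})


@pytest.fixture(scope="session")
def small_study():
    """1 x 1.2 Mb scenario for mid-weight integration tests."""
    scenario = Scenario(
        genome_spec=SyntheticGenomeSpec(n_chromosomes=1, chrom_length=1_200_000),
        damage_model=DamageModel(),
        n_replicates=3,
        fragments_per_replicate=100_000,
        anchors_per_chrom=8,
    )
    return simulate_scenario(SESSION_SEED, scenario)


@pytest.fixture(scope="session")
def default_study():
    """The default desk-scale study: 2 x 5 Mb, 3 replicates, 5e5 fragments."""
    return simulate_scenario(SESSION_SEED)


@pytest.fixture(scope="session")
def default_enrichment(default_study):
    return run_enrichment(default_study.genome,
                          default_study.libraries["xray_AP"])
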