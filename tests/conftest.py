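import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from penliab.datatypes import AnalysisConfig, ScoringTable
from penliab.simulate import SimConfig, run_breeding_program

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def small_table() -> ScoringTable:
    """Hand-built six-animal table: two strains, one phenotype scored NA once."""
    df = pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(6)],
            "strain": ["low", "low", "low", "high", "high", "high"],
            "generation": [1] * 6,
            "family_id": ["f1"] * 3 + ["f2"] * 3,
            "mef2ca": ["mut", "mut", "het", "mut", "mut", "wt"],
            "ectopic-bone": pd.array(
                [True, False, False, True, pd.NA, False], dtype="boolean"
            ),
        }
    )
    return ScoringTable(df, loci=("mef2ca",), phenotypes=("ectopic-bone",))


@pytest.fixture(scope="session")
def breeding_replicates():
    """Fifty replicates of the default breeding program per direction.

    High direction runs 8 selection rounds, low runs 7, mirroring the lengths
    of the two selectively-bred lines.  Shared across tests because the
    replicate set is the single most expensive simulation in the suite.
    """
    out = {}
    for direction, gens in (("high", 8), ("low", 7)):
        cfg = SimConfig(direction=direction, n_generations=gens)
        out[direction] = [
            run_breeding_program(cfg, seed=s) for s in range(1, cfg.n_replicates + 1)
        ]
    return out


def final_penetrance(trajectories, phenotype="ectopic-bone", who="mut"):
    return np.array(
        [t.table[f"{who}_penetrance[{phenotype}]"].iloc[-1] for t in trajectories]
    )
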