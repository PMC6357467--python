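import numpy as np
import pytest

from dmrkit.calling import DMRCallingParams, call_dmrs
from dmrkit.simulate import (
    PlantedDMR,
    SimulationConfig,
    choose_planted_regions,
    plant_dmr_truth,
    simulate_cohort,
    simulate_cpg_landscape,
)


@pytest.fixture(scope="session")
def small_cohort():
    """1 Mb toy chromosome, 6 WD vs 6 HC, ten planted DMRs of |delta| 0.3."""
    config = SimulationConfig(
        seed=20, chromosomes=[("chr1", 1_000_000)], n_per_group={"WD": 6, "HC": 6}
    )
    landscape = simulate_cpg_landscape(config)
    specs = choose_planted_regions(
        landscape, 10, [0.3, -0.3], n_cpgs=10, rng=np.random.default_rng(4)
    )
    truth = plant_dmr_truth(landscape, specs)
    cohort = simulate_cohort(landscape, truth, config)
    return landscape, truth, cohort


@pytest.fixture(scope="session")
def small_call(small_cohort):
    """A full DMR call on the small cohort (enumeration-free, 200 perms)."""
    _, _, cohort = small_cohort
    params = DMRCallingParams(n_perm=200, seed=5)
    return call_dmrs(cohort.matrix, cohort.sample_sheet, "WD", "HC", params)
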