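import numpy as np
import pytest

import betadm as bd


@pytest.fixture(scope="session")
def cell18():
    return bd.UnitCell(18.0, 18.0, 18.0)


@pytest.fixture(scope="session")
def _toy_base(cell18):
    """50-atom toy data set at 2.5 A with 5% noise and kappa=1 phases."""
    model = bd.generate_toy_structure(50, cell18, seed=7)
    refl = bd.direct_structure_factors(model, 2.5)
    refl = bd.add_amplitude_noise(refl, 0.05, seed=11)
    phases = bd.simulate_experimental_phases(refl, 1.0, seed=13)
    return refl, phases


@pytest.fixture
def toy_dataset(_toy_base):
    refl, phases = _toy_base
    return refl.copy(), phases.copy()


@pytest.fixture(scope="session")
def paired_ensemble():
    """The paired 20-data-set study ensemble (uncorrected, beta-corrected)."""
    return bd.paired_dm_ensemble(bd.EnsembleConfig(), seed=1)
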