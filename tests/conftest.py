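import numpy as np
import pytest

from aeropk import pbpk
from aeropk.deposition import AirwayTree, discretize_lognormal, diskus_breathing, regional_deposition


@pytest.fixture(scope="session")
def default_params():
    """(DrugParams, LungDispositionParams, SystemicParams) from the bundled config."""
    return pbpk.load_config()


@pytest.fixture(scope="session")
def diskus_deposition():
    """Deposition model run at the reference aerosol and Diskus manoeuvre."""
    aero = discretize_lognormal(1.83, 3.60, 128, particle_density=1.33)
    return regional_deposition(aero, AirwayTree.default(), diskus_breathing())


@pytest.fixture(scope="session")
def validation_run(default_params):
    """Diskus validation PBPK simulation: 600 ug, lung 12.6% / ET 79.2%."""
    drug, lungp, sysp = default_params
    dep = pbpk.diskus_validation_deposition()
    model = pbpk.build_model(dep, 600.0, drug, lungp, sysp)
    profile = pbpk.simulate(model)
    return model, profile, pbpk.pk_descriptors(profile, sysp.plasma_volume)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
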