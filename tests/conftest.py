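import pytest

from hgtkit.model import RoleMap
from hgtkit.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 12-family synthetic dataset with 4 planted transfers."""
    cfg = SimulationConfig(seed=11, n_families=12, n_transfer_families=4)
    return simulate(cfg)


@pytest.fixture()
def roles():
    return RoleMap.from_dict(
        {
            "Shim": "focal",
            "Vvin": "donor_clade",
            "Tpla": "donor_clade",
            "Mesc": "relative_clade",
            "Ptri": "relative_clade",
            "Osat": "outgroup",
        }
    )
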