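import numpy as np
import pytest

from hbquant import synthetic as syn


@pytest.fixture(scope="session")
def dimer_traj():
    """100 ps hydrogen-bonded dimer, R around 3 Å, role switches at 15 and 64 ps."""
    return syn.generate_dimer_trajectory(
        ou=syn.OUParams.from_sd(3.0, 0.15),
        switches=syn.SwitchSchedule((15.0, 64.0)),
        n_steps=200_000,
        dt=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def free_oh_traj():
    """Widely separated pair — the donor hydroxyl behaves as a free O-H."""
    return syn.generate_dimer_trajectory(
        ou=syn.OUParams.from_sd(6.0, 0.05),
        n_steps=2**15,
        dt=0.5,
        seed=3,
    )


@pytest.fixture(scope="session")
def liquid_cfg():
    """200-molecule ring-associated liquid in the reference 39.182 Å cell."""
    return syn.generate_liquid_config(
        n_molecules=200, cell=39.182, first_shell=(2.7, 2.9), seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
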