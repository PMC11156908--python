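import pytest

from picoflux import synthetic as syn


@pytest.fixture(scope="session")
def toy_setups():
    """Name -> (network, fluxes, pools, label) for every bundled oracle toy."""
    return {name: syn.toy_setup(name) for name in syn.TOY_NAMES}


@pytest.fixture(scope="session")
def scn_small():
    return syn.scenario("tg2-small")


@pytest.fixture(scope="session")
def emunet_small(scn_small):
    return scn_small.emu_network()


@pytest.fixture(scope="session")
def scn_tg2():
    return syn.scenario("tg2")


@pytest.fixture(scope="session")
def emunet_tg2(scn_tg2):
    return scn_tg2.emu_network()


@pytest.fixture(scope="session")
def small_measurements(scn_small, emunet_small):
    """One noisy experiment on the minimal scenario (fixed seed)."""
    meas, truth = syn.generate_experiment(
        scn_small, emunet=emunet_small, seed=11, truncate=False
    )
    return meas, truth
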