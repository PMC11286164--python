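import pytest

from loopfbm import default_kukulcania_config


@pytest.fixture(scope="session")
def default_config():
    return default_kukulcania_config()


@pytest.fixture(scope="session")
def default_run():
    """One full default simulation, shared across tests (state-free result)."""
    from loopfbm import build_bundle, simulate

    cfg = default_kukulcania_config()
    bundle = build_bundle(cfg, seed=11)
    return simulate(bundle, x_max=cfg.x_max, dx=cfg.dx, seed=11)
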