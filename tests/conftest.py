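import numpy as np
import pytest

import exocube as xc


@pytest.fixture
def worked_cube() -> xc.Datacube:
    """The fixed two-isolate R2A compatibility fixture."""
    return xc.worked_example_fixture()


@pytest.fixture
def search_cube() -> xc.Datacube:
    """Four compounds, three of which contain the substring 'aden'."""
    cube = xc.Datacube()
    for name in ("adenine", "adenosine", "methyladenosine", "glycine"):
        cube.add_metabolite(xc.MetaboliteRecord(name))
    return cube


@pytest.fixture
def small_cube() -> xc.Datacube:
    """One environment, one organism, three metabolites (plus control rows)."""
    cube = xc.Datacube()
    rows = [
        ("adenine", xc.CONTROL_NAME, xc.ActionCode.DETECTED, None, 0.0),
        ("creatinine", xc.CONTROL_NAME, xc.ActionCode.NOT_DETECTED, None, 0.0),
        ("glycine", xc.CONTROL_NAME, xc.ActionCode.DETECTED, None, 0.0),
        ("adenine", "OrgA", xc.ActionCode.DECREASED, -1.5, 1.5),
        ("creatinine", "OrgA", xc.ActionCode.INCREASED, 2.0, 2.0),
        ("glycine", "OrgA", xc.ActionCode.NO_CHANGE, None, 0.0),
    ]
    for met, org, action, log2fc, conf in rows:
        cube.add_observation(
            xc.Observation(met, org, "R2A", action, log2fc=log2fc, confidence=conf),
            register=True,
        )
    return cube


def random_cube_specs(n: int, seed: int, max_metabolites: int = 200,
                      max_organisms: int = 10, max_environments: int = 3):
    """Seed-deterministic stream of random CubeSpec of bounded size."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield xc.CubeSpec(
            n_metabolites=int(rng.integers(2, max_metabolites + 1)),
            n_organisms=int(rng.integers(2, max_organisms + 1)),
            n_environments=int(rng.integers(1, max_environments + 1)),
            seed=int(rng.integers(0, 2**31)),
        )
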