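import numpy as np
import pytest

from fmkit.synthetic import (ToySystemSpec, make_toy_system,
                             sample_configurations, generate_reference_data)


@pytest.fixture(scope="session")
def butane_system():
    return make_toy_system(ToySystemSpec(template="butane"))


@pytest.fixture(scope="session")
def chain5_system():
    return make_toy_system(ToySystemSpec(template="chain", chain_length=5))


@pytest.fixture(scope="session")
def acetone_system():
    return make_toy_system(ToySystemSpec(template="acetone"))


@pytest.fixture(scope="session")
def chain5_dataset(chain5_system):
    """The standard charge-fit fixture: 5 QM atoms, 50 probes, 20 snapshots,
    zero noise."""
    cfg = sample_configurations(chain5_system, 20, amplitude=0.005, seed=101)
    return generate_reference_data(chain5_system, cfg, seed=102)


@pytest.fixture(scope="session")
def butane_dataset(butane_system):
    cfg = sample_configurations(butane_system, 50, amplitude=0.005, seed=103)
    return generate_reference_data(butane_system, cfg, seed=104)


@pytest.fixture()
def perturbed_butane(butane_system):
    """Butane topology with bonds/angles perturbed away from the truth the
    reference data was generated with (an 'inaccurate starting force
    field'), plus the truth parameters for recovery checks."""
    top = butane_system.topology.copy()
    mol = top.moleculetypes["MOL"]
    truth = {}
    for t in mol.bonds + mol.angles:
        truth[(t.kind, t.atoms)] = list(t.params)
        t.params[0] *= 1.04
        t.params[1] *= 1.25
    return top, truth
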