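import numpy as np
import pytest

from perturbkit import synthdata, tmt


@pytest.fixture(scope="session")
def small_tmt_fit():
    """A small single-fraction TMT simulation with a fitted model, shared
    across tests that only need a representative posterior."""
    psms, designs, truth = synthdata.simulate_tmt_experiment(
        n_proteins=60, seed=101, fractions=("cytosolic",))
    ratios = tmt.psm_log_ratios(psms, designs)
    model = tmt.TmtHierarchicalModel(n_chains=3, n_steps=800,
                                     random_state=101).fit(ratios, designs)
    return psms, designs, truth, ratios, model


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
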