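import numpy as np
import pytest

from icinma.data import ContrastObservation, EvidenceNetwork, Treatment, TrialArm
from icinma.datasets import load_melanoma_network
from icinma.model import (
    McmcConfig,
    ModelSpec,
    PosteriorDraws,
    build_design,
    sample_posterior,
)

# a short schedule for unit tests; accuracy-sensitive tests use longer ones
QUICK = dict(n_chains=2, burn_in=1500, keep=800, thin=2)


@pytest.fixture(scope="session")
def melanoma_net():
    """Analysis-ready melanoma PFS network (dose arms pooled, gp100 aux)."""
    return load_melanoma_network()


@pytest.fixture(scope="session")
def paper_fixed_fit(melanoma_net):
    """Fixed-effect fit at the primary MCMC schedule (3 chains, 10,000-draw
    burn-in, 10,000 retained per chain at thinning 50).  Shared across the
    league-table, consistency and convergence checks."""
    spec = ModelSpec()
    config = McmcConfig(seed=20170701)
    return sample_posterior(melanoma_net, spec, config)


def two_node_network(y=np.log(0.5), se=0.2, outcome="PFS"):
    treatments = {"A": Treatment("A", "A"), "B": Treatment("B", "B")}
    arms = [TrialArm("t1", "A", 100), TrialArm("t1", "B", 100)]
    contrasts = [ContrastObservation("t1", "A", "B", outcome, float(y), float(se))]
    return EvidenceNetwork(treatments, arms, contrasts).validate()


def fake_draws(basic_matrix, names=None, reference="A"):
    """PosteriorDraws with prescribed basic-parameter draws, for ranking and
    league-table unit tests.  ``basic_matrix`` is (n_draws, n_basic)."""
    basic_matrix = np.asarray(basic_matrix, dtype=float)
    n_basic = basic_matrix.shape[1]
    if names is None:
        names = [chr(ord("B") + i) for i in range(n_basic)]
    treatments = {reference: Treatment(reference, reference)}
    arms = [TrialArm("t1", reference, 50)]
    contrasts = []
    for t in names:
        treatments[t] = Treatment(t, t)
        arms.append(TrialArm("t1", t, 50))
        contrasts.append(
            ContrastObservation("t1", reference, t, "PFS", 0.0, 1.0)
        )
    net = EvidenceNetwork(treatments, arms, contrasts).validate()
    spec = ModelSpec(reference=reference)
    design = build_design(net, spec)
    # two pseudo-chains so the container shape is well-formed
    half = basic_matrix.shape[0] // 2
    if half * 2 != basic_matrix.shape[0]:
        basic_matrix = basic_matrix[: 2 * half]
    samples = basic_matrix.reshape(half, 2, n_basic)
    return PosteriorDraws(
        samples=samples,
        param_names=list(design.param_names),
        design=design,
        config=McmcConfig(n_chains=2, burn_in=1, keep=max(half, 500), thin=1),
    )
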