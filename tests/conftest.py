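import warnings

import numpy as np
import pytest

import armnma as am
from armnma.network_data import BinaryArm, ContinuousArm, NetworkDataset, Treatment

warnings.filterwarnings("ignore", message="ArviZ is undergoing")


def make_binary_ds(rows, reference="A", outcome="toy", direction="harm"):
    """rows: (study, treatment, events, total)."""
    arms = [BinaryArm(s, t, e, n) for s, t, e, n in rows]
    treats = sorted({t for _, t, _, _ in rows})
    treats.remove(reference)
    ts = [Treatment(reference, reference=True)] + [Treatment(t) for t in treats]
    return NetworkDataset(outcome, "binary", direction, ts, arms)


def make_continuous_ds(rows, reference="A", outcome="toy", direction="harm"):
    """rows: (study, treatment, n, mean, sd)."""
    arms = [ContinuousArm(s, t, n, m, sd) for s, t, n, m, sd in rows]
    treats = sorted({t for _, t, _, _, _ in rows})
    treats.remove(reference)
    ts = [Treatment(reference, reference=True)] + [Treatment(t) for t in treats]
    return NetworkDataset(outcome, "continuous", direction, ts, arms)


@pytest.fixture(scope="session")
def toy2x2():
    """Two studies, two treatments, binary outcome."""
    return make_binary_ds([
        ("s1", "A", 12, 100), ("s1", "B", 20, 100),
        ("s2", "A", 8, 120), ("s2", "B", 15, 110),
    ])


@pytest.fixture(scope="session")
def sim_ds():
    """Simulated 10-trial, 4-treatment network with known non-null truth."""
    truth = am.trial_network_truth(seed=3, d_true=(0.3, 0.1, -0.2), tau_true=0.1)
    return am.simulate_network(truth)


@pytest.fixture(scope="session")
def sim_draws(sim_ds):
    """Short but usable posterior fit of the simulated network (shared)."""
    cfg = am.SamplerConfig(iterations=4000, burn_in=1500, thin=2, chains=3, seed=11)
    return am.run_mcmc(sim_ds, cfg=cfg)


@pytest.fixture(scope="session")
def cont_ds():
    rng = np.random.default_rng(42)
    rows = []
    for i, (ta, tb) in enumerate([("A", "B"), ("A", "B"), ("A", "C")]):
        base = 100 + 10 * rng.standard_normal()
        rows.append((f"s{i}", ta, 80, base, 15.0))
        rows.append((f"s{i}", tb, 80, base + 5 + rng.standard_normal(), 15.0))
    return make_continuous_ds(rows, outcome="minutes")


@pytest.fixture(scope="session")
def cont_draws(cont_ds):
    cfg = am.SamplerConfig(iterations=3000, burn_in=1000, thin=2, chains=2, seed=21)
    return am.run_mcmc(cont_ds, cfg=cfg)
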