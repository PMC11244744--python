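"""Shared fixtures: small simulated cohorts and a fast fitted model."""

from __future__ import annotations

import numpy as np
import pytest

from abimbalance.curves import HyperbolaParams
from abimbalance.model import HyperbolicImbalanceModel
from abimbalance.simulate import SimulationConfig, simulate_cohort, simulate_longitudinal

#: discovery-scale truth curve (CSF in pg/mL, PET in Centiloid)
DISCOVERY_CURVE = HyperbolaParams("rational", 3673.1, -2924.9, -0.3, (0.0, 180.0))


@pytest.fixture(scope="session")
def small_sim():
    """Simulated cohort of 150 subjects plus ground truth and visits."""
    cfg = SimulationConfig(n=150, seed=7)
    cohort, truth = simulate_cohort(cfg)
    visits = simulate_longitudinal(cohort, truth, cfg)
    return cfg, cohort, truth, visits


@pytest.fixture(scope="session")
def fitted_small(small_sim):
    """A quickly fitted imbalance model on the small cohort."""
    _, cohort, _, _ = small_sim
    pts = cohort[["centiloid", "csf_ab42"]].to_numpy()
    est = HyperbolicImbalanceModel(
        scaling="zscore", n_restarts=2, maxfev=500
    ).fit(pts)
    return est, pts


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)


def bh_step_up_oracle(p):
    """Independent Benjamini-Hochberg enumeration: adjusted p for the k-th
    smallest value is min over j >= k of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        running = min(running, p[order[k]] * m / (k + 1))
        adj[order[k]] = running
    return adj
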