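"""Shared fixtures.

The two replicated simulation studies (CI coverage on the linear
benchmark; finite-J bias and its correction on the curved scenario) are
session-scoped so every test that interrogates them shares one run.
"""

import logging

import numpy as np
import pandas as pd
import pytest

import coarsecause as cc
from coarsecause.bias_correction import bias_corrected_estimate
from coarsecause.synthetic import SCENARIOS, generate

logging.getLogger("coarsecause").setLevel(logging.ERROR)


@pytest.fixture
def toy_dataset():
    """Two strata of four units each with hand-computable arm means.

    Stratum 1: treated Y = {3, 5}, control Y = {1, 3};
    stratum 2: treated Y = {8, 6}, control Y = {5, 3}.
    Stratified ATE = 0.5*(4-2) + 0.5*(7-4) = 2.5 with SE exactly 1.
    """
    y = np.array([3, 5, 1, 3, 8, 6, 5, 3], dtype=float)
    t = np.array([1, 1, 0, 0, 1, 1, 0, 0])
    x = pd.DataFrame({"x": [0, 0, 0, 0, 1, 1, 1, 1]})
    labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
    dataset = cc.Dataset(y=y, t=t, x=x)
    assignment = cc.StrataAssignment(labels=labels, method="manual")
    return dataset, assignment


def random_stratified_dataset(rng, min_strata=2, max_strata=6):
    """A random dataset plus an assignment where every stratum has both arms."""
    j = rng.integers(min_strata, max_strata + 1)
    sizes = rng.integers(4, 15, size=j)
    labels, t = [], []
    for s, size in enumerate(sizes, start=1):
        n1 = rng.integers(1, size)
        labels += [s] * size
        t += [1] * n1 + [0] * (size - n1)
    labels, t = np.array(labels), np.array(t)
    n = len(labels)
    y = rng.normal(size=n) * rng.uniform(0.5, 3) + rng.normal() * labels
    x = pd.DataFrame({"x": rng.normal(size=n)})
    return cc.Dataset(y=y, t=t, x=x), cc.StrataAssignment(labels=labels, method="manual")


@pytest.fixture(scope="session")
def linear_coverage_report():
    """Linear benchmark, k-means K=50, n=2000, 500 replicates, seed 0."""
    return cc.simulate_performance(
        "linear", "kmeans", n=2000, n_reps=500, seed=0, k=50
    )


@pytest.fixture(scope="session")
def curved_bias_study():
    """Curved-outcome scenario: 200 replicates of the default-grid
    bias correction at n=2000, recording the smallest-J (J=5) estimate
    and the extrapolated estimate per replicate. Master seed 0."""
    truth = SCENARIOS["curved"]
    tau = truth.true_ate()
    reps = 200
    seeds = np.random.SeedSequence(0).generate_state(2 * reps) % (2**31)
    naive_err, corrected_err = [], []
    for r in range(reps):
        data = generate(truth, n=2000, seed=int(seeds[2 * r]))
        config = cc.RunConfig(method="kmeans", seed=int(seeds[2 * r + 1]))
        result = bias_corrected_estimate(data, "kmeans", config)
        smallest = result.grid.sort_values("J_used").iloc[0]
        naive_err.append(float(smallest["tau_J"]) - tau)
        corrected_err.append(result.tau_corrected - tau)
    return {
        "true_ate": tau,
        "naive_err": np.asarray(naive_err),
        "corrected_err": np.asarray(corrected_err),
    }
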