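"""Shared fixtures: synthetic cohorts and pipeline runs reused across tests."""

import logging

import numpy as np
import pandas as pd
import pytest

import ikcscore as ik

logging.getLogger("ikcscore").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config():
    return ik.SimulationConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """The default simulated cohort (seed 42): (expression, clinical, truth)."""
    return ik.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def default_library(default_config, default_cohort):
    _, _, truth = default_cohort
    return ik.simulate_signature_library(default_config, truth)


@pytest.fixture(scope="session")
def derive_result(default_cohort, default_library):
    """Full derivation pipeline run on the default cohort."""
    expr, clinical, _ = default_cohort
    return ik.derive_signatures(expr, clinical, default_library, ik.PipelineConfig(seed=42))


@pytest.fixture
def toy_expression():
    """4-gene x 3-sample normalized matrix with known ordering."""
    data = pd.DataFrame(
        {"s1": [5.0, 4.0, 2.0, 1.0], "s2": [1.0, 2.0, 4.0, 5.0], "s3": [3.0, 3.0, 3.0, 3.0]},
        index=pd.Index(["A", "B", "C", "D"], name="gene"),
    )
    return ik.ExpressionMatrix(data, "normalized")


@pytest.fixture
def clinical_rnr():
    """Minimal clinical table: 3 responders, 3 non-responders."""
    df = pd.DataFrame(
        {"response": ["PR", "CR", "PR", "SD", "PD", "SD"]},
        index=pd.Index([f"s{i}" for i in range(1, 7)], name="sample_id"),
    )
    return ik.core_io.make_clinical(df)


def brute_force_es(rank_by_gene: dict, members: set, alpha: float) -> float:
    """Independent ssGSEA running-sum oracle: explicit position-by-position walk.

    ``rank_by_gene`` maps gene symbol -> rank; walk order is decreasing rank,
    ties broken by ascending symbol.
    """
    genes = sorted(rank_by_gene, key=lambda g: (-rank_by_gene[g], g))
    n = len(genes)
    m = sum(1 for g in genes if g in members)
    assert 0 < m < n
    denom = sum(rank_by_gene[g] ** alpha for g in genes if g in members)
    es = 0.0
    p_in = 0.0
    p_out = 0.0
    for g in genes:
        if g in members:
            p_in += rank_by_gene[g] ** alpha / denom
        else:
            p_out += 1.0 / (n - m)
        es += p_in - p_out
    return es


def efron_partial_loglik(beta: float, times, events, x) -> float:
    """Efron-tie partial log-likelihood for a single covariate (oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    theta = np.exp(beta * x)
    loglik = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        at_risk = times >= t
        d = dead.sum()
        sum_risk = theta[at_risk].sum()
        sum_tie = theta[dead].sum()
        loglik += beta * x[dead].sum()
        for j in range(d):
            loglik -= np.log(sum_risk - j / d * sum_tie)
    return loglik
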