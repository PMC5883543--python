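"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library code paths they check: the
log-rank oracle builds the 2x2 table at every event time directly, the
enrichment oracle enumerates the hypergeometric pmf with exact integer
combinatorics, and the Cox oracle maximizes the Efron partial likelihood on
a dense beta grid.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import gbmsig as G


# ---------------------------------------------------------------------------
# oracles


def logrank_oracle(time, event, group) -> float:
    """Chi-square of the two-group log-rank test from per-event-time 2x2
    tables: (O_A - E_A)^2 / V with the hypergeometric variance."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = np.unique(g)
    assert len(levels) == 2
    a = g == levels[0]
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n_i = at_risk.sum()
        n_a = (at_risk & a).sum()
        d_i = ((t == ti) & (e == 1)).sum()
        d_a = ((t == ti) & (e == 1) & a).sum()
        o_minus_e += d_a - d_i * n_a / n_i
        if n_i > 1:
            var += d_i * (n_a / n_i) * (1 - n_a / n_i) * (n_i - d_i) / (n_i - 1)
    if var == 0.0:
        return float("nan")  # statistic undefined; callers skip these
    return o_minus_e**2 / var


def hypergeom_tail_oracle(n_bg: int, n_set: int, n_query: int, k: int) -> float:
    """P(X >= k) for X ~ hypergeometric, by exact integer enumeration."""
    total = math.comb(n_bg, n_query)
    hits = 0
    for x in range(k, min(n_set, n_query) + 1):
        if n_query - x <= n_bg - n_set:
            hits += math.comb(n_set, x) * math.comb(n_bg - n_set, n_query - x)
    return hits / total


def efron_log_partial_likelihood(beta: float, x, time, event) -> float:
    """Efron-tie-corrected Cox log partial likelihood for one covariate."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    theta = np.exp(beta * x)
    lpl = 0.0
    for ti in np.unique(t[e == 1]):
        dead = (t == ti) & (e == 1)
        risk = t >= ti
        d = int(dead.sum())
        s_risk = theta[risk].sum()
        s_dead = theta[dead].sum()
        lpl += beta * x[dead].sum()
        for l in range(d):
            lpl -= math.log(s_risk - (l / d) * s_dead)
    return lpl


def cox_grid_oracle(x, time, event, lo=-3.0, hi=3.0, step=0.001) -> float:
    """argmax over a dense beta grid of the Efron partial likelihood."""
    grid = np.arange(lo, hi + step / 2, step)
    vals = [efron_log_partial_likelihood(b, x, time, event) for b in grid]
    return float(grid[int(np.argmax(vals))])


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted-signal cohort shared by read-mostly tests."""
    cfg = G.SimulationConfig(
        n_samples=200, n_genes=300, n_signature_genes=10, effect_size=2.0,
        censoring_rate=0.2, n_gene_sets=8, set_size=20, seed=101)
    return G.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def two_class_strong():
    """Strongly separated two-class matrix (3-SD shifts on 20 of 300 genes)."""
    return G.simulate_two_class(40, 300, 20, 3.0, seed=42)


def random_survival_cohort(rng, n_max=12):
    """Small random right-censored cohort with ties, for oracle sweeps."""
    n = rng.integers(4, n_max + 1)
    t = rng.integers(1, 7, size=n).astype(float)
    e = rng.integers(0, 2, size=n)
    g = rng.integers(0, 2, size=n)
    return t, e, g
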