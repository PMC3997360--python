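"""Shared fixtures and independent oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from pbmcnet.model import ModuleNetworkModel
from pbmcnet.panel import default_panel
from pbmcnet.qpcr import quantify
from pbmcnet.simulate import (
    default_control_spec,
    default_hypertensive_spec,
    generate_cohort,
)

# ---------------------------------------------------------------- oracles


def brute_force_maximal_cliques(nodes, adj):
    """All maximal cliques by exhaustive subset enumeration (<= ~12 nodes)."""
    nodes = list(nodes)
    n = len(nodes)
    cliques = []
    for mask in range(1, 1 << n):
        members = [nodes[i] for i in range(n) if mask >> i & 1]
        if all(b in adj[a] for a, b in combinations(members, 2)):
            cliques.append(frozenset(members))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return sorted(set(maximal), key=lambda s: (-len(s), tuple(sorted(s))))


def pearson_sum_formula(x, y):
    """Pearson r from the raw-sum formula (independent of numpy.corrcoef)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x * x).sum() - sx * sx) * np.sqrt(n * (y * y).sum() - sy * sy)
    return num / den


def random_graph(rng, n, p):
    """Random adjacency-set graph over string node names."""
    nodes = [f"g{i}" for i in range(n)]
    adj = {v: set() for v in nodes}
    for a, b in combinations(nodes, 2):
        if rng.random() < p:
            adj[a].add(b)
            adj[b].add(a)
    return nodes, adj


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def control_cohort():
    return generate_cohort(default_control_spec(seed=0))


@pytest.fixture(scope="session")
def control_rcn(control_cohort):
    cq, _ = control_cohort
    return quantify(cq)


@pytest.fixture(scope="session")
def control_fit(control_cohort):
    cq, ph = control_cohort
    return ModuleNetworkModel.from_cq(cq, phenotypes=ph).fit()


@pytest.fixture(scope="session")
def ht_cohort():
    return generate_cohort(default_hypertensive_spec(seed=1))


@pytest.fixture(scope="session")
def ht_rcn(ht_cohort):
    cq, _ = ht_cohort
    return quantify(cq)


@pytest.fixture(scope="session")
def ht_fit(ht_cohort):
    cq, _ = ht_cohort
    return ModuleNetworkModel.from_cq(cq).fit()
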