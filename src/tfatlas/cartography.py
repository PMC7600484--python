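"""Functional cartography: within-module degree z and participation p.

Following the standard cartographic characterization of complex networks,
each node *i* with module assignment s_i gets

* a within-module degree z-score
  ``z_i = (kappa_i - mean(kappa | s_i)) / sd(kappa | s_i)``
  where ``kappa_i`` counts links from *i* to nodes of its own module and the
  standard deviation is the population sd over the module (z_i = 0 when the
  module's kappa values are constant), and
* a participation coefficient ``p_i = 1 - sum_s (k_is / k_i)^2`` where
  ``k_is`` counts links from *i* into module *s* and ``k_i`` is the total
  degree; p is 0 when all links stay in one module and at most 1 - 1/N_M.

Nodes are then binned into eight roles: (1) no experimental interactions;
non-hubs, z < 2.5: (2) ultra-peripheral p < 0.05, (3) peripheral
0.05 <= p < 0.625, (4) non-hub connector 0.625 <= p < 0.8, (5) non-hub
kinless p >= 0.8; hubs, z >= 2.5: (6) provincial p < 0.3, (7) connector
0.3 <= p < 0.75, (8) kinless p >= 0.75.  (Requiring z >= 2.5 for role 8
makes hub and non-hub roles a clean partition.)

Module detection is greedy modularity maximization — deterministic for a
given graph — and a precomputed assignment can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "detect_modules",
    "within_module_degree_z",
    "participation_coefficient",
    "classify_roles",
    "cartography",
    "ROLE_NAMES",
]

ROLE_NAMES = {
    1: "no_interactions",
    2: "ultra_peripheral",
    3: "peripheral",
    4: "non_hub_connector",
    5: "non_hub_kinless",
    6: "provincial_hub",
    7: "connector_hub",
    8: "kinless_hub",
}


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Assign modules by greedy modularity maximization.

    Returns ``node -> module`` with contiguous integer labels, largest
    module first (ties broken by smallest member).  The greedy
    agglomeration is deterministic; ``seed`` is accepted for interface
    stability with stochastic optimizers.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("network is empty")
    del seed  # greedy agglomeration has no stochastic component
    if graph.number_of_edges() == 0:
        return {n: 0 for n in graph.nodes}
    comms = nx.algorithms.community.greedy_modularity_communities(graph)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    return {node: i for i, comm in enumerate(comms) for node in comm}


def _check_assignment(graph: nx.Graph, assignment: dict) -> None:
    missing = [n for n in graph.nodes if n not in assignment]
    if missing:
        raise ValueError(
            f"module assignment misses {len(missing)} node(s), e.g. {missing[:3]}"
        )


def within_module_degree_z(graph: nx.Graph, assignment: dict) -> pd.Series:
    """Within-module degree z-score per node.

    kappa_i is the number of links between node i and other members of its
    module; z standardizes kappa against its module's population mean and
    sd.  Modules with constant kappa (sd = 0) give z = 0 for all members.
    """
    _check_assignment(graph, assignment)
    kappa = {
        n: sum(1 for nb in graph.neighbors(n) if assignment[nb] == assignment[n])
        for n in graph.nodes
    }
    z = {}
    by_module: dict = {}
    for n, k in kappa.items():
        by_module.setdefault(assignment[n], []).append(k)
    stats = {
        m: (float(np.mean(v)), float(np.std(v)))  # population sd
        for m, v in by_module.items()
    }
    for n, k in kappa.items():
        mean, sd = stats[assignment[n]]
        z[n] = (k - mean) / sd if sd > 0 else 0.0
    return pd.Series(z, name="z")


def participation_coefficient(graph: nx.Graph, assignment: dict) -> pd.Series:
    """Participation coefficient p_i = 1 - sum_s (k_is / k_i)^2 per node.

    Degree-0 nodes have no defined participation; they get NaN.
    """
    _check_assignment(graph, assignment)
    p = {}
    for n in graph.nodes:
        k = graph.degree(n)
        if k == 0:
            p[n] = float("nan")
            continue
        per_module: dict = {}
        for nb in graph.neighbors(n):
            m = assignment[nb]
            per_module[m] = per_module.get(m, 0) + 1
        p[n] = 1.0 - sum((kis / k) ** 2 for kis in per_module.values())
    return pd.Series(p, name="p")


def classify_roles(z: pd.Series, p: pd.Series) -> pd.Series:
    """Role class 1-8 from (z, p); NaN participation means no interactions.

    Boundaries are lower-bound inclusive; hubs require z >= 2.5 in every
    hub role including kinless hubs.
    """
    z, p = z.align(p)
    roles = pd.Series(0, index=z.index, dtype=int, name="role")
    none = p.isna()
    roles[none] = 1
    hub = ~none & (z >= 2.5)
    nonhub = ~none & (z < 2.5)
    roles[nonhub & (p < 0.05)] = 2
    roles[nonhub & (p >= 0.05) & (p < 0.625)] = 3
    roles[nonhub & (p >= 0.625) & (p < 0.8)] = 4
    roles[nonhub & (p >= 0.8)] = 5
    roles[hub & (p < 0.3)] = 6
    roles[hub & (p >= 0.3) & (p < 0.75)] = 7
    roles[hub & (p >= 0.75)] = 8
    return roles


@dataclass
class CartographyResult:
    """Per-node module, z, p and role, plus the module count."""

    table: pd.DataFrame
    n_modules: int


def cartography(
    graph: nx.Graph,
    assignment: dict | None = None,
    seed: int = 0,
) -> CartographyResult:
    """Full cartography: modules (unless supplied), z, p and role per node."""
    if assignment is None:
        assignment = detect_modules(graph, seed=seed)
    else:
        _check_assignment(graph, assignment)
    z = within_module_degree_z(graph, assignment)
    p = participation_coefficient(graph, assignment)
    roles = classify_roles(z, p)
    table = pd.DataFrame(
        {
            "module": pd.Series(assignment),
            "degree": pd.Series(dict(graph.degree())),
            "z": z,
            "p": p,
            "role": roles,
            "role_name": roles.map(ROLE_NAMES),
        }
    ).loc[list(graph.nodes)]
    table.index.name = "node"
    return CartographyResult(table=table, n_modules=len(set(assignment.values())))
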