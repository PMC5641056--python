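"""Pathway Flux scoring of dosage-correlation values on an interaction network.

Per-gene CNV–mRNA correlations are first pivoted at the CR-high cutoff
(f(x) = x − 0.4, so dosage-coupled genes become positive) and then
exponentiated (f(x) = 2^x) to give strictly positive walk-bias values
centered around 1. A random walk with restart, biased toward high-value
nodes both in its transitions and its restart distribution, yields a
stationary distribution π over genes; the flux through an edge is the
stationary probability of traversing it in either direction. A pathway's
flux score sums the flux over its member nodes and internal edges, so
pathways enriched for CR-high genes score high and those enriched for
CR-low genes score low. Significance comes from a permutation null that
relabels pathway membership within node-degree bins, which controls for
hub effects.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "PathwayFluxResult",
    "read_edge_list",
    "read_gmt",
    "transform_cr_values",
    "stationary_flux",
    "pathway_flux",
]

RESTART_DEFAULT = 0.05
TOL_DEFAULT = 1e-10
MAX_POWER_ITER = 100_000
DEGREE_BIN_EXACT_MAX = 10
MIN_PATHWAY_GENES = 3


@dataclass
class InteractionNetwork:
    """Undirected weighted gene interaction network (no self-loops)."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network contains self-loops: {loops[:3]}")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @classmethod
    def from_edges(
        cls, edges: list[tuple] | pd.DataFrame
    ) -> "InteractionNetwork":
        g = nx.Graph()
        if isinstance(edges, pd.DataFrame):
            edges = list(edges.itertuples(index=False, name=None))
        for e in edges:
            a, b = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            if w < 0:
                raise ValueError("edge weights must be non-negative")
            g.add_edge(a, b, weight=w)
        return cls(g)


@dataclass
class PathwayFluxResult:
    """Flux score of one pathway against its degree-matched permutation null."""

    pathway: str
    members: list
    n_members_in_network: int
    flux_score: float
    null_mean: float
    null_sd: float
    z: float


def read_edge_list(path: str | Path) -> InteractionNetwork:
    """Build a network from a 2- or 3-column (geneA, geneB[, weight]) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] not in (2, 3):
        raise ValueError("edge list must have 2 or 3 columns")
    return InteractionNetwork.from_edges(df)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def transform_cr_values(
    r_values: pd.Series, pivot: float = 0.4
) -> pd.Series:
    """Map correlations in [−1, 1] to positive walk-bias values 2^(r − pivot).

    Genes at the pivot map to 1; CR-high genes (r > pivot) map above 1 and
    CR-low genes below 1. Values outside [−1, 1] or non-finite are rejected.
    """
    r = pd.Series(r_values).astype(float)
    if not np.isfinite(r.to_numpy()).all():
        raise ValueError("correlation values must be finite")
    if (r < -1.0).any() or (r > 1.0).any():
        raise ValueError("correlation values must lie in [-1, 1]")
    return np.exp2(r - pivot)


def _walk_component(
    graph: nx.Graph, nodes: list, values: np.ndarray, restart: float, tol: float
) -> tuple[np.ndarray, dict[tuple, float]]:
    """Stationary distribution and edge flux on one connected component."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", format="csr")
    # transition i→j proportional to edge weight times target value
    biased = adj.multiply(values[None, :]).tocsr()
    row_sum = np.asarray(biased.sum(axis=1)).ravel()
    row_sum[row_sum == 0.0] = 1.0  # isolated nodes: no outflow, restart only
    p = biased.multiply(1.0 / row_sum[:, None]).tocsr()

    v_bar = values / values.sum()
    pi = v_bar.copy()
    pt = p.T.tocsr()
    for _ in range(MAX_POWER_ITER):
        new = (1.0 - restart) * (pt @ pi) + restart * v_bar
        # isolated-node outflow mass is redistributed through the restart
        new /= new.sum()
        if np.abs(new - pi).sum() < tol:
            pi = new
            break
        pi = new
    else:
        raise RuntimeError("power iteration did not converge")

    edge_flux: dict[tuple, float] = {}
    for a, b in graph.edges(nodes):
        i, j = idx[a], idx[b]
        flux = pi[i] * p[i, j] + pi[j] * p[j, i]
        edge_flux[(a, b)] = float(flux)
    return pi, edge_flux


def stationary_flux(
    network: InteractionNetwork,
    values: pd.Series,
    restart: float = RESTART_DEFAULT,
    tol: float = TOL_DEFAULT,
) -> tuple[pd.Series, dict[tuple, float]]:
    """Biased random walk with restart: node flux π and symmetric edge flux.

    Transition probability from i to j is proportional to
    weight(i, j)·value(j); the restart distribution is proportional to the
    node values. Nodes missing from ``values`` get the neutral bias 1.
    Disconnected networks are walked per component, with each component's
    π scaled by its share of the total node-value mass, so the global π
    still sums to 1. Edge flux is π(i)·P(i→j) + π(j)·P(j→i).
    """
    if not (0.0 < restart < 1.0):
        raise ValueError("restart must lie in (0, 1)")
    nodes = network.nodes
    vals = pd.Series(1.0, index=pd.Index(nodes))
    present = values.index.intersection(vals.index)
    vals.loc[present] = values.loc[present].astype(float)
    if (vals <= 0).any():
        raise ValueError("walk-bias values must be positive")

    total_mass = float(vals.sum())
    node_flux = pd.Series(0.0, index=vals.index)
    edge_flux: dict[tuple, float] = {}
    for comp in network.components:
        comp_nodes = [v for v in nodes if v in comp]
        sub = network.graph.subgraph(comp_nodes)
        comp_vals = vals.loc[comp_nodes].to_numpy()
        pi, ef = _walk_component(sub, comp_nodes, comp_vals, restart, tol)
        weight = comp_vals.sum() / total_mass
        node_flux.loc[comp_nodes] = pi * weight
        edge_flux.update({k: v * weight for k, v in ef.items()})
    return node_flux, edge_flux


def _degree_bins(degrees: dict) -> dict:
    """Node → bin id: exact degree up to 10, logarithmic (base 2) above."""
    bins: dict = {}
    for node, deg in degrees.items():
        if deg <= DEGREE_BIN_EXACT_MAX:
            bins[node] = deg
        else:
            bins[node] = DEGREE_BIN_EXACT_MAX + 1 + int(
                math.log2(deg / DEGREE_BIN_EXACT_MAX)
            )
    return bins


def _pathway_score(
    member_mask: np.ndarray,
    node_flux_arr: np.ndarray,
    edge_u: np.ndarray,
    edge_v: np.ndarray,
    edge_f: np.ndarray,
) -> float:
    internal = member_mask[edge_u] & member_mask[edge_v]
    return float(node_flux_arr[member_mask].sum() + edge_f[internal].sum())


def pathway_flux(
    node_flux: pd.Series,
    edge_flux: dict[tuple, float],
    pathways: dict[str, list],
    n_permutations: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> list[PathwayFluxResult]:
    """Score pathways by summed member/edge flux against a permutation null.

    The flux score of a pathway is the sum of node flux over its members
    plus edge flux over edges internal to it. The null redraws which nodes
    are members by permuting node labels within degree bins (preserving
    the pathway's per-bin membership counts); ``exhaustive=True``
    enumerates every distinct degree-matched member set instead of
    sampling. Pathways with fewer than 3 members in the network are
    skipped; z is 0 when the null is invariant (sd = 0 and score equals
    the null mean).
    """
    nodes = list(node_flux.index)
    idx = {v: i for i, v in enumerate(nodes)}
    nf = node_flux.to_numpy(float)
    edge_u = np.array([idx[a] for a, _ in edge_flux], dtype=int)
    edge_v = np.array([idx[b] for _, b in edge_flux], dtype=int)
    edge_f = np.array(list(edge_flux.values()), dtype=float)

    degrees: dict = {v: 0 for v in nodes}
    for a, b in edge_flux:
        degrees[a] += 1
        degrees[b] += 1
    bins = _degree_bins(degrees)
    bin_members: dict = {}
    for v, b in bins.items():
        bin_members.setdefault(b, []).append(idx[v])

    rng = np.random.default_rng(seed)
    results: list[PathwayFluxResult] = []
    for name, members in pathways.items():
        present = [g for g in members if g in idx]
        if len(present) < MIN_PATHWAY_GENES:
            continue
        member_idx = np.array([idx[g] for g in present], dtype=int)
        mask = np.zeros(len(nodes), dtype=bool)
        mask[member_idx] = True
        score = _pathway_score(mask, nf, edge_u, edge_v, edge_f)

        # per-bin membership counts to preserve under permutation
        counts = {}
        for g in present:
            counts[bins[g]] = counts.get(bins[g], 0) + 1

        null_scores = []
        if exhaustive:
            choices_per_bin = [
                [list(c) for c in itertools.combinations(bin_members[b], k)]
                for b, k in sorted(counts.items())
            ]
            for combo in itertools.product(*choices_per_bin):
                m = np.zeros(len(nodes), dtype=bool)
                for part in combo:
                    m[part] = True
                null_scores.append(
                    _pathway_score(m, nf, edge_u, edge_v, edge_f)
                )
        else:
            for _ in range(n_permutations):
                m = np.zeros(len(nodes), dtype=bool)
                for b, k in counts.items():
                    pick = rng.choice(bin_members[b], size=k, replace=False)
                    m[pick] = True
                null_scores.append(
                    _pathway_score(m, nf, edge_u, edge_v, edge_f)
                )
        null_arr = np.array(null_scores)
        mean, sd = float(null_arr.mean()), float(null_arr.std(ddof=0))
        if sd > 0:
            z = (score - mean) / sd
        else:
            z = 0.0 if np.isclose(score, mean) else float("nan")
        results.append(
            PathwayFluxResult(name, present, len(present), score, mean, sd, float(z))
        )
    return results
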