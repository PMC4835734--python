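"""Edge-list I/O and structural covariates.

Real contact networks arrive as whitespace-separated edge lists; they are read
as simple undirected graphs (direction and weights discarded), reduced to the
giant connected component, and summarized by the covariates used to stratify
predictor error: degree moments, assortativity r, clustering c, modularity Q,
and the maximum k-core index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "Network",
    "DegreeStats",
    "StructureMetrics",
    "UndefinedMetricError",
    "read_edge_list",
    "giant_component",
    "degree_stats",
    "assortativity",
    "clustering",
    "transitivity",
    "modularity",
    "max_kcore",
    "structure_metrics",
    "metrics_row",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no value on the given graph (e.g. r on a
    regular graph, where the endpoint degree variance is zero)."""


@dataclass(frozen=True)
class DegreeStats:
    """First two degree moments plus the degree range."""

    mean_k: float
    mean_k2: float
    k_min: int
    k_max: int

    @property
    def kappa(self) -> float:
        """The moment ratio ⟨k²⟩/⟨k⟩ (the k-core localization proxy)."""
        return self.mean_k2 / self.mean_k


@dataclass(frozen=True)
class StructureMetrics:
    r: Optional[float]  # None when undefined (zero endpoint-degree variance)
    c: float
    Q: float
    kcore_max: int
    transitivity: float
    modularity_algorithm: str = "greedy_cnm"
    modularity_seed: int = 0


def read_edge_list(path) -> Network:
    """Parse a whitespace-separated edge list into a simple undirected graph.

    Tokens beyond the first two on a line (weights, timestamps) are ignored;
    duplicate and reversed-duplicate edges collapse; self-loops are dropped.
    Arbitrary string labels are mapped to 0..N-1 in order of first appearance,
    with the mapping kept on ``Network.labels``.
    """
    seen: dict[str, None] = {}
    raw_pairs: list[tuple[str, str]] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            n_lines += 1
            u, v = tokens[0], tokens[1]
            seen.setdefault(u)
            seen.setdefault(v)
            if u != v:
                raw_pairs.append((u, v))
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    # integer-labeled files keep numeric order; others first-appearance order
    int_like = all(tok.lstrip("-").isdigit() for tok in seen)
    order = sorted(seen, key=int) if int_like else list(seen)
    index = {tok: i for i, tok in enumerate(order)}
    pairs = [(index[u], index[v]) for u, v in raw_pairs]
    canonical = int_like and order == [str(i) for i in range(len(order))]
    return Network(len(order), pairs,
                   labels=None if canonical else order)


def giant_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component, relabeled 0..N'-1.

    Size ties break toward the component containing the smallest original
    node label.  Node order inside the component follows original labels, so
    the operation is deterministic.
    """
    g = net.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    keep = comps[0]
    index = {u: i for i, u in enumerate(keep)}
    edges = [(index[u], index[v]) for u, v in net.edges
             if u in index and v in index]
    labels = None
    if net.labels is not None:
        labels = [net.labels[u] for u in keep]
    elif keep != list(range(len(keep))):
        labels = keep
    return Network(len(keep), edges, labels=labels)


def degree_stats(net: Network) -> DegreeStats:
    d = net.degrees.astype(float)
    return DegreeStats(
        mean_k=float(d.mean()),
        mean_k2=float((d**2).mean()),
        k_min=int(net.degrees.min()),
        k_max=int(net.degrees.max()),
    )


def assortativity(net: Network) -> float:
    """Pearson correlation of degrees across edge endpoints (Newman's r).

    Each undirected edge contributes both orientations.  Raises
    ``UndefinedMetricError`` when the endpoint degree variance vanishes.
    """
    if net.n_edges < 2:
        raise UndefinedMetricError("assortativity needs at least 2 edges")
    d = net.degrees.astype(float)
    x = np.concatenate([d[net.edges[:, 0]], d[net.edges[:, 1]]])
    y = np.concatenate([d[net.edges[:, 1]], d[net.edges[:, 0]]])
    mu = x.mean()
    var = np.mean(x**2) - mu**2
    if var <= 1e-12 * max(1.0, mu**2):
        raise UndefinedMetricError(
            "assortativity undefined: zero degree variance at edge endpoints"
        )
    return float((np.mean(x * y) - mu**2) / var)


def clustering(net: Network) -> float:
    """Mean local (Watts-Strogatz) clustering; degree-<2 nodes count as 0."""
    return float(nx.average_clustering(net.to_networkx(), count_zeros=True))


def transitivity(net: Network) -> float:
    """Global transitivity 3·triangles/triads, kept for diagnostics."""
    return float(nx.transitivity(net.to_networkx()))


class ModularityResult(NamedTuple):
    Q: float
    communities: list[frozenset]
    algorithm: str
    seed: int


def modularity(net: Network, seed: int = 0) -> ModularityResult:
    """Newman-Girvan modularity of a greedy (CNM) agglomerative partition.

    The greedy merge order is deterministic for a given graph; the seed is
    recorded in the result for provenance even though this algorithm does not
    consume randomness.
    """
    if net.n_edges < 1:
        raise ValueError("modularity needs at least one edge")
    g = net.to_networkx()
    comms = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, comms)
    return ModularityResult(float(q), [frozenset(c) for c in comms],
                            "greedy_cnm", seed)


def max_kcore(net: Network) -> int:
    """Largest k with a non-empty k-core (iterative degree pruning)."""
    core = nx.core_number(net.to_networkx())
    return int(max(core.values()))


def structure_metrics(net: Network, seed: int = 0) -> StructureMetrics:
    try:
        r = assortativity(net)
    except UndefinedMetricError:
        r = None
    mod = modularity(net, seed=seed)
    return StructureMetrics(
        r=r,
        c=clustering(net),
        Q=mod.Q,
        kcore_max=max_kcore(net),
        transitivity=transitivity(net),
        modularity_algorithm=mod.algorithm,
        modularity_seed=seed,
    )


def metrics_row(name: str, net: Network, seed: int = 0) -> pd.DataFrame:
    """One-row per-network metrics table (the CSV reporting format)."""
    stats = degree_stats(net)
    sm = structure_metrics(net, seed=seed)
    return pd.DataFrame(
        [
            {
                "name": name,
                "N": net.n_nodes,
                "E": net.n_edges,
                "mean_k": stats.mean_k,
                "mean_k2": stats.mean_k2,
                "kmax": stats.k_max,
                "r": np.nan if sm.r is None else sm.r,
                "c": sm.c,
                "Q": sm.Q,
                "kcore_max": sm.kcore_max,
            }
        ]
    )
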