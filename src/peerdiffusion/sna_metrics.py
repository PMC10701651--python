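"""Network descriptives, cross-network comparison and influencer selection.

Centralities follow the normalized unweighted-directed conventions of
networkx (which the underlying study field uses for classroom networks):

* in-degree: incoming ties / (n-1);
* betweenness: shortest-path pair dependencies, normalized by
  (n-1)(n-2) for a directed graph;
* closeness: incoming-distance closeness with the Wasserman-Faust
  reachable-component correction, 0 for nodes nobody reaches.

Influential peers are the per-class top 15% by a chosen centrality,
quota = round-half-up(fraction * class size) clamped to at least 2; ties
are broken by higher physical activity level, residual ties by a seeded
random draw, and every tie-break is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network_builder import ClassNetwork

__all__ = [
    "MetricError",
    "SelectionError",
    "InfluentialSelection",
    "density",
    "jaccard_similarity",
    "centrality",
    "centrality_table",
    "quota",
    "select_influential",
    "select_cohort",
    "selection_overlap",
    "STRATEGIES",
]

STRATEGIES = ("in_degree", "betweenness", "closeness")


class MetricError(ValueError):
    """A metric is undefined for the given network(s)."""


class SelectionError(ValueError):
    """Influencer selection is impossible for the given class."""


def _graph(net) -> nx.DiGraph:
    return net.graph if isinstance(net, ClassNetwork) else net


def density(net) -> float:
    """Directed density |E| / (n (n-1))."""
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 2:
        raise MetricError(f"density undefined for a network of {n} node(s)")
    return g.number_of_edges() / (n * (n - 1))


def jaccard_similarity(net_a, net_b) -> float:
    """Edge-set Jaccard index of two directed networks on the same nodes."""
    ga, gb = _graph(net_a), _graph(net_b)
    if set(ga.nodes()) != set(gb.nodes()):
        raise MetricError("Jaccard similarity requires the same node universe")
    ea, eb = set(ga.edges()), set(gb.edges())
    union = ea | eb
    if not union:
        raise MetricError("Jaccard similarity undefined: both edge sets empty")
    return len(ea & eb) / len(union)


def centrality(net, measure: str) -> dict[int, float]:
    """Normalized centrality scores on the unweighted directed structure."""
    g = _graph(net)
    if measure == "in_degree":
        return dict(nx.in_degree_centrality(g))
    if measure == "betweenness":
        return dict(nx.betweenness_centrality(g, normalized=True))
    if measure == "closeness":
        # incoming distance, Wasserman-Faust correction for disconnected classes
        return dict(nx.closeness_centrality(g, wf_improved=True))
    raise ValueError(f"unknown centrality measure {measure!r}; choose from {STRATEGIES}")


def centrality_table(net) -> pd.DataFrame:
    """All three centralities per node, columns node/in_degree/betweenness/closeness."""
    tabs = {m: centrality(net, m) for m in STRATEGIES}
    nodes = sorted(_graph(net).nodes())
    return pd.DataFrame(
        {"node": nodes, **{m: [tabs[m][v] for v in nodes] for m in STRATEGIES}}
    )


def quota(class_size: int, fraction: float = 0.15, minimum: int = 2) -> int:
    """Per-class influencer quota: round-half-up(fraction*size), >= minimum."""
    return max(minimum, int(np.floor(fraction * class_size + 0.5)))


@dataclass(frozen=True)
class InfluentialSelection:
    """Selected influential peers of one class under one strategy."""

    class_id: int
    strategy: str
    selected: tuple[int, ...]
    k: int
    tie_log: tuple[str, ...] = field(default_factory=tuple)


def select_influential(
    net,
    centrality_scores: dict[int, float],
    pal: dict[int, float],
    strategy: str,
    fraction: float = 0.15,
    rng: np.random.Generator | None = None,
) -> InfluentialSelection:
    """Pick the per-class quota of peers with the highest centrality.

    Ranking: centrality descending, then PAL descending, then a seeded
    random permutation. The selection depends only on (graph, PAL, seed);
    node insertion order never matters.
    """
    if not 0 < fraction <= 1:
        raise SelectionError(f"fraction must lie in (0, 1], got {fraction}")
    g = _graph(net)
    nodes = sorted(g.nodes())
    missing = [v for v in nodes if v not in pal]
    if missing:
        raise SelectionError(f"PAL missing for nodes {missing}")
    k = quota(len(nodes), fraction)
    if k > len(nodes):
        raise SelectionError(f"class of {len(nodes)} smaller than quota {k}")

    rng = rng if rng is not None else np.random.default_rng(0)
    jitter = {v: r for v, r in zip(nodes, rng.permutation(len(nodes)))}
    order = sorted(nodes, key=lambda v: (-centrality_scores[v], -pal[v], jitter[v]))
    selected = tuple(order[:k])

    tie_log: list[str] = []
    boundary_c = centrality_scores[order[k - 1]]
    tied_c = [v for v in nodes if centrality_scores[v] == boundary_c]
    if len(tied_c) > 1 and any(v not in selected for v in tied_c):
        tie_log.append(
            f"centrality tie at score {boundary_c:.6g} among {sorted(tied_c)}: broken by PAL"
        )
        boundary_p = pal[order[k - 1]]
        tied_p = [v for v in tied_c if pal[v] == boundary_p]
        if len(tied_p) > 1 and any(v not in selected for v in tied_p):
            tie_log.append(
                f"residual PAL tie at {boundary_p:.6g} among {sorted(tied_p)}: broken by seeded draw"
            )
    class_id = net.class_id if isinstance(net, ClassNetwork) else -1
    return InfluentialSelection(class_id, strategy, selected, k, tuple(tie_log))


def select_cohort(
    networks: dict[int, ClassNetwork],
    pal: pd.DataFrame,
    strategy: str,
    fraction: float = 0.15,
    rng: np.random.Generator | None = None,
) -> dict[int, InfluentialSelection]:
    """Run :func:`select_influential` for every class of a cohort."""
    rng = rng if rng is not None else np.random.default_rng(0)
    pal_map = dict(zip(pal["participant_id"], pal["pal"]))
    return {
        c: select_influential(net, centrality(net, strategy), pal_map, strategy, fraction, rng)
        for c, net in sorted(networks.items())
    }


def selection_overlap(
    sel_a: dict[int, InfluentialSelection] | InfluentialSelection,
    sel_b: dict[int, InfluentialSelection] | InfluentialSelection,
) -> tuple[int, float]:
    """Count and fraction of influential peers common to two selections."""
    if isinstance(sel_a, InfluentialSelection):
        sel_a = {sel_a.class_id: sel_a}
    if isinstance(sel_b, InfluentialSelection):
        sel_b = {sel_b.class_id: sel_b}
    if set(sel_a) != set(sel_b):
        raise MetricError("selections cover different cohorts (class sets differ)")
    a = {v for s in sel_a.values() for v in s.selected}
    b = {v for s in sel_b.values() for v in s.selected}
    if len(a) != len(b):
        raise MetricError("selections have different sizes; not comparable")
    inter = len(a & b)
    return inter, inter / len(a) if a else 0.0
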