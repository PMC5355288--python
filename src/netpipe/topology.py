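"""Degree/betweenness centrality, μ+kσ node classification, hub selection.

Nodes of a network are classified from the mean μ and standard deviation σ
of the degree distribution: low (degree <= μ+2σ), medium
(μ+2σ < degree <= μ+3σ) and high (degree > μ+3σ). Hub genes are the
high-degree nodes plus a betweenness "rescue": nodes that are not highly
connected but whose normalized betweenness exceeds μ_btw + k·σ_btw sit on
many shortest paths and are retained as hubs despite their low degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .interactome import GeneList, Interactome

log = logging.getLogger(__name__)

__all__ = [
    "TopologyProfile",
    "Hub",
    "HubSet",
    "degree_centrality",
    "betweenness_centrality",
    "profile_graph",
    "class_thresholds",
    "classify_nodes",
    "select_hubs",
    "first_neighbors",
]


def degree_centrality(g: Interactome) -> dict[str, int]:
    """Number of edges incident to each node (mean over nodes is 2E/N)."""
    return {n: int(d) for n, d in g.graph.degree()}


def betweenness_centrality(g: Interactome) -> dict[str, float]:
    """Exact normalized betweenness: for node v, sum over ordered pairs
    (s, t) of σ_st(v)/σ_st, divided by (N-1)(N-2)/2 — the whole-graph pair
    count, so values of a disconnected graph stay comparable across
    components. Values lie in [0, 1]."""
    return dict(nx.betweenness_centrality(g.graph, normalized=True))


@dataclass
class TopologyProfile:
    """Per-node degree and betweenness with their distribution moments.

    Moments use the sample standard deviation (n-1 denominator) by default;
    ``ddof=0`` switches to the population SD.
    """

    degree: dict[str, int]
    betweenness: dict[str, float]
    mu_deg: float
    sigma_deg: float
    mu_btw: float
    sigma_btw: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.degree)


def profile_graph(g: Interactome, ddof: int = 1) -> TopologyProfile:
    """Compute degree and betweenness centrality plus μ/σ summaries."""
    deg = degree_centrality(g)
    btw = betweenness_centrality(g)
    dvals = np.array(list(deg.values()), dtype=float)
    bvals = np.array([btw[n] for n in deg])
    sd = lambda x: float(np.std(x, ddof=ddof)) if len(x) > ddof else 0.0
    return TopologyProfile(
        degree=deg,
        betweenness=btw,
        mu_deg=float(dvals.mean()) if len(dvals) else 0.0,
        sigma_deg=sd(dvals),
        mu_btw=float(bvals.mean()) if len(bvals) else 0.0,
        sigma_btw=sd(bvals),
    )


def class_thresholds(mu: float, sigma: float) -> tuple[float, float]:
    """Degree cutoffs (μ+2σ, μ+3σ) separating low/medium/high connectivity."""
    return mu + 2.0 * sigma, mu + 3.0 * sigma


def classify_nodes(degrees: dict[str, int], ddof: int = 1) -> dict[str, str]:
    """Label each node low / medium / high from the degree distribution.

    Boundary ties go downward (strict inequalities): degree exactly μ+3σ is
    medium, exactly μ+2σ is low. A degenerate distribution (σ = 0) labels
    everything low with a warning.
    """
    if len(degrees) < 2:
        raise ValueError("need at least two nodes to classify")
    dvals = np.array(list(degrees.values()), dtype=float)
    mu = float(dvals.mean())
    sigma = float(np.std(dvals, ddof=ddof))
    if sigma == 0.0:
        log.warning("all degrees identical (sigma = 0); every node labelled low")
        return {n: "low" for n in degrees}
    t2, t3 = class_thresholds(mu, sigma)
    out = {}
    for n, d in degrees.items():
        out[n] = "high" if d > t3 else ("medium" if d > t2 else "low")
    return out


@dataclass
class Hub:
    gene: str
    reason: str  # "degree" or "betweenness_rescue"
    degree: int
    betweenness: float


@dataclass
class HubSet:
    hubs: list[Hub]

    @property
    def genes(self) -> list[str]:
        return [h.gene for h in self.hubs]

    def __len__(self) -> int:
        return len(self.hubs)

    def __iter__(self):
        return iter(self.hubs)


def select_hubs(
    profile: TopologyProfile, classes: dict[str, str], k_rescue: float = 1.0
) -> HubSet:
    """Hub genes: high-degree nodes plus low/medium nodes rescued by
    betweenness exceeding μ_btw + k_rescue·σ_btw.

    The default k_rescue = 1.0 is permissive on purpose: in sparse networks
    the betweenness distribution is heavily right-skewed, and genuine
    bottleneck nodes can sit barely one SD above the mean.
    """
    if set(profile.degree) != set(classes):
        raise ValueError("profile and classes cover different node sets")
    rescue_cut = profile.mu_btw + k_rescue * profile.sigma_btw
    hubs = []
    for n in sorted(profile.degree):
        if classes[n] == "high":
            hubs.append(Hub(n, "degree", profile.degree[n], profile.betweenness[n]))
        elif profile.betweenness[n] > rescue_cut:
            hubs.append(Hub(n, "betweenness_rescue", profile.degree[n], profile.betweenness[n]))
    return HubSet(hubs=hubs)


def first_neighbors(g: Interactome, hubs: HubSet) -> tuple[GeneList, float]:
    """Union of hub genes and their direct neighbours, with graph coverage.

    Coverage is |union| / |nodes of g|. A hub absent from the graph raises.
    """
    nodes = g.nodes
    union: set[str] = set()
    for h in hubs.genes:
        if h not in nodes:
            raise ValueError(f"hub gene {h!r} is not in the graph")
        union.add(h)
        union.update(g.graph.neighbors(h))
    coverage = len(union) / len(nodes) if nodes else 0.0
    return GeneList(sorted(union), label="hub_first_neighbors"), coverage
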