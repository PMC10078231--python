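"""Signed interaction networks and their descriptive topology metrics.

Networks carry only the pairs that survived the confound filter (label
``potential_biological``) with the requested sign; edge weights are the
link strengths.  Metrics mirror the descriptive set commonly reported for
co-occurrence networks: mean degree, modularity of the best partition,
diameter and average path length (largest connected component, unweighted
shortest paths), and heterogeneity of the degree distribution.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .community_data import CommunityMatrix
from .confound import LABEL_BIOLOGICAL, PairClassification
from .cooccur import SIGN_NEGATIVE, SIGN_POSITIVE

logger = logging.getLogger("cooxnet")

#: Metric names reported for every network and null replicate.
METRIC_NAMES = ("n_nodes", "n_edges", "mean_degree", "modularity",
                "diameter", "average_path_length", "heterogeneity")


@dataclass
class InteractionNetwork:
    """Simple undirected graph of potential biological interactions."""

    sign: str
    bin: str
    graph: nx.Graph
    group_labels: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    mean_degree: float
    modularity: float
    diameter: float
    average_path_length: float
    heterogeneity: float
    n_components: int = 0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass(frozen=True)
class GroupWeight:
    group_label: str
    weighted_degree_share: float
    representativeness: float
    ratio: float


def build_network(classifications: list[PairClassification], sign: str,
                  bin_label: str = "full") -> InteractionNetwork:
    """Assemble the interaction network for one sign from classified pairs.

    Only pairs labeled potential-biological with the matching sign become
    edges; nodes are exactly the incident taxa.
    """
    if sign not in (SIGN_POSITIVE, SIGN_NEGATIVE):
        raise ValueError(f"sign must be positive or negative, got {sign!r}")
    g = nx.Graph()
    for c in classifications:
        if c.label != LABEL_BIOLOGICAL or c.pair.sign != sign:
            continue
        a, b = c.pair.taxon_a, c.pair.taxon_b
        if a == b:
            raise ValueError(f"self-loop on taxon {a!r}")
        if g.has_edge(a, b):
            raise ValueError(f"duplicate edge ({a!r}, {b!r})")
        g.add_edge(a, b, weight=float(c.pair.strength))
    return InteractionNetwork(sign=sign, bin=bin_label, graph=g)


def network_from_edges(edges, sign: str = SIGN_POSITIVE,
                       bin_label: str = "full") -> InteractionNetwork:
    """Build directly from (taxon_a, taxon_b, weight) triples (testing and
    null-model replicates bypass classification)."""
    g = nx.Graph()
    for a, b, w in edges:
        if a == b:
            raise ValueError(f"self-loop on taxon {a!r}")
        if g.has_edge(a, b):
            raise ValueError(f"duplicate edge ({a!r}, {b!r})")
        g.add_edge(a, b, weight=float(w))
    return InteractionNetwork(sign=sign, bin=bin_label, graph=g)


def degree_heterogeneity(degrees, *, variant: str = "cv") -> float:
    """Dispersion of the degree sequence.

    ``cv`` (default): population coefficient of variation sd/mean — zero
    iff the graph is regular.  ``moment_ratio``: <k^2>/<k>^2, the scaling
    commonly used in degree-distribution theory.
    """
    k = np.asarray(list(degrees), dtype=float)
    if k.size == 0 or k.mean() == 0:
        return float("nan")
    if variant == "cv":
        return float(k.std() / k.mean())
    if variant == "moment_ratio":
        return float((k ** 2).mean() / k.mean() ** 2)
    raise ValueError(f"unknown heterogeneity variant {variant!r}")


def topology(net: InteractionNetwork | nx.Graph, *, seed: int = 0,
             resolution: float = 1.0, weighted_modularity: bool = False,
             heterogeneity_variant: str = "cv") -> TopologyReport:
    """Descriptive metrics for one network.

    Diameter and average path length are computed on the largest connected
    component with unweighted shortest paths (the full graphs are typically
    disconnected).  Modularity is Newman modularity of the Louvain partition
    at the given resolution, deterministic for a fixed seed; by default the
    partition is found on the unweighted graph.
    """
    g = net.graph if isinstance(net, InteractionNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        nan = float("nan")
        return TopologyReport(0, 0, nan, nan, nan, nan, nan, 0)
    mean_degree = 2.0 * e / n
    hdd = degree_heterogeneity((d for _, d in g.degree()),
                               variant=heterogeneity_variant)
    components = list(nx.connected_components(g))
    giant = g.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        diameter = float(nx.diameter(giant))
        apl = float(nx.average_shortest_path_length(giant))
    else:
        diameter, apl = float("nan"), float("nan")
    if e > 0:
        weight_key = "weight" if weighted_modularity else None
        # Louvain is a stochastic heuristic; keep the best of several
        # deterministic restarts, plus the CNM greedy partition which
        # often wins on small sparse graphs
        candidates = [nx.community.louvain_communities(
            g, weight=weight_key, resolution=resolution,
            threshold=1e-10, seed=seed + restart) for restart in range(10)]
        try:
            candidates.append(nx.community.greedy_modularity_communities(
                g, weight=weight_key, resolution=resolution))
        except Exception:  # CNM can fail on degenerate graphs
            pass
        modularity = max(float(nx.community.modularity(
            g, c, weight=weight_key, resolution=resolution))
            for c in candidates)
    else:
        modularity = float("nan")
    return TopologyReport(
        n_nodes=n, n_edges=e, mean_degree=mean_degree, modularity=modularity,
        diameter=diameter, average_path_length=apl, heterogeneity=hdd,
        n_components=len(components))


def group_weights(net: InteractionNetwork, taxonomy: dict[str, str],
                  m: CommunityMatrix) -> list[GroupWeight]:
    """Taxonomic-group share of total weighted degree vs. data share.

    ``weighted_degree_share`` is the fraction of the network's total
    weighted degree carried by a group's nodes; ``representativeness`` is
    the group's fraction of the 1-entries of the filtered presence matrix;
    ``ratio`` their quotient (overrepresentation when > 1).
    """
    g = net.graph
    wdeg = dict(g.degree(weight="weight"))
    total_w = sum(wdeg.values())
    group_of = lambda t: taxonomy.get(t, "Unknown")

    presence_per_taxon = dict(zip(m.taxa, m.occurrence_counts()))
    total_obs = sum(presence_per_taxon.values())
    groups = sorted({group_of(t) for t in list(g.nodes) + list(m.taxa)})
    out = []
    for grp in groups:
        share = (sum(w for t, w in wdeg.items() if group_of(t) == grp)
                 / total_w) if total_w > 0 else 0.0
        rep = (sum(c for t, c in presence_per_taxon.items()
                   if group_of(t) == grp) / total_obs) if total_obs else 0.0
        if rep > 0:
            ratio = share / rep
        elif share > 0:
            logger.warning("group %r present in network but absent from "
                           "presence data; ratio reported as inf", grp)
            ratio = float("inf")
        else:
            ratio = float("nan")
        out.append(GroupWeight(group_label=grp, weighted_degree_share=share,
                               representativeness=rep, ratio=ratio))
    return out


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_edge_list(net: InteractionNetwork, path) -> None:
    rows = [{"taxon_a": a, "taxon_b": b, "weight": d["weight"]}
            for a, b, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "weight"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(net: InteractionNetwork, path) -> None:
    g = net.graph.copy()
    for node, grp in net.group_labels.items():
        if node in g:
            g.nodes[node]["group"] = grp
    nx.write_graphml(g, path)


def write_topology_report(report: TopologyReport, path) -> None:
    with open(path, "w") as fh:
        json.dump({**report.as_dict(), "n_components": report.n_components},
                  fh, indent=2, default=float)


def group_weight_table(weights: list[GroupWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": w.group_label, "weighted_degree_share":
          w.weighted_degree_share, "representativeness": w.representativeness,
          "ratio": w.ratio} for w in weights],
        columns=["group", "weighted_degree_share", "representativeness",
                 "ratio"])
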