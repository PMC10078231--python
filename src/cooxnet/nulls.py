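"""Null models for network significance: Erdős–Rényi graphs and curveball
matrix randomization.

Two complementary nulls assess whether an observed network's topology could
arise by chance.  The Erdős–Rényi model draws G(n, p) graphs with the
observed node count and edge density (so the expected mean degree matches
the observed one) and recomputes every metric on each replicate.  The
matrix-randomization model shuffles the filtered presence–absence matrix
with the curveball algorithm — a Markov chain that trades columns between
row pairs, preserving every row and column sum exactly — and replays the
whole inference (pairwise exact tests, optional confound filtering, network
construction) on each randomized matrix before measuring it.

Empirical two-sided p-values use the add-one estimator
p = 2 * min((1 + #{null <= obs}), (1 + #{null >= obs})) / (B + 1), capped
at 1, with direction flags H/L relative to the null median.  Significance
codes mirror the usual convention: ``*`` p < 0.05, ``**`` p < 0.001.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .community_data import CommunityMatrix, SampleMetadata
from .confound import LABEL_BIOLOGICAL, classify_pairs
from .cooccur import SIGN_NEGATIVE, SIGN_POSITIVE, TestConfig, all_pairs
from .topology import METRIC_NAMES, InteractionNetwork, TopologyReport, topology

logger = logging.getLogger("cooxnet")

MODEL_ER = "erdos_renyi"
MODEL_MATRIX = "matrix_randomization"

DIRECTION_HIGH = "H"
DIRECTION_LOW = "L"
DIRECTION_NONE = "none"


@dataclass
class NullEnsemble:
    """Null distribution of one metric under one model."""

    model: str
    metric: str
    observed: float
    null_values: np.ndarray
    p_value: float
    direction: str
    degenerate: bool = False  # all null values identical

    @property
    def B(self) -> int:
        return int(self.null_values.size)

    @property
    def significance_code(self) -> str:
        if not np.isfinite(self.p_value):
            return ""
        if self.p_value < 0.001:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def empirical_two_sided(observed: float, null_values,
                        threshold: float = 0.05) -> tuple[float, str]:
    """Add-one empirical two-sided p and H/L/none direction flag."""
    null = np.asarray(null_values, dtype=float)
    null = null[np.isfinite(null)]
    if null.size == 0 or not np.isfinite(observed):
        return float("nan"), DIRECTION_NONE
    B = null.size
    p_low = (1 + np.sum(null <= observed)) / (B + 1)
    p_high = (1 + np.sum(null >= observed)) / (B + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    median = float(np.median(null))
    if p < threshold and observed > median:
        direction = DIRECTION_HIGH
    elif p < threshold and observed < median:
        direction = DIRECTION_LOW
    else:
        direction = DIRECTION_NONE
    return float(p), direction


def make_ensemble(model: str, metric: str, observed: float,
                  null_values, threshold: float = 0.05) -> NullEnsemble:
    null = np.asarray(null_values, dtype=float)
    finite = null[np.isfinite(null)]
    degenerate = finite.size > 1 and np.all(finite == finite[0])
    if degenerate:
        logger.debug("degenerate null for %s/%s: all values %.4g",
                     model, metric, finite[0])
    p, direction = empirical_two_sided(observed, null, threshold)
    return NullEnsemble(model=model, metric=metric, observed=float(observed),
                        null_values=null, p_value=p, direction=direction,
                        degenerate=degenerate)


# --------------------------------------------------------------------------
# Erdős–Rényi model
# --------------------------------------------------------------------------

def erdos_renyi_null(n_nodes: int, n_edges_obs: int, B: int,
                     seed: int | np.random.Generator) -> list[nx.Graph]:
    """B replicates of G(n, p) with p chosen to preserve the mean degree."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    p = 2.0 * n_edges_obs / (n_nodes * (n_nodes - 1))
    if p > 1:
        raise ValueError(f"observed density implies p={p:.3f} > 1")
    rng = np.random.default_rng(seed)
    return [nx.fast_gnp_random_graph(n_nodes, p,
                                     seed=int(rng.integers(2 ** 31)))
            for _ in range(B)]


def er_null_distribution(observed: TopologyReport, B: int,
                         seed: int | np.random.Generator, *,
                         n_universe: int | None = None,
                         threshold: float = 0.05,
                         topology_kwargs: dict | None = None
                         ) -> dict[str, NullEnsemble]:
    """Null ensembles of every metric under the Erdős–Rényi model.

    With ``n_universe`` set (typically the number of filtered taxa), each
    replicate draws random interactions among all candidate taxa with the
    observed expected edge count and the network is then *derived* by
    dropping isolated nodes — exactly how the observed network arises from
    its pair list.  This keeps the derived node count and mean degree
    comparable to the observed ones; squeezing the same number of edges
    onto only the observed (incident) nodes would force extra endpoint
    sharing and bias every shape metric.  Without ``n_universe`` the
    classic construction on the observed node count is used.
    """
    topology_kwargs = topology_kwargs or {}
    if n_universe is None:
        graphs = erdos_renyi_null(observed.n_nodes, observed.n_edges, B,
                                  seed)
    else:
        graphs = erdos_renyi_null(n_universe, observed.n_edges, B, seed)
        for g in graphs:
            g.remove_nodes_from(list(nx.isolates(g)))
    null_reports = [topology(g, **topology_kwargs) for g in graphs]
    return {metric: make_ensemble(
                MODEL_ER, metric, getattr(observed, metric),
                [getattr(r, metric) for r in null_reports], threshold)
            for metric in METRIC_NAMES}


# --------------------------------------------------------------------------
# Curveball matrix randomization
# --------------------------------------------------------------------------

def curveball(matrix, n_trades: int | None = None,
              seed: int | np.random.Generator = 0) -> np.ndarray:
    """Randomize a binary matrix preserving all row and column sums.

    Each trade picks two distinct rows, finds the columns held by exactly
    one of them, and randomly re-partitions that set between the rows,
    keeping each row's share.  Default number of trades is 5x the row
    count.
    """
    m = np.asarray(matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("curveball requires a binary matrix")
    out = m.astype(np.int8).copy()
    n_rows = out.shape[0]
    if n_rows < 2:
        warnings.warn("fewer than 2 rows; curveball is the identity",
                      stacklevel=2)
        return out
    if n_trades is None:
        n_trades = 5 * n_rows
    rng = np.random.default_rng(seed)
    rows = [set(np.flatnonzero(out[i]).tolist()) for i in range(n_rows)]
    for _ in range(n_trades):
        i, j = rng.choice(n_rows, size=2, replace=False)
        a, b = rows[i], rows[j]
        a_only = list(a - b)
        b_only = list(b - a)
        diff = a_only + b_only
        if not diff:
            continue
        perm = rng.permutation(len(diff))
        new_a = {diff[k] for k in perm[:len(a_only)]}
        new_b = {diff[k] for k in perm[len(a_only):]}
        rows[i] = (a & b) | new_a
        rows[j] = (a & b) | new_b
    out[:] = 0
    for i, cols in enumerate(rows):
        out[i, list(cols)] = 1
    return out


def _presence_to_matrix(presence: np.ndarray, taxa, samples) -> CommunityMatrix:
    """Wrap a binary matrix as a CommunityMatrix (presence view preserved)."""
    colsum = presence.sum(axis=0)
    rel = presence / np.maximum(colsum, 1)
    return CommunityMatrix(taxa=list(taxa), samples=list(samples),
                           rel_abundance=rel)


def matrix_null_distribution(m: CommunityMatrix,
                             meta: list[SampleMetadata],
                             observed: dict[str, TopologyReport],
                             cfg: TestConfig,
                             B: int,
                             seed: int | np.random.Generator, *,
                             with_confound: bool = True,
                             n_trades: int | None = None,
                             threshold: float = 0.05,
                             topology_kwargs: dict | None = None
                             ) -> dict[str, dict[str, NullEnsemble]]:
    """Replay the inference chain on B curveball-randomized matrices.

    ``observed`` maps sign -> the observed network's TopologyReport.  Each
    replicate randomizes the filtered presence matrix, reruns the exact
    pairwise tests (and, when ``with_confound``, the environmental/spatial
    classification), rebuilds the positive and negative networks and
    measures them.  Returns sign -> metric -> NullEnsemble.
    """
    topology_kwargs = topology_kwargs or {}
    rng = np.random.default_rng(seed)
    presence = m.presence
    null_values: dict[str, dict[str, list[float]]] = {
        s: {metric: [] for metric in METRIC_NAMES} for s in observed}
    for _ in range(B):
        randomized = curveball(presence, n_trades,
                               int(rng.integers(2 ** 31)))
        rm = _presence_to_matrix(randomized, m.taxa, m.samples)
        tests = all_pairs(rm, cfg, significant_only=True)
        if with_confound:
            classifications = classify_pairs(tests, meta, rm)
            edges = {s: [(c.pair.taxon_a, c.pair.taxon_b, c.pair.strength)
                         for c in classifications
                         if c.label == LABEL_BIOLOGICAL and c.pair.sign == s]
                     for s in observed}
        else:
            edges = {s: [(t.taxon_a, t.taxon_b, t.strength)
                         for t in tests if t.sign == s] for s in observed}
        for s in observed:
            g = nx.Graph()
            for a, b, w in edges[s]:
                g.add_edge(a, b, weight=float(w))
            report = topology(g, **topology_kwargs)
            for metric in METRIC_NAMES:
                null_values[s][metric].append(getattr(report, metric))
    return {s: {metric: make_ensemble(MODEL_MATRIX, metric,
                                      getattr(observed[s], metric),
                                      null_values[s][metric], threshold)
                for metric in METRIC_NAMES}
            for s in observed}


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def null_summary_table(ensembles: dict[str, NullEnsemble]) -> pd.DataFrame:
    rows = []
    for metric, e in ensembles.items():
        finite = e.null_values[np.isfinite(e.null_values)]
        rows.append({
            "model": e.model, "metric": metric, "observed": e.observed,
            "null_mean": float(finite.mean()) if finite.size else float("nan"),
            "null_sd": float(finite.std()) if finite.size else float("nan"),
            "p_value": e.p_value, "direction": e.direction,
            "significance": e.significance_code,
            "B": e.B, "degenerate": e.degenerate})
    return pd.DataFrame(rows, columns=["model", "metric", "observed",
                                       "null_mean", "null_sd", "p_value",
                                       "direction", "significance", "B",
                                       "degenerate"])


def write_null_summary(ensembles: dict[str, NullEnsemble], path) -> None:
    null_summary_table(ensembles).to_csv(path, sep="\t", index=False)


def write_null_replicates(ensembles: dict[str, NullEnsemble], path) -> None:
    """Dump raw replicate values, one column per metric, for audit."""
    pd.DataFrame({m: e.null_values for m, e in ensembles.items()}).to_csv(
        path, sep="\t", index=False)
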