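"""Environmental / spatial confound classification of significant pairs.

A significant co-occurrence or co-exclusion may simply reflect shared (or
opposed) habitat preferences or spatial structure rather than a biological
interaction.  Following the niche/space/interaction attribution framework,
each significant pair defines two groups of samples:

* positive pair — samples where both taxa co-occur vs. all remaining
  samples (aggregation contrast);
* negative pair — samples holding only taxon A vs. samples holding only
  taxon B (segregation contrast; joint and joint-absent samples excluded).

Each of the five environmental variables (salinity, temperature, pH,
dissolved oxygen, redox) is tested independently with a one-way ANOVA at
p < 0.05; spatial segregation/aggregation is tested with a one-way MANOVA
on the (x, y) coordinates (Pillai's trace).  Pairs explained by environment
and/or space are treated as potential artifacts; the remainder are the
potential biological interactions that enter the networks.

The two-group ANOVA and the two-group Pillai MANOVA are computed in closed
form (a pair sweep may run millions of such tiny tests inside the
matrix-randomization null), using `scipy.special.fdtrc` for the F tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import fdtrc

from .community_data import ENV_VARIABLES, CommunityMatrix, SampleMetadata
from .cooccur import SIGN_NEGATIVE, SIGN_POSITIVE, PairTest

logger = logging.getLogger("cooxnet")

LABEL_ENV = "environmental"
LABEL_SPATIAL = "spatial"
LABEL_BOTH = "environmental_and_spatial"
LABEL_BIOLOGICAL = "potential_biological"
LABEL_NA = "not_classifiable"

ALPHA_CLASSIFY = 0.05


@dataclass(frozen=True)
class PairClassification:
    """Confound attribution for one significant pair.

    ``env_pvalues`` maps each environmental variable to its ANOVA p-value
    (NaN where a group was too small or a value missing); ``spatial_pvalue``
    is the MANOVA p (NaN likewise).  NaN never counts as explanation.
    """

    pair: PairTest
    env_pvalues: dict[str, float]
    spatial_pvalue: float
    label: str
    group_sizes: tuple[int, int]

    @property
    def explaining_variables(self) -> list[str]:
        return [v for v, p in self.env_pvalues.items()
                if np.isfinite(p) and p < ALPHA_CLASSIFY]


def pair_groups(pair: PairTest, m: CommunityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Sample-index arrays (G1, G2) for a significant pair's contrast."""
    if pair.sign not in (SIGN_POSITIVE, SIGN_NEGATIVE):
        raise ValueError("pair_groups requires a non-random pair")
    ia = m.taxa.index(pair.taxon_a)
    ib = m.taxa.index(pair.taxon_b)
    a = m.presence[ia].astype(bool)
    b = m.presence[ib].astype(bool)
    if pair.sign == SIGN_POSITIVE:
        g1 = a & b
        g2 = ~g1
    else:
        g1 = a & ~b
        g2 = b & ~a
    return np.flatnonzero(g1), np.flatnonzero(g2)


def env_anova(values1, values2) -> tuple[float, float]:
    """One-way fixed-effects ANOVA for two groups; returns (F, p).

    Equivalent to the squared two-sided pooled t-test.  Both groups need
    at least two finite values; identical constant groups give (0, 1);
    distinct constant groups give (inf, 0) with a log record.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    v1, v2 = v1[np.isfinite(v1)], v2[np.isfinite(v2)]
    n1, n2 = v1.size, v2.size
    if n1 < 2 or n2 < 2:
        return float("nan"), float("nan")
    m1, m2 = v1.mean(), v2.mean()
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((v1 - m1) ** 2).sum() + ((v2 - m2) ** 2).sum()
    dfb, dfw = 1, n1 + n2 - 2
    if ssw <= 0:
        if ssb <= 1e-300:
            return 0.0, 1.0
        logger.debug("zero within-group variance with unequal means")
        return float("inf"), 0.0
    F = (ssb / dfb) / (ssw / dfw)
    return float(F), float(fdtrc(dfb, dfw, F))


def spatial_manova(coords1, coords2) -> float:
    """Two-group one-way MANOVA p-value on (x, y), Pillai's trace.

    For two groups Pillai's trace V relates to Hotelling's T^2; the exact
    F statistic is F = V/(1-V) * (n-3)/2 on (2, n-3) degrees of freedom.
    Rank-deficient responses (one axis constant or the two collinear) fall
    back to a one-dimensional ANOVA on the informative axis.
    """
    c1 = np.asarray(coords1, dtype=float).reshape(-1, 2)
    c2 = np.asarray(coords2, dtype=float).reshape(-1, 2)
    c1 = c1[np.isfinite(c1).all(axis=1)]
    c2 = c2[np.isfinite(c2).all(axis=1)]
    n1, n2 = c1.shape[0], c2.shape[0]
    if n1 < 3 or n2 < 3:
        return float("nan")
    n = n1 + n2
    m1, m2 = c1.mean(axis=0), c2.mean(axis=0)
    d1, d2 = c1 - m1, c2 - m2
    E = d1.T @ d1 + d2.T @ d2  # within-group SSCP
    grand = (n1 * m1 + n2 * m2) / n
    H = (n1 * np.outer(m1 - grand, m1 - grand)
         + n2 * np.outer(m2 - grand, m2 - grand))
    T = H + E
    det_T = T[0, 0] * T[1, 1] - T[0, 1] * T[1, 0]
    scale = max(T[0, 0], T[1, 1], 1e-300)
    if det_T <= 1e-12 * scale * scale:
        # collinear or constant axis: reduce to 1-D along the larger spread
        axis = 0 if T[0, 0] >= T[1, 1] else 1
        if T[axis, axis] <= 0:
            return float("nan")
        logger.debug("rank-deficient coordinates; 1-D ANOVA fallback")
        return env_anova(c1[:, axis], c2[:, axis])[1]
    # V = trace(H (H+E)^-1) via explicit 2x2 inverse
    inv_T = np.array([[T[1, 1], -T[0, 1]], [-T[1, 0], T[0, 0]]]) / det_T
    V = float(np.trace(H @ inv_T))
    V = min(max(V, 0.0), 1.0)
    if n <= 3:
        return float("nan")
    if V >= 1.0:
        return 0.0
    F = V / (1.0 - V) * (n - 3) / 2.0
    return float(fdtrc(2, n - 3, F))


def _label(env_pvalues: dict[str, float], spatial_p: float) -> str:
    finite = [p for p in env_pvalues.values() if np.isfinite(p)]
    if not finite and not np.isfinite(spatial_p):
        return LABEL_NA
    env = any(p < ALPHA_CLASSIFY for p in finite)
    spatial = np.isfinite(spatial_p) and spatial_p < ALPHA_CLASSIFY
    if env and spatial:
        return LABEL_BOTH
    if env:
        return LABEL_ENV
    if spatial:
        return LABEL_SPATIAL
    return LABEL_BIOLOGICAL


def classify_pair(pair: PairTest, meta: list[SampleMetadata],
                  m: CommunityMatrix) -> PairClassification:
    """Attribute one significant pair to environment, space, both or neither."""
    by_id = {s.sample_id: s for s in meta}
    env = {v: np.array([by_id[s].env_value(v) if s in by_id else np.nan
                        for s in m.samples]) for v in ENV_VARIABLES}
    coords = np.array([[by_id[s].x, by_id[s].y] if s in by_id
                       else [np.nan, np.nan] for s in m.samples])
    return _classify_one(pair, m, env, coords)


def _classify_one(pair: PairTest, m: CommunityMatrix,
                  env: dict[str, np.ndarray],
                  coords: np.ndarray) -> PairClassification:
    g1, g2 = pair_groups(pair, m)
    if g1.size == 0 or g2.size == 0:
        logger.debug("pair (%s, %s): empty contrast group; not classifiable",
                     pair.taxon_a, pair.taxon_b)
        return PairClassification(
            pair=pair, env_pvalues={v: float("nan") for v in ENV_VARIABLES},
            spatial_pvalue=float("nan"), label=LABEL_NA,
            group_sizes=(int(g1.size), int(g2.size)))
    env_p = {v: env_anova(env[v][g1], env[v][g2])[1] for v in ENV_VARIABLES}
    spatial_p = spatial_manova(coords[g1], coords[g2])
    return PairClassification(
        pair=pair, env_pvalues=env_p, spatial_pvalue=spatial_p,
        label=_label(env_p, spatial_p),
        group_sizes=(int(g1.size), int(g2.size)))


def classify_pairs(tests: list[PairTest], meta: list[SampleMetadata],
                   m: CommunityMatrix) -> list[PairClassification]:
    """Classify every significant pair in ``tests`` (random pairs skipped)."""
    by_id = {s.sample_id: s for s in meta}
    env = {v: np.array([by_id[s].env_value(v) if s in by_id else np.nan
                        for s in m.samples]) for v in ENV_VARIABLES}
    coords = np.array([[by_id[s].x, by_id[s].y] if s in by_id
                       else [np.nan, np.nan] for s in m.samples])
    if coords.size == 0:
        coords = coords.reshape(0, 2)
    # index lookup once; pair_groups would re-scan the taxa list per pair
    return [_classify_one(t, m, env, coords) for t in tests
            if t.sign in (SIGN_POSITIVE, SIGN_NEGATIVE)]


# --------------------------------------------------------------------------
# Explanation summary (ordered / cumulative attribution)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExplanationSummary:
    """Greedy ordered attribution of significant pairs to variables.

    Variables are ordered by how many still-unexplained pairs each explains;
    ``cumulative`` is the running union fraction, followed by the fraction
    explained only by space and the residual (potential biological) fraction.
    """

    variables: tuple[str, ...]
    counts: tuple[int, ...]          # newly explained pairs per variable
    cumulative: tuple[float, ...]    # union fraction after each variable
    space_only_fraction: float
    biological_fraction: float
    n_pairs: int                     # classifiable pairs (denominator)
    n_not_classifiable: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": v, "newly_explained": c, "cumulative_fraction": f}
                for v, c, f in zip(self.variables, self.counts, self.cumulative)]
        rows.append({"variable": "space_only", "newly_explained":
                     round(self.space_only_fraction * self.n_pairs),
                     "cumulative_fraction":
                     (self.cumulative[-1] if self.cumulative else 0.0)
                     + self.space_only_fraction})
        rows.append({"variable": "potential_biological", "newly_explained":
                     round(self.biological_fraction * self.n_pairs),
                     "cumulative_fraction": 1.0})
        return pd.DataFrame(rows)


def explanation_summary(classifications: list[PairClassification]
                        ) -> ExplanationSummary:
    """Order variables by marginal explanatory power over significant pairs."""
    usable = [c for c in classifications if c.label != LABEL_NA]
    n_na = len(classifications) - len(usable)
    n = len(usable)
    if n == 0:
        return ExplanationSummary(variables=tuple(ENV_VARIABLES),
                                  counts=(0,) * len(ENV_VARIABLES),
                                  cumulative=(0.0,) * len(ENV_VARIABLES),
                                  space_only_fraction=0.0,
                                  biological_fraction=0.0,
                                  n_pairs=0, n_not_classifiable=n_na)
    explained_by = [set(c.explaining_variables) for c in usable]
    spatial = [np.isfinite(c.spatial_pvalue)
               and c.spatial_pvalue < ALPHA_CLASSIFY for c in usable]

    remaining = set(range(n))
    order: list[str] = []
    counts: list[int] = []
    cumulative: list[float] = []
    explained_total = 0
    pool = list(ENV_VARIABLES)
    while pool:
        gains = {v: sum(1 for i in remaining if v in explained_by[i])
                 for v in pool}
        best = max(pool, key=lambda v: (gains[v], -pool.index(v)))
        order.append(best)
        counts.append(gains[best])
        explained_total += gains[best]
        remaining = {i for i in remaining if best not in explained_by[i]}
        cumulative.append(explained_total / n)
        pool.remove(best)
    space_only = sum(1 for i in remaining if spatial[i])
    biological = len(remaining) - space_only
    return ExplanationSummary(
        variables=tuple(order), counts=tuple(counts),
        cumulative=tuple(cumulative),
        space_only_fraction=space_only / n,
        biological_fraction=biological / n,
        n_pairs=n, n_not_classifiable=n_na)


def classification_table(classifications: list[PairClassification]
                         ) -> pd.DataFrame:
    rows = []
    for c in classifications:
        row = {"taxon_a": c.pair.taxon_a, "taxon_b": c.pair.taxon_b,
               "sign": c.pair.sign, "strength": c.pair.strength}
        row.update({f"p_{v}": c.env_pvalues[v] for v in ENV_VARIABLES})
        row["p_spatial"] = c.spatial_pvalue
        row["label"] = c.label
        row["n_group1"], row["n_group2"] = c.group_sizes
        rows.append(row)
    cols = (["taxon_a", "taxon_b", "sign", "strength"]
            + [f"p_{v}" for v in ENV_VARIABLES]
            + ["p_spatial", "label", "n_group1", "n_group2"])
    return pd.DataFrame(rows, columns=cols)


def write_classification_table(classifications, path) -> None:
    classification_table(classifications).to_csv(path, sep="\t", index=False)
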