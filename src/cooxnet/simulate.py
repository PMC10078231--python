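"""Synthetic metacommunities with known ground truth.

The generator emulates the statistical structure the inference chain
assumes: a multi-lake survey along a wide salinity gradient (defaults: 14
lakes, 116 samples, salinity 0.1–40 % with lake means log-uniform), taxa
with Gaussian occupancy niches on log10 salinity, lake-restricted taxa,
and planted pairwise interactions that are environment-independent by
construction — so the confound filter should let them through, which makes
recovery of the planted pairs a meaningful end-to-end check.

Presence is drawn per sample as Bernoulli with probability

    P(i present | salinity S) = p_max_i * exp(-(log10 S - mu_i)^2 / (2 sigma_i^2))

masked to the taxon's allowed lakes.  A planted positive pair (i, j)
replaces j's draw with i's state with probability rho+; a planted negative
pair suppresses j where i is present with probability rho- (optionally
bin-dependent, which is how the stress-gradient demonstration configures a
decline of exclusion with salinity).  Abundances conditional on presence
are lognormal, renormalized per sample.  Other environmental variables are
linear in log10 salinity plus Gaussian noise, mimicking the strong
collinearity of real gradient surveys.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community_data import (CommunityMatrix, SampleMetadata,
                             assign_salinity_bin)
from .confound import (LABEL_BIOLOGICAL, LABEL_BOTH, LABEL_ENV,
                       PairClassification)
from .cooccur import SIGN_NEGATIVE, SIGN_POSITIVE

TRUTH_POSITIVE = "planted_positive"
TRUTH_NEGATIVE = "planted_negative"
TRUTH_GUILD = "env_guild"
TRUTH_SPATIAL = "spatial"
TRUTH_NONE = "none"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the study conditions emulated."""

    n_lakes: int = 14
    n_samples: int = 116
    n_taxa: int = 300
    salinity_range: tuple[float, float] = (0.1, 40.0)
    #: sd of within-lake temporal salinity variation, log10 units
    salinity_jitter: float = 0.12
    #: narrow-niche (salinity guild) taxa
    guild_fraction: float = 0.3
    guild_sigma: float = 0.3
    #: generalists: niche breadth wide relative to the ~2.6-decade gradient
    broad_sigma: float = 2.5
    #: peak occupancy probabilities, drawn log-uniformly over this range —
    #: occupancy distributions of real communities are strongly right-skewed
    p_max_range: tuple[float, float] = (0.03, 0.8)
    #: planted interactions (environment-independent, flat occupancy)
    n_planted_positive: int = 30
    n_planted_negative: int = 10
    rho_positive: float = 0.8
    rho_negative: float = 0.8
    #: optional per-salinity-bin exclusion strength (stress-gradient demo)
    rho_negative_by_bin: dict[str, float] | None = None
    planted_p: float = 0.45
    #: half-width of the uniform spread of planted-taxon occupancies; taxa
    #: with identical margins would make the discrete test's attainable
    #: p-values coincide and the false-positive count jumpy
    planted_p_spread: float = 0.15
    #: fraction of non-planted taxa confined to a random lake subset
    spatial_fraction: float = 0.1
    spatial_n_lakes: int = 3
    #: lognormal sd of abundance conditional on presence
    abundance_sigma: float = 1.0
    #: covariate = intercept + slope * log10(salinity) + N(0, noise_sd);
    #: noise is small relative to the gradient signal, giving the strong
    #: covariate collinearity typical of salinity-dominated surveys
    env_coefficients: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "temperature": (20.0, 3.0, 1.0),
            "ph": (8.0, -0.5, 0.15),
            "dissolved_oxygen": (7.0, -2.0, 0.6),
            "redox": (150.0, -80.0, 20.0),
        })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 * (self.n_planted_positive + self.n_planted_negative):
            raise ValueError("n_taxa too small for the planted pairs")
        for name, rho in (("rho_positive", self.rho_positive),
                          ("rho_negative", self.rho_negative)):
            if not 0 < rho <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Truth label per taxon pair (planted pairs listed explicitly)."""

    positive_pairs: list[tuple[str, str]]
    negative_pairs: list[tuple[str, str]]
    guild_taxa: set[str]
    spatial_taxa: set[str]

    def label(self, taxon_a: str, taxon_b: str) -> str:
        pair = tuple(sorted((taxon_a, taxon_b)))
        if pair in self._pos:
            return TRUTH_POSITIVE
        if pair in self._neg:
            return TRUTH_NEGATIVE
        if taxon_a in self.guild_taxa and taxon_b in self.guild_taxa:
            return TRUTH_GUILD
        if taxon_a in self.spatial_taxa and taxon_b in self.spatial_taxa:
            return TRUTH_SPATIAL
        return TRUTH_NONE

    def __post_init__(self) -> None:
        self._pos = {tuple(sorted(p)) for p in self.positive_pairs}
        self._neg = {tuple(sorted(p)) for p in self.negative_pairs}

    def to_frame(self) -> pd.DataFrame:
        rows = ([{"taxon_a": a, "taxon_b": b, "truth": TRUTH_POSITIVE}
                 for a, b in self.positive_pairs]
                + [{"taxon_a": a, "taxon_b": b, "truth": TRUTH_NEGATIVE}
                   for a, b in self.negative_pairs])
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "truth"])


def simulate(cfg: SimConfig = SimConfig()
             ) -> tuple[CommunityMatrix, list[SampleMetadata], GroundTruth]:
    """Draw one metacommunity; fully determined by ``cfg`` (incl. its seed)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = np.log10(cfg.salinity_range[0]), np.log10(cfg.salinity_range[1])

    # --- lakes: fixed coordinates and mean salinities -------------------
    lake_ids = [f"L{k + 1:02d}" for k in range(cfg.n_lakes)]
    lake_xy = rng.uniform(0.0, 10.0, size=(cfg.n_lakes, 2))
    # lake means stratified over the three salinity bins (log-uniform within
    # each, inset from the bin edges so temporal jitter rarely crosses
    # them), mirroring the near-balanced bin sizes of a designed gradient
    # survey; a plain log-uniform would leave the middle bin underpopulated
    edges = [lo, np.log10(2.5), np.log10(5.0), hi]
    inset = 0.1
    lake_bin = np.arange(cfg.n_lakes) % 3
    lake_logsal = np.array([
        rng.uniform(edges[b] + inset, edges[b + 1] - inset)
        for b in lake_bin])

    # --- samples: round-robin over bins, then lakes within bin ----------
    lakes_by_bin = [np.flatnonzero(lake_bin == b) for b in range(3)]
    counters = [0, 0, 0]
    lake_of = np.empty(cfg.n_samples, dtype=int)
    for s in range(cfg.n_samples):
        b = s % 3
        members = lakes_by_bin[b]
        lake_of[s] = members[counters[b] % members.size]
        counters[b] += 1
    logsal = np.clip(lake_logsal[lake_of]
                     + rng.normal(0, cfg.salinity_jitter, cfg.n_samples),
                     lo, hi)
    salinity = 10.0 ** logsal
    base = _dt.date(2015, 1, 15)
    meta = []
    for s in range(cfg.n_samples):
        month = s // cfg.n_lakes
        date = _dt.date(base.year + month // 12, 1 + month % 12, base.day)
        env = {}
        for var, (b0, b1, sd) in cfg.env_coefficients.items():
            env[var] = b0 + b1 * logsal[s] + rng.normal(0, sd)
        meta.append(SampleMetadata(
            sample_id=f"S{s + 1:03d}", lake_id=lake_ids[lake_of[s]],
            date=date, x=float(lake_xy[lake_of[s], 0]),
            y=float(lake_xy[lake_of[s], 1]),
            salinity=float(salinity[s]), temperature=env["temperature"],
            ph=env["ph"], dissolved_oxygen=env["dissolved_oxygen"],
            redox=env["redox"]))

    # --- taxon roles ----------------------------------------------------
    taxa = [f"T{k + 1:04d}" for k in range(cfg.n_taxa)]
    n_planted = 2 * (cfg.n_planted_positive + cfg.n_planted_negative)
    planted_idx = np.arange(n_planted)
    free = np.arange(n_planted, cfg.n_taxa)
    n_spatial = int(round(cfg.spatial_fraction * free.size))
    spatial_idx = free[:n_spatial]
    rest = free[n_spatial:]
    n_guild = int(round(cfg.guild_fraction * rest.size))
    guild_idx = rest[:n_guild]
    broad_idx = rest[n_guild:]

    mu = rng.uniform(lo, hi, size=cfg.n_taxa)
    sigma = np.full(cfg.n_taxa, cfg.broad_sigma)
    sigma[guild_idx] = cfg.guild_sigma
    p_max = np.exp(rng.uniform(np.log(cfg.p_max_range[0]),
                               np.log(cfg.p_max_range[1]),
                               size=cfg.n_taxa))

    # occupancy probability per taxon x sample
    prob = p_max[:, None] * np.exp(-(logsal[None, :] - mu[:, None]) ** 2
                                   / (2 * sigma[:, None] ** 2))
    # planted taxa: flat niches so the confound filter has nothing to find
    planted_p = rng.uniform(cfg.planted_p - cfg.planted_p_spread,
                            cfg.planted_p + cfg.planted_p_spread,
                            size=n_planted)
    prob[planted_idx, :] = planted_p[:, None]
    # lake-restricted taxa
    allowed = np.ones((cfg.n_taxa, cfg.n_samples), dtype=bool)
    spatial_taxa = set()
    for i in spatial_idx:
        lakes = rng.choice(cfg.n_lakes, size=min(cfg.spatial_n_lakes,
                                                 cfg.n_lakes), replace=False)
        allowed[i] = np.isin(lake_of, lakes)
        spatial_taxa.add(taxa[i])
    presence = (rng.random((cfg.n_taxa, cfg.n_samples)) < prob) & allowed

    # --- planted couplings ----------------------------------------------
    bins = np.array([assign_salinity_bin(s) for s in salinity])
    positive_pairs, negative_pairs = [], []
    k = 0
    for _ in range(cfg.n_planted_positive):
        i, j = k, k + 1
        k += 2
        match = rng.random(cfg.n_samples) < cfg.rho_positive
        presence[j, match] = presence[i, match]
        positive_pairs.append((taxa[i], taxa[j]))
    for _ in range(cfg.n_planted_negative):
        i, j = k, k + 1
        k += 2
        if cfg.rho_negative_by_bin is None:
            rho = np.full(cfg.n_samples, cfg.rho_negative)
        else:
            rho = np.array([cfg.rho_negative_by_bin.get(b, cfg.rho_negative)
                            for b in bins])
        suppress = presence[i] & (rng.random(cfg.n_samples) < rho)
        presence[j, suppress] = False
        negative_pairs.append((taxa[i], taxa[j]))

    # --- abundances -------------------------------------------------------
    raw = np.where(presence,
                   rng.lognormal(0.0, cfg.abundance_sigma,
                                 (cfg.n_taxa, cfg.n_samples)), 0.0)
    colsum = raw.sum(axis=0)
    rel = raw / np.maximum(colsum, 1e-300)

    truth = GroundTruth(positive_pairs=positive_pairs,
                        negative_pairs=negative_pairs,
                        guild_taxa={taxa[i] for i in guild_idx},
                        spatial_taxa=spatial_taxa)
    matrix = CommunityMatrix(taxa=taxa, samples=[s.sample_id for s in meta],
                             rel_abundance=rel)
    return matrix, meta, truth


def random_presence_fixed_margins(n_taxa: int, n_samples: int,
                                  occupancy, seed) -> np.ndarray:
    """Independent placement null: each taxon occupies its given number of
    samples uniformly at random (fixed row margins, free columns)."""
    rng = np.random.default_rng(seed)
    occ = np.asarray(occupancy, dtype=int)
    if occ.size != n_taxa:
        raise ValueError("one occupancy count per taxon required")
    out = np.zeros((n_taxa, n_samples), dtype=np.int8)
    for i, n in enumerate(occ):
        out[i, rng.choice(n_samples, size=n, replace=False)] = 1
    return out


# --------------------------------------------------------------------------
# Recovery scoring
# --------------------------------------------------------------------------

def recovery_metrics(classifications: list[PairClassification],
                     truth: GroundTruth) -> dict[str, dict[str, float]]:
    """Sensitivity/precision per truth class.

    A planted pair counts as recovered when it is significant with the
    correct sign AND labeled potential-biological.  A guild pair counts as
    recovered when it is significant and labeled environmental (or
    environmental-and-spatial) — the filter is *supposed* to absorb those.
    """
    pred_bio = {SIGN_POSITIVE: set(), SIGN_NEGATIVE: set()}
    sig_guild_env, sig_guild_all = set(), set()
    for c in classifications:
        pair = tuple(sorted((c.pair.taxon_a, c.pair.taxon_b)))
        if c.label == LABEL_BIOLOGICAL:
            pred_bio[c.pair.sign].add(pair)
        if truth.label(*pair) == TRUTH_GUILD:
            sig_guild_all.add(pair)
            if c.label in (LABEL_ENV, LABEL_BOTH):
                sig_guild_env.add(pair)

    out: dict[str, dict[str, float]] = {}
    for cls, planted, sign in ((TRUTH_POSITIVE, truth.positive_pairs,
                                SIGN_POSITIVE),
                               (TRUTH_NEGATIVE, truth.negative_pairs,
                                SIGN_NEGATIVE)):
        planted_set = {tuple(sorted(p)) for p in planted}
        hits = pred_bio[sign] & planted_set
        out[cls] = {
            "n_truth": len(planted_set),
            "sensitivity": (len(hits) / len(planted_set)
                            if planted_set else float("nan")),
            "precision": (len(hits) / len(pred_bio[sign])
                          if pred_bio[sign] else float("nan")),
        }
    out[TRUTH_GUILD] = {
        "n_truth": len(sig_guild_all),
        "sensitivity": (len(sig_guild_env) / len(sig_guild_all)
                        if sig_guild_all else float("nan")),
        "precision": float("nan"),
    }
    return out
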