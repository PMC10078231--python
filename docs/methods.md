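# Methods

## The inference chain

`cooxnet` treats a survey as a taxa × samples relative-abundance matrix
with per-sample metadata (lake, date, coordinates, and five environmental
variables: salinity in percent mass, temperature in °C, pH, dissolved
oxygen in mg/L, redox in mV). Presence is `rel_abundance > 0`; there is no
separate detection cutoff. The chain runs in five stages.

**1. Taxon filtering.** A taxon is kept when it occurs in more than 5 % of
samples and reaches a relative abundance strictly above 0.1 % in at least
one sample. "More than 5 %" is operationalized as the smallest integer
strictly greater than `0.05·N` — 6 occurrences for N = 116. The
per-salinity-bin reanalyses drop the occurrence rule (bins have far fewer
samples) but keep the abundance rule.

**2. Exact pairwise testing.** Under the null that each taxon occupies its
observed number of samples uniformly at random, the joint count is
hypergeometric. Both tails are inclusive of the observed count — the
conservative convention for a discrete test; the sign rule (positive if the
upper tail beats `P₀`, negative if the lower tail does) runs two one-sided
tests at level `P₀` each, so the procedure's size is bounded by `2·P₀` and
in practice stays near `P₀` only because attainable tail probabilities are
coarse for the low-occupancy taxa that dominate real communities. The pmf
is evaluated in exact integer arithmetic for N ≤ 2000 (the returned double
is correctly rounded) and in log-space beyond. Link strength
`s = log₁₀(P₀/P)` uses the tail probability of the assigned sign, since
the significance decision itself is tail-based; `P = 0` underflows are
capped at the smallest positive double with a warning. No multiple-testing
correction is applied across pairs, and no minimum-expected-overlap
pre-filter removes pairs; both choices keep the procedure faithful to how
such survey analyses are usually run, at the cost of a known type-I
background (quantified below in the null calibration).

**3. Confound attribution.** A positive pair's contrast is joint-presence
samples vs. all others (aggregation); a negative pair's is each taxon's
exclusive-presence samples (segregation), excluding joint and joint-absent
samples. Each environmental variable is tested independently with a
two-group one-way ANOVA at p < 0.05; coordinates are tested with a
two-group one-way MANOVA using Pillai's trace (for two groups the exact
relation `F = V/(1−V)·(n−3)/2` on (2, n−3) df). Both are computed in
closed form — a matrix-randomization null may run millions of these tiny
tests — and are verified against `scipy.stats.f_oneway` and statsmodels'
MANOVA in the test suite. Missing environmental values are dropped
per-test. Groups smaller than 2 (ANOVA) or 3 (MANOVA) yield NA, which
never counts as explanation; a pair with an empty contrast group is
excluded from networks and accounting as not classifiable. Collinear or
constant coordinates fall back to a one-dimensional ANOVA on the
informative axis. The ordered explanation summary greedily picks the
variable explaining the most still-unexplained significant pairs, then the
next, yielding a cumulative union curve, a space-only fraction and the
residual potential-biological fraction.

**4. Networks and metrics.** Edges are the potential-biological pairs of
one sign, weighted by link strength; nodes are exactly the incident taxa.
Diameter and average path length are computed on the largest connected
component with unweighted shortest paths (these networks are typically
disconnected; the component count is reported alongside). Modularity is
Newman modularity at resolution 1 of the best partition over ten seeded
Louvain restarts plus the deterministic CNM greedy partition — a single
Louvain run can trail an independent optimizer by more than the 0.02
cross-library tolerance the tests enforce. Degree heterogeneity is the
population coefficient of variation of the degree sequence (zero iff
regular); the moment ratio ⟨k²⟩/⟨k⟩² is available behind a switch.
Modularity is unweighted by default, with a weighted switch.
Taxonomic-group weight is a group's share of total weighted degree; its
representativeness is its share of presence-matrix 1-entries; their ratio
measures overrepresentation.

**5. Null models.** Two complementary nulls, 1000 replicates each by
default (configurable; runs below 100 are flagged underpowered). The
Erdős–Rényi ensemble draws random interactions among the *filtered-taxa
universe* with the observed expected edge count and derives each replicate
network by dropping isolated nodes — exactly how the observed network
arises from its pair list. This emergently preserves the derived networks'
node count and mean degree; drawing the same number of edges over only the
observed (incident) node count would force extra endpoint sharing and
bias modularity, path length and heterogeneity even on structureless data.
The low-level `erdos_renyi_null(n, E, B, seed)` primitive with
`p = 2E/(n(n−1))` is also exposed directly. The matrix-randomization
ensemble applies the curveball algorithm — repeatedly trading the
columns held by exactly one of two random rows, preserving all row and
column sums — with 5×(number of rows) trades per replicate, then reruns
the exact tests, optionally the confound filter (default on; off trades
fidelity for speed), and the network construction before measuring.
Empirical two-sided p-values use the add-one estimator
`p = 2·min(r_low+1, r_high+1)/(B+1)` capped at 1, with H/L direction flags
relative to the null median and the usual `*` p < 0.05 / `**` p < 0.001
codes. Degenerate (all-identical) null distributions are flagged.

The pipeline analyzes the full gradient plus the three salinity bins
([0, 2.5) %, [2.5, 5) %, [5, ∞) %; half-open so every value maps to one
bin, values below 0.1 % logged), skipping bins with fewer than 5 samples.
All randomness flows from one master seed through a spawned
`SeedSequence` tree (one child per scope, then per null model), so runs
are bit-reproducible.

## The synthetic-metacommunity generator

The generator emulates the survey design the chain assumes: 14 lakes with
fixed coordinates, 116 samples, salinity 0.1–40 %. Lake mean salinities
are log-uniform within each of the three bins (5/5/4 lakes) and samples
are allocated round-robin over bins, giving near-balanced bins (≈ 39/38/39)
as in a designed gradient survey; within-lake temporal jitter is lognormal
with sd 0.12 log₁₀ units, inset from bin edges so samples rarely migrate.
Occupancy follows Gaussian niches on log₁₀ salinity,
`P(present) = p_max·exp(−(log₁₀S − μ)²/2σ²)`, with peak occupancies drawn
log-uniformly on [0.03, 0.8] — occupancy distributions of real communities
are strongly right-skewed, and this is also the regime in which the
discrete pairwise test is conservative. 30 % of non-planted taxa are
narrow-niche guild specialists (σ = 0.3), the rest broad generalists
(σ = 2.5); 10 % are confined to three random lakes. The other four
environmental covariates are linear in log₁₀ salinity with small Gaussian
noise, reproducing the strong collinearity of salinity-dominated systems;
with independent covariates the union of five 0.05-level ANOVAs would
absorb ~25 % of genuinely environment-independent pairs.

Planted interactions are environment-independent by construction: the
paired taxa have flat occupancy (drawn from 0.45 ± 0.15 — heterogeneous,
because identical margins make the discrete test's attainable p-values
coincide across pairs and the type-I edge count jumpy). A positive pair
copies the partner's presence with probability ρ⁺ per sample; a negative
pair suppresses the partner where the first is present with probability
ρ⁻, optionally per salinity bin. Defaults: 30 positive and 10 negative
pairs at ρ = 0.8. Abundances conditional on presence are lognormal
(σ = 1), renormalized per sample.

What the generator does **not** emulate: read-count noise, PCR/primer
bias, compositional closure artifacts, temporal autocorrelation within a
lake, or taxon-abundance correlation between interacting partners. Passing
recovery tests therefore show that the chain detects and correctly labels
presence–absence-level couplings under realistic occupancy and confounding
structure — not that it is robust to sequencing artifacts.

## Calibration and recovery checks

- **Type-I**: on 116-sample × 200-taxon matrices with fixed right-skewed
  (log-uniform) margins and independent placement, the mean significant
  fraction at P₀ = 0.01 measures ≈ 0.007. With common-heavy uniform
  margins the two-tailed procedure can exceed P₀ (bounded by 2·P₀).
- **Null calibration**: on structureless communities the observed topology
  is a draw from both null models; ≥ 90 % (measured ≈ 96–98 %) of
  per-metric empirical tests are non-significant. The curveball uniformity
  chi-square uses a thinned chain (every 10th state) because consecutive
  chain states are autocorrelated.
- **Recovery** (default settings, seed 1): ≥ 70 % of planted pairs return
  significant, correctly signed and potential-biological; ≥ 70 % of
  significant guild pairs are labeled environmental.
- **Stress-gradient demonstration**: with ρ⁻ = 0.95/0.7/0.05 across bins
  and constant ρ⁺, negative subnetworks shrink monotonically while
  positive subnetworks stay within ±20 % of their mean size. The
  demonstration uses a compact community (120 taxa, 30+30 planted pairs,
  well-occupied planted taxa) so the planted signal dominates the pairwise
  type-I background at per-bin sample sizes near 38. This demonstrates
  what the chain reports under that regime; it does not validate the
  generator.

Problem sizes in the test suite and acceptance script (20 calibration
runs, 60–100 null replicates, 50-graph cross-library sweeps) are chosen to
make each check statistically meaningful at interactive runtimes; the
pipeline defaults remain 1000 replicates.

## Known limitations

- The confound framework cannot split environment from space under strong
  spatial autocorrelation; the joint label is reported without further
  decomposition.
- ANOVA/MANOVA p-values assume independent samples; repeated sampling of
  the same lakes violates this, and no mixed-effects correction is
  attempted (matching the standard practice the chain reproduces).
- The exact test conditions on margins and ignores abundance information;
  correlation-based association methods are deliberately out of scope.
- With ~10⁴–10⁶ pairs and no multiplicity correction, networks built from
  weak-signal data contain a predictable type-I edge background; the
  matrix-randomization null quantifies it.
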