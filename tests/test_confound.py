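"""Environmental/spatial attribution: group contrasts, ANOVA/MANOVA,
labels and the ordered explanation summary."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

import cooxnet as cx
from cooxnet.community_data import ENV_VARIABLES
from cooxnet.confound import (LABEL_BIOLOGICAL, LABEL_BOTH, LABEL_ENV,
                              LABEL_NA, LABEL_SPATIAL, PairClassification,
                              _label)
from cooxnet.cooccur import PairTest, SIGN_NEGATIVE, SIGN_POSITIVE


def make_pair(sign, a="tA", b="tB"):
    return PairTest(taxon_a=a, taxon_b=b, n_samples=6, occ_a=3, occ_b=3,
                    j_obs=3 if sign == SIGN_POSITIVE else 0,
                    p_lt=0.5, p_gt=0.005, sign=sign, strength=1.0)


class TestPairGroups:
    def test_positive_pair_joint_vs_rest(self, tiny_matrix):
        g1, g2 = cx.pair_groups(make_pair(SIGN_POSITIVE), tiny_matrix)
        assert sorted(g1) == [0, 1, 2]
        assert sorted(g2) == [3, 4, 5]

    def test_negative_pair_exclusive_sites(self, tiny_matrix):
        pair = make_pair(SIGN_NEGATIVE, a="tA", b="tC")
        g1, g2 = cx.pair_groups(pair, tiny_matrix)
        assert sorted(g1) == [0, 1, 2]  # tA only
        assert sorted(g2) == [3, 4, 5]  # tC only

    def test_random_pair_rejected(self, tiny_matrix):
        pair = make_pair(SIGN_POSITIVE)
        object.__setattr__(pair, "sign", "random")
        with pytest.raises(ValueError):
            cx.pair_groups(pair, tiny_matrix)

    def test_degenerate_negative_contrast_flagged_na(self):
        # tB occurs nowhere alone: G2 empty -> not classifiable
        rel = np.array([[0.5, 0.5, 0.0], [0.5, 0.0, 0.0]])
        m = cx.CommunityMatrix(taxa=["tA", "tB"], samples=["s0", "s1", "s2"],
                               rel_abundance=rel)
        pair = PairTest("tA", "tB", 3, 2, 1, 1, 0.9, 0.9,
                        SIGN_NEGATIVE, 1.0)
        meta = [cx.SampleMetadata(f"s{i}", "L1", None, 0, 0, 1.0,
                                  20, 8, 6, 100) for i in range(3)]
        c = cx.classify_pair(pair, meta, m)
        assert c.label == LABEL_NA
        assert c.group_sizes[1] == 0


class TestEnvAnova:
    def test_hand_computed_F_and_p(self):
        """{1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5 on (1, 4)."""
        F, p = cx.env_anova([1, 2, 3], [4, 5, 6])
        assert F == pytest.approx(13.5, abs=1e-12)
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_identical_constant_groups(self):
        F, p = cx.env_anova([2, 2, 2], [2, 2, 2])
        assert (F, p) == (0.0, 1.0)

    def test_distinct_constant_groups(self):
        F, p = cx.env_anova([2, 2, 2], [3, 3, 3])
        assert p == 0.0 and math.isinf(F)

    def test_small_group_gives_nan(self):
        F, p = cx.env_anova([1.0], [2.0, 3.0])
        assert math.isnan(F) and math.isnan(p)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            g1 = rng.normal(0, 1, rng.integers(2, 20))
            g2 = rng.normal(0.5, 2, rng.integers(2, 20))
            F, p = cx.env_anova(g1, g2)
            ref = scipy.stats.f_oneway(g1, g2)
            assert F == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_missing_values_dropped(self):
        F, p = cx.env_anova([1, 2, 3, np.nan], [4, np.nan, 5, 6])
        F2, p2 = cx.env_anova([1, 2, 3], [4, 5, 6])
        assert (F, p) == (F2, p2)


class TestSpatialManova:
    def test_separated_clouds_significant(self):
        rng = np.random.default_rng(7)
        c1 = rng.normal((0, 0), 1, (10, 2))
        c2 = rng.normal((100, 100), 1, (10, 2))
        assert cx.spatial_manova(c1, c2) < 1e-3

    def test_same_cloud_typically_null(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(40):
            pts = rng.normal(0, 1, (20, 2))
            ps.append(cx.spatial_manova(pts[:10], pts[10:]))
        assert np.mean(np.array(ps) < 0.05) <= 0.15

    def test_degenerate_axis_reduces_to_anova(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(0, 1, 8), rng.normal(2, 1, 8)
        c1 = np.column_stack([x1, np.full(8, 5.0)])
        c2 = np.column_stack([x2, np.full(8, 5.0)])
        assert cx.spatial_manova(c1, c2) == pytest.approx(
            cx.env_anova(x1, x2)[1], rel=1e-9)

    def test_small_groups_nan(self):
        assert math.isnan(cx.spatial_manova([(0, 0), (1, 1)],
                                            [(2, 2), (3, 3), (4, 4)]))

    def test_agrees_with_statsmodels_pillai(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA
        rng = np.random.default_rng(5)
        for _ in range(10):
            n1, n2 = rng.integers(5, 15, 2)
            c1 = rng.normal(0, 1, (n1, 2))
            c2 = rng.normal(0.8, 1.3, (n2, 2))
            df = pd.DataFrame(np.vstack([c1, c2]), columns=["x", "y"])
            df["g"] = ["a"] * n1 + ["b"] * n2
            res = MANOVA.from_formula("x + y ~ g", data=df).mv_test()
            ref = res.results["g"]["stat"].loc["Pillai's trace",
                                               "Pr > F"]
            assert cx.spatial_manova(c1, c2) == pytest.approx(float(ref),
                                                              rel=1e-6)


class TestLabels:
    def base_pvalues(self, **over):
        p = {v: 0.5 for v in ENV_VARIABLES}
        p.update(over)
        return p

    def test_environmental(self):
        assert _label(self.base_pvalues(salinity=0.001), 0.4) == LABEL_ENV

    def test_potential_biological(self):
        assert _label(self.base_pvalues(), 0.2) == LABEL_BIOLOGICAL

    def test_both(self):
        assert _label(self.base_pvalues(salinity=0.03), 0.01) == LABEL_BOTH

    def test_spatial_only(self):
        assert _label(self.base_pvalues(), 0.01) == LABEL_SPATIAL

    def test_nan_does_not_explain(self):
        p = {v: float("nan") for v in ENV_VARIABLES}
        assert _label(p, 0.4) == LABEL_BIOLOGICAL
        assert _label(p, float("nan")) == LABEL_NA

    def test_partition_on_synthetic_data(self, default_classifications):
        """Every classified pair carries exactly one of the five labels."""
        classifications, _, _, _ = default_classifications
        labels = {LABEL_ENV, LABEL_SPATIAL, LABEL_BOTH, LABEL_BIOLOGICAL,
                  LABEL_NA}
        counts = {lab: sum(c.label == lab for c in classifications)
                  for lab in labels}
        assert all(c.label in labels for c in classifications)
        assert sum(counts.values()) == len(classifications)


def fake_classification(env_sig=(), spatial=False):
    p = {v: (0.01 if v in env_sig else 0.5) for v in ENV_VARIABLES}
    return PairClassification(
        pair=make_pair(SIGN_POSITIVE), env_pvalues=p,
        spatial_pvalue=0.01 if spatial else 0.5,
        label=_label(p, 0.01 if spatial else 0.5), group_sizes=(3, 3))


class TestExplanationSummary:
    def test_single_variable_saturation(self):
        cls = [fake_classification(env_sig=("salinity",)) for _ in range(5)]
        s = cx.explanation_summary(cls)
        assert s.variables[0] == "salinity"
        assert s.cumulative == (1.0,) * 5
        assert s.space_only_fraction == 0.0
        assert s.biological_fraction == 0.0

    def test_nothing_explained(self):
        cls = [fake_classification() for _ in range(4)]
        s = cx.explanation_summary(cls)
        assert s.biological_fraction == 1.0
        assert s.cumulative[-1] == 0.0

    def test_greedy_union_ordering(self):
        """10 pairs by salinity, 4 by temperature of which 2 also by
        salinity: order (salinity, temperature), increments (10, 2)."""
        cls = ([fake_classification(env_sig=("salinity",))
                for _ in range(8)]
               + [fake_classification(env_sig=("salinity", "temperature"))
                  for _ in range(2)]
               + [fake_classification(env_sig=("temperature",))
                  for _ in range(2)])
        s = cx.explanation_summary(cls)
        assert s.variables[0] == "salinity" and s.variables[1] == "temperature"
        assert s.counts[0] == 10 and s.counts[1] == 2
        assert s.cumulative[1] == pytest.approx(1.0)

    def test_matches_brute_force_union(self, default_classifications):
        """Greedy increments and the final union agree with set arithmetic."""
        classifications, _, _, _ = default_classifications
        s = cx.explanation_summary(classifications)
        usable = [c for c in classifications if c.label != LABEL_NA]
        explained_sets = [set(c.explaining_variables) for c in usable]
        union = sum(1 for e in explained_sets if e)
        assert s.cumulative[-1] == pytest.approx(union / len(usable))
        # cumulative curve is non-decreasing and fractions partition
        assert all(b >= a - 1e-12 for a, b in
                   zip(s.cumulative, s.cumulative[1:]))
        assert (s.cumulative[-1] + s.space_only_fraction
                + s.biological_fraction) == pytest.approx(1.0)

    def test_accounting_on_synthetic_data(self, default_classifications):
        classifications, _, _, _ = default_classifications
        s = cx.explanation_summary(classifications)
        n_env = sum(c.label in (LABEL_ENV, LABEL_BOTH)
                    for c in classifications)
        assert s.cumulative[-1] == pytest.approx(n_env / s.n_pairs)
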