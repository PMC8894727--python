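"""Core metric tests, anchored by an independent exhaustive-permutation
oracle on tiny trees."""

import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest

import bntifeat as bf
from bntifeat.feature_bnti import _ntd_matrix
from bntifeat.relational_io import ValidationError


def brute_force_pairwise_null(D, a_idx, present_idx, f_weight=1.0):
    """Enumerate every tip permutation and return the per-permutation
    weighted nearest-taxon distance of feature ``a`` to the present set.
    Pure-python path, independent of the package's vectorised engine."""
    n = D.shape[0]
    vals = []
    for perm in itertools.permutations(range(n)):
        d = min(D[perm[a_idx], perm[b]] for b in present_idx)
        vals.append(f_weight * d)
    return np.array(vals)


class TestNearestTaxonDistance:
    def test_cross_cherry(self, four_tip_tree, four_tip_D):
        df = pd.DataFrame([[1.0, 0, 0, 0], [0.0, 0, 1, 1]],
                          index=["S1", "S2"], columns=list("ABCD"))
        t = bf.CommunityTable(df)
        assert bf.nearest_taxon_distance("A", "S2", t, four_tip_D) == 4

    def test_conspecific_zero_vs_excluded(self, four_tip_D):
        df = pd.DataFrame([[1.0, 0, 1, 0]], index=["S1"], columns=list("ABCD"))
        t = bf.CommunityTable(df)
        assert bf.nearest_taxon_distance("A", "S1", t, four_tip_D) == 0
        assert bf.nearest_taxon_distance(
            "A", "S1", t, four_tip_D, allow_conspecifics=False) == 4

    def test_no_comparator_is_nan(self, four_tip_D):
        df = pd.DataFrame([[1.0, 0, 0, 0]], index=["S1"], columns=list("ABCD"))
        t = bf.CommunityTable(df)
        assert math.isnan(bf.nearest_taxon_distance(
            "A", "S1", t, four_tip_D, allow_conspecifics=False))


class TestFeatureBmntd:
    def test_pairwise_single_term(self, cherry_table, four_tip_D):
        v = bf.feature_bmntd("A", bf.Scope("pairwise", ("S1", "S2"),
                                           focal="S1"),
                             cherry_table, four_tip_D)
        assert v["S2"] == pytest.approx(0.5 * 4)

    def test_dataset_hand_value(self, cherry_table, four_tip_D):
        # A present only in S1 (w=0.5); ntd over {S1, S2} = (0 + 4)/2
        v = bf.feature_bmntd("A", bf.Scope("dataset", ("S1", "S2")),
                             cherry_table, four_tip_D)
        assert v == pytest.approx(0.5 * 2.0)

    def test_absent_feature_nan(self, four_tip_D):
        df = pd.DataFrame([[1.0, 1, 0, 0]], index=["S1"], columns=list("ABCD"))
        t = bf.CommunityTable(df)
        v = bf.feature_bmntd("C", bf.Scope("dataset", ("S1",)), t, four_tip_D)
        assert math.isnan(v)


class TestNullDistribution:
    def test_exhaustive_enumeration_matches_brute_force(
            self, singleton_table, four_tip_D):
        cfg = bf.NullConfig(exhaustive=True, seed=0)
        nulls = bf.null_distribution(
            "A", bf.Scope("pairwise", ("S1", "S2"), focal="S1"),
            singleton_table, four_tip_D, cfg)["S2"]
        assert len(nulls) == 24
        # within-cherry distance 2 for 8 of 24 ordered assignments, 4 else
        assert np.sum(nulls == 2) == 8
        assert np.sum(nulls == 4) == 16
        oracle = brute_force_pairwise_null(four_tip_D.values, 0, [1])
        assert np.array_equal(np.sort(nulls), np.sort(oracle))

    def test_seed_determinism(self, singleton_table, four_tip_D):
        cfg = bf.NullConfig(n_null=50, seed=7)
        sc = bf.Scope("pairwise", ("S1", "S2"), focal="S1")
        a = bf.null_distribution("A", sc, singleton_table, four_tip_D, cfg)
        b = bf.null_distribution("A", sc, singleton_table, four_tip_D, cfg)
        assert np.array_equal(a["S2"], b["S2"])

    def test_zero_noise_gives_pure_shuffled_values(self, singleton_table,
                                                   four_tip_D):
        cfg = bf.NullConfig(n_null=50, seed=7, noise_low=0.0, noise_high=0.0)
        nulls = bf.null_distribution(
            "A", bf.Scope("pairwise", ("S1", "S2"), focal="S1"),
            singleton_table, four_tip_D, cfg)["S2"]
        assert set(np.unique(nulls)) <= {2.0, 4.0}

    def test_exhaustive_above_cap_rejected(self):
        tree = bf.random_tree(12, 1)
        table = bf.neutral_communities(tree, 3, 0.8, 2)
        with pytest.raises(ValidationError, match="sampled"):
            bf.run(table, tree.cophenetic(), "dataset",
                   cfg=bf.NullConfig(exhaustive=True))

    def test_sampled_moments_converge_to_exhaustive(self, singleton_table,
                                                    four_tip_D):
        """On a tiny tree the sampled null must agree with full enumeration
        within Monte-Carlo error (3 standard errors)."""
        sc = bf.Scope("pairwise", ("S1", "S2"), focal="S1")
        ex = bf.null_distribution("A", sc, singleton_table, four_tip_D,
                                  bf.NullConfig(exhaustive=True))["S2"]
        n = 4000
        sm = bf.null_distribution("A", sc, singleton_table, four_tip_D,
                                  bf.NullConfig(n_null=n, seed=3))["S2"]
        se = ex.std(ddof=1) / math.sqrt(n)
        assert abs(sm.mean() - ex.mean()) < 3 * se


class TestFeatureBnti:
    def test_exhaustive_z_matches_oracle(self, singleton_table, four_tip_D):
        rec = bf.feature_bnti("A", bf.Scope("pairwise", ("S1", "S2"),
                                            focal="S1"),
                              singleton_table, four_tip_D,
                              bf.NullConfig(exhaustive=True))["S2"]
        oracle = brute_force_pairwise_null(four_tip_D.values, 0, [1])
        z = (2.0 - oracle.mean()) / oracle.std(ddof=1)
        assert rec.bnti == pytest.approx(z, abs=1e-12)
        assert rec.bnti == pytest.approx(-1.3844, abs=1e-4)
        # population-SD convention gives exactly -sqrt(2) on this fixture
        z_pop = (2.0 - oracle.mean()) / oracle.std(ddof=0)
        assert z_pop == pytest.approx(-math.sqrt(2), abs=1e-12)

    def test_record_invariant_z_formula(self, small_instance):
        table, D = small_instance
        recs = bf.run(table, D, "dataset", cfg=bf.NullConfig(n_null=59, seed=1))
        for r in recs:
            if r.category in (bf.ContributionCategory.ABSENT,
                              bf.ContributionCategory.UNDEFINED):
                continue
            assert r.bnti == pytest.approx(
                (r.bmntd_obs - r.null_mean) / r.null_sd, rel=1e-12)

    def test_conspecific_everywhere_quirk(self, four_tip_D, caplog):
        """A feature present in every sample has observed 0 and null 0 + eps;
        the uniform-noise moments pin z near -(mean/sd) = -2.6."""
        df = pd.DataFrame([[1.0, 1, 0, 0], [1.0, 0, 1, 0]],
                          index=["S1", "S2"], columns=list("ABCD"))
        t = bf.CommunityTable(df)
        with caplog.at_level(logging.WARNING, logger="bntifeat"):
            recs = bf.run(t, four_tip_D, "dataset",
                          cfg=bf.NullConfig(n_null=999, seed=5))
        rec = {r.feature: r for r in recs}["A"]
        assert rec.bmntd_obs == 0
        assert -2.8 < rec.bnti < -2.4
        assert any("conspecific in every sample" in m for m in caplog.messages)


class TestClassify:
    @pytest.mark.parametrize("z,cat", [
        (2.5, bf.ContributionCategory.SIG_DIVERGENCE),
        (-1.5, bf.ContributionCategory.CONVERGENCE),
        (0.99, bf.ContributionCategory.INSIGNIFICANT),
        (-0.99, bf.ContributionCategory.INSIGNIFICANT),
        (1.0, bf.ContributionCategory.DIVERGENCE),
        (-1.0, bf.ContributionCategory.CONVERGENCE),
        (2.0, bf.ContributionCategory.SIG_DIVERGENCE),
        (-2.0, bf.ContributionCategory.SIG_CONVERGENCE),
        (float("nan"), bf.ContributionCategory.UNDEFINED),
        (None, bf.ContributionCategory.UNDEFINED),
    ])
    def test_thresholds(self, z, cat):
        assert bf.classify(z) is cat


class TestRunDriver:
    def test_group_mode_cardinality(self):
        tree = bf.random_tree(20, 3)
        table = bf.neutral_communities(tree, 6, 0.6, 4)
        groups = {s: ("G1" if i < 3 else "G2")
                  for i, s in enumerate(table.samples)}
        recs = bf.run(table, tree.cophenetic(), "group", groups=groups,
                      cfg=bf.NullConfig(n_null=19, seed=0))
        assert len(recs) == 2 * 20
        assert {r.scope_label for r in recs} == {"G1", "G2"}

    def test_dataset_mode_cardinality_and_absent_flag(self, four_tip_D):
        df = pd.DataFrame([[1.0, 1, 0, 0], [1.0, 1, 0, 0]],
                          index=["S1", "S2"], columns=list("ABCD"))
        recs = bf.run(bf.CommunityTable(df), four_tip_D, "dataset",
                      cfg=bf.NullConfig(n_null=19, seed=0))
        assert len(recs) == 4
        cats = {r.feature: r.category for r in recs}
        assert cats["C"] is bf.ContributionCategory.ABSENT

    def test_pairwise_mode_cardinality(self):
        tree = bf.random_tree(10, 5)
        table = bf.neutral_communities(tree, 5, 0.9, 6)
        recs = bf.run(table, tree.cophenetic(), "pairwise",
                      focal=table.samples[0],
                      cfg=bf.NullConfig(n_null=19, seed=0))
        per_feature = pd.Series([r.feature for r in recs]).value_counts()
        assert (per_feature == 4).all()

    def test_focal_missing_raises(self, small_instance):
        table, D = small_instance
        with pytest.raises(ValidationError, match="focal"):
            bf.run(table, D, "pairwise", focal="nope")

    def test_unknown_group_sample_raises(self, small_instance):
        table, D = small_instance
        with pytest.raises(ValidationError, match="unknown"):
            bf.run(table, D, "group", groups={"nope": "G1"})


class TestInvariants:
    def test_abundance_invariance(self):
        """Counts, relative and presence tables give identical z: abundance
        weights multiply observed and null identically and cancel."""
        tree = bf.random_tree(25, 11)
        table = bf.neutral_communities(tree, 6, 0.5, 12)
        D = tree.cophenetic()
        cfg = bf.NullConfig(n_null=199, seed=13)
        rel = bf.to_relative(table)
        pres = bf.CommunityTable(
            (table.data > 0).astype(float), "presence")
        z = {}
        for name, t in (("counts", table), ("relative", rel),
                        ("presence", pres)):
            recs = bf.run(t, D, "dataset", cfg=cfg)
            z[name] = np.array([r.bnti for r in recs])
        for name in ("relative", "presence"):
            both = np.isfinite(z["counts"]) & np.isfinite(z[name])
            assert both.sum() > 10
            assert np.allclose(z["counts"][both], z[name][both], atol=1e-9)

    def test_feature_community_aggregation_identity(self, small_instance):
        """Directed feature-level values sum to twice the community
        beta-MNTD for every sample pair."""
        table, D = small_instance
        cm = bf.community_bmntd_matrix(table, D).to_frame()
        cfg = bf.NullConfig(n_null=1, seed=0)
        obs = {}
        for focal in table.samples:
            recs = bf.run(table, D, "pairwise", focal=focal, cfg=cfg)
            for r in recs:
                if not math.isnan(r.bmntd_obs):
                    obs[(focal, r.partner, r.feature)] = r.bmntd_obs
        for i in table.samples:
            for j in table.samples:
                if i >= j:
                    continue
                s_ij = sum(v for (f, p, _), v in obs.items()
                           if f == i and p == j)
                s_ji = sum(v for (f, p, _), v in obs.items()
                           if f == j and p == i)
                assert s_ij + s_ji == pytest.approx(2 * cm.loc[i, j],
                                                    abs=1e-10)
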