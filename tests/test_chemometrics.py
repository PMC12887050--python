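"""Tests for the chemometrics pipeline: filtering through enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomics import chemometrics as chem
from cardiomics.flim_synth import ValidationError
from cardiomics.metabo_synth import EffectSpec, FeatureTable, synth_table, toy_pathways


def _table(values, groups, qc_flags, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i:04d}" for i in range(values.shape[1])]
    samples = [f"s{i}" for i in range(values.shape[0])]
    intens = pd.DataFrame(values, index=samples, columns=features)
    meta = pd.DataFrame({"group": groups, "is_qc": qc_flags}, index=samples)
    fmeta = pd.DataFrame({"name": features}, index=features)
    return FeatureTable(intens, meta, fmeta)


class TestFilterFeatures:
    def _demo(self):
        # 6 biological + 3 QC samples, 3 features:
        #   F0: 70 % missing; F1: stable QC (RSD ~ 0.23); F2: noisy QC (RSD 0.5)
        vals = np.array(
            [
                [np.nan, 5.0, 5.0],
                [np.nan, 6.0, 6.0],
                [np.nan, 5.5, 5.5],
                [np.nan, 5.2, 5.2],
                [np.nan, 5.8, 5.8],
                [1.0, 5.4, 5.4],
                [np.nan, 10.0, 10.0],
                [1.2, 13.0, 20.0],
                [1.1, 16.0, 30.0],
            ]
        )
        return _table(vals, ["a"] * 3 + ["b"] * 3 + ["QC"] * 3,
                      [False] * 6 + [True] * 3)

    def test_missing_and_rsd_rules(self):
        out, report = chem.filter_features(self._demo())
        assert list(out.intensities.columns) == ["F0001"]
        assert report.n_removed_missing == 1  # F0: 7/9 missing
        assert report.n_removed_qc_rsd == 1  # F2: QC {10,20,30} RSD 0.5
        # F1: QC {10,13,16} -> RSD 3/13 = 0.23 < 0.30, kept

    def test_idempotent(self):
        once, _ = chem.filter_features(self._demo())
        twice, rep = chem.filter_features(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)
        assert rep.n_removed_missing == rep.n_removed_qc_rsd == 0

    def test_no_qc_skips_rsd_rule_with_warning(self):
        t = _table([[1.0, 2.0]] * 4, ["a", "a", "b", "b"], [False] * 4)
        with pytest.warns(UserWarning, match="QC"):
            out, rep = chem.filter_features(t)
        assert rep.n_removed_qc_rsd == 0


class TestNormalize:
    def test_autoscale_gives_zero_mean_unit_sd(self):
        table, _ = synth_table(50, seed=0)
        norm = chem.normalize(chem.impute_half_min(table))
        X = norm.table.intensities
        assert np.allclose(X.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_median_norm_identity_up_to_constant_for_proportional_samples(self):
        vals = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [4.0, 8.0, 12.0]])
        t = _table(vals, ["a", "a", "b"], [False] * 3)
        out = chem.normalize(t, steps=("median_norm",)).table.intensities.to_numpy()
        assert np.allclose(out, out[0][None, :])

    def test_hand_computed_two_by_two(self):
        # samples (4, 16) and (1, 9): medians 10 and 5, overall median 7.5
        t = _table([[4.0, 16.0], [1.0, 9.0]], ["a", "b"], [False, False])
        out = chem.normalize(t, steps=("median_norm", "sqrt_transform")).table
        expected = np.sqrt(np.array([[4 / 10, 16 / 10], [1 / 5, 9 / 5]]) * 7.5)
        assert np.allclose(out.intensities.to_numpy(), expected)

    def test_zero_median_names_offending_sample(self):
        t = _table([[0.0, 0.0], [1.0, 2.0]], ["a", "b"], [False, False])
        with pytest.raises(ValidationError, match="s0"):
            chem.normalize(t, steps=("median_norm",))


class TestPca:
    def test_collinear_data_loads_on_single_component(self):
        base = np.linspace(1, 5, 8)
        vals = np.column_stack([base, 2 * base, -base])
        t = _table(vals, ["a"] * 4 + ["b"] * 4, [False] * 8)
        res = chem.pca(t, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_splits_variance_evenly(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(500, 2))
        t = _table(vals, ["a"] * 250 + ["b"] * 250, [False] * 500)
        res = chem.pca(t, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.06)

    def test_scores_orthogonal(self):
        table, _ = synth_table(30, seed=1)
        res = chem.pca(chem.impute_half_min(table), n_components=3)
        S = res.scores.to_numpy()
        G = S.T @ S
        norms = np.sqrt(np.diag(G))
        cosines = G / np.outer(norms, norms)
        assert np.allclose(cosines - np.eye(len(G)), 0.0, atol=1e-6)

    def test_missing_values_error_mentions_imputation(self):
        table, _ = synth_table(30, effect=EffectSpec(missing_rate=0.3), seed=2)
        with pytest.raises(ValidationError, match="impute"):
            chem.pca(table)


class TestPlsda:
    def _normed(self, n_features=50, effects=None, seed=0):
        table, _ = synth_table(
            n_features, effect=EffectSpec(log2_effects=effects or {}, missing_rate=0.0),
            seed=seed,
        )
        return chem.normalize(chem.impute_half_min(table)).table

    def test_vip_identity_sum_of_squares_equals_n_features(self):
        t = self._normed(effects={0: 3.0, 5: -2.0}, seed=3)
        model = chem.plsda(t)
        assert float((model.vip**2).sum()) == pytest.approx(t.intensities.shape[1], rel=1e-9)

    def test_single_discriminant_feature_attains_max_vip(self):
        t = self._normed(n_features=51, effects={7: 4.0}, seed=4)
        model = chem.plsda(t)
        assert model.vip.idxmax() == "F0007"

    def test_univariate_x_has_unit_vip(self):
        vals = np.array([[1.0], [1.2], [0.9], [3.0], [3.3], [2.8]])
        t = _table(vals, ["a"] * 3 + ["b"] * 3, [False] * 6)
        model = chem.plsda(t, n_components=1)
        assert model.vip.iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_component_truncation_warns(self):
        t = self._normed(seed=6)
        with pytest.warns(UserWarning, match="truncated"):
            chem.plsda(t, n_components=10)


class TestCrossValidate:
    def test_separated_groups_predict_well(self):
        # ~40 % of features shifted by |log2| = 3 between groups, mimicking a
        # strongly remodelled metabolome
        table, _ = synth_table(
            60, effect=EffectSpec(log2_effects={i: 3.0 * (-1) ** i for i in range(25)},
                                  missing_rate=0.0, replicate_cv=0.15),
            seed=7,
        )
        t = chem.normalize(chem.impute_half_min(table)).table
        cv = chem.cross_validate(t)
        assert cv.folds == "loo"  # triplicate design -> leave-one-out
        assert cv.q2 > 0.8
        assert cv.r2 >= cv.q2

    def test_pure_noise_labels_do_not_predict(self):
        table, _ = synth_table(60, effect=EffectSpec(missing_rate=0.0), seed=8)
        t = chem.normalize(chem.impute_half_min(table)).table
        rng = np.random.default_rng(0)
        q2s = []
        for _ in range(10):
            labels = pd.Series(
                rng.permutation(t.groups.to_numpy()), index=t.biological.index
            )
            q2s.append(chem.cross_validate(t, labels).q2)
        assert np.median(q2s) <= 0.0

    def test_single_sample_group_is_error(self):
        table, _ = synth_table(10, seed=9)
        t = chem.impute_half_min(table)
        labels = pd.Series(["a"] + ["b"] * 5, index=t.biological.index)
        with pytest.raises(ValidationError, match=">= 2"):
            chem.cross_validate(t, labels)


def brute_force_bh(p):
    """Textbook BH step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return q


class TestUnivariate:
    def test_bh_hand_case(self):
        q = chem.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bh_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        assert np.allclose(chem.benjamini_hochberg(p), brute_force_bh(p))

    def test_identically_distributed_groups_not_significant(self):
        table, _ = synth_table(40, effect=EffectSpec(missing_rate=0.0), seed=0)
        norm = chem.normalize(chem.impute_half_min(table))
        res = chem.univariate(norm.table, fc_table=norm.stages["median_norm"])
        assert not res.table["significant"].any()
        assert res.table["q"].median() > 0.5

    def test_zero_within_group_variance_flagged(self):
        vals = np.tile(np.array([[5.0, 8.0]]), (6, 1))
        t = _table(vals, ["a"] * 3 + ["b"] * 3, [False] * 6)
        res = chem.univariate(t)
        assert res.table["p"].isna().all()
        assert not res.table["significant"].any()

    def test_three_way_rule_applied_when_vip_given(self):
        table, _ = synth_table(
            40, effect=EffectSpec(log2_effects={0: 4.0}, missing_rate=0.0), seed=10
        )
        norm = chem.normalize(chem.impute_half_min(table))
        model = chem.plsda(norm.table)
        res = chem.univariate(norm.table, fc_table=norm.stages["median_norm"], vip=model.vip)
        assert "VIP" in res.rule
        sig = res.table[res.table["significant"]]
        assert (sig["vip"] > 1.0).all() and (sig["p"] < 0.05).all() and (sig["q"] < 0.05).all()

    def test_planted_effect_usually_significant(self):
        """A 3-log2-unit shift at n = 3/group passes the three-way rule in
        at least 90 % of seeds."""
        hits = 0
        n_seeds = 50
        planted = {i: 3.0 * (-1) ** i for i in range(8)}  # ~20 % of the metabolome
        for seed in range(n_seeds):
            table, _ = synth_table(
                40, effect=EffectSpec(log2_effects=planted, missing_rate=0.0), seed=seed
            )
            norm = chem.normalize(chem.impute_half_min(table))
            model = chem.plsda(norm.table)
            res = chem.univariate(
                norm.table, fc_table=norm.stages["median_norm"], vip=model.vip
            )
            hits += bool(res.table.loc["F0000", "significant"])
        assert hits >= 0.9 * n_seeds

    def test_fold_change_sign_tracks_direction(self):
        table, _ = synth_table(
            30, effect=EffectSpec(log2_effects={0: 2.0, 1: -2.0}, missing_rate=0.0), seed=11
        )
        norm = chem.normalize(chem.impute_half_min(table))
        res = chem.univariate(norm.table, fc_table=norm.stages["median_norm"])
        assert res.table.loc["F0000", "log2_fc"] > 0 > res.table.loc["F0001", "log2_fc"]


def enumerate_hypergeom_p(M, K, n, k_obs):
    """P[X >= k_obs] by exhaustive enumeration of all C(M, n) query draws."""
    universe = range(M)
    pathway = set(range(K))
    hits_ge = total = 0
    for combo in itertools.combinations(universe, n):
        total += 1
        if len(pathway & set(combo)) >= k_obs:
            hits_ge += 1
    return hits_ge / total


class TestOra:
    def test_matches_exhaustive_enumeration(self):
        universe = [f"F{i}" for i in range(20)]
        library = {"pw": universe[:5]}
        query = universe[:3] + [universe[10]]  # overlap 3
        res = chem.ora_enrichment(query, library, universe)
        expected = enumerate_hypergeom_p(20, 5, 4, 3)
        assert res.table.loc["pw", "p"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.032, abs=0.0005)

    @pytest.mark.parametrize("M,K,n,k", [(10, 4, 3, 1), (12, 6, 5, 3), (8, 8, 2, 2)])
    def test_enumeration_parametrised(self, M, K, n, k):
        universe = [f"F{i}" for i in range(M)]
        library = {"pw": universe[:K]}
        query = universe[:k] + universe[K : K + (n - k)]
        res = chem.ora_enrichment(query, library, universe)
        assert res.table.loc["pw", "p"] == pytest.approx(
            enumerate_hypergeom_p(M, K, n, k), rel=1e-9
        )

    def test_zero_overlap_probability_one(self):
        universe = [f"F{i}" for i in range(10)]
        res = chem.ora_enrichment(universe[5:7], {"pw": universe[:3]}, universe)
        assert res.table.loc["pw", "hits"] == 0
        assert res.table.loc["pw", "p"] == pytest.approx(1.0)

    def test_pathway_equal_to_universe_probability_one(self):
        universe = [f"F{i}" for i in range(6)]
        res = chem.ora_enrichment(universe[:2], {"pw": universe}, universe)
        assert res.table.loc["pw", "p"] == pytest.approx(1.0)

    def test_empty_query_is_error(self):
        with pytest.raises(ValidationError, match="empty"):
            chem.ora_enrichment([], {"pw": ["F1"]}, ["F1"])

    def test_lenient_cutoff_flags_enrichment(self):
        universe = [f"F{i}" for i in range(30)]
        library = toy_pathways(3, 5, universe, seed=0)
        query = library["pathway_01"][:4] + [u for u in universe if u not in
                                             library["pathway_01"]][:2]
        res = chem.ora_enrichment(query, library, universe, p_max=0.1)
        assert bool(res.table.loc["pathway_01", "enriched"])
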