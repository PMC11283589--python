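"""Differential statistics, multiplicity control and clinical-table tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_block
from omicsfuse.containers import OmicsFuseError
from omicsfuse.gsva import ESMatrix
from omicsfuse.stats import (
    bh_fdr,
    clinical_compare,
    cluster_vs_rest_dep,
    covariate_adjusted_diff,
    pearson_chi2,
    spearman_corr,
)

CLUSTER_SIZES = np.array([20, 12, 18, 12, 10])


class TestBH:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_and_all_ones(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(OmicsFuseError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_never_decreases_and_preserves_order(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        # adjustment preserves the ordering of the input p-values
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestChi2:
    def test_uniform_table_is_null(self):
        stat, df, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_granulocyte_mixed_row_reproduces_printed_p(self):
        # mixed-phenotype counts 0/6/1/1/1 across clusters of 20/12/18/12/10
        row = np.array([0, 6, 1, 1, 1])
        table = np.vstack([row, CLUSTER_SIZES - row])
        stat, df, p = pearson_chi2(table)
        assert df == 4
        assert stat == pytest.approx(19.327, abs=0.01)
        assert round(p, 3) == 0.001

    def test_random_table_matches_direct_summation(self, rng):
        obs = rng.integers(1, 30, size=(2, 3)).astype(float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row * col / obs.sum()
        by_hand = ((obs - expected) ** 2 / expected).sum()
        stat, df, _ = pearson_chi2(obs)
        assert stat == pytest.approx(by_hand)
        assert df == 2

    def test_permutation_invariance(self, rng):
        obs = rng.integers(1, 30, size=(3, 4))
        s1, _, p1 = pearson_chi2(obs)
        s2, _, p2 = pearson_chi2(obs[::-1, ::-1])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_margin_rejected(self):
        with pytest.raises(OmicsFuseError):
            pearson_chi2([[0, 0], [1, 2]])


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 5.0, 9.0]
        rho, _ = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_corr(x, [-v for v in x])
        assert rho == pytest.approx(-1.0)

    def test_six_point_rank_formula(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0]
        y = [2.0, 0.5, 7.0, 1.0, 3.0, 8.0]
        # no ties: rho = 1 - 6 sum d^2 / (n(n^2-1))
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        expected = 1 - 6 * np.sum((rx - ry) ** 2) / (6 * 35)
        rho, p = spearman_corr(x, y)
        assert rho == pytest.approx(expected)
        assert 0 <= p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(OmicsFuseError):
            spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])


def _es_from(values, subjects):
    df = pd.DataFrame(values, columns=subjects)
    df.index = [f"set{i}" for i in range(df.shape[0])]
    return ESMatrix(df, {name: 5 for name in df.index})


class TestDEP:
    def test_identical_groups_not_significant(self, rng):
        subjects = [f"s{j}" for j in range(12)]
        vals = np.tile(rng.normal(size=(3, 6)), (1, 2))
        es = _es_from(vals, subjects)
        labels = pd.Series([1] * 6 + [2] * 6, index=subjects)
        table = cluster_vs_rest_dep(es, labels)
        assert not table["significant"].any()

    def test_planted_shift_power(self):
        # effect 3 SD, cluster of 12 vs rest of 60: q < .05 in >= 90/100 runs
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(10, 72))
            vals[0, :12] += 3.0
            subjects = [f"s{j}" for j in range(72)]
            es = _es_from(vals, subjects)
            labels = pd.Series([1] * 12 + [2] * 60, index=subjects)
            table = cluster_vs_rest_dep(es, labels)
            row = table[(table["cluster"] == 1) & (table["set"] == "set0")]
            hits += int((row["q"] < 0.05).all())
        assert hits >= 90

    def test_pooling_across_datasets(self, rng):
        subjects = [f"s{j}" for j in range(20)]
        labels = pd.Series([1] * 10 + [2] * 10, index=subjects)
        es1 = _es_from(rng.normal(size=(4, 20)), subjects)
        es2 = _es_from(rng.normal(size=(3, 20)), subjects)
        table = cluster_vs_rest_dep([es1, es2], labels)
        one_cluster = table[table["cluster"] == 1]
        assert len(one_cluster) == 7  # all sets of both datasets pooled
        assert set(one_cluster["block"]) == {"dataset1", "dataset2"}
        assert (one_cluster["q"] >= one_cluster["p"] - 1e-12).all()

    def test_type_one_error_controlled_under_null(self):
        # global null: expected share of q<.05 discoveries stays below 5%
        false_rates = []
        for seed in range(50):
            r = np.random.default_rng(seed + 1000)
            subjects = [f"s{j}" for j in range(40)]
            es = _es_from(r.normal(size=(20, 40)), subjects)
            labels = pd.Series([1] * 20 + [2] * 20, index=subjects)
            table = cluster_vs_rest_dep(es, labels)
            false_rates.append(table["significant"].mean())
        assert np.mean(false_rates) <= 0.05

    def test_small_group_rejected(self, rng):
        subjects = [f"s{j}" for j in range(5)]
        es = _es_from(rng.normal(size=(2, 5)), subjects)
        labels = pd.Series([1] + [2] * 4, index=subjects)
        with pytest.raises(OmicsFuseError):
            cluster_vs_rest_dep(es, labels)


class TestClinicalCompare:
    def test_normality_gate_routes_gaussian_to_ttest(self):
        routed = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            clinical = pd.DataFrame(
                {"v": r.normal(size=30)}, index=[f"s{j}" for j in range(30)]
            )
            labels = pd.Series([1] * 15 + [2] * 15, index=clinical.index)
            table = clinical_compare(clinical, labels)
            routed += int((table["test"] == "t-test").all())
        # Shapiro at alpha=.05 accepts a true Gaussian ~95% of the time
        assert routed >= 0.85 * 40

    def test_identical_categorical_distribution_not_significant(self):
        clinical = pd.DataFrame(
            {"sex": ["F", "M"] * 10}, index=[f"s{j}" for j in range(20)]
        )
        labels = pd.Series([1] * 10 + [2] * 10, index=clinical.index)
        table = clinical_compare(clinical, labels)
        assert not table["significant"].any()

    def test_planted_eosinophil_shift_detected(self, default_dataset):
        ds, truth = default_dataset
        table = clinical_compare(
            ds.clinical[["sputum_eosinophils_pct"]], truth.labels
        )
        vs3 = table[(table["cluster_a"] == 3) | (table["cluster_b"] == 3)]
        assert vs3["significant"].all()

    def test_single_level_variable_rejected(self):
        clinical = pd.DataFrame({"v": ["x"] * 8}, index=[f"s{j}" for j in range(8)])
        labels = pd.Series([1] * 4 + [2] * 4, index=clinical.index)
        with pytest.raises(OmicsFuseError):
            clinical_compare(clinical, labels)


class TestCovariateAdjusted:
    def _setup(self, rng, n=40, p=30, confounded=False):
        group = pd.Series(
            ["A"] * (n // 2) + ["B"] * (n // 2), index=[f"s{j}" for j in range(n)]
        )
        bmi = rng.normal(27, 3, size=n)
        x = rng.normal(size=(p, n))
        if confounded:
            bmi = np.where(group == "B", bmi + 6, bmi)  # group difference via BMI only
            x[0] += 0.8 * (bmi - bmi.mean())
        else:
            x[0, n // 2 :] += 2.0  # planted group shift orthogonal to covariates
        block = make_block(x, subjects=list(group.index))
        covariates = pd.DataFrame({"bmi": bmi}, index=group.index)
        return block, group, covariates

    def test_confounder_absorbs_group_effect(self, rng):
        block, group, covariates = self._setup(rng, confounded=True)
        table = covariate_adjusted_diff(block, group, covariates)
        assert table.loc[table["feature"] == "f0", "q"].iloc[0] > 0.05

    def test_planted_shift_recovered_with_sign(self, rng):
        block, group, covariates = self._setup(rng, confounded=False)
        table = covariate_adjusted_diff(block, group, covariates)
        top = table.iloc[0]
        assert top["feature"] == "f0"
        assert top["q"] < 0.05
        assert top["direction"] == "up_in_B"

    def test_collinear_covariates_named(self, rng):
        block, group, covariates = self._setup(rng)
        covariates["bmi_copy"] = covariates["bmi"] * 2.0
        with pytest.raises(OmicsFuseError, match="bmi"):
            covariate_adjusted_diff(block, group, covariates)
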