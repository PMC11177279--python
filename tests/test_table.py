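"""FeatureTable assembly, fold plan, harmonization, imputation, demographics."""

import io

import numpy as np
import pandas as pd
import pytest

from neurofuse.cohort import simulate_feature_table
from neurofuse.errors import ConfigError, LeakageError
from neurofuse.table import (FeatureTable, apply_site_normalizer,
                             assemble_table, build_modality_subsets,
                             demographics_report, fit_site_normalizer,
                             impute_features, make_fold_plan, sex_chi_square)


def _subjects(n, sites=("A",), groups=("HC", "bvFTD")):
    rows = []
    i = 0
    while len(rows) < n:
        rows.append({"subject_id": f"s{i}", "site": sites[i % len(sites)],
                     "group": groups[i % len(groups)]})
        i += 1
    return pd.DataFrame(rows).set_index("subject_id")


class TestAssemble:
    def test_absent_modality_rows_masked(self):
        subjects = _subjects(2)
        nps = pd.DataFrame({"CogA total": [25.0, 20.0]}, index=subjects.index)
        eeg = pd.DataFrame({"PLV:beta:R1-R2": [0.4]}, index=subjects.index[:1])
        table = assemble_table({"NPS": nps, "EEG-FC": eeg}, subjects)
        assert not table.mask.loc["s0", "PLV:beta:R1-R2"]
        assert table.mask.loc["s1", "PLV:beta:R1-R2"]

    def test_duplicate_feature_name_across_modalities_rejected(self):
        subjects = _subjects(2)
        frame = pd.DataFrame({"x": [1.0, 2.0]}, index=subjects.index)
        with pytest.raises(ConfigError, match="appears in both"):
            assemble_table({"NPS": frame, "Atrophy": frame}, subjects)

    def test_deterministic_feature_order(self):
        subjects = _subjects(2)
        nps = pd.DataFrame({"b": [1.0, 2.0], "a": [0.0, 1.0]}, index=subjects.index)
        dem = pd.DataFrame({"age": [70.0, 72.0]}, index=subjects.index)
        table = assemble_table({"NPS": nps, "DEM": dem}, subjects)
        assert list(table.feature_names) == ["age", "a", "b"]

    def test_empty_modality_map_keeps_remaining(self):
        subjects = _subjects(2)
        nps = pd.DataFrame({"a": [1.0, 2.0]}, index=subjects.index)
        table = assemble_table(
            {"NPS": nps, "EEG-FC": pd.DataFrame(index=subjects.index)}, subjects)
        assert list(table.feature_names) == ["a"]
        assert set(table.modality) == {"NPS"}

    def test_tsv_round_trip(self, small_table):
        table, _ = small_table
        buf = io.StringIO()
        table.to_tsv(buf)
        buf.seek(0)
        back = FeatureTable.from_tsv(buf)
        pd.testing.assert_frame_equal(back.values, table.values)
        assert (back.modality == table.modality).all()
        assert (back.site == table.site).all()


class TestFoldPlan:
    def test_cohort_sized_split_arithmetic(self):
        table, _ = simulate_feature_table(n_per_group_per_site=1, n_sites=1,
                                          groups=tuple(f"g{i}" for i in range(2)),
                                          blocks=None, seed=0)
        # directly on a 282-subject frame: 20% -> 56 or 57 test subjects
        ids = pd.Index([f"s{i}" for i in range(282)], name="subject_id")
        vals = pd.DataFrame({"x": np.zeros(282)}, index=ids)
        site = pd.Series(["A", "B", "C"] * 94, index=ids)
        group = pd.Series((["HC"] * 152 + ["bvFTD"] * 54 + ["AD"] * 76), index=ids)
        t = FeatureTable(vals, pd.Series({"x": "NPS"}), site, group)
        plan = make_fold_plan(t, test_frac=0.2, k=10, seed=0)
        assert len(plan.test_ids) in (56, 57)
        assert len(plan.outer_train_ids) + len(plan.test_ids) == 282

    def test_same_seed_reproduces_plan(self, small_table):
        table, _ = small_table
        p1 = make_fold_plan(table, k=5, seed=3)
        p2 = make_fold_plan(table, k=5, seed=3)
        pd.testing.assert_series_equal(p1.fold, p2.fold)

    def test_folds_partition_training_rows(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=1)
        seen = set()
        for f in range(5):
            val = set(plan.val_ids(f))
            assert not (val & seen)
            seen |= val
        assert seen == set(plan.outer_train_ids)

    def test_test_proportions_track_strata(self, small_table):
        table, _ = small_table
        for seed in range(20):
            plan = make_fold_plan(table, k=5, seed=seed)
            strata = table.group.astype(str) + "|" + table.site.astype(str)
            for s in strata.unique():
                total = (strata == s).sum()
                in_test = strata.loc[plan.test_ids].eq(s).sum()
                assert abs(in_test - 0.2 * total) <= 1

    def test_invalid_parameters_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ConfigError):
            make_fold_plan(table, test_frac=1.5)
        with pytest.raises(ConfigError):
            make_fold_plan(table, k=1)


class TestHarmonization:
    def test_control_mean_and_sample_sd_hand_example(self):
        # site-A training controls hold {4, 6}: mu = 5, sigma = sqrt(2)
        from neurofuse.table import FoldPlan
        ids = pd.Index([f"s{i}" for i in range(10)], name="subject_id")
        vals = pd.DataFrame(
            {"f": [4.0, 6.0, 1.0, 9.0, 3.0, 5.0, 2.0, 8.0, 7.0, 0.5]}, index=ids)
        site = pd.Series(["A"] * 4 + ["B"] * 6, index=ids)
        group = pd.Series(["HC", "HC", "bvFTD", "bvFTD",
                           "HC", "HC", "HC", "bvFTD", "HC", "bvFTD"], index=ids)
        t = FeatureTable(vals, pd.Series({"f": "NPS"}), site, group)
        fold = pd.Series([0, 1, 0, 1, 0, 1, 0, 1, -1, -1], index=ids)
        plan = FoldPlan(fold=fold, k=2, seed=0)
        model = fit_site_normalizer(t, plan, fold=None)
        assert model.mu.loc["A", "f"] == pytest.approx(5.0)
        assert model.sigma.loc["A", "f"] == pytest.approx(np.sqrt(2.0))
        assert "s8" not in model.fitted_on  # test-set control never fitted on

    def test_fitting_with_test_rows_raises(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=2)
        rows = list(plan.outer_train_ids) + [plan.test_ids[0]]
        with pytest.raises(LeakageError):
            fit_site_normalizer(table, plan, fold=None, rows=rows)

    def test_training_controls_standardized_exactly(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=2)
        model = fit_site_normalizer(table, plan, fold=None)
        harm = apply_site_normalizer(model, table)
        hc = [i for i in model.fitted_on]
        z = harm.values.loc[hc]
        sites = harm.site.loc[hc]
        for s in sites.unique():
            block = z.loc[sites == s]
            assert np.abs(block.mean(axis=0)).max() < 1e-12
            np.testing.assert_allclose(block.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_planted_site_offsets_removed(self):
        table, _ = simulate_feature_table(n_per_group_per_site=50, n_sites=3,
                                          groups=("HC", "bvFTD"),
                                          site_shift=(0.0, 1.0, -1.0), seed=4)
        plan = make_fold_plan(table, k=5, seed=4)
        model = fit_site_normalizer(table, plan, fold=None)
        harm = apply_site_normalizer(model, table)
        def site_spread(tbl):
            hc = [i for i in tbl.subjects if tbl.group.loc[i] == "HC"]
            means = tbl.values.loc[hc].groupby(tbl.site.loc[hc].to_numpy()).mean()
            feats = [f for f in tbl.feature_names if f != "sex"]
            return means[feats].max(axis=0) - means[feats].min(axis=0)

        # the planted 1-SD offsets are removed down to control-sampling noise:
        # the signed between-site difference, averaged over features, is ~0 ...
        hc = [i for i in harm.subjects if harm.group.loc[i] == "HC"]
        means = harm.values.loc[hc].groupby(harm.site.loc[hc].to_numpy()).mean()
        feats = [f for f in harm.feature_names if f != "sex"]
        assert abs((means.loc["site2", feats] - means.loc["site1", feats]).mean()) < 0.05
        # ... and the per-feature residual is a small fraction of the offset
        spread = site_spread(harm)
        assert spread.median() < 0.3
        # ... and indistinguishable from a cohort that never had site effects
        null_table, _ = simulate_feature_table(n_per_group_per_site=50, n_sites=3,
                                               groups=("HC", "bvFTD"), seed=4)
        null_plan = make_fold_plan(null_table, k=5, seed=4)
        null_harm = apply_site_normalizer(
            fit_site_normalizer(null_table, null_plan, fold=None), null_table)
        assert spread.median() < 1.5 * site_spread(null_harm).median()

    def test_patients_use_their_sites_control_stats(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=2)
        model = fit_site_normalizer(table, plan, fold=None)
        harm = apply_site_normalizer(model, table)
        sid = [i for i in table.subjects if table.group.loc[i] == "AD"][0]
        s = table.site.loc[sid]
        f = model.mu.columns[0]
        expected = (table.values.loc[sid, f] - model.mu.loc[s, f]) / model.sigma.loc[s, f]
        assert harm.values.loc[sid, f] == pytest.approx(expected, rel=1e-12)

    def test_fold_dependent_statistics(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=2)
        m0 = fit_site_normalizer(table, plan, fold=0)
        m1 = fit_site_normalizer(table, plan, fold=1)
        assert set(m0.fitted_on) != set(m1.fitted_on)
        assert not m0.mu.equals(m1.mu)

    def test_unseen_site_rejected(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=2)
        model = fit_site_normalizer(table, plan, fold=None)
        other = table.copy()
        other.site.iloc[0] = "siteX"
        with pytest.raises(ConfigError, match="siteX"):
            apply_site_normalizer(model, other)


class TestImputation:
    def _table_with_missing(self):
        ids = pd.Index([f"s{i}" for i in range(10)], name="subject_id")
        f1 = [2.0, 2.0, 2.0, np.nan, np.nan, np.nan, 2.0, 2.0, 2.0, 2.0]
        f2 = [1.0, np.nan, np.nan, np.nan, np.nan, 1.0, 1.0, 1.0, 1.0, 1.0]
        vals = pd.DataFrame({"a": f1, "b": f2, "c": np.arange(10.0)}, index=ids)
        site = pd.Series(["A"] * 5 + ["B"] * 5, index=ids)
        group = pd.Series(["HC", "bvFTD"] * 5, index=ids)
        t = FeatureTable(vals, pd.Series({"a": "NPS", "b": "NPS", "c": "NPS"}),
                         site, group)
        plan = type("P", (), {})()  # all rows are training rows
        from neurofuse.table import FoldPlan
        fold = pd.Series(np.arange(10) % 2, index=ids)
        return t, FoldPlan(fold=fold, k=2, seed=0)

    def test_under_threshold_filled_with_training_mean(self):
        t, plan = self._table_with_missing()
        out, model = impute_features(t, plan, fold=None, threshold=0.30)
        assert "a" in out.feature_names
        assert out.values["a"].loc["s3"] == pytest.approx(2.0)
        assert model.means["a"] == pytest.approx(2.0)

    def test_over_threshold_dropped(self):
        t, plan = self._table_with_missing()
        out, model = impute_features(t, plan, fold=None, threshold=0.30)
        assert "b" not in out.feature_names
        assert model.excluded == ["b"]

    def test_no_missing_data_is_identity(self, small_table):
        table, _ = small_table
        plan = make_fold_plan(table, k=5, seed=1)
        out, model = impute_features(table, plan, fold=None)
        pd.testing.assert_frame_equal(out.values, table.values)
        assert model.excluded == []

    def test_idempotent(self):
        t, plan = self._table_with_missing()
        once, _ = impute_features(t, plan, fold=None)
        twice, _ = impute_features(once, plan, fold=None)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_feature_missing_in_all_training_rows_errors(self):
        ids = pd.Index(["s0", "s1", "s2", "s3"], name="subject_id")
        vals = pd.DataFrame({"a": [np.nan] * 4, "b": [1.0, 2, 3, 4]}, index=ids)
        t = FeatureTable(vals, pd.Series({"a": "NPS", "b": "NPS"}),
                         pd.Series(["A"] * 4, index=ids),
                         pd.Series(["HC", "bvFTD"] * 2, index=ids))
        from neurofuse.table import FoldPlan
        plan = FoldPlan(fold=pd.Series([0, 1, 0, 1], index=ids), k=2, seed=0)
        with pytest.raises(ConfigError, match="every training row"):
            impute_features(t, plan, fold=None)


class TestDemographics:
    def test_printed_contingency_tables_reproduced(self):
        # complete-data cohort sex counts (F:M per HC/bvFTD/AD)
        chi2, p, dof = sex_chi_square([[26, 28], [13, 6], [14, 18]])
        assert round(chi2, 2) == 3.14
        assert dof == 2
        assert p > 0.05
        # full cohort with missing data
        chi2, p, dof = sex_chi_square([[101, 51], [22, 32], [24, 54]])
        assert round(chi2, 2) == 29.52
        assert p < 0.05

    def test_homogeneous_ratios_give_zero(self):
        chi2, _, _ = sex_chi_square([[10, 20], [20, 40], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_report_from_subject_rows(self, rng):
        n = 90
        subjects = pd.DataFrame({
            "group": np.repeat(["HC", "bvFTD", "AD"], 30),
            "sex": rng.integers(0, 2, n),
            "age": rng.normal(72, 8, n),
            "education": rng.normal(14, 4, n),
        })
        rep = demographics_report(subjects)
        assert rep.sex_df == 2
        assert rep.sex_chi2 >= 0
        assert set(rep.anova) == {"age", "education"}
        for f, p in rep.anova.values():
            assert f >= 0 and 0 <= p <= 1

    def test_single_group_rejected(self):
        subjects = pd.DataFrame({"group": ["HC"] * 5, "sex": [0, 1, 0, 1, 0],
                                 "age": np.arange(5.0), "education": np.arange(5.0)})
        with pytest.raises(ConfigError):
            demographics_report(subjects)


class TestModalitySubsets:
    def test_partition_and_dem_content(self, small_table):
        table, _ = small_table
        subsets = build_modality_subsets(table)
        assert sorted(subsets["DEM"].feature_names) == ["age", "education", "sex"]
        union = [f for sub in subsets.values() for f in sub.feature_names]
        assert sorted(union) == sorted(table.feature_names)
        assert len(union) == len(set(union))
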