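"""Synthetic cohort generation: determinism, planted effects, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurofuse.cohort import (BlockSpec, SimConfig, inject_missingness,
                              simulate_cohort, simulate_eeg,
                              simulate_feature_table, simulate_fmri,
                              write_cohort)
from neurofuse.eeg import BandSpec, epoch_and_filter, plv_adjacency
from neurofuse.errors import ConfigError
from neurofuse.fmri import DcfaParams, dcfa_features, sfc_features

SMALL = dict(n_per_group_per_site=2, eeg_duration=4.0, eeg_rate=128.0,
             eeg_channels=32, fmri_volumes=60)


class TestDeterminism:
    def test_same_seed_reproduces_cohort_bit_for_bit(self, tmp_path):
        c1 = simulate_cohort(SimConfig(seed=7, **SMALL))
        c2 = simulate_cohort(SimConfig(seed=7, **SMALL))
        pd.testing.assert_frame_equal(c1.subjects, c2.subjects)
        pd.testing.assert_frame_equal(c1.cognition, c2.cognition)
        for sid in c1.eeg:
            np.testing.assert_array_equal(c1.eeg[sid].samples, c2.eeg[sid].samples)
            np.testing.assert_array_equal(c1.fmri[sid].values, c2.fmri[sid].values)
        # and on disk
        write_cohort(c1, tmp_path / "a")
        write_cohort(c2, tmp_path / "b")
        for rel in ("subjects.tsv", "ground_truth.json", "eeg/sub0001.tsv"):
            assert (tmp_path / "a" / rel).read_bytes() == \
                   (tmp_path / "b" / rel).read_bytes()

    def test_different_seed_changes_payloads(self):
        c1 = simulate_cohort(SimConfig(seed=7, **SMALL))
        c2 = simulate_cohort(SimConfig(seed=8, **SMALL))
        assert not np.array_equal(c1.eeg["sub0001"].samples,
                                  c2.eeg["sub0001"].samples)

    def test_feature_table_determinism(self):
        t1, g1 = simulate_feature_table(n_per_group_per_site=5, seed=3)
        t2, g2 = simulate_feature_table(n_per_group_per_site=5, seed=3)
        pd.testing.assert_frame_equal(t1.values, t2.values)
        assert g1 == g2

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_per_group_per_site=0)
        with pytest.raises(ConfigError):
            SimConfig(eeg_coupling={"HC": 1.5})
        with pytest.raises(ConfigError):
            SimConfig(missing_rates={"EEG": 1.2})
        with pytest.raises(ConfigError):
            SimConfig(eeg_channels=30)


class TestEegGenerator:
    def test_full_coupling_without_noise_gives_perfect_locking(self):
        rec = simulate_eeg("HC", 1.0, seed=3, duration=5, rate=128,
                           n_channels=32, noise_amp=0.0)
        band = BandSpec("broad", 0.5, 45)
        adj = plv_adjacency(epoch_and_filter(rec, band), band,
                            node_ids=rec.channel_labels)
        coupled = [i for i, lab in enumerate(rec.channel_labels)
                   if rec.roi_map[lab] in ("ROI01", "ROI02")]
        assert adj.values[coupled[0], coupled[1]] == pytest.approx(1.0, abs=1e-9)

    def test_zero_coupling_gives_near_null_locking(self):
        rec = simulate_eeg("HC", 0.0, seed=5, duration=60, rate=128,
                           n_channels=32, noise_amp=0.0)
        band = BandSpec("broad", 0.5, 45)
        adj = plv_adjacency(epoch_and_filter(rec, band), band,
                            node_ids=rec.channel_labels)
        assert adj.values[0, 2] < 0.2  # designated pair, 60 segments

    def test_locking_monotone_in_coupling(self):
        band = BandSpec("broad", 0.5, 45)
        means = []
        for kappa in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(10):
                rec = simulate_eeg("HC", kappa, seed=seed, duration=10, rate=128,
                                   n_channels=32, noise_amp=0.0)
                adj = plv_adjacency(epoch_and_filter(rec, band), band,
                                    node_ids=rec.channel_labels)
                vals.append(adj.values[0, 2])
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ConfigError):
            simulate_eeg("HC", 1.2, seed=0, duration=2, rate=128, n_channels=32)


class TestFmriGenerator:
    def test_stationary_perfect_correlation_gives_zero_dcfa(self):
        ts = simulate_fmri("HC", 0.0, seed=2, n_volumes=100, r_level=1.0)
        feats = dcfa_features(ts, DcfaParams(window=20, step=2))
        assert feats["DCFA:DMN"] == pytest.approx(0.0, abs=1e-6)

    def test_state_switching_inflates_dcfa(self):
        params = DcfaParams(window=20, step=2)
        diffs = []
        for seed in range(10):
            switching = simulate_fmri("HC", 0.5, seed=seed, n_volumes=200,
                                      r_level=0.8)
            stationary = simulate_fmri("HC", 0.0, seed=seed, n_volumes=200,
                                       r_level=0.8)
            diffs.append(dcfa_features(switching, params)["DCFA:DMN"] -
                         dcfa_features(stationary, params)["DCFA:DMN"])
        assert np.median(diffs) > 0

    def test_uncorrelated_network_gives_near_zero_sfc(self):
        ts = simulate_fmri("HC", 0.0, seed=4, n_volumes=400, r_level=0.0)
        assert abs(sfc_features(ts)["SFC:DMN"]) < 2 / np.sqrt(400)


class TestTabularEffects:
    def test_planted_effect_size_recovered_in_group_means(self):
        d = 1.5
        blocks = {"NPS": BlockSpec("NPS", 5, 1, {"bvFTD": d, "AD": d})}
        table, gt = simulate_feature_table(n_per_group_per_site=100, n_sites=1,
                                           blocks=blocks, seed=9)
        feat = gt["informative_features"][0]
        hc = table.values.loc[table.group == "HC", feat]
        pat = table.values.loc[table.group == "bvFTD", feat]
        pooled_sd = np.sqrt((hc.var(ddof=1) + pat.var(ddof=1)) / 2)
        observed_d = (pat.mean() - hc.mean()) / pooled_sd
        assert observed_d == pytest.approx(d, abs=0.35)  # ~2 SE at n=100

    def test_null_effects_calibrate_t_tests(self):
        blocks = {"NPS": BlockSpec("NPS", 200, 0)}
        table, _ = simulate_feature_table(n_per_group_per_site=30, n_sites=1,
                                          groups=("HC", "bvFTD"), blocks=blocks,
                                          seed=10)
        hc = table.group == "HC"
        feats = [f for f in table.feature_names if f.startswith("NPS")]
        ps = [stats.ttest_ind(table.values.loc[hc, f],
                              table.values.loc[~hc, f]).pvalue for f in feats]
        # false-positive rate compatible with alpha = 0.05 (binomial 99% band)
        hits = sum(p < 0.05 for p in ps)
        assert stats.binom.ppf(0.005, len(ps), 0.05) <= hits \
            <= stats.binom.ppf(0.995, len(ps), 0.05)

    def test_site_shift_visible_in_control_means(self):
        table, _ = simulate_feature_table(n_per_group_per_site=100, n_sites=3,
                                          groups=("HC",),
                                          site_shift=(0.0, 1.0, -1.0), seed=11)
        feats = [f for f in table.feature_names if f not in ("sex", "age", "education")]
        means = table.values[feats].groupby(table.site.to_numpy()).mean()
        assert means.loc["site2"].mean() == pytest.approx(1.0, abs=0.1)
        assert means.loc["site3"].mean() == pytest.approx(-1.0, abs=0.1)

    def test_cognition_totals_within_instrument_range(self):
        config = SimConfig(seed=1, **SMALL)
        cohort = simulate_cohort(config)
        cog = cohort.cognition
        assert (cog >= 0).all().all() and (cog <= 30).all().all()


class TestMissingness:
    def test_zero_rate_is_identity(self, small_table):
        table, _ = small_table
        out = inject_missingness(table, {"CogA": 0.0}, seed=1)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_unit_rate_saturates_block(self, small_table):
        table, _ = small_table
        out = inject_missingness(table, {"EEG": 1.0}, seed=1)
        eeg_feats = [f for f in table.feature_names if f.startswith("PLV")]
        assert out.mask[eeg_feats].all().all()
        other = [f for f in table.feature_names if not f.startswith("PLV")]
        assert not out.mask[other].any().any()

    def test_block_level_missingness(self, small_table):
        # a subject losing one CogA feature loses the whole assessment
        table, _ = small_table
        out = inject_missingness(table, {"CogA": 0.5}, seed=2)
        cog = [f for f in table.feature_names if f.startswith("CogA")]
        per_subject = out.mask[cog].sum(axis=1)
        assert set(per_subject.unique()) <= {0, len(cog)}

    def test_realized_rate_within_binomial_bounds(self):
        blocks = {"NPS": BlockSpec("NPS", 8, 0, prefix="CogA")}
        table, _ = simulate_feature_table(n_per_group_per_site=152, n_sites=1,
                                          groups=("HC",), blocks=blocks, seed=3)
        out = inject_missingness(table, {"CogA": 0.25}, seed=3)
        cog = [f for f in table.feature_names if f.startswith("CogA")]
        realized = out.mask[cog].iloc[:, 0].mean()
        lo = stats.binom.ppf(0.005, 152, 0.25) / 152
        hi = stats.binom.ppf(0.995, 152, 0.25) / 152
        assert lo <= realized <= hi

    def test_per_group_rates_realized(self):
        rates = {"EEG": {"HC": 0.29, "bvFTD": 0.27, "AD": 0.26}}
        blocks = {"EEG-FC": BlockSpec("EEG-FC", 10, 0, prefix="PLV:beta")}
        table, _ = simulate_feature_table(n_per_group_per_site=300, n_sites=1,
                                          blocks=blocks, seed=5)
        out = inject_missingness(table, rates, seed=5)
        eeg = [f for f in table.feature_names if f.startswith("PLV")]
        for g, r in rates["EEG"].items():
            realized = out.mask.loc[out.group == g, eeg].iloc[:, 0].mean()
            assert realized == pytest.approx(r, abs=0.03)

    def test_rate_above_one_rejected(self, small_table):
        table, _ = small_table
        with pytest.raises(ConfigError):
            inject_missingness(table, {"CogA": 1.5}, seed=1)

    def test_observed_values_untouched(self, small_table):
        table, _ = small_table
        out = inject_missingness(table, {"CogA": 0.5}, seed=2)
        kept = ~out.mask
        pd.testing.assert_frame_equal(out.values.where(kept),
                                      table.values.where(kept))
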