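import numpy as np
import pytest
from scipy import stats

from amni import SyntheticCohortConfig, generate_cohort, generate_timeseries, generate_volume, pearson_fcn
from amni.errors import ConfigError
from amni.synthetic import Blob, base_covariance, blob_mask, effect_covariance


class TestCovarianceConstruction:
    def test_base_covariance_is_positive_definite_block_matrix(self):
        cfg = SyntheticCohortConfig()
        cov = base_covariance(cfg)
        assert np.allclose(np.diag(cov), 1.0)
        assert cov[0, 1] == pytest.approx(cfg.within_community_cov)
        assert cov[0, 19] == 0.0
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_effect_applies_full_delta_when_admissible(self):
        cfg = SyntheticCohortConfig()
        cov, alpha = effect_covariance(cfg)
        assert alpha == pytest.approx(1.0)
        i, j = cfg.functional_effect_edges[0]
        assert cov[i, j] == pytest.approx(
            base_covariance(cfg)[i, j] + cfg.functional_effect_delta
        )

    def test_inadmissible_delta_is_shrunk_to_positive_definite(self):
        cfg = SyntheticCohortConfig(functional_effect_delta=5.0)
        cov, alpha = effect_covariance(cfg)
        assert 0 < alpha < 1
        assert np.linalg.eigvalsh(cov)[0] >= 1e-7


class TestTimeseries:
    def test_seeded_determinism(self):
        cfg = SyntheticCohortConfig()
        a = generate_timeseries(cfg, 1, np.random.default_rng(5))
        b = generate_timeseries(cfg, 1, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_null_effect_gives_no_group_difference(self):
        """Monte-Carlo null: with delta 0 both classes share one covariance,
        so mean Pearson on the (would-be) effect edges agrees across groups."""
        cfg = SyntheticCohortConfig(functional_effect_delta=0.0)
        edges = cfg.functional_effect_edges
        means = []
        for label in (0, 1):
            vals = []
            for i in range(200):
                ts = generate_timeseries(cfg, label, np.random.default_rng(9000 + 2 * i + label))
                b = pearson_fcn(ts).values
                vals.append(np.mean([b[e] for e in edges]))
            means.append(np.mean(vals))
        assert abs(means[1] - means[0]) <= 0.05

    def test_effect_edge_shows_group_difference(self):
        """delta = 0.4 on edge (1, 2) raises that edge's mean Pearson
        estimate by at least 0.15 over 200 subjects per group."""
        cfg = SyntheticCohortConfig(
            functional_effect_edges=[(1, 2)], functional_effect_delta=0.4
        )
        diffs = []
        for label in (0, 1):
            vals = [
                pearson_fcn(
                    generate_timeseries(cfg, label, np.random.default_rng(400 + 2 * i + label))
                ).values[1, 2]
                for i in range(200)
            ]
            diffs.append(np.mean(vals))
        assert diffs[1] - diffs[0] >= 0.15

    def test_pearson_estimates_converge_to_generating_correlation(self):
        cfg = SyntheticCohortConfig(n_timepoints=2000, temporal_ar_coeff=0.3)
        cov, _ = effect_covariance(cfg)
        corr = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        estimates = [
            pearson_fcn(generate_timeseries(cfg, 1, np.random.default_rng(70 + i))).values
            for i in range(8)
        ]
        assert np.abs(np.mean(estimates, axis=0) - corr).max() <= 0.05

    def test_null_generators_indistinguishable_by_ks_test(self):
        """With all deltas 0 the two class generators are the same process:
        a two-sample KS test on a summary feature must not reject."""
        cfg = SyntheticCohortConfig(functional_effect_delta=0.0)
        edges = cfg.functional_effect_edges

        def summary(label, offset):
            out = []
            for i in range(200):
                ts = generate_timeseries(cfg, label, np.random.default_rng(offset + i))
                b = pearson_fcn(ts).values
                out.append(np.mean([b[e] for e in edges]))
            return out

        result = stats.ks_2samp(summary(0, 10_000), summary(1, 20_000))
        assert result.pvalue > 0.01


class TestVolumes:
    def test_noiseless_null_volumes_identical_across_classes(self):
        cfg = SyntheticCohortConfig(noise_sd=0.0, structural_effect_blobs=[])
        v0 = generate_volume(cfg, 0, np.random.default_rng(0))
        v1 = generate_volume(cfg, 1, np.random.default_rng(1))
        assert np.array_equal(v0.values, v1.values)

    def test_blob_delta_recovered_by_monte_carlo_mean(self):
        cfg = SyntheticCohortConfig()
        blob = cfg.structural_effect_blobs[0]
        mask = blob_mask(cfg.volume_shape, blob)
        diffs = []
        for i in range(100):
            v0 = generate_volume(cfg, 0, np.random.default_rng(3000 + i))
            v1 = generate_volume(cfg, 1, np.random.default_rng(7000 + i))
            diffs.append(v1.values[mask].mean() - v0.values[mask].mean())
        mean_diff = float(np.mean(diffs))
        assert abs(mean_diff - blob.delta) <= 0.2 * abs(blob.delta)

    def test_output_shape_contract(self):
        cfg = SyntheticCohortConfig(
            volume_shape=(10, 12, 14),
            structural_effect_blobs=[Blob(center=(5.0, 6.0, 7.0), radius=2.0, delta=-0.3)],
        )
        v = generate_volume(cfg, 0, np.random.default_rng(0))
        assert v.values.shape == (10, 12, 14)

    def test_blob_outside_volume_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticCohortConfig(
                structural_effect_blobs=[Blob(center=(2.0, 2.0, 2.0), radius=5.0, delta=0.1)]
            )


class TestCohortRouting:
    def test_split_one_removes_structural_class_signal(self):
        cfg = SyntheticCohortConfig(
            n_class0=8, n_class1=8, modality_signal_split=1.0, seed=3
        )
        cohort = generate_cohort(cfg)
        assert all(
            not s.ground_truth["structural_blobs"] for s in cohort if s.label == 1
        )
        assert all(
            s.ground_truth["route"] == "functional" for s in cohort if s.label == 1
        )

    def test_split_zero_removes_functional_class_signal(self):
        cfg = SyntheticCohortConfig(
            n_class0=8, n_class1=8, modality_signal_split=0.0, seed=3
        )
        cohort = generate_cohort(cfg)
        assert all(
            not s.ground_truth["functional_edges"] for s in cohort if s.label == 1
        )

    def test_half_split_routes_half_each_way(self):
        cfg = SyntheticCohortConfig(n_class0=10, n_class1=10, seed=3)
        cohort = generate_cohort(cfg)
        routes = [s.ground_truth["route"] for s in cohort if s.label == 1]
        assert routes.count("functional") == 5
        assert routes.count("structural") == 5
        assert all(s.ground_truth["route"] is None for s in cohort if s.label == 0)

    def test_cohort_is_pure_function_of_config_and_seed(self):
        cfg = SyntheticCohortConfig(n_class0=4, n_class1=4, seed=8)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id and sa.label == sb.label
            assert np.array_equal(sa.time_series.values, sb.time_series.values)
            assert np.array_equal(sa.volume.values, sb.volume.values)
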