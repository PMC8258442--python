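import numpy as np
import pytest

from thicknet import (
    NodeSet,
    ParameterError,
    SyntheticSpec,
    build_block_covariance,
    generate_cohort,
    make_two_group_scenario,
)


class TestBlockCovariance:
    def test_matches_definition(self):
        C = build_block_covariance([0, 0, 1], 0.6, 0.1)
        expected = np.array([[1, 0.6, 0.1], [0.6, 1, 0.1], [0.1, 0.1, 1]])
        np.testing.assert_allclose(C, expected)

    def test_zero_correlations_give_identity(self):
        np.testing.assert_allclose(
            build_block_covariance([0, 1, 2], 0.0, 0.0), np.eye(3)
        )

    def test_extreme_blocks_stay_positive_definite(self):
        C = build_block_covariance([0] * 5 + [1] * 5, 0.95, -0.5)
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_repair_warns_and_restores_positive_definiteness(self):
        # 4 mutually anticorrelated singleton blocks cannot form a valid
        # correlation matrix; the builder must shrink toward identity
        with pytest.warns(UserWarning, match="shrunk toward identity"):
            C = build_block_covariance([0, 1, 2, 3], 0.0, -0.5)
        assert np.linalg.eigvalsh(C)[0] > 0

    def test_invalid_correlations_rejected(self):
        with pytest.raises(ParameterError):
            build_block_covariance([0, 1], 0.2, 0.5)  # r_out > r_in
        with pytest.raises(ParameterError):
            build_block_covariance([0, 1], 1.0, 0.0)


class TestGenerateCohort:
    def test_reproducible_from_seed(self, nodes6):
        spec = SyntheticSpec(n_subjects=30, regions=nodes6, seed=11)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        assert a == b

    def test_seed_changes_values(self, nodes6):
        spec = SyntheticSpec(n_subjects=30, regions=nodes6, seed=11)
        a = generate_cohort(spec)
        c = generate_cohort(spec, seed=12)
        assert not a.data.equals(c.data)

    def test_block_correlation_recovery(self, nodes12):
        # age slope off so the shared age effect does not confound the
        # planted correlation targets
        cols = nodes12.columns
        spec = SyntheticSpec(
            n_subjects=500,
            regions=nodes12,
            blocks=(tuple(cols[:6]), tuple(cols[6:])),
            r_in=0.6,
            r_out=0.0,
            atrophy_slope=0.0,
            seed=21,
        )
        X = generate_cohort(spec).thickness_matrix(nodes12)
        R = np.corrcoef(X, rowvar=False)
        within = np.concatenate(
            [R[:6, :6][np.triu_indices(6, 1)], R[6:, 6:][np.triu_indices(6, 1)]]
        )
        between = R[:6, 6:].ravel()
        # Monte-Carlo windows from the sampling distribution of r at n=500
        # (SE ~ (1-r^2)/sqrt(n)); averages are the stable summary, individual
        # pairs get a family-wise 99% Fisher-z envelope
        assert 0.52 < within.mean() < 0.68
        assert abs(between.mean()) < 0.09
        from scipy.stats import norm

        z_fw = norm.ppf(1 - (1 - 0.99 ** (1 / 66)) / 2)  # Sidak, 66 pairs
        half = z_fw / np.sqrt(500 - 3)
        assert np.abs(np.arctanh(within) - np.arctanh(0.6)).max() < half
        assert np.abs(np.arctanh(between)).max() < half

    def test_convergence_within_fisher_z_bounds(self, nodes6):
        cols = nodes6.columns
        spec = SyntheticSpec(
            n_subjects=2000,
            regions=nodes6,
            blocks=(tuple(cols),),
            r_in=0.5,
            r_out=0.5,
            atrophy_slope=0.0,
            seed=8,
        )
        X = generate_cohort(spec).thickness_matrix(nodes6)
        R = np.corrcoef(X, rowvar=False)
        z = np.arctanh(R[np.triu_indices(6, 1)])
        se = 1.0 / np.sqrt(2000 - 3)
        assert np.abs(z - np.arctanh(0.5)).max() < 4 * se

    def test_atrophy_slope_recovery(self, nodes6):
        spec = SyntheticSpec(
            n_subjects=500, regions=nodes6, atrophy_slope=0.005, seed=4
        )
        cohort = generate_cohort(spec)
        mean_thick = cohort.thickness_matrix(nodes6).mean(axis=1)
        slope = np.polyfit(cohort.data["age"], mean_thick, 1)[0]
        assert -0.006 <= slope <= -0.004  # within 20% of -0.005 mm/yr

    def test_ages_within_range(self, nodes6):
        spec = SyntheticSpec(
            n_subjects=200, regions=nodes6, age_range=(32.0, 79.0), seed=2
        )
        ages = generate_cohort(spec).data["age"]
        assert ages.min() >= 32 and ages.max() <= 79

    def test_small_cohort_warns(self, nodes12):
        with pytest.warns(UserWarning, match="recommended"):
            SyntheticSpec(n_subjects=10, regions=nodes12, seed=0)


class TestTwoGroupScenario:
    def test_group_column_and_sizes(self, nodes6):
        cols = nodes6.columns
        hp = SyntheticSpec(
            n_subjects=20, regions=nodes6,
            blocks=(tuple(cols[:3]), tuple(cols[3:])), r_in=0.7, r_out=0.1,
            seed=1,
        )
        lp = SyntheticSpec(
            n_subjects=15, regions=nodes6, blocks=(tuple(cols),), r_in=0.4,
            r_out=0.0, seed=2,
        )
        cohort = make_two_group_scenario(hp, lp)
        counts = cohort.data["group"].value_counts()
        assert counts["HP"] == 20 and counts["LP"] == 15

    def test_mismatched_regions_rejected(self, nodes6, nodes12):
        a = SyntheticSpec(n_subjects=20, regions=nodes6, seed=1)
        b = SyntheticSpec(n_subjects=40, regions=nodes12, seed=1)
        with pytest.raises(ParameterError, match="region"):
            make_two_group_scenario(a, b)

    def test_empty_group_rejected(self, nodes6):
        with pytest.raises(ParameterError, match="n_subjects"):
            SyntheticSpec(n_subjects=0, regions=nodes6, seed=1)

    def test_blocks_must_partition_regions(self, nodes6):
        with pytest.raises(ParameterError, match="partition"):
            SyntheticSpec(
                n_subjects=20, regions=nodes6,
                blocks=(("lh_r0", "lh_r1"),), seed=1,
            )
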