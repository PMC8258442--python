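import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thicknet import (
    DensitySweep,
    ParameterError,
    SyntheticSpec,
    ValidationError,
    compare_global,
    compare_nodal,
    fdr_adjust,
    generate_cohort,
    hochberg_adjust,
    permute_groups,
)

from _oracles import literal_bh, literal_hochberg


class TestPermuteGroups:
    def test_sizes_preserved(self):
        for a, b in permute_groups(["a", "b"], ["c", "d"], seed=1, n_perm=20):
            assert len(a) == 2 and len(b) == 2
            assert sorted(a + b) == ["a", "b", "c", "d"]

    def test_reproducible_stream(self):
        s1 = list(permute_groups(["a", "b"], ["c", "d"], seed=9, n_perm=10))
        s2 = list(permute_groups(["a", "b"], ["c", "d"], seed=9, n_perm=10))
        assert s1 == s2

    def test_uniform_over_splits(self):
        counts = {}
        for a, _ in permute_groups(["a", "b"], ["c", "d"], seed=3, n_perm=10000):
            counts[frozenset(a)] = counts.get(frozenset(a), 0) + 1
        assert len(counts) == 6  # C(4,2)
        se = np.sqrt((1 / 6) * (5 / 6) / 10000)
        for k in counts:
            assert abs(counts[k] / 10000 - 1 / 6) < 3 * se + 1e-9

    def test_overlap_rejected(self):
        with pytest.raises(ParameterError, match="disjoint"):
            list(permute_groups(["a", "b"], ["b", "c"], seed=0))

    def test_small_pool_rejected(self):
        with pytest.raises(ParameterError, match="4"):
            list(permute_groups(["a"], ["b", "c"], seed=0))


@pytest.fixture(scope="module")
def small_cohort(request):
    from thicknet import NodeSet

    nodes = NodeSet.from_columns("t", [f"lh_r{i}" for i in range(8)])
    spec = SyntheticSpec(
        n_subjects=40, regions=nodes, blocks=(), r_in=0.3, r_out=0.3,
        atrophy_slope=0.0, seed=77,
    )
    return generate_cohort(spec), nodes


class TestCompareGlobal:
    def test_identity_contrast_observed_zero(self, small_cohort):
        cohort, nodes = small_cohort
        ids = cohort.subjects[:20]
        res = compare_global(
            cohort, (ids, ids), nodes, DensitySweep((27.0,), 27.0),
            n_perm=20, seed=0,
        )
        assert np.all(res["observed"] == 0.0)
        assert not res["significant"].any()

    def test_label_swap_invariance(self, small_cohort):
        cohort, nodes = small_cohort
        ids = cohort.subjects
        a, b = ids[:20], ids[20:]
        sweep = DensitySweep((10.0, 27.0), 27.0)
        r1 = compare_global(cohort, (a, b), nodes, sweep, n_perm=99, seed=5)
        r2 = compare_global(cohort, (b, a), nodes, sweep, n_perm=99, seed=5)
        np.testing.assert_allclose(r1["observed"], -r2["observed"], atol=1e-12)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-12)
        assert (r1["significant"] == r2["significant"]).all()

    def test_decision_rules_agree(self, small_cohort):
        # the CI rule and the p<=alpha rule must agree on every row
        cohort, nodes = small_cohort
        ids = cohort.subjects
        res = compare_global(
            cohort, (ids[:20], ids[20:]), nodes,
            DensitySweep((10.0, 27.0, 45.0), 27.0), n_perm=99, seed=2,
        )
        outside = (res["observed"].abs() > res["ci_high"]).to_numpy()
        assert np.array_equal(outside, res["significant"].to_numpy())
        assert np.array_equal(
            (res["p"] <= 0.05).to_numpy(), res["significant"].to_numpy()
        )
        assert (res["p"] > 0).all() and (res["p"] <= 1).all()

    def test_group_column_resolution(self, small_cohort):
        from thicknet import CohortTable

        cohort, nodes = small_cohort
        df = cohort.data.copy()
        df["group"] = ["A"] * 20 + ["B"] * 20
        tagged = CohortTable(df)
        res = compare_global(
            tagged, ("A", "B"), nodes, DensitySweep((27.0,), 27.0),
            n_perm=20, seed=1,
        )
        assert set(res["measure"]) == {
            "global_efficiency", "local_efficiency", "transitivity", "strength",
        }
        with pytest.raises(ValidationError, match="C"):
            compare_global(tagged, ("A", "C"), nodes, n_perm=10, seed=1)


class TestCompareNodal:
    def test_small_n_perm_warns_and_blocks_significance(self, small_cohort):
        cohort, nodes = small_cohort
        ids = cohort.subjects
        with pytest.warns(UserWarning, match="minimum attainable p"):
            res = compare_nodal(
                cohort, (ids[:20], ids[20:]), nodes, density=27.0,
                n_perm=10, alpha=0.05, seed=3,
            )
        assert res["p"].min() >= 1 / 11 - 1e-12
        assert not res["significant"].any()
        assert (res["p_fdr"] >= res["p"] - 1e-12).all()
        assert (res["p_fdr"] <= 1).all()


class TestMultiplicityAdjustments:
    def test_bh_worked_example(self):
        assert fdr_adjust([0.01, 0.04, 0.03, 0.005]) == pytest.approx(
            [0.02, 0.04, 0.04, 0.02]
        )

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.3]) == [0.3]
        assert hochberg_adjust([0.5]) == [0.5]

    def test_equal_ps_all_map_to_top_rank(self):
        assert fdr_adjust([0.04] * 4) == pytest.approx([0.04] * 4)

    def test_hochberg_worked_example(self):
        assert hochberg_adjust([0.02, 0.04]) == pytest.approx([0.04, 0.04])

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
            with pytest.raises(ValidationError):
                fdr_adjust(bad)
            with pytest.raises(ValidationError):
                hochberg_adjust(bad)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=20,
        )
    )
    def test_agree_with_literal_step_up(self, ps):
        np.testing.assert_allclose(fdr_adjust(ps), literal_bh(ps), atol=1e-12)
        np.testing.assert_allclose(
            hochberg_adjust(ps), literal_hochberg(ps), atol=1e-12
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=15
        )
    )
    def test_adjusted_order_preserved_and_monotone(self, ps):
        adj = np.asarray(hochberg_adjust(ps))
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
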