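import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from _oracles import fisher_p_enumeration, is_conditional_mle

from rpmap import (
    FdrConfig,
    PermutationNull,
    ValidationError,
    VoxelGrid,
    adjusted_p,
    build_cohort_maps,
    compare_cohorts,
    compare_maps,
    conditional_mle_or,
    fisher_two_sided,
    log_odds_ratio,
    permutation_null,
    q_values,
)
from rpmap.voxelstats import FisherLookup, two_sided_p_grid


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table, expected",
        [
            # 10/12 vs 3/10 resected: the single-voxel worked example
            ((10, 2, 3, 7), 0.0274214949137550),
            # permanent deficits 0/56 vs 1/52
            ((0, 56, 1, 51), 0.4814814814814815),
            ((5, 5, 5, 5), 1.0),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_two_sided(table) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_tables(self):
        assert np.isnan(fisher_two_sided((0, 0, 0, 0)))
        assert fisher_two_sided((0, 0, 3, 2)) == 1.0  # empty row: single table
        assert fisher_two_sided((0, 4, 0, 6)) == 1.0  # empty column

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValidationError):
            fisher_two_sided((1, -1, 2, 3))
        with pytest.raises(ValidationError):
            fisher_two_sided((1, 2, 3))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        m_a=st_h.integers(0, 20),
        m_b=st_h.integers(0, 20),
        af=st_h.floats(0, 1),
        cf=st_h.floats(0, 1),
    )
    def test_matches_exhaustive_enumeration(self, m_a, m_b, af, cf):
        if m_a + m_b == 0:
            return
        a, c = int(round(af * m_a)), int(round(cf * m_b))
        table = (a, m_a - a, c, m_b - c)
        assert fisher_two_sided(table) == pytest.approx(fisher_p_enumeration(*table), abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m_a, m_b = rng.integers(1, 40, size=2)
            a, c = rng.integers(0, m_a + 1), rng.integers(0, m_b + 1)
            table = [[a, m_a - a], [c, m_b - c]]
            assert fisher_two_sided(table) == pytest.approx(
                st.fisher_exact(table).pvalue, abs=1e-9
            )


class TestConditionalMleOr:
    def test_worked_example_odds_ratio(self):
        # conditional MLE, not the sample cross-product ratio 11.67
        assert conditional_mle_or((10, 2, 3, 7)) == pytest.approx(10.1269, abs=1e-3)

    def test_symmetric_table_is_one(self):
        assert conditional_mle_or((5, 5, 5, 5)) == pytest.approx(1.0, abs=1e-9)

    def test_boundaries_and_degeneracies(self):
        assert conditional_mle_or((12, 0, 3, 7)) == np.inf  # cell at upper bound
        assert conditional_mle_or((0, 12, 3, 7)) == 0.0  # cell at lower bound
        assert np.isnan(conditional_mle_or((0, 0, 0, 0)))
        assert np.isnan(conditional_mle_or((3, 0, 2, 0)))  # single-point support
        assert log_odds_ratio((5, 5, 5, 5)) == pytest.approx(0.0, abs=1e-9)

    def test_estimate_maximizes_conditional_likelihood(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m_a, m_b = rng.integers(2, 15, size=2)
            a, c = rng.integers(0, m_a + 1), rng.integers(0, m_b + 1)
            table = (a, m_a - a, c, m_b - c)
            psi = conditional_mle_or(table)
            if not np.isfinite(psi) or psi == 0.0:
                continue
            assert is_conditional_mle(*table, psi)

    def test_agrees_with_noncentral_hypergeometric_expectation(self):
        # independent route: scipy's Fisher noncentral hypergeometric mean
        for table in [(10, 2, 3, 7), (4, 6, 7, 3), (1, 9, 5, 5), (8, 2, 2, 8)]:
            a, b, c, d = table
            psi = conditional_mle_or(table)
            mean = st.nchypergeom_fisher.mean(a + b + c + d, a + b, a + c, psi)
            assert mean == pytest.approx(a, abs=1e-6)


class TestCompareMaps:
    def test_identical_cohorts_give_null_statistics(self, grid16, random_cases):
        cases = random_cases(grid16, 6, seed=3)
        maps = build_cohort_maps(cases, "left")
        cmp = compare_maps(maps, maps)
        p = cmp.p_raw[cmp.testable_mask]
        assert np.allclose(p, 1.0)
        lor = cmp.log_or[cmp.testable_mask]
        assert np.allclose(lor[~np.isnan(lor)], 0.0, atol=1e-9)

    def test_voxel_testable_in_one_cohort_only_is_nan(self, grid16, case_factory):
        a = build_cohort_maps([case_factory(grid16, case_id="a", tumor_voxels=((1, 1, 1),))], "left")
        b = build_cohort_maps([case_factory(grid16, case_id="b", tumor_voxels=((2, 2, 2),))], "left")
        cmp = compare_maps(a, b)
        assert np.isnan(cmp.p_raw[1, 1, 1]) and np.isnan(cmp.p_raw[2, 2, 2])
        assert cmp.comparison_mask.sum() == 2 and cmp.testable_mask.sum() == 0

    def test_memoized_lookup_is_bit_identical_to_direct_computation(self, random_cases):
        grid = VoxelGrid.default((16, 16, 16))
        maps_a = build_cohort_maps(random_cases(grid, 7, cohort="A", seed=11), "left")
        maps_b = build_cohort_maps(random_cases(grid, 5, cohort="B", seed=12), "left")
        cmp = compare_maps(maps_a, maps_b)
        a, b, c, d = cmp.tables()
        direct = np.array([fisher_two_sided(t) for t in zip(a, b, c, d)])
        assert np.array_equal(cmp.p_raw[cmp.testable_mask], direct)

    def test_lookup_vectorization_matches_scalar(self):
        lut = FisherLookup(8, 8)
        rng = np.random.default_rng(5)
        t_a, t_b = rng.integers(1, 9, size=(2, 50))
        a = rng.integers(0, t_a + 1)
        c = rng.integers(0, t_b + 1)
        got = lut.p_many(t_a, a, t_b, c)
        want = [fisher_two_sided((x, ta - x, y, tb - y)) for ta, x, tb, y in zip(t_a, a, t_b, c)]
        assert np.array_equal(got, np.array(want))


def _make_null(null_p, shape=(1, 1, 1)):
    """Assemble a PermutationNull directly for rank-formula unit tests."""
    null_p = np.asarray(null_p, dtype=float)
    mask = np.ones(shape, dtype=bool)
    assert mask.sum() == null_p.shape[1]
    return PermutationNull(
        m=null_p.shape[0],
        seed=0,
        null_p=null_p,
        testable_mask=mask,
        assignments=np.zeros((null_p.shape[0], 1), dtype=np.intp),
        case_ids=("a", "b"),
        n_a=1,
    )


class TestAdjustedP:
    def test_hand_counted_rank(self):
        null = _make_null(np.array([[0.2], [0.5], [0.7], [1.0]]))
        padj = adjusted_p(np.array([0.5]), null)
        assert padj[0, 0, 0] == pytest.approx((1 + 2) / 5)

    def test_extreme_ranks(self):
        null = _make_null(np.array([[0.2], [0.5], [0.7], [1.0]]))
        assert adjusted_p(np.array([0.1]), null)[0, 0, 0] == pytest.approx(1 / 5)
        assert adjusted_p(np.array([1.0]), null)[0, 0, 0] == pytest.approx(1.0)


class TestQValues:
    def test_unreachable_minimum_gives_zero_q(self):
        # each voxel's null minimum is tied, so no relabeling attains the
        # smallest possible adjusted p; a voxel observed below every null
        # value then has estimated false discoveries 0, hence q = 0
        null_p = np.array([[0.3, 0.4], [0.3, 0.4], [0.7, 0.8], [1.0, 0.9]])
        null = _make_null(null_p, shape=(2, 1, 1))
        padj = adjusted_p(np.array([0.1, 0.85]), null)
        q, diff = q_values(padj, null, FdrConfig(0.2))
        assert q[0, 0, 0] == 0.0
        assert diff[0, 0, 0] and not diff[1, 0, 0]

    def test_q_monotone_in_adjusted_p_and_nested_masks(self, random_cases):
        grid = VoxelGrid.default((10, 10, 10))
        ca = random_cases(grid, 6, cohort="A", seed=21, p_resect=0.8)
        cb = random_cases(grid, 6, cohort="B", seed=22, p_resect=0.3)
        res = compare_cohorts(ca, cb, m=60, seed=9)
        mask = res.testable_mask
        padj, q = res.p_adj[mask], res.q[mask]
        order = np.argsort(padj)
        assert (np.diff(q[order]) >= -1e-12).all()
        _, diff_strict = q_values(res.p_adj, res.null, FdrConfig(0.05))
        _, diff_loose = q_values(res.p_adj, res.null, FdrConfig(0.3))
        assert not (diff_strict & ~diff_loose).any()
        assert (q >= 0).all() and (q <= 1).all()


class TestPermutationNull:
    def test_single_swap_is_exhaustive(self, grid16, case_factory):
        a = [case_factory(grid16, case_id="a", tumor_voxels=((1, 1, 1),))]
        b = [case_factory(grid16, case_id="b", cohort="B", tumor_voxels=((1, 1, 1),), residual_voxels=((1, 1, 1),))]
        null = permutation_null(a, b, m=1, seed=0)
        assert null.m == 1
        with pytest.raises(ValidationError, match="1"):
            permutation_null(a, b, m=2, seed=0)

    def test_seed_determinism(self, grid16, random_cases):
        ca = random_cases(grid16, 5, cohort="A", seed=1)
        cb = random_cases(grid16, 5, cohort="B", seed=2)
        n1 = permutation_null(ca, cb, m=30, seed=7)
        n2 = permutation_null(ca, cb, m=30, seed=7)
        n3 = permutation_null(ca, cb, m=30, seed=8)
        assert np.array_equal(n1.null_p, n2.null_p)
        assert not np.array_equal(n1.assignments, n3.assignments)

    def test_relabelings_distinct_and_exclude_identity(self, grid16, random_cases):
        ca = random_cases(grid16, 4, cohort="A", seed=1)
        cb = random_cases(grid16, 4, cohort="B", seed=2)
        null = permutation_null(ca, cb, m=40, seed=0)
        keys = {row.tobytes() for row in null.assignments}
        assert len(keys) == 40
        a_ids = {c.id for c in ca}
        identity = np.flatnonzero([cid in a_ids for cid in null.case_ids])
        assert identity.astype(null.assignments.dtype).tobytes() not in keys

    def test_null_p_matches_bruteforce_recomputation(self, random_cases):
        grid = VoxelGrid.default((8, 8, 8))
        ca = random_cases(grid, 4, cohort="A", seed=31)
        cb = random_cases(grid, 4, cohort="B", seed=32)
        null = permutation_null(ca, cb, m=20, seed=5)
        by_id = {c.id: c for c in ca + cb}
        pooled = [by_id[cid] for cid in null.case_ids]
        vox = np.argwhere(null.testable_mask)
        for j in range(null.m):
            in_a = np.zeros(len(pooled), dtype=bool)
            in_a[null.assignments[j]] = True
            group_a = [c for c, f in zip(pooled, in_a) if f]
            group_b = [c for c, f in zip(pooled, in_a) if not f]
            for vi, (x, y, z) in enumerate(vox):
                t_a = sum(c.tumor[x, y, z] for c in group_a)
                r_a = sum(c.residual[x, y, z] for c in group_a)
                t_b = sum(c.tumor[x, y, z] for c in group_b)
                r_b = sum(c.residual[x, y, z] for c in group_b)
                expected = fisher_two_sided((t_a - r_a, r_a, t_b - r_b, r_b))
                assert null.null_p[j, vi] == expected

    def test_adjusted_p_invariant_to_within_cohort_order(self, grid16, random_cases):
        ca = random_cases(grid16, 5, cohort="A", seed=41)
        cb = random_cases(grid16, 5, cohort="B", seed=42)
        r1 = compare_cohorts(ca, cb, m=25, seed=3)
        r2 = compare_cohorts(ca[::-1], cb[::-1], m=25, seed=3)
        assert np.array_equal(r1.p_adj, r2.p_adj, equal_nan=True)
        assert np.array_equal(r1.p_raw, r2.p_raw, equal_nan=True)


class TestAdjustedPCalibration:
    def test_super_uniform_under_exchangeable_null(self):
        # both cohorts drawn from one process: the empirical CDF of p_adj
        # must not exceed the uniform CDF beyond Monte-Carlo noise
        from rpmap import synthdata as sd

        xs = np.linspace(0.1, 0.9, 9)
        ecdfs = []
        for rep in range(10):
            truth = sd.uniform_truth(0.6, shape=(14, 14, 14), residual_model="bernoulli", seed=rep)
            ca = sd.simulate_cohort(truth, 6, "A", seed=100 + rep)
            cb = sd.simulate_cohort(truth, 6, "B", seed=200 + rep)
            res = compare_cohorts(ca, cb, m=40, seed=rep)
            padj = res.p_adj[res.testable_mask]
            ecdfs.append([(padj <= x).mean() for x in xs])
        ecdfs = np.asarray(ecdfs)
        mean = ecdfs.mean(axis=0)
        se = ecdfs.std(axis=0, ddof=1) / np.sqrt(len(ecdfs))
        assert (mean <= xs + 3 * se + 1e-9).all()


class TestCompareCohorts:
    def test_summary_counts_are_self_consistent(self, grid16, random_cases):
        ca = random_cases(grid16, 5, cohort="A", seed=51)
        cb = random_cases(grid16, 5, cohort="B", seed=52)
        res = compare_cohorts(ca, cb, m=30, seed=2)
        s = res.summary()
        assert s["testable_voxels"] == int(res.testable_mask.sum())
        assert s["differential_voxels"] == int(res.differential.sum())
        assert s["m"] == 30 and s["seed"] == 2
        thr = res.log_or_thresholded
        assert int(np.isfinite(thr).sum()) <= s["differential_voxels"]

    def test_grid_mismatch_rejected(self, random_cases):
        g1 = VoxelGrid.default((10, 10, 10))
        g2 = VoxelGrid.default((10, 10, 10), voxel_mm=2.0)
        a = build_cohort_maps(random_cases(g1, 3, seed=1), "left")
        b = build_cohort_maps(random_cases(g2, 3, cohort="B", seed=2), "left")
        with pytest.raises(ValidationError):
            compare_maps(a, b)
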