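import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cpmnet.cpm import ThresholdSpec, run_cpm_cv
from cpmnet.inference import (
    build_blocks,
    enumerate_reachable,
    fdr_bh,
    mannwhitney_exact,
    permutation_pvalue,
    permute_trait,
    split_half_stability,
    steiger_z,
)
from cpmnet.io import CohortTable
from cpmnet.synthetic import generate_cohort, generate_stack


def cohort_from(families):
    """families: list of (family_id, sibling_type) per subject."""
    return CohortTable(
        pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(families))],
                "family_id": [f for f, _ in families],
                "sibling_type": [s for _, s in families],
                "gF": np.arange(len(families), dtype=float),
            }
        )
    )


class TestBlocks:
    def test_all_singletons_form_one_group(self):
        blocks = build_blocks(cohort_from([(f"F{i}", "nontwin") for i in range(5)]))
        assert len(blocks.signature_groups) == 1
        (sig,) = blocks.signature_groups
        assert len(blocks.signature_groups[sig]) == 5

    def test_mz_and_dz_pairs_never_mix(self):
        blocks = build_blocks(
            cohort_from([("F1", "MZ"), ("F1", "MZ"), ("F2", "DZ"), ("F2", "DZ")])
        )
        assert len(blocks.signature_groups) == 2
        trait = np.array([1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(0)
        for _ in range(200):
            out = permute_trait(trait, blocks, rng)
            assert set(out[:2]) == {1.0, 2.0}  # MZ values stay in the MZ family
            assert set(out[2:]) == {3.0, 4.0}

    def test_identical_structure_families_swap_wholesale(self):
        fams = [("A", "MZ"), ("A", "MZ"), ("A", "nontwin"),
                ("B", "MZ"), ("B", "MZ"), ("B", "nontwin")]
        blocks = build_blocks(cohort_from(fams))
        assert len(blocks.signature_groups) == 1
        trait = np.arange(6.0)
        rng = np.random.default_rng(1)
        swapped = False
        for _ in range(100):
            out = permute_trait(trait, blocks, rng)
            # family blocks move wholesale: the nontwin slot of family A holds
            # either its own nontwin value or family B's
            assert out[2] in (2.0, 5.0)
            if out[2] == 5.0:
                swapped = True
                assert set(out[:2]) == {3.0, 4.0}
        assert swapped

    def test_missing_family_info_becomes_singleton(self):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "family_id": [None, "F1"],
                "sibling_type": ["nontwin", "nontwin"],
            }
        )
        blocks = build_blocks(CohortTable(df))
        assert len(blocks.families) == 2
        assert all(len(f.indices) == 1 for f in blocks.families)


class TestPermuteTrait:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_multiset_always_preserved(self, seed):
        fams = [("A", "MZ"), ("A", "MZ"), ("B", "DZ"), ("B", "DZ"),
                ("C", "nontwin"), ("C", "nontwin"), ("D", "nontwin")]
        blocks = build_blocks(cohort_from(fams))
        trait = np.random.default_rng(seed).standard_normal(len(fams))
        out = permute_trait(trait, blocks, np.random.default_rng(seed + 1))
        assert sorted(out.tolist()) == sorted(trait.tolist())

    def test_empirical_support_equals_enumerated_reachable_set(self):
        # 8 subjects: two identical two-nontwin families + one MZ pair + 2 singletons
        fams = [("A", "nontwin"), ("A", "nontwin"), ("B", "nontwin"), ("B", "nontwin"),
                ("C", "MZ"), ("C", "MZ"), ("D", "nontwin"), ("E", "nontwin")]
        blocks = build_blocks(cohort_from(fams))
        trait = np.arange(8.0)
        reachable = enumerate_reachable(trait, blocks)
        # 2 family perms x 2!x2! within + MZ 2! + singleton 2! = 2*4*2*2 = 32
        assert len(reachable) == 32
        rng = np.random.default_rng(99)
        seen = {tuple(permute_trait(trait, blocks, rng)) for _ in range(10000)}
        assert seen == reachable

    def test_mz_values_never_reach_nontwin_slots(self):
        fams = [("A", "MZ"), ("A", "MZ"), ("B", "nontwin"), ("B", "nontwin")]
        blocks = build_blocks(cohort_from(fams))
        trait = np.array([10.0, 11.0, 20.0, 21.0])
        rng = np.random.default_rng(3)
        for _ in range(500):
            out = permute_trait(trait, blocks, rng)
            assert set(out[2:]) == {20.0, 21.0}


class TestPermutationPvalue:
    def test_extreme_observed_statistics(self):
        fams = [(f"F{i}", "nontwin") for i in range(6)]
        blocks = build_blocks(cohort_from(fams))
        trait = np.arange(6.0)

        # runner that returns a statistic below/above anything the null gives
        low = permutation_pvalue(lambda s, t: -1.0 if t is trait else 0.0,
                                 None, trait, blocks, n_iterations=50, seed=0)
        assert low.p_value == 1.0
        high = permutation_pvalue(lambda s, t: 1.0 if t is trait else 0.0,
                                  None, trait, blocks, n_iterations=50, seed=0)
        assert high.p_value == 0.0

    def test_b_zero_rejected(self):
        blocks = build_blocks(cohort_from([("A", "nontwin")] * 4))
        with pytest.raises(ValueError):
            permutation_pvalue(lambda s, t: 0.0, None, np.arange(4.0), blocks,
                               n_iterations=0)

    def test_null_p_roughly_uniform_on_exchangeable_data(self):
        # fully exchangeable null data: p should be ~uniform; check a coarse
        # Kolmogorov band over repeated small cohorts
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(60):
            trait = rng.standard_normal(16)
            edges = rng.standard_normal((16, 45))
            blocks = build_blocks(cohort_from([(f"F{i}", "nontwin") for i in range(16)]))

            def runner(_, t, e=edges):
                return run_cpm_cv(e, t, ThresholdSpec("p", 0.1)).scores["combined"].r_s

            nd = permutation_pvalue(runner, None, trait, blocks,
                                    n_iterations=40, seed=int(rng.integers(2**31)))
            pvals.append(nd.p_value)
        grid = np.linspace(0, 1, 21)
        ecdf = [(np.asarray(pvals) <= g).mean() for g in grid]
        assert np.abs(np.array(ecdf) - grid).max() < 0.25


class TestFdr:
    def test_step_up_hand_computation(self):
        q = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh(np.full(5, 0.2)), np.full(5, 0.2))

    def test_monotone_in_sorted_order_and_bounded(self, rng):
        p = rng.uniform(0, 1, 50)
        q = fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestMannWhitney:
    def test_rank_sum_71_worked_example(self):
        # larger group (n=9) holding ranks summing to 71 of 78
        x = [3, 5, 6, 7, 8, 9, 10, 11, 12]
        y = [1, 2, 4]
        res = mannwhitney_exact(x, y)
        assert res.rank_sum_x == 71
        assert res.p_value == pytest.approx(0.018, abs=5e-4)
        assert res.exact

    def test_complete_separation_9_vs_3(self):
        res = mannwhitney_exact(list(range(10, 19)), [1, 2, 3])
        assert res.p_value == pytest.approx(2 / 220)

    def test_identical_singletons(self):
        assert mannwhitney_exact([1.0], [1.0]).p_value == 1.0

    @pytest.mark.parametrize("n_x,n_y", [(1, 1), (2, 3), (4, 4), (5, 3), (7, 3), (5, 5)])
    def test_agrees_with_itertools_enumeration(self, n_x, n_y, rng):
        # complete oracle sweep for small group sizes without ties
        x = rng.standard_normal(n_x)
        y = rng.standard_normal(n_y)
        res = mannwhitney_exact(x, y)
        ranks = stats.rankdata(np.concatenate([x, y]))
        obs = ranks[:n_x].sum()
        sums = [sum(c) for c in itertools.combinations(ranks, n_x)]
        p_le = np.mean([s <= obs for s in sums])
        p_ge = np.mean([s >= obs for s in sums])
        assert res.p_value == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_ties_handled_with_midranks(self):
        res = mannwhitney_exact([1.0, 2.0, 2.0, 3.0], [2.0, 4.0])
        ranks = stats.rankdata([1.0, 2.0, 2.0, 3.0, 2.0, 4.0])
        obs = ranks[4:].sum()
        sums = [sum(c) for c in itertools.combinations(ranks, 2)]
        p = min(1.0, 2 * min(np.mean([s <= obs for s in sums]),
                             np.mean([s >= obs for s in sums])))
        assert res.p_value == pytest.approx(p)

    def test_large_samples_fall_back_to_normal_approximation(self, rng):
        res = mannwhitney_exact(rng.standard_normal(20), rng.standard_normal(15))
        assert not res.exact

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_exact([], [1.0])


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        res = steiger_z(0.4, 0.4, 0.3, 50)
        assert res.z == pytest.approx(0.0)
        assert res.p_value == pytest.approx(0.5)

    def test_formula_transcription_oracle(self):
        # independent transcription of the dependent-correlation z with one
        # shared variable (pooled-rbar covariance term)
        r1, r2, r12, n = 0.5, 0.3, 0.4, 103
        rbar = (r1 + r2) / 2
        psi = r12 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)
        s = psi / (1 - rbar**2) ** 2
        expect = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt((n - 3) / (2 - 2 * s))
        res = steiger_z(r1, r2, r12, n)
        assert res.z == pytest.approx(expect, abs=1e-6)
        assert res.z == pytest.approx(2.0661, abs=1e-3)

    def test_z_increases_with_n(self):
        zs = [steiger_z(0.5, 0.3, 0.4, n).z for n in (10, 50, 200)]
        assert zs[0] < zs[1] < zs[2]

    def test_degenerate_correlations_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(1.0, 0.3, 0.2, 50)


class TestSplitHalf:
    def test_fixed_seed_reproducible(self, signal_data):
        cohort, _, stack = signal_data
        trait = cohort.trait("gF")
        a = split_half_stability(stack, trait, n_iterations=20, seed=5)
        b = split_half_stability(stack, trait, n_iterations=20, seed=5)
        np.testing.assert_array_equal(a.r_s, b.r_s)
        np.testing.assert_array_equal(a.degrees_pos, b.degrees_pos)

    def test_null_data_centered_near_zero(self):
        cohort, gt = generate_cohort(80, seed=31, n_nodes=15, beta=0.0,
                                     lambda_motion=0.0)
        stack = generate_stack(cohort, "task1", gt)
        res = split_half_stability(stack, cohort.trait("gF"),
                                   n_iterations=100, seed=6)
        assert abs(res.r_s.mean()) < 0.1

    def test_signal_data_tracks_full_sample_loocv(self, signal_data):
        cohort, _, stack = signal_data
        trait = cohort.trait("gF")
        res = split_half_stability(stack, trait, ThresholdSpec("p", 0.01),
                                   n_iterations=100, seed=7)
        full = run_cpm_cv(stack, trait, ThresholdSpec("p", 0.01))
        assert res.r_s.mean() > 0
        assert res.r_s.mean() == pytest.approx(full.scores["combined"].r_s, abs=0.15)
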