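import numpy as np
import pytest
from scipy import stats

from cpmnet.cpm import (
    EdgeMaskPair,
    ThresholdSpec,
    edge_trait_association,
    fit_strength_model,
    make_folds,
    network_strength,
    run_cpm_cv,
    score_performance,
    select_edges,
)
from cpmnet.edges import n_edges, vec_to_sym


def brute_force_cpm_loocv(edges, trait, p_level):
    """Independent naive re-implementation: per-edge scipy pearsonr, explicit
    loops, np.polyfit — used as the oracle for run_cpm_cv."""
    n, e = edges.shape
    preds = {"cn": np.empty(n), "an": np.empty(n), "combined": np.empty(n)}
    for left_out in range(n):
        tr = [i for i in range(n) if i != left_out]
        rs, ps = [], []
        for j in range(e):
            r, p = stats.pearsonr(edges[tr, j], trait[tr])
            rs.append(r)
            ps.append(p)
        pos = [j for j in range(e) if rs[j] > 0 and ps[j] < p_level]
        neg = [j for j in range(e) if rs[j] < 0 and ps[j] < p_level]
        strengths = {
            "cn": lambda row: sum(row[j] for j in pos),
            "an": lambda row: sum(row[j] for j in neg),
            "combined": lambda row: sum(row[j] for j in pos) - sum(row[j] for j in neg),
        }
        for net, fn in strengths.items():
            s_tr = np.array([fn(edges[i]) for i in tr])
            if np.ptp(s_tr) == 0:
                preds[net][left_out] = trait[tr].mean()
                continue
            slope, intercept = np.polyfit(s_tr, trait[tr], 1)
            preds[net][left_out] = intercept + slope * fn(edges[left_out])
    return preds


class TestEdgeTraitAssociation:
    def test_trait_equal_to_edge_gives_unit_correlation(self, rng):
        edges = rng.standard_normal((10, n_edges(4)))
        r, p = edge_trait_association(edges, edges[:, 2])
        assert r[2] == pytest.approx(1.0)
        assert p[2] == pytest.approx(0.0, abs=1e-12)

    def test_p_value_matches_t_distribution_oracle(self, rng):
        # construct an edge with Pearson r = 0.6328 at n = 10 -> p ~ 0.05
        y = rng.standard_normal(10)
        yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
        resid = rng.standard_normal(10)
        resid -= resid.mean() + (resid @ yc) * yc  # orthogonal to y
        target_r = 0.6328
        x = target_r * yc + np.sqrt(1 - target_r**2) * resid / np.linalg.norm(resid)
        edges = np.column_stack([x] * n_edges(3))
        r, p = edge_trait_association(edges, y)
        t = target_r * np.sqrt(8 / (1 - target_r**2))
        assert r[0] == pytest.approx(target_r, abs=1e-9)
        assert p[0] == pytest.approx(2 * stats.t.sf(t, 8), rel=1e-9)
        assert p[0] == pytest.approx(0.05, abs=0.001)

    def test_covariate_identical_to_trait_kills_partial_r(self, rng):
        edges = rng.standard_normal((30, n_edges(5)))
        y = rng.standard_normal(30)
        r, _ = edge_trait_association(edges, y, covariates=y[:, None])
        assert np.abs(r).max() < 1e-8

    def test_partial_correlation_matches_residualization_oracle(self, rng):
        edges = rng.standard_normal((40, n_edges(5)))
        y = rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        r, _ = edge_trait_association(edges, y, covariates=cov)
        design = np.column_stack([np.ones(40), cov])
        beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
        yr = y - design @ beta_y
        for j in [0, 3, 7]:
            beta_x, *_ = np.linalg.lstsq(design, edges[:, j], rcond=None)
            xr = edges[:, j] - design @ beta_x
            assert r[j] == pytest.approx(stats.pearsonr(xr, yr).statistic, abs=1e-10)

    def test_constant_trait_rejected_constant_edge_warned(self, rng):
        edges = rng.standard_normal((10, n_edges(4)))
        with pytest.raises(ValueError, match="constant"):
            edge_trait_association(edges, np.ones(10))
        edges[:, 1] = 5.0
        with pytest.warns(UserWarning, match="constant edge"):
            r, p = edge_trait_association(edges, rng.standard_normal(10))
        assert r[1] == 0.0 and p[1] == 1.0


class TestSelectEdges:
    def test_sparsity_mode_cardinality(self, rng):
        e = n_edges(15)  # 105 edges
        r = rng.uniform(-1, 1, e)
        p = rng.uniform(0, 1, e)
        masks = select_edges(r, p, ThresholdSpec("sparsity", 10 / e))
        assert masks.pos.sum() == 10 and masks.neg.sum() == 10

    @pytest.mark.parametrize("spec", [ThresholdSpec("p", 0.05), ThresholdSpec("sparsity", 0.1)])
    def test_cn_an_always_disjoint(self, spec, rng):
        r = rng.uniform(-1, 1, n_edges(12))
        p = rng.uniform(0, 1, n_edges(12))
        masks = select_edges(r, p, spec)
        assert not (masks.pos & masks.neg).any()

    def test_matches_brute_force_on_toy_instance(self, rng):
        # 6 subjects, 5-node universe: re-derive the mask from a correlation table
        edges = rng.standard_normal((6, n_edges(5)))
        trait = rng.standard_normal(6)
        r, p = edge_trait_association(edges, trait)
        masks = select_edges(r, p, ThresholdSpec("p", 0.3))
        for j in range(n_edges(5)):
            rr, pp = stats.pearsonr(edges[:, j], trait)
            assert masks.pos[j] == (rr > 0 and pp < 0.3)
            assert masks.neg[j] == (rr < 0 and pp < 0.3)

    def test_threshold_nesting(self, rng):
        # stricter p-threshold masks are subsets of looser ones
        edges = rng.standard_normal((40, n_edges(10)))
        trait = edges[:, 0] + 0.5 * rng.standard_normal(40)
        r, p = edge_trait_association(edges, trait)
        strict = select_edges(r, p, ThresholdSpec("p", 0.001))
        loose = select_edges(r, p, ThresholdSpec("p", 0.01))
        assert not (strict.pos & ~loose.pos).any()
        assert not (strict.neg & ~loose.neg).any()

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec("p", 1.5)
        with pytest.raises(ValueError):
            ThresholdSpec("bogus", 0.1)


class TestNetworkStrength:
    def test_single_edge_and_empty_masks(self, rng):
        e = n_edges(6)
        vec = rng.standard_normal(e)
        mat = vec_to_sym(vec, 6)
        pos = np.zeros(e, bool)
        pos[4] = True
        s = network_strength(mat, EdgeMaskPair(pos, np.zeros(e, bool), 6))
        assert s.cn == pytest.approx(vec[4])
        assert s.an == 0.0 and s.combined == pytest.approx(vec[4])
        empty = network_strength(mat, EdgeMaskPair(np.zeros(e, bool), np.zeros(e, bool), 6))
        assert empty.cn == empty.an == empty.combined == 0.0

    def test_matches_exhaustive_pair_loop(self, rng):
        # brute-force oracle: loop over all node pairs once
        n = 8
        vec = rng.standard_normal(n_edges(n))
        mat = vec_to_sym(vec, n)
        pos = rng.random(n_edges(n)) < 0.3
        neg = ~pos & (rng.random(n_edges(n)) < 0.3)
        masks = EdgeMaskPair(pos, neg, n)
        pos_sq, neg_sq = masks.pos_square(), masks.neg_square()
        cn = sum(mat[i, j] * pos_sq[i, j] for i in range(n) for j in range(i + 1, n))
        an = sum(mat[i, j] * neg_sq[i, j] for i in range(n) for j in range(i + 1, n))
        s = network_strength(mat, masks)
        assert s.cn == pytest.approx(cn) and s.an == pytest.approx(an)
        assert s.combined == s.cn - s.an  # exact identity

    def test_uncovered_edge_rejected(self):
        e = n_edges(4)
        vec = np.zeros(e)
        vec[0] = np.nan
        pos = np.zeros(e, bool)
        pos[0] = True
        with pytest.raises(ValueError, match="uncovered"):
            network_strength(vec, EdgeMaskPair(pos, np.zeros(e, bool), 4))


class TestFitStrengthModel:
    def test_noiseless_recovery(self, rng):
        s = rng.standard_normal(20)
        coef = fit_strength_model(s, 2 * s + 1)
        assert coef[1] == pytest.approx(2.0) and coef[0] == pytest.approx(1.0)

    def test_four_point_normal_equations(self):
        s = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        n = 4
        slope = (n * (s * y).sum() - s.sum() * y.sum()) / (n * (s**2).sum() - s.sum() ** 2)
        intercept = y.mean() - slope * s.mean()
        coef = fit_strength_model(s, y)
        assert coef[0] == pytest.approx(intercept) and coef[1] == pytest.approx(slope)

    def test_null_covariate_leaves_predictions_unchanged(self, rng):
        n = 500
        s = rng.standard_normal(n)
        y = 1.5 * s + rng.standard_normal(n)
        cov = rng.integers(0, 2, n).astype(float)  # true zero effect
        plain = fit_strength_model(s, y)
        with_cov = fit_strength_model(s, y, covariates=cov[:, None])
        pred_plain = plain[0] + plain[1] * s
        pred_cov = with_cov[0] + with_cov[1] * s + with_cov[2] * cov
        assert np.abs(pred_plain - pred_cov).max() < 0.2  # within noise

    def test_rank_deficient_design_names_columns(self, rng):
        s = rng.standard_normal(10)
        with pytest.raises(ValueError, match="covariate_0"):
            fit_strength_model(s, rng.standard_normal(10), covariates=s[:, None])


class TestScorePerformance:
    def test_perfect_and_anti_prediction(self, rng):
        y = rng.standard_normal(10)
        s = score_performance(y, y)
        assert s.r_s == pytest.approx(1.0) and s.r_s_squared == pytest.approx(100.0)
        s = score_performance(-y, y)
        assert s.r_s == pytest.approx(-1.0) and s.r_s_squared == 0.0  # clamp

    def test_ties_use_midranks(self):
        pred = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        obs = np.array([2.0, 1.0, 4.0, 4.0, 6.0])
        rank_then_pearson = stats.pearsonr(
            stats.rankdata(pred), stats.rankdata(obs)
        ).statistic
        assert score_performance(pred, obs).r_s == pytest.approx(rank_then_pearson)

    def test_constant_prediction_flagged(self):
        s = score_performance(np.ones(5), np.arange(5.0))
        assert s.flagged and s.r_s == 0.0


class TestRunCpmCv:
    def test_loocv_matches_brute_force_oracle(self, rng):
        edges = rng.standard_normal((6, n_edges(5)))
        trait = rng.standard_normal(6)
        res = run_cpm_cv(edges, trait, ThresholdSpec("p", 0.3))
        oracle = brute_force_cpm_loocv(edges, trait, 0.3)
        for net in ("cn", "an", "combined"):
            np.testing.assert_allclose(res.predicted[net], oracle[net], atol=1e-9)

    def test_left_out_trait_does_not_affect_own_prediction(self, rng):
        edges = rng.standard_normal((12, n_edges(6)))
        trait = rng.standard_normal(12)
        res1 = run_cpm_cv(edges, trait, ThresholdSpec("p", 0.2))
        trait2 = trait.copy()
        trait2[5] += 100.0
        res2 = run_cpm_cv(edges, trait2, ThresholdSpec("p", 0.2))
        assert res2.predicted["combined"][5] == pytest.approx(
            res1.predicted["combined"][5]
        )

    def test_kfold_with_k_equal_n_matches_loocv(self, rng):
        n = 10
        edges = rng.standard_normal((n, n_edges(6)))
        trait = rng.standard_normal(n)
        loo = run_cpm_cv(edges, trait, ThresholdSpec("p", 0.3), cv="loo")
        kf = run_cpm_cv(edges, trait, ThresholdSpec("p", 0.3), cv="kfold", k=n, seed=0)
        np.testing.assert_allclose(
            np.sort(kf.predicted["combined"]), np.sort(loo.predicted["combined"])
        )
        # identical per subject, not just as a multiset
        np.testing.assert_allclose(kf.predicted["combined"], loo.predicted["combined"])

    def test_combined_identity_in_every_fold(self, signal_data):
        cohort, _, stack = signal_data
        res = run_cpm_cv(stack, cohort.trait("gF"), ThresholdSpec("p", 0.05))
        for masks in res.fold_masks:
            s = network_strength(stack.edge_matrix(), masks)
            np.testing.assert_array_equal(s.combined, s.cn - s.an)

    def test_missing_trait_rejected(self, rng):
        edges = rng.standard_normal((8, n_edges(5)))
        trait = rng.standard_normal(8)
        trait[2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            run_cpm_cv(edges, trait)

    @pytest.mark.parametrize(
        "spec", [ThresholdSpec("p", 0.05), ThresholdSpec("sparsity", 0.1)]
    )
    def test_batched_kernel_matches_per_trait_cv(self, spec, rng):
        # the batched multi-trait kernel must reproduce the plain CV loop
        # column by column (combined network)
        from cpmnet.cpm import batched_cpm_combined

        n = 20
        edges = rng.standard_normal((n, n_edges(8)))
        traits = rng.standard_normal((n, 5))
        traits[:, 0] = edges[:, 0] + 0.3 * rng.standard_normal(n)  # one signal column
        folds = make_folds(n, "kfold", 5, seed=3)
        r_s, preds = batched_cpm_combined(edges, traits, spec, folds)
        for b in range(traits.shape[1]):
            res = run_cpm_cv(edges, traits[:, b], spec, cv="kfold", k=5, seed=3)
            np.testing.assert_allclose(preds[:, b], res.predicted["combined"], atol=1e-9)
            assert r_s[b] == pytest.approx(res.scores["combined"].r_s, abs=1e-12)

    def test_kfold_requires_seed_and_balanced_folds(self):
        with pytest.raises(ValueError, match="seed"):
            make_folds(20, "kfold", 10, None)
        folds = make_folds(23, "kfold", 10, seed=1)
        sizes = sorted(len(f) for f in folds)
        assert sizes[-1] - sizes[0] <= 1
        assert sorted(np.concatenate(folds).tolist()) == list(range(23))
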