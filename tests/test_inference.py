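"""Statistics layer: rank correlations, Wilcoxon, permutation test, controls."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lesiongrad import (
    bin_delta_concordance,
    fit_slope_intercept,
    kendall_clinical,
    lesion_size_control,
    permutation_group_diff,
    residualize_anatomy,
    run_group_analysis,
    spearman_distance_concordance,
    wilcoxon_signed_rank,
)


class TestSpearman:
    def test_monotone_relations(self):
        d = np.arange(12.0)
        assert spearman_distance_concordance(d, d**3) == pytest.approx(1.0)
        assert spearman_distance_concordance(d, -d) == pytest.approx(-1.0)

    def test_tied_toy_matches_hand_ranking(self):
        d = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        c = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        # hand ranks: d -> 1, 2.5, 2.5, 4, 5, 6 ; c -> 2, 1, 4, 3, 6, 5
        rd = np.array([1.0, 2.5, 2.5, 4.0, 5.0, 6.0])
        rc = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        expect = np.corrcoef(rd, rc)[0, 1]
        assert spearman_distance_concordance(d, c, min_voxels=5) == pytest.approx(expect, abs=1e-12)

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="usable voxels"):
            spearman_distance_concordance(np.arange(5.0), np.arange(5.0))

    def test_nan_voxels_dropped(self):
        d = np.arange(15.0)
        c = d.copy()
        c[3] = np.nan
        assert spearman_distance_concordance(d, c) == pytest.approx(1.0)


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0], alternative="greater")
        assert w == 0.0
        assert p == pytest.approx(1 / 32)

    def test_exact_tail_matches_full_enumeration(self, rng):
        v = rng.standard_normal(8)
        _, p = wilcoxon_signed_rank(v, alternative="greater")
        ranks = stats.rankdata(np.abs(v))
        t_obs = ranks[v > 0].sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=8):
            t = sum(r for s, r in zip(signs, ranks) if s)
            if t >= t_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / 256, abs=1e-12)

    def test_negation_symmetry(self, rng):
        v = rng.standard_normal(9)
        _, p_pos = wilcoxon_signed_rank(v, alternative="greater")
        _, p_neg = wilcoxon_signed_rank(-v, alternative="less")
        assert p_pos == pytest.approx(p_neg, abs=1e-12)

    def test_symmetric_pairs_split_rank_sum(self):
        v = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        w, _ = wilcoxon_signed_rank(v)
        n = 6
        assert w == pytest.approx(n * (n + 1) / 4)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            v = rng.standard_normal(12)
            w, p = wilcoxon_signed_rank(v, alternative="greater")
            sp = stats.wilcoxon(v, alternative="greater", method="exact")
            assert p == pytest.approx(sp.pvalue, abs=1e-12)

    def test_normal_approximation_regime(self, rng):
        v = rng.standard_normal(40) + 0.4
        _, p = wilcoxon_signed_rank(v, alternative="greater")
        sp = stats.wilcoxon(v, alternative="greater", method="approx", correction=True)
        assert p == pytest.approx(sp.pvalue, rel=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank([1.0, 2.0, 0.0])


class TestResidualize:
    def test_exact_linear_relation_leaves_zero_residuals(self):
        anat = np.linspace(0, 30, 40)
        conc = 0.02 * anat + 0.5
        r, resid = residualize_anatomy(conc, anat)
        assert r == pytest.approx(1.0)
        assert np.allclose(resid, 0, atol=1e-10)

    def test_orthogonal_predictor_returns_centred_outcome(self):
        anat = np.array([1.0, -1.0, 1.0, -1.0])
        conc = np.array([1.0, 1.0, -1.0, -1.0]) + 5.0
        _, resid = residualize_anatomy(conc, anat)
        assert np.allclose(resid, conc - conc.mean(), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        anat = rng.random(8) * 20
        conc = rng.standard_normal(8)
        X = np.column_stack([np.ones(8), anat])
        beta = np.linalg.solve(X.T @ X, X.T @ conc)
        _, resid = residualize_anatomy(conc, anat)
        assert np.allclose(resid, conc - X @ beta, atol=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            residualize_anatomy(np.arange(5.0), np.full(5, 3.0))


class TestSlopeIntercept:
    def test_exact_line(self):
        d = np.linspace(0, 1, 20)
        s, i = fit_slope_intercept(d, 2.0 * d + 1.0)
        assert s == pytest.approx(2.0, abs=1e-10)
        assert i == pytest.approx(1.0, abs=1e-10)

    def test_constant_outcome(self):
        d = np.linspace(0, 1, 10)
        s, i = fit_slope_intercept(d, np.full(10, 0.4))
        assert s == pytest.approx(0.0, abs=1e-12)
        assert i == pytest.approx(0.4)

    def test_matches_normal_equations(self, rng):
        d = rng.random(5)
        c = rng.standard_normal(5)
        X = np.column_stack([np.ones(5), d])
        beta = np.linalg.solve(X.T @ X, X.T @ c)
        s, i = fit_slope_intercept(d, c)
        assert (i, s) == pytest.approx(tuple(beta), abs=1e-10)

    def test_degenerate_distance_rejected(self):
        with pytest.raises(ValueError):
            fit_slope_intercept(np.full(8, 1.0), np.arange(8.0))


class TestLesionSizeControl:
    def test_perfect_linear_dependence(self):
        vols = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r, _ = lesion_size_control(vols, 0.1 * vols - 0.2)
        assert r == pytest.approx(1.0)

    def test_toy_matches_direct_pearson(self, rng):
        vols = rng.random(6) * 10
        rs = rng.standard_normal(6)
        r, p = lesion_size_control(vols, rs)
        vc, rc = vols - vols.mean(), rs - rs.mean()
        expect = (vc * rc).sum() / np.sqrt((vc**2).sum() * (rc**2).sum())
        assert r == pytest.approx(expect, abs=1e-12)

    def test_constant_volumes_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lesion_size_control(np.full(6, 2.0), np.arange(6.0))


class TestBinDelta:
    def test_uniform_concordance_gives_zero_delta(self):
        g = np.linspace(0, 1, 40)
        ba = bin_delta_concordance(g, np.array([0.05]), np.full(40, 0.7), 5)
        assert ba.delta_concordance == pytest.approx(0.0)

    def test_lower_concordance_in_affected_bins_positive_delta(self):
        g = np.linspace(0, 1, 40)
        conc = np.where(g < 0.2, 0.2, 0.8)  # affected low end changed more
        ba = bin_delta_concordance(g, np.array([0.05]), conc, 5)
        assert ba.delta_concordance > 0

    def test_three_bin_toy_matches_enumeration(self):
        # bins over [0, 0.9]: [0, 0.3), [0.3, 0.6), [0.6, 0.9]; lesion in middle bin
        g = np.array([0.0, 0.1, 0.35, 0.5, 0.7, 0.9])
        conc = np.array([0.9, 0.8, 0.3, 0.4, 0.7, 0.6])
        ba = bin_delta_concordance(g, np.array([0.4]), conc, 3)
        mu_aff = (0.3 + 0.4) / 2
        mu_unaff = (0.9 + 0.8 + 0.7 + 0.6) / 4
        assert ba.mu_affected == pytest.approx(mu_aff)
        assert ba.mu_unaffected == pytest.approx(mu_unaff)
        assert ba.delta_concordance == pytest.approx(mu_unaff - mu_aff)
        assert list(ba.affected_bins) == [1]

    def test_final_bin_right_closed(self):
        g = np.array([0.0, 0.5, 1.0])
        ba = bin_delta_concordance(g, np.array([1.0]), np.array([0.5, 0.5, 0.1]), 2)
        assert list(ba.affected_bins) == [1]
        assert ba.mu_affected == pytest.approx((0.5 + 0.1) / 2)

    def test_all_bins_affected_rejected(self):
        g = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="affected"):
            bin_delta_concordance(g, g, np.full(10, 0.5), 2)


class TestPermutationTest:
    def test_identical_groups_centre_p(self):
        v = np.concatenate([np.full(6, 1.0), np.full(6, 1.0)])
        labels = ["a"] * 6 + ["b"] * 6
        assert permutation_group_diff(v, labels, n_perm=500, seed=0) >= 0.5

    def test_complete_separation_exhaustive(self):
        v = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        labels = ["a"] * 5 + ["b"] * 5
        p = permutation_group_diff(v, labels, exact=True)
        assert p == pytest.approx(1 / 252)

    def test_input_order_invariance(self, rng):
        v = rng.standard_normal(14)
        labels = np.array(["a"] * 8 + ["b"] * 6)
        p1 = permutation_group_diff(v, labels, n_perm=300, seed=7)
        perm = rng.permutation(14)
        p2 = permutation_group_diff(v[perm], labels[perm], n_perm=300, seed=7)
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_group_diff(np.arange(4.0), ["a"] * 4)

    def test_uniform_p_under_null(self, rng):
        # reduced version of the calibration invariant: p-values roughly
        # uniform for exchangeable data
        labels = ["a"] * 8 + ["b"] * 6
        ps = [
            permutation_group_diff(rng.standard_normal(14), labels, n_perm=200, seed=int(s))
            for s in rng.integers(0, 2**31, 200)
        ]
        assert stats.kstest(ps, "uniform").statistic < 0.1


class TestKendall:
    def test_perfect_orders(self):
        v = np.arange(6.0)
        assert kendall_clinical(v, v * 3)[0] == pytest.approx(1.0)
        assert kendall_clinical(v, -v)[0] == pytest.approx(-1.0)

    def test_tied_scores_match_hand_tau_b(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        # pairs: concordant C = 9, discordant D = 0, one tie in s
        # tau_b = (C - D) / sqrt((10 - 0) * (10 - 1))
        expect = 9.0 / np.sqrt(10.0 * 9.0)
        tau, _ = kendall_clinical(v, s)
        assert tau == pytest.approx(expect, abs=1e-12)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            kendall_clinical(np.arange(5.0), np.full(5, 3.0))


class TestGroupReport:
    @staticmethod
    def _fake_results(n=8, K=2, rs=0.2):
        out = []
        for i in range(n):
            out.append(
                {
                    "patient_id": f"pat-{i:02d}",
                    "r_s": [rs] * K,
                    "r_s_residualized": [rs / 2] * K,
                    "slope": [0.1 * (i + 1)] * K,
                    "intercept": [0.5 - 0.01 * i] * K,
                    "anat_r": 0.3,
                    "lesion_volume_cm3": 0.1 * (i + 1),
                    "delta_concordance": {"5": [0.01 * (i % 3)] * K},
                }
            )
        return out

    @staticmethod
    def _clinical(n=8):
        import pandas as pd

        ids = [f"pat-{i:02d}" for i in range(n)]
        return pd.DataFrame(
            {
                "nihss_day0": [5 + i for i in range(n)],
                "nihss_day5": [5 + i - (i % 2) for i in range(n)],
                "mrs_day0": [min(5, 1 + i % 4) for i in range(n)],
                "mrs_day5": [min(5, i % 4) for i in range(n)],
            },
            index=pd.Index(ids, name="subject_id"),
        )

    def test_identical_patients_median_equals_common_value(self):
        rep = run_group_analysis(self._fake_results(rs=0.25), clinical=self._clinical(), n_perm=200)
        for k in ("1", "2"):
            assert rep["gradients"][k]["median_r_s"] == pytest.approx(0.25)

    def test_deterministic_given_seed(self):
        a = run_group_analysis(self._fake_results(), clinical=self._clinical(), n_perm=200, seed=3)
        b = run_group_analysis(self._fake_results(), clinical=self._clinical(), n_perm=200, seed=3)
        assert a == b

    def test_missing_clinical_skips_blocks_with_warning(self):
        rep = run_group_analysis(self._fake_results(), clinical=None, n_perm=100)
        assert rep["bin_analysis"] == {}
        assert rep["clinical_association"] == {}
        assert any("clinical" in w for w in rep["warnings"])

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            run_group_analysis(self._fake_results(n=3))
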