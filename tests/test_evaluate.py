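"""Diagnostic-agreement statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from hrmesim.evaluate import (AgreementTable, UndefinedStatisticError,
                              cohens_kappa, diagnostics_from_table,
                              matched_operating_point, mcnemar_exact,
                              noise_floor, printed_agreement_fixture,
                              qc_failure_fraction, roc_analysis,
                              two_proportion_chisq, weber_fraction,
                              wilson_interval)


class TestAgreementTable:
    def test_printed_fixture_marginals(self):
        t = printed_agreement_fixture()
        np.testing.assert_array_equal(t.class_totals, [11, 71, 22])
        assert t.total == 104
        assert t.counts[1, 1, 2] == 18  # device+/comparator+/AIN2+

    def test_negative_counts_rejected(self):
        c = np.zeros((2, 2, 3), dtype=int)
        c[0, 0, 0] = -1
        with pytest.raises(ValueError):
            AgreementTable(counts=c)


class TestDiagnosticsFromTable:
    def test_published_statistics_recovered(self):
        s = diagnostics_from_table(printed_agreement_fixture())
        assert s.fractions["device_sensitivity"] == (20, 22)
        assert s.fractions["device_specificity"] == (71, 82)
        assert round(s.device_sensitivity, 2) == 0.91
        assert round(s.device_specificity, 2) == 0.87
        assert s.agreement_count == 68
        assert s.n_sites == 104
        assert round(s.kappa, 2) == 0.34
        assert round(100 * s.prevalence) == 21
        assert s.fractions["discordant_ain1"] == (28, 36)

    def test_comparator_marginals(self):
        s = diagnostics_from_table(printed_agreement_fixture())
        assert s.fractions["hra_sensitivity"] == (20, 22)
        assert s.fractions["hra_specificity"] == (43, 82)
        assert round(s.hra_sensitivity, 2) == 0.91
        assert s.hra_specificity == pytest.approx(43 / 82)

    def test_perfect_agreement_table(self):
        c = np.zeros((2, 2, 3), dtype=int)
        c[0, 0] = (10, 20, 0)
        c[1, 1] = (0, 0, 15)
        s = diagnostics_from_table(AgreementTable(counts=c))
        assert s.device_sensitivity == 1.0
        assert s.device_specificity == 1.0
        assert s.kappa == 1.0
        assert s.agreement_fraction == 1.0

    def test_no_positive_sites_raises(self):
        c = np.zeros((2, 2, 3), dtype=int)
        c[0, 0] = (5, 5, 0)
        with pytest.raises(UndefinedStatisticError, match="sensitivity"):
            diagnostics_from_table(AgreementTable(counts=c))


class TestWilsonInterval:
    def test_printed_sensitivity_interval(self):
        lo, hi = wilson_interval(20, 22)
        assert np.trunc(lo * 100) / 100 == 0.72
        assert np.trunc(hi * 100) / 100 == 0.97

    def test_printed_specificity_interval(self):
        lo, hi = wilson_interval(71, 82)
        assert np.trunc(lo * 100) / 100 == 0.77
        assert np.trunc(hi * 100) / 100 == 0.92

    def test_all_successes_upper_bound_is_one(self):
        lo, hi = wilson_interval(25, 25)
        assert hi == pytest.approx(1.0)
        assert lo < 1.0

    def test_contains_point_estimate_and_stays_in_unit_interval(self):
        # exhaustive over n <= 200
        for n in range(1, 201, 7):
            k = np.arange(0, n + 1)
            for ki in k:
                lo, hi = wilson_interval(int(ki), n)
                assert 0.0 <= lo <= ki / n <= hi <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 3)


class TestMcNemarExact:
    def test_balanced_discordants_give_p_one(self):
        assert mcnemar_exact(2, 2) == 1.0

    def test_lopsided_discordants_highly_significant(self):
        assert mcnemar_exact(30, 2) < 1e-4

    def test_no_discordance_p_one(self):
        assert mcnemar_exact(0, 0) == 1.0

    def test_symmetry_exhaustive(self):
        for b in range(21):
            for c in range(21):
                assert mcnemar_exact(b, c) == mcnemar_exact(c, b)

    @pytest.mark.parametrize("b,c", [(2, 2), (30, 2), (5, 12), (1, 9)])
    def test_matches_statsmodels_exact(self, b, c):
        from statsmodels.stats.contingency_tables import mcnemar

        table = [[0, b], [c, 0]]
        expected = mcnemar(table, exact=True).pvalue
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)


class TestCohensKappa:
    def test_published_collapsed_table(self):
        # the stratified fixture collapsed over severity classes
        collapsed = printed_agreement_fixture().collapsed()
        np.testing.assert_array_equal(collapsed, [[41, 32], [4, 27]])
        assert round(cohens_kappa(collapsed), 2) == 0.34

    def test_diagonal_table_kappa_one(self):
        assert cohens_kappa([[10, 0], [0, 5]]) == 1.0

    def test_uniform_table_kappa_zero(self):
        assert cohens_kappa([[1, 1], [1, 1]]) == pytest.approx(0.0)

    def test_rater_swap_invariance(self):
        t = np.array([[12, 7], [3, 20]])
        assert cohens_kappa(t) == pytest.approx(cohens_kappa(t.T))

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        t = np.array([[41, 32], [4, 27]])
        assert cohens_kappa(t) == pytest.approx(
            sm_kappa(t, return_results=False))


def brute_force_auc(scores, labels):
    """Exhaustive Mann-Whitney pairwise count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAnalysis:
    def test_perfect_separation(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_analysis([0.5] * 6, [True, False] * 3)
        assert roc.auc == 0.5

    def test_auc_equals_pairwise_count_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(4, 31)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.9], [True, True])

    def test_curve_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.random(40) < 0.4
        roc = roc_analysis(scores, labels)
        # thresholds descend, so sensitivity is non-decreasing and
        # specificity non-increasing along the sweep
        assert (np.diff(roc.sensitivities) >= 0).all()
        assert (np.diff(roc.specificities) <= 0).all()


class TestMatchedOperatingPoint:
    def test_target_one_on_separated_scores(self):
        roc = roc_analysis([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        thr, sens, spec, matched = matched_operating_point(roc, 1.0)
        assert matched and sens == 1.0 and spec == 1.0
        assert thr <= 0.8

    def test_target_zero_gives_most_specific_point(self):
        roc = roc_analysis([0.9, 0.1, 0.6, 0.4], [True, False, True, False])
        thr, sens, spec, matched = matched_operating_point(roc, 0.0)
        assert matched and spec == 1.0

    def test_matches_comparator_sensitivity_on_constructed_cohort(self):
        # 22 positives of which 20 score above the cutoff; 82 negatives
        # of which 71 score below: operating point at 0.4 reproduces
        # sensitivity 20/22 with specificity 71/82
        rng = np.random.default_rng(2)
        pos = np.concatenate([rng.uniform(0.45, 0.95, 20),
                              rng.uniform(0.05, 0.35, 2)])
        neg = np.concatenate([rng.uniform(0.02, 0.38, 71),
                              rng.uniform(0.42, 0.9, 11)])
        scores = np.concatenate([pos, neg])
        labels = np.array([True] * 22 + [False] * 82)
        roc = roc_analysis(scores, labels)
        thr, sens, spec, matched = matched_operating_point(roc, 20 / 22)
        assert matched
        assert sens == pytest.approx(20 / 22)
        assert spec >= 71 / 82

    def test_unreachable_target_flagged(self):
        roc = roc_analysis([0.5] * 4, [True, True, False, False])
        # sensitivity can reach 1.0 here; force an unreachable target by
        # demanding more than any threshold's sensitivity on a degenerate
        # sweep restricted to the sentinel
        import numpy as np
        from hrmesim.evaluate import ROCResult

        restricted = ROCResult(
            thresholds=np.array([1.5]), sensitivities=np.array([0.6]),
            specificities=np.array([0.8]), auc=0.7, pr_auc=0.7)
        thr, sens, spec, matched = matched_operating_point(restricted, 0.9)
        assert not matched
        assert sens == 0.6


class TestTwoProportionChisq:
    def test_equal_proportions_p_one(self):
        assert two_proportion_chisq(5, 10, 5, 10) == pytest.approx(1.0)

    def test_matches_hand_computed_chi_square(self):
        k1, n1, k2, n2 = 71, 82, 30, 50
        # brute-force Pearson statistic on the pooled 2x2 table
        obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        exp = row @ col / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        expected_p = stats.chi2.sf(chi2, df=1)
        assert two_proportion_chisq(k1, n1, k2, n2) == pytest.approx(
            expected_p, rel=1e-12)

    def test_symmetric_in_group_order(self):
        assert two_proportion_chisq(71, 82, 30, 50) == pytest.approx(
            two_proportion_chisq(30, 50, 71, 82))

    def test_degenerate_pooled_proportion_raises(self):
        with pytest.raises(UndefinedStatisticError):
            two_proportion_chisq(0, 10, 0, 10)


class TestQCAndContrast:
    @pytest.mark.parametrize("imaged,passed,expected", [
        (109, 104, 4.6), (100, 100, 0.0), (10, 7, 30.0),
    ])
    def test_qc_failure_fraction(self, imaged, passed, expected):
        assert qc_failure_fraction(imaged, passed) == expected

    def test_qc_invalid_inputs(self):
        with pytest.raises(ValueError):
            qc_failure_fraction(0, 0)
        with pytest.raises(ValueError):
            qc_failure_fraction(5, 7)

    @pytest.mark.parametrize("fg,bg,expected", [
        (8.3, 1.0, 7.3), (2.7, 1.0, 1.7), (0.4, 0.4, 0.0),
    ])
    def test_weber_fraction_definition(self, fg, bg, expected):
        img = np.zeros((10, 10))
        fg_mask = np.zeros((10, 10), dtype=bool)
        bg_mask = np.zeros((10, 10), dtype=bool)
        fg_mask[:5] = True
        bg_mask[5:] = True
        img[fg_mask] = fg
        img[bg_mask] = bg
        assert weber_fraction(img, fg_mask, bg_mask) == pytest.approx(expected)

    def test_weber_zero_background_raises(self):
        img = np.zeros((4, 4))
        img[:2] = 1.0
        fg = np.zeros((4, 4), dtype=bool)
        bg = np.zeros((4, 4), dtype=bool)
        fg[:2] = True
        bg[2:] = True
        with pytest.raises(UndefinedStatisticError):
            weber_fraction(img, fg, bg)

    def test_noise_floor_constant_frame_zero(self):
        assert noise_floor(np.full((16, 16), 0.5)) == 0.0

    def test_noise_floor_recovers_sigma(self):
        rng = np.random.default_rng(3)
        blank = 0.5 + rng.normal(0, 0.02, (256, 256))
        assert noise_floor(blank) == pytest.approx(0.02, rel=0.05)

    def test_degraded_blank_noise_floor_four_times_input(self):
        # the default injected-noise sigma is calibrated so a degraded
        # blank shows a 4x higher noise floor than the fast camera's
        from hrmesim.degrade import DegradationConfig, apply_method, method_config
        from conftest import make_sequence
        from hrmesim.acquisition import AcquisitionParams

        rng = np.random.default_rng(4)
        sigma_in = 0.01
        params = AcquisitionParams(gamma_exponent=1.0, noise_sigma=sigma_in)
        arrays = [np.clip(0.4 + rng.normal(0, sigma_in, (128, 128)), 0, 1)
                  for _ in range(5)]
        seq = make_sequence(arrays, params)
        cfg = method_config(6, DegradationConfig(  # keep native grayscale
            source_gamma=1.0, target_gamma=1.0, seed=11))
        degraded = apply_method(seq, cfg)
        ratio = noise_floor(degraded.pixels - 0.4) / sigma_in
        assert ratio == pytest.approx(4.0, rel=0.10)
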