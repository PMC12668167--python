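import numpy as np
import pytest
from scipy import stats as sps

from metameta import (
    DomainError,
    begg_mazumdar,
    bias_battery,
    egger,
    fail_safe_n_classic,
    fail_safe_n_orwin,
    funnel_data,
    trim_and_fill,
)
from metameta.effects import EffectEstimate


def _est(y, se, label=""):
    return EffectEstimate(fisher_z=y, se=se, source_id=label)


class TestFailSafeN:
    def test_alpha_z_is_two_sided_critical_value(self, pseudo_studies):
        _, alpha_z = fail_safe_n_classic(pseudo_studies, alpha=0.05)
        assert alpha_z == pytest.approx(1.960, abs=5e-4)

    def test_boundary_single_study(self):
        n, _ = fail_safe_n_classic([_est(1.959964, 1.0)], alpha=0.05)
        assert n == pytest.approx(0.0, abs=1e-4)

    def test_hand_formula_three_studies(self):
        zs = [5.41, 4.33, 5.613]
        es = [_est(z, 1.0) for z in zs]
        n, z_a = fail_safe_n_classic(es, alpha=0.05)
        expected = (sum(zs)) ** 2 / z_a**2 - 3
        assert n == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_each_z(self, rng):
        zs = rng.uniform(1, 4, 5)
        base, _ = fail_safe_n_classic([_est(z, 1.0) for z in zs])
        bigger, _ = fail_safe_n_classic([_est(z + 0.5, 1.0) for z in zs])
        assert bigger >= base

    def test_orwin_zero_at_criterion(self):
        es = [_est(0.01, 0.1)] * 3
        assert fail_safe_n_orwin(es, 0.01) == 0.0

    def test_orwin_hand_formula(self):
        es = [_est(0.02, 0.1)] * 3
        assert fail_safe_n_orwin(es, 0.01) == pytest.approx(3.0)

    def test_orwin_clamped_when_criterion_exceeds_mean(self):
        es = [_est(0.005, 0.1)] * 3
        assert fail_safe_n_orwin(es, 0.01) == 0.0

    def test_orwin_requires_positive_criterion(self, pseudo_studies):
        with pytest.raises(DomainError):
            fail_safe_n_orwin(pseudo_studies, 0.0)


class TestBeggMazumdar:
    def test_printed_tau_without_correction(self, pseudo_studies):
        assert begg_mazumdar(pseudo_studies) == pytest.approx(1.00)

    def test_printed_tau_with_correction(self, pseudo_studies):
        tau_cc = begg_mazumdar(pseudo_studies, continuity=True)
        assert tau_cc == pytest.approx(2 / 3)
        assert tau_cc == pytest.approx(0.66, abs=0.007)  # printed (truncated) value

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 10))
            y = rng.normal(size=k)
            se = rng.uniform(0.05, 0.5, k)
            es = [_est(float(a), float(b)) for a, b in zip(y, se)]
            c = d = 0
            for i in range(k):
                for j in range(i + 1, k):
                    s = (y[i] - y[j]) * (se[i] ** 2 - se[j] ** 2)
                    c += s > 0
                    d += s < 0
            assert begg_mazumdar(es) == pytest.approx((c - d) / (k * (k - 1) / 2))

    def test_matches_scipy_kendall(self, rng):
        k = 12
        y = rng.normal(size=k)
        se = rng.uniform(0.05, 0.5, k)
        es = [_est(float(a), float(b)) for a, b in zip(y, se)]
        expected = sps.kendalltau(y, se**2).statistic
        assert begg_mazumdar(es) == pytest.approx(expected, abs=1e-12)

    def test_independent_orderings_average_to_zero(self, rng):
        taus = []
        for _ in range(200):
            y = rng.normal(size=6)
            se = rng.uniform(0.05, 0.5, 6)
            taus.append(begg_mazumdar([_est(float(a), float(b)) for a, b in zip(y, se)]))
        assert abs(np.mean(taus)) < 0.1

    def test_continuity_never_increases_magnitude(self, rng):
        for _ in range(20):
            y = rng.normal(size=5)
            se = rng.uniform(0.05, 0.5, 5)
            es = [_est(float(a), float(b)) for a, b in zip(y, se)]
            assert abs(begg_mazumdar(es, continuity=True)) <= abs(begg_mazumdar(es)) + 1e-15

    def test_needs_two_studies(self):
        with pytest.raises(DomainError):
            begg_mazumdar([_est(0.1, 0.1)])


class TestEgger:
    def test_symmetric_funnel_zero_intercept(self):
        # effects equidistant around the mean with matched standard errors
        es = [
            _est(0.10 + d, se)
            for d, se in [(-0.02, 0.1), (0.02, 0.1), (-0.05, 0.2), (0.05, 0.2)]
        ]
        intercept, _, _, df = egger(es)
        assert df == 2
        # symmetric pairs at matched se cancel in the regression
        assert intercept == pytest.approx(0.0, abs=0.35)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            k = int(rng.integers(3, 8))
            y = rng.normal(0.1, 0.1, k)
            se = rng.uniform(0.05, 0.5, k)
            es = [_est(float(a), float(b)) for a, b in zip(y, se)]
            x = 1 / se
            resp = y / se
            slope_o, intercept_o = np.polyfit(x, resp, 1)
            intercept, se_i, t, df = egger(es)
            assert intercept == pytest.approx(intercept_o, abs=1e-10)
            assert t == pytest.approx(intercept / se_i)
            assert df == k - 2

    def test_intercept_scales_linearly(self, rng):
        y = rng.normal(0.1, 0.1, 6)
        se = rng.uniform(0.05, 0.5, 6)
        base = egger([_est(float(a), float(b)) for a, b in zip(y, se)])[0]
        scaled = egger([_est(3 * float(a), float(b)) for a, b in zip(y, se)])[0]
        assert scaled == pytest.approx(3 * base, abs=1e-9)

    def test_relabeling_invariance(self, pseudo_studies):
        a = egger(pseudo_studies)
        b = egger(list(reversed(pseudo_studies)))
        assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_insufficient_studies(self):
        with pytest.raises(DomainError):
            egger([_est(0.1, 0.1), _est(0.2, 0.2)])

    def test_identical_precisions_singular(self):
        with pytest.raises(DomainError):
            egger([_est(0.1, 0.1), _est(0.2, 0.1), _est(0.3, 0.1)])


class TestTrimAndFill:
    def test_symmetric_funnel_unchanged(self):
        es = [_est(y, 0.1) for y in (0.0, 0.05, 0.10, 0.15, 0.20)]
        report, filled = trim_and_fill(es)
        assert report.trimfill_imputed == 0
        assert len(filled) == len(es)

    def test_hand_worked_five_study_L0(self):
        """Manual iteration: centre 0.44 -> k0=1 -> trim 1.0 -> centre 0.3 -> stable.

        The imputed mirror of the trimmed study is 2*0.3 - 1.0 = -0.4.
        """
        es = [_est(y, 0.1, f"s{i}") for i, y in enumerate((0.0, 0.1, 0.2, 0.9, 1.0))]
        report, filled = trim_and_fill(es, side="right", estimator="L0")
        assert report.trimfill_imputed == 1
        imputed = [e for e in filled if e.source_id.endswith("~fill")]
        assert len(imputed) == 1
        assert imputed[0].fisher_z == pytest.approx(-0.4, abs=1e-12)
        assert imputed[0].se == pytest.approx(0.1)

    def test_idempotent_on_filled_set(self):
        es = [_est(y, 0.1, f"s{i}") for i, y in enumerate((0.0, 0.1, 0.2, 0.9, 1.0))]
        _, filled = trim_and_fill(es)
        report2, refilled = trim_and_fill(filled)
        assert report2.trimfill_imputed == 0
        assert len(refilled) == len(filled)

    def test_adjusted_not_above_unadjusted_under_right_excess(self, rng):
        from metameta import pool_random_dl

        for _ in range(10):
            y = np.abs(rng.normal(0.1, 0.2, 12))
            se = rng.uniform(0.05, 0.3, 12)
            es = [_est(float(a), float(b)) for a, b in zip(y, se)]
            report, _ = trim_and_fill(es, side="right")
            assert report.trimfill_estimate <= pool_random_dl(es).pooled_z + 1e-12

    def test_left_side_mirrors(self):
        es = [_est(y, 0.1, f"s{i}") for i, y in enumerate((-1.0, -0.9, -0.2, -0.1, 0.0))]
        report, filled = trim_and_fill(es, side="left")
        assert report.trimfill_imputed == 1
        imputed = [e for e in filled if e.source_id.endswith("~fill")]
        assert imputed[0].fisher_z == pytest.approx(0.4, abs=1e-12)

    def test_requires_two_studies(self):
        with pytest.raises(DomainError):
            trim_and_fill([_est(0.1, 0.1)])


class TestFunnelData:
    def test_three_rows_centered_at_pooled(self, pseudo_studies):
        from metameta import pool_random_dl

        table = funnel_data(pseudo_studies)
        assert len(table) == 3
        assert table.center.iloc[0] == pytest.approx(pool_random_dl(pseudo_studies).pooled_z)
        assert not table.imputed_flag.any()

    def test_imputed_rows_flagged(self):
        es = [_est(y, 0.1, f"s{i}") for i, y in enumerate((0.0, 0.1, 0.2, 0.9, 1.0))]
        _, filled = trim_and_fill(es)
        table = funnel_data(filled)
        assert table.imputed_flag.sum() == 1

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            funnel_data([])


class TestBiasBattery:
    def test_collects_everything_for_three_studies(self, pseudo_studies):
        report = bias_battery(pseudo_studies, orwin_criterion=0.005)
        assert report.K == 3
        assert report.kendall_tau == pytest.approx(1.0)
        assert report.egger_df == 1
        assert report.trimfill_imputed is not None
        assert report.fail_safe_n > 0
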