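"""MIC estimators: worked examples, oracle cross-checks, invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

import oracles
from anchormic import (
    ChangeDataset,
    Domain,
    LogisticFit,
    build_change_dataset,
    compute_S,
    compute_odds_pre,
    estimate_domain,
    fit_logistic,
    mic_adj,
    mic_pred,
    mic_roc,
    point_biserial,
)
from anchormic.errors import (
    AnchorMicError,
    DegenerateAnchorError,
    DegeneratePrevalenceError,
    SeparationError,
    UndefinedCorrelationError,
    UndefinedMicError,
)


def dataset(change, anchor, domain=Domain.MOTOR):
    return ChangeDataset(domain, np.asarray(change, float), np.asarray(anchor), check_range=False)


@st.composite
def small_datasets(draw, min_n=8, max_n=30):
    """Integer change scores with both anchor classes present."""
    n = draw(st.integers(min_n, max_n))
    change = draw(st.lists(st.integers(-20, 20), min_size=n, max_size=n))
    n_improved = draw(st.integers(1, n - 1))
    anchor = [1] * n_improved + [0] * (n - n_improved)
    return dataset(change, anchor)


class TestPointBiserial:
    def test_hand_computed_example(self):
        assert point_biserial(dataset([1, 2, 3, 4], [0, 0, 1, 1])) == pytest.approx(
            0.8944, abs=1e-4
        )

    def test_zero_under_exchangeable_permutations(self):
        # averaging the correlation over all distinct-position permutations
        # of a balanced anchor is 0 by symmetry; check a closed orbit
        change = [1.0, 2.0, 3.0, 4.0]
        anchors = [(1, 0, 0, 1), (0, 1, 1, 0)]
        mean_r = np.mean([point_biserial(dataset(change, a)) for a in anchors])
        assert mean_r == pytest.approx(0.0, abs=1e-12)

    def test_constant_change_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            point_biserial(dataset([5, 5, 5], [0, 1, 1]))

    def test_single_class_anchor_undefined(self):
        with pytest.raises(DegenerateAnchorError):
            point_biserial(dataset([1, 2, 3], [1, 1, 1]))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(small_datasets())
    def test_equals_scipy_point_biserial(self, data):
        assume(np.ptp(data.change) > 0)
        ours = point_biserial(data)
        assert ours == pytest.approx(
            oracles.point_biserial_scipy(data.change, data.anchor), abs=1e-10
        )


class TestLogisticFit:
    def test_uninformative_symmetric_fixture_gives_zero_slope_and_intercept(self):
        # invariant under change -> -change with anchors fixed: slope must be 0;
        # balanced classes with zero slope force intercept 0
        fit = fit_logistic(dataset([-2, -1, 1, 2], [0, 1, 1, 0]))
        assert fit.B == pytest.approx(0.0, abs=1e-8)
        assert fit.C == pytest.approx(0.0, abs=1e-8)

    def test_class_balanced_antisymmetric_fixture_gives_zero_intercept(self):
        # invariant under (change, anchor) -> (-change, 1-anchor): C = 0
        fit = fit_logistic(dataset([-2, -1, 1, 2], [0, 1, 0, 1]))
        assert fit.C == pytest.approx(0.0, abs=1e-8)

    def test_recovers_generating_logit(self):
        rng = np.random.default_rng(1234)
        n = 10_000
        c_true, b_true = -0.5, 0.3
        x = rng.uniform(-6, 6, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(c_true + b_true * x)))).astype(int)
        fit = fit_logistic(dataset(x, y))
        assert fit.C == pytest.approx(c_true, abs=0.05)
        assert fit.B == pytest.approx(b_true, abs=0.05)
        assert fit.converged

    def test_perfect_separation_raises(self):
        with pytest.raises(SeparationError):
            fit_logistic(dataset([1, 2, 3, 4], [0, 0, 1, 1]))

    def test_single_class_raises(self):
        with pytest.raises(DegenerateAnchorError):
            fit_logistic(dataset([1, 2, 3, 4], [1, 1, 1, 1]))

    def test_centered_fit_shifts_intercept_only(self, hand_cohort20):
        data = build_change_dataset(hand_cohort20, Domain.MOTOR)
        plain = fit_logistic(data)
        centered = fit_logistic(data, center=True)
        assert centered.B == pytest.approx(plain.B, rel=1e-6)
        assert centered.C == pytest.approx(
            plain.C + plain.B * data.change.mean(), abs=1e-6
        )
        # MIC invariant to centering
        odds = compute_odds_pre(data.n_improved, data.n)
        assert mic_pred(centered, odds) == pytest.approx(mic_pred(plain, odds), abs=1e-6)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(small_datasets(min_n=12, max_n=25))
    def test_matches_direct_likelihood_optimisation(self, data):
        try:
            fit = fit_logistic(data)
        except AnchorMicError:
            assume(False)
        c_oracle, b_oracle = oracles.logit_mle(data.change, data.anchor)
        assert fit.C == pytest.approx(c_oracle, abs=1e-4)
        assert fit.B == pytest.approx(b_oracle, abs=1e-4)


class TestFormulaChain:
    def test_odds_from_published_counts(self):
        assert compute_odds_pre(187, 277) == pytest.approx(187 / 90, abs=1e-10)

    def test_even_odds_at_half_prevalence(self):
        assert compute_odds_pre(50, 100) == pytest.approx(1.0)

    @pytest.mark.parametrize("n_improved,n_total", [(0, 100), (100, 100)])
    def test_degenerate_prevalence(self, n_improved, n_total):
        with pytest.raises(DegeneratePrevalenceError):
            compute_odds_pre(n_improved, n_total)

    def test_mic_pred_arithmetic(self):
        fit = LogisticFit(C=0.0, B=0.5, converged=True, n_iter=1)
        assert mic_pred(fit, 2.0) == pytest.approx(math.log(2) / 0.5, abs=1e-10)

    def test_mic_pred_zero_when_intercept_cancels(self):
        fit = LogisticFit(C=math.log(2.0778), B=0.3, converged=True, n_iter=1)
        assert mic_pred(fit, 2.0778) == pytest.approx(0.0, abs=1e-12)

    def test_mic_pred_from_calibrated_motor_logit(self):
        # closed-form logistic coefficients of the calibrated equal-variance
        # motor model: B = d/sd_within^2, C = ln(odds) - B * midpoint
        fit = LogisticFit(C=-0.2076, B=0.04662, converged=True, n_iter=1)
        assert mic_pred(fit, 2.0778) == pytest.approx(20.13, abs=0.01)

    def test_mic_pred_undefined_for_flat_slope(self):
        fit = LogisticFit(C=0.1, B=0.0, converged=True, n_iter=1)
        with pytest.raises(UndefinedMicError):
            mic_pred(fit, 2.0)

    @pytest.mark.parametrize(
        "sd,cor,expected",
        [(14.5, 0.29, 1.7381), (4.8, 0.02, 0.4419), (0.0, 0.7, 0.0)],
    )
    def test_S_formula(self, sd, cor, expected):
        assert compute_S(sd, cor) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "pred,S,expected",
        [(19.9, 1.7381, 18.6), (24.2, 1.9562, 22.8)],
    )
    def test_adjustment_reproduces_published_values(self, pred, S, expected):
        assert round(mic_adj(pred, S, 2.0778), 1) == expected

    def test_adjustment_vanishes_at_even_odds(self):
        assert mic_adj(12.3, 5.0, 1.0) == 12.3


class TestMicRoc:
    def test_separating_gap_gives_midpoint(self):
        data = dataset([0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert mic_roc(data) == 6.0

    def test_identical_distributions_tie_to_smallest_candidate(self):
        # both classes uniform on {0, 10}: J = 0 at every candidate
        data = dataset([0, 10, 0, 10], [1, 1, 0, 0])
        assert mic_roc(data) == 5.0

    def test_interleaved_fixture_matches_exhaustive_scan(self):
        change = [0, 3, 1, 7, 2, 9, 4, 11, 6, 13, 8, 5]
        anchor = [0, 0, 0, 1, 0, 1, 0, 1, 1, 1, 1, 0]
        data = dataset(change, anchor)
        assert mic_roc(data) == oracles.youden_scan(change, anchor)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateAnchorError):
            mic_roc(dataset([1, 2], [1, 1]))

    def test_single_distinct_value_rejected(self):
        with pytest.raises(UndefinedMicError):
            mic_roc(dataset([3, 3, 3], [0, 1, 1]))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(small_datasets())
    def test_equals_exhaustive_midpoint_oracle(self, data):
        assume(np.unique(data.change).size >= 2)
        assert mic_roc(data) == oracles.youden_scan(data.change, data.anchor)


class TestEstimateDomain:
    def test_half_prevalence_identity(self):
        rng = np.random.default_rng(77)
        n = 400
        anchor = np.repeat([0, 1], n // 2)
        change = rng.normal(np.where(anchor == 1, 25.0, 15.0), 14.0)
        est = estimate_domain(dataset(change, anchor))
        assert est.odds_pre == pytest.approx(1.0)
        assert est.mic_adj == pytest.approx(est.mic_pred, abs=1e-12)
        assert est.mic_pred == pytest.approx(-est.fit.C / est.fit.B, abs=1e-9)

    def test_hand_cohort_matches_independent_chain(self, hand_cohort20):
        data = build_change_dataset(hand_cohort20, Domain.MOTOR)
        est = estimate_domain(data)
        oracle = oracles.mic_chain(data.change, data.anchor)
        assert est.prevalence == pytest.approx(oracle["prevalence"])
        assert est.odds_pre == pytest.approx(oracle["odds_pre"])
        assert est.sd_chang == pytest.approx(oracle["sd_chang"])
        assert est.cor == pytest.approx(oracle["cor"], abs=1e-9)
        assert est.S == pytest.approx(oracle["S"], abs=1e-9)
        assert est.fit.C == pytest.approx(oracle["C"], abs=1e-4)
        assert est.fit.B == pytest.approx(oracle["B"], abs=1e-4)
        assert est.mic_roc == oracle["mic_roc"]
        assert est.mic_pred == pytest.approx(oracle["mic_pred"], abs=1e-3)
        assert est.mic_adj == pytest.approx(oracle["mic_adj"], abs=1e-3)

    def test_internal_consistency_invariants(self, motor_cohort_277):
        est = estimate_domain(motor_cohort_277)
        p = est.prevalence
        assert est.odds_pre == pytest.approx(p / (1 - p), abs=1e-12)
        assert est.mic_adj == pytest.approx(
            est.mic_pred - est.S * math.log(est.odds_pre), abs=1e-10
        )
        assert est.S >= 0  # cor well above -0.874


class TestEquivariance:
    @pytest.mark.parametrize("shift", [-7.0, 3.5, 12.0])
    def test_shift_equivariance(self, motor_cohort_277, shift):
        base = estimate_domain(motor_cohort_277)
        shifted = estimate_domain(
            dataset(motor_cohort_277.change + shift, motor_cohort_277.anchor)
        )
        assert shifted.fit.B == pytest.approx(base.fit.B, rel=1e-6)
        assert shifted.fit.C == pytest.approx(base.fit.C - base.fit.B * shift, rel=1e-5)
        for attr in ("mic_roc", "mic_pred", "mic_adj"):
            assert getattr(shifted, attr) == pytest.approx(
                getattr(base, attr) + shift, abs=1e-6
            )
        assert shifted.cor == pytest.approx(base.cor, abs=1e-12)
        assert shifted.sd_chang == pytest.approx(base.sd_chang, abs=1e-9)

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.0])
    def test_scale_equivariance(self, motor_cohort_277, scale):
        base = estimate_domain(motor_cohort_277)
        scaled = estimate_domain(
            dataset(motor_cohort_277.change * scale, motor_cohort_277.anchor)
        )
        for attr in ("mic_roc", "mic_pred", "mic_adj", "sd_chang", "S"):
            assert getattr(scaled, attr) == pytest.approx(
                getattr(base, attr) * scale, rel=1e-5
            )
        assert scaled.cor == pytest.approx(base.cor, abs=1e-9)
        assert scaled.prevalence == base.prevalence

    @pytest.mark.parametrize("prevalence,expect_lower", [(0.7, True), (0.3, False)])
    def test_adjustment_direction_tracks_prevalence(self, prevalence, expect_lower):
        # improved proportion > 50% biases the unadjusted estimate upward,
        # so the adjustment pulls it down; and vice versa
        rng = np.random.default_rng(99)
        n = 1000
        anchor = (rng.random(n) < prevalence).astype(int)
        change = rng.normal(np.where(anchor == 1, 25.0, 15.0), 14.0)
        est = estimate_domain(dataset(change, anchor))
        assert est.S > 0
        assert (est.mic_adj < est.mic_pred) is expect_lower
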