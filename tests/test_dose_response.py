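"""Step-binning against a brute-force oracle; constrained 4PL recovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speckscore import (
    FitConfig,
    StepBinConfig,
    TransformSpec,
    compute_asc50,
    fit_4pl,
    four_pl,
    octile_curve,
    score_replicates,
    step_binned_curve,
    transform_expression,
)
from speckscore.dose_response import CurveTooSparseError, DoseResponseCurve
import pandas as pd


# ---------------------------------------------------------------------------
# Brute-force oracle: explicit window enumeration, pure python counting
# ---------------------------------------------------------------------------

def brute_force_curve(pos, neg, width_fraction=0.25, step=0.1, min_events=1):
    pooled = list(pos) + list(neg)
    lo, hi = min(pooled), max(pooled)
    width = width_fraction * (hi - lo)
    rows = []
    k = 0
    while True:
        left = lo + k * step
        right = left + width
        closed = right >= hi - 1e-12
        if closed:
            right = hi

        def inside(v):
            if closed:
                return left <= v <= right
            return left <= v < right

        n_pos = sum(1 for v in pos if inside(v))
        n_neg = sum(1 for v in neg if inside(v))
        n_total = n_pos + n_neg
        if n_total >= min_events:
            rows.append((0.5 * (left + right), n_pos, n_total))
        if closed:
            break
        k += 1
    return rows


def assert_matches_oracle(pos, neg, cfg):
    curve = step_binned_curve(pos, neg, cfg)
    oracle = brute_force_curve(pos, neg, cfg.width_fraction, cfg.step,
                               cfg.min_events_per_window)
    got = list(zip(curve.points["x_center"], curve.points["n_pos"],
                   curve.points["n_total"]))
    assert len(got) == len(oracle)
    for (xc, np_, nt), (oxc, onp, ont) in zip(got, oracle):
        assert xc == pytest.approx(oxc, abs=1e-12)
        assert (np_, nt) == (onp, ont)


class TestStepBinning:
    def test_four_event_example_matches_hand_count(self):
        """pos {2, 3}, neg {1, 1.5}: first window [1, 1.5) holds 1 neg, 0 pos."""
        cfg = StepBinConfig(min_events_per_window=1)
        curve = step_binned_curve([2.0, 3.0], [1.0, 1.5], cfg)
        first = curve.points.iloc[0]
        assert first["n_total"] == 1 and first["proportion"] == 0.0
        assert_matches_oracle([2.0, 3.0], [1.0, 1.5], cfg)

    def test_window_width_is_quarter_of_range(self):
        cfg = StepBinConfig(min_events_per_window=1)
        curve = step_binned_curve([0.0, 4.0], [1.0, 2.0, 3.0], cfg)
        lo, hi = curve.range
        first = curve.points.iloc[0]
        # first window [0, 1): center 0.5 implies width (hi-lo)/4 = 1.0
        assert first["x_center"] == pytest.approx(lo + 0.5)

    def test_all_positive_events_give_unit_proportion(self):
        cfg = StepBinConfig(min_events_per_window=1)
        curve = step_binned_curve(np.linspace(0, 2, 50), [], cfg)
        assert (curve.points["proportion"] == 1.0).all()

    def test_zero_range_raises(self):
        with pytest.raises(ValueError, match="range"):
            step_binned_curve([1.0, 1.0], [1.0], StepBinConfig())

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="no events"):
            step_binned_curve([], [], StepBinConfig())

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        pos=st.lists(st.floats(min_value=0, max_value=5, allow_nan=False,
                               width=32), min_size=0, max_size=20),
        neg=st.lists(st.floats(min_value=0, max_value=5, allow_nan=False,
                               width=32), min_size=0, max_size=20),
        width_fraction=st.sampled_from([0.1, 0.25, 0.5, 1.0]),
        step=st.sampled_from([0.05, 0.1, 0.3]),
    )
    def test_matches_brute_force_on_random_inputs(self, pos, neg,
                                                  width_fraction, step):
        pooled = pos + neg
        if len(pooled) < 2 or max(pooled) - min(pooled) <= 0:
            return
        cfg = StepBinConfig(width_fraction=width_fraction, step=step,
                            min_events_per_window=1)
        assert_matches_oracle(pos, neg, cfg)

    def test_conservation_and_bounds(self, wt_clean, wt_gates):
        from speckscore import apply_gates
        clean, _, _ = wt_clean
        gated = apply_gates(clean, wt_gates)
        pos, neg = gated.expression()
        curve = step_binned_curve(transform_expression(pos),
                                  transform_expression(neg))
        pts = curve.points
        assert (pts["n_pos"] <= pts["n_total"]).all()
        assert ((pts["proportion"] >= 0) & (pts["proportion"] <= 1)).all()
        assert (pts["proportion"] == pts["n_pos"] / pts["n_total"]).all()
        assert (np.diff(pts["x_center"]) > 0).all()
        assert (pts["n_total"] >= curve.config.min_events_per_window).all()


class TestTransform:
    def test_log10_closed_form(self):
        out = transform_expression([1.0, 10.0, 100.0])
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0])

    def test_clip_floor(self):
        assert transform_expression([0.5])[0] == 0.0

    def test_asinh_zero(self):
        spec = TransformSpec(method="asinh", cofactor=150)
        assert transform_expression([0.0], spec)[0] == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            transform_expression([np.nan])


class TestOctiles:
    def test_equal_count_splits_800_events_into_100s(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 4, 300)
        neg = rng.uniform(0, 4, 500)
        curve = octile_curve(pos, neg, "equal_count")
        assert curve.n_points == 8
        assert (curve.points["n_total"] == 100).all()

    def test_all_negative_gives_zero_proportions(self):
        curve = octile_curve([], np.linspace(0, 1, 80), "equal_count")
        assert (curve.points["proportion"] == 0.0).all()

    def test_too_few_events_raises(self):
        with pytest.raises(ValueError, match="8"):
            octile_curve([1.0], [2.0], "equal_count")

    def test_octile_and_stepbin_phi_agree_on_simulated_sample(
            self, wt_clean, wt_gates):
        from speckscore import apply_gates
        clean, _, _ = wt_clean
        gated = apply_gates(clean, wt_gates)
        pos, neg = gated.expression()
        pos_x, neg_x = transform_expression(pos), transform_expression(neg)
        phi_step = fit_4pl(step_binned_curve(pos_x, neg_x)).phi
        phi_oct = fit_4pl(octile_curve(pos_x, neg_x)).phi
        assert abs(phi_oct - phi_step) / phi_step < 0.05


def _curve_from_params(alpha, delta, eta, phi, x):
    p = four_pl(x, alpha, delta, eta, phi)
    pts = pd.DataFrame({
        "x_center": x, "n_pos": np.round(p * 1000).astype(int),
        "n_total": 1000, "proportion": p,
    })
    return DoseResponseCurve(points=pts, range=(x.min(), x.max()))


class TestFourPL:
    def test_noiseless_recovery_to_1e3(self):
        x = np.arange(0.5, 3.51, 0.5)
        curve = _curve_from_params(0.05, 0.9, 4.0, 2.0, x)
        fit = fit_4pl(curve)
        assert fit.converged
        assert abs(fit.phi - 2.0) < 1e-3
        for got, want in ((fit.alpha, 0.05), (fit.delta, 0.9), (fit.eta, 4.0)):
            assert abs(got - want) / want < 1e-3

    def test_midpoint_identity(self):
        x = np.linspace(0.2, 4, 12)
        fit = fit_4pl(_curve_from_params(0.1, 0.8, 3.0, 2.0, x))
        assert fit.predict(fit.phi) == pytest.approx(fit.alpha + fit.delta / 2)

    def test_decreasing_curve_gets_negative_steepness(self):
        x = np.linspace(0.5, 4, 10)
        fit = fit_4pl(_curve_from_params(0.05, 0.9, -3.0, 2.0, x))
        assert fit.converged and fit.eta < 0

    def test_bounds_are_respected(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            x = np.linspace(0.3, 4.5, 15)
            alpha = rng.uniform(0.01, 0.3)
            delta = rng.uniform(0.3, 1 - alpha)
            eta = rng.choice([-1, 1]) * rng.uniform(1.5, 8)
            phi = rng.uniform(0.8, 4.0)
            noisy = _curve_from_params(alpha, delta, eta, phi, x)
            noisy.points["proportion"] = np.clip(
                noisy.points["proportion"] + rng.normal(0, 0.03, len(x)), 0, 1)
            fit = fit_4pl(noisy)
            assert 0 < fit.alpha < 1
            assert fit.delta <= 1
            assert fit.phi > 0

    def test_sparse_curve_is_excluded(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(CurveTooSparseError):
            fit_4pl(_curve_from_params(0.05, 0.9, 3.0, 2.0, x))


class TestASC50:
    @pytest.mark.parametrize("phi_wt, phi_sample, expected", [
        (3.0, 3.0, 0.0),
        (3.0, 1.5, 0.5),
        (3.0, 4.5, -0.5),
    ])
    def test_closed_form(self, phi_wt, phi_sample, expected):
        def fake(phi):
            from speckscore.dose_response import FourPLFit
            return FourPLFit(0.05, 0.9, 3.0, phi, True, 0.0, 10)
        assert compute_asc50(fake(phi_sample), fake(phi_wt)) == pytest.approx(expected)

    def test_nonconverged_fit_is_not_scorable(self):
        from speckscore.dose_response import FourPLFit
        bad = FourPLFit(0.05, 0.9, 3.0, 2.0, False, 0.0, 10)
        good = FourPLFit(0.05, 0.9, 3.0, 3.0, True, 0.0, 10)
        with pytest.raises(ValueError, match="converged"):
            compute_asc50(bad, good)

    def test_replicate_aggregation(self):
        s = score_replicates([0.5, 0.5, 0.5], "V", "untreated")
        assert s.mean == 0.5 and s.sem == 0.0
        s2 = score_replicates([0.4, 0.6], "V", "untreated")
        assert s2.mean == pytest.approx(0.5)
        assert s2.sem == pytest.approx(0.1)
        s1 = score_replicates([0.3])
        assert s1.single_replicate and s1.sem == 0.0
        with pytest.raises(ValueError):
            score_replicates([])
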