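"""Equilibration reduction: exchange fractions, δ²H_ne, corrections, batch QC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hydrofrac.equilibration import (
    BatchConfig,
    calibrate_to_vsmow,
    compute_delta_ne,
    compute_exchange_fraction,
    forward_equilibrate,
    offset_correct,
    process_equilibration_batch,
)
from hydrofrac.types import (
    PAIR_INCONSISTENT,
    X_E_OUT_OF_RANGE,
    CalibrationStandard,
    EquilibrationMeasurement,
)

WATERS = dict(delta_w1=-160.0, delta_w2=-428.0, alpha_ew=1.082)


def make(e1, e2, **kw):
    return EquilibrationMeasurement("s", e1, e2, **{**WATERS, **kw})


class TestExchangeFraction:
    @pytest.mark.parametrize(
        "e1, e2, expected",
        [
            (-100.0, -100.0, 0.0),  # exchange-free (PEF-like): pairs coincide
            (-83.892, -185.3836, 0.35),  # sucrose-like sample simulated at x_e = 0.35
            (-250.0, -250.0, 0.0),
        ],
    )
    def test_examples(self, e1, e2, expected):
        assert compute_exchange_fraction(make(e1, e2)) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_water_pair_rejected(self):
        with pytest.raises(ValueError, match="degenerate water pair"):
            EquilibrationMeasurement("s", -100, -120, delta_w1=-160, delta_w2=-160)

    @given(
        spread=st.floats(-100, 100),
        e2=st.floats(-400, 0),
    )
    def test_linear_in_pair_spread(self, spread, e2):
        """x_e is linear in (e1 − e2) with slope 1/(α·(w1 − w2))."""
        x = compute_exchange_fraction(make(e2 + spread, e2))
        slope = 1.0 / (1.082 * (-160.0 - -428.0))
        assert x == pytest.approx(spread * slope, abs=1e-12)


class TestDeltaNe:
    def test_no_exchange_returns_input(self):
        assert compute_delta_ne(-83.9, 0.0, -160.0, 1.082) == -83.9

    @pytest.mark.parametrize(
        "delta_e, delta_w",
        [(-83.892, -160.0), (-185.3836, -428.0)],
    )
    def test_both_pairs_recover_same_truth(self, delta_e, delta_w):
        assert compute_delta_ne(delta_e, 0.35, delta_w, 1.082) == pytest.approx(-80.0, abs=1e-9)

    def test_fully_exchanged_is_singular(self):
        with pytest.raises(ZeroDivisionError):
            compute_delta_ne(-100.0, 1.0, -160.0, 1.082)


class TestForwardEquilibrate:
    def test_hand_example(self):
        assert forward_equilibrate(-80.0, 0.35, -160.0, 1.082) == pytest.approx(-83.892, abs=1e-9)

    def test_no_exchange_identity(self):
        assert forward_equilibrate(-80.0, 0.0, -160.0, 1.082) == -80.0

    def test_full_exchange_forgets_delta_ne(self):
        for ne in (-300.0, -80.0, 50.0):
            assert forward_equilibrate(ne, 1.0, -160.0, 1.082) == pytest.approx(-91.12, abs=1e-9)

    @given(
        ne=st.floats(-400, 100),
        x=st.floats(0, 0.9),
        w=st.sampled_from([-160.0, -428.0]),
    )
    def test_round_trip_with_reduction(self, ne, x, w):
        """forward_equilibrate is the exact inverse of the Eq.-style reduction."""
        e1 = forward_equilibrate(ne, x, -160.0, 1.082)
        e2 = forward_equilibrate(ne, x, -428.0, 1.082)
        x_back = compute_exchange_fraction(make(e1, e2))
        assert x_back == pytest.approx(x, abs=1e-9)
        e, ww = (e1, -160.0) if w == -160.0 else (e2, -428.0)
        assert compute_delta_ne(e, x_back, ww, 1.082) == pytest.approx(ne, abs=1e-6)


class TestCorrections:
    def test_offset_identity_and_shift(self):
        assert offset_correct([-83.9], -100.0, -100.0) == [-83.9]
        assert offset_correct([-83.9], -105.0, -100.0) == [pytest.approx(-78.9)]

    def test_offset_preserves_differences(self):
        out = offset_correct([-10.0, -50.0, 30.0], -105.0, -95.0)
        assert np.ptp(out) == pytest.approx(np.ptp([-10.0, -50.0, 30.0]))

    def test_vsmow_two_point(self):
        standards = [
            CalibrationStandard("a", known_delta=-80.0, measured_delta=-90.0),
            CalibrationStandard("b", known_delta=-40.0, measured_delta=-45.0),
        ]
        (out,) = calibrate_to_vsmow([-70.0], standards)
        assert out == pytest.approx(-62.2222, abs=1e-3)

    def test_vsmow_identity_standards(self):
        standards = [
            CalibrationStandard("a", known_delta=-80.0, measured_delta=-80.0),
            CalibrationStandard("b", known_delta=-40.0, measured_delta=-40.0),
        ]
        assert calibrate_to_vsmow([-70.0, 5.0], standards) == pytest.approx([-70.0, 5.0])

    def test_vsmow_degenerate_standards(self):
        standards = [
            CalibrationStandard("a", known_delta=-80.0, measured_delta=-60.0),
            CalibrationStandard("b", known_delta=-40.0, measured_delta=-60.0),
        ]
        with pytest.raises(ValueError, match="identical measured_delta"):
            calibrate_to_vsmow([-70.0], standards)

    @given(shift=st.floats(-50, 50), value=st.floats(-300, 100))
    def test_vsmow_is_affine(self, shift, value):
        standards = [
            CalibrationStandard("a", known_delta=-80.0, measured_delta=-90.0),
            CalibrationStandard("b", known_delta=-40.0, measured_delta=-45.0),
        ]
        a, b = calibrate_to_vsmow([value, value + shift], standards)
        slope = 40.0 / 45.0
        assert b - a == pytest.approx(slope * shift, abs=1e-8)


class TestBatch:
    def test_pef_like_batch_unflagged(self):
        batch = [make(-100.0, -100.0), make(-95.5, -95.5)]
        outcome = process_equilibration_batch(batch)
        assert [r.x_e for r in outcome.results] == [0.0, 0.0]
        assert all(not r.qc_flags for r in outcome.results)
        assert not outcome.failures

    def test_zero_noise_round_trip(self):
        truth = [(-80.0, 0.35), (-120.0, 0.21), (-60.0, 0.0)]
        batch = [
            make(
                forward_equilibrate(ne, x, -160.0, 1.082),
                forward_equilibrate(ne, x, -428.0, 1.082),
            )
            for ne, x in truth
        ]
        outcome = process_equilibration_batch(batch)
        for result, (ne, x) in zip(outcome.results, truth):
            assert result.delta_ne == pytest.approx(ne, abs=1e-9)
            assert result.x_e == pytest.approx(x, abs=1e-9)
            assert result.pair_residual <= 1e-9

    def test_out_of_range_x_e_flagged_but_retained(self):
        # e1 - e2 spread larger than α·(w1 − w2) forces x_e > 1
        wide = make(
            forward_equilibrate(-80.0, 1.2, -160.0, 1.082),
            forward_equilibrate(-80.0, 1.2, -428.0, 1.082),
        )
        outcome = process_equilibration_batch([make(-100.0, -100.0), wide])
        assert len(outcome.results) == 2
        flagged = outcome.results[1]
        assert flagged.x_e == pytest.approx(1.2, abs=1e-9)
        assert X_E_OUT_OF_RANGE in flagged.qc_flags

    def test_fully_exchanged_record_fails_without_aborting(self):
        singular = make(
            forward_equilibrate(-80.0, 1.0, -160.0, 1.082),
            forward_equilibrate(-80.0, 1.0, -428.0, 1.082),
        )
        ok = make(-100.0, -100.0)
        outcome = process_equilibration_batch([singular, ok])
        assert len(outcome.results) == 1
        assert len(outcome.failures) == 1
        assert outcome.failures[0][0] == "s"

    def test_offset_and_vsmow_stages_compose(self):
        ne, x = -80.0, 0.35
        shift = 5.0  # instrument bias removed by the PEF offset stage
        raw = make(
            forward_equilibrate(ne, x, -160.0, 1.082) - shift,
            forward_equilibrate(ne, x, -428.0, 1.082) - shift,
        )
        standards = [
            CalibrationStandard("PEF", known_delta=-100.0, measured_delta=-105.0, exchangeable=False),
            CalibrationStandard("sucrose", known_delta=-80.0, measured_delta=-80.0),
            CalibrationStandard("cellulose", known_delta=-40.0, measured_delta=-40.0),
        ]
        outcome = process_equilibration_batch([raw], standards)
        assert outcome.results[0].delta_ne == pytest.approx(ne, abs=1e-9)
        assert outcome.results[0].x_e == pytest.approx(x, abs=1e-9)

    def test_pair_inconsistency_flag_threshold(self):
        outcome = process_equilibration_batch(
            [make(-100.0, -100.0)], config=BatchConfig(pair_tolerance=-1.0)
        )
        # residual is an algebraic zero; forcing the tolerance negative flags it
        assert PAIR_INCONSISTENT in outcome.results[0].qc_flags
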