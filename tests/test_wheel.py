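"""Modulation wheel model: WET lookup, delivery translation, SOBP synthesis."""

import numpy as np
import pytest

from sobplet.curves import (
    SobpRequest,
    measure_modwidth,
    measure_range,
    normalize_sobp,
    plateau_level,
    pristine_let,
    shift_curve,
)
from sobplet.synthetic import TABLE1_REQUESTS
from sobplet.wheel import (
    BLOCKED,
    DeliveryProtocol,
    WheelSpec,
    WheelStep,
    _synthesize_raw,
    flatten_weights,
    pristine_for_request,
    replay_delivery,
    rotation_for_modwidth,
    synthesize_sobp,
    wet_at_angle,
    wheel_from_yaml,
    wheel_to_yaml,
)


def small_wheel():
    """Four-step wheel with hand-checkable thicknesses."""
    steps = (
        WheelStep(40.0, 80.0, 10.0, 0.40),
        WheelStep(120.0, 80.0, 11.0, 0.30),
        WheelStep(200.0, 80.0, 12.0, 0.20),
        WheelStep(280.0, 80.0, 13.0, 0.10),
    )
    return WheelSpec(steps=steps, brass_start=0.0, brass_span=40.0)


class TestWetAtAngle:
    def test_hand_sum(self):
        # 10*1.15 + 1*2.1 + 0.4*5.0 = 15.6 mm WET
        assert wet_at_angle(small_wheel(), 45.0) == pytest.approx(15.6)

    def test_brass_is_blocked(self):
        assert wet_at_angle(small_wheel(), 20.0) is BLOCKED

    def test_piecewise_constant_within_step(self):
        w = small_wheel()
        assert wet_at_angle(w, 121.0) == wet_at_angle(w, 199.0)

    def test_angle_wraps_modulo_360(self):
        w = small_wheel()
        assert wet_at_angle(w, 45.0 + 720.0) == wet_at_angle(w, 45.0)


class TestWheelSpecInvariants:
    def test_gap_rejected(self):
        steps = (WheelStep(50.0, 70.0, 10.0, 0.4), WheelStep(120.0, 240.0, 11.0, 0.3))
        with pytest.raises(ValueError, match="tile"):
            WheelSpec(steps=steps, brass_start=0.0, brass_span=40.0)

    def test_non_monotone_thickness_rejected(self):
        steps = (
            WheelStep(40.0, 110.0, 10.0, 0.40),
            WheelStep(150.0, 110.0, 12.0, 0.30),
            WheelStep(260.0, 100.0, 11.0, 0.20),
        )
        with pytest.raises(ValueError, match="monotonic"):
            WheelSpec(steps=steps, brass_start=0.0, brass_span=40.0)

    def test_center_plate_fixed(self):
        with pytest.raises(ValueError, match="1 mm"):
            WheelSpec(steps=small_wheel().steps, brass_start=0.0,
                      brass_span=40.0, center_plate_mm=2.0)

    def test_yaml_round_trip(self, tmp_path, wheel1):
        path = tmp_path / "wheel.yaml"
        wheel_to_yaml(wheel1, path)
        back = wheel_from_yaml(path)
        np.testing.assert_allclose(back.wets, wheel1.wets)
        assert back.brass_start == pytest.approx(wheel1.brass_start)


class TestRotationForModwidth:
    def test_zero_angle_must_be_in_brass(self, wheel1):
        outside = (wheel1.brass_end + 5.0) % 360.0
        with pytest.raises(ValueError, match="brass"):
            rotation_for_modwidth(wheel1, outside, SobpRequest(20.0, 5.0))

    def test_unreachable_modwidth_names_maximum(self, wheel1, zero1):
        with pytest.raises(ValueError, match="maximum"):
            rotation_for_modwidth(wheel1, zero1, SobpRequest(30.0, 25.0))

    def test_rotation_monotone_in_modwidth(self, wheel1, zero1):
        rots = [
            rotation_for_modwidth(wheel1, zero1, SobpRequest(23.0, m)).rotation_angle
            for m in (3.0, 6.0, 9.0, 12.0, 15.0)
        ]
        assert np.all(np.diff(rots) >= 0)

    def test_minimal_sweep_for_single_step_span(self, wheel1, zero1):
        # a request matching the smallest pull-backs sweeps only the first steps
        req = SobpRequest(23.0, 2.5)
        proto = rotation_for_modwidth(wheel1, zero1, req)
        active = np.flatnonzero(proto.step_weights > 0)
        assert active.max() <= np.searchsorted(wheel1.pullbacks, 25.0) + 1

    def test_delivered_modwidth_tracks_request(self, table1_sobps):
        for (wheel_no, req), (dose, _) in table1_sobps.items():
            assert measure_modwidth(dose) == pytest.approx(req.modwidth_mm, abs=2.0)

    def test_delivered_range_matches_request(self, table1_sobps):
        for (wheel_no, req), (dose, _) in table1_sobps.items():
            assert measure_range(dose) == pytest.approx(req.range_mm, abs=1.0)


class TestFlattenWeights:
    def test_single_peak(self):
        pristine = pristine_for_request(SobpRequest(20.0, 5.0))
        w = flatten_weights([0.0], pristine, (150.0, 190.0))
        np.testing.assert_array_equal(w, [1.0])

    def test_symmetric_tie_for_duplicate_pullbacks(self):
        pristine = pristine_for_request(SobpRequest(20.0, 5.0))
        w = flatten_weights([0.0, 30.0, 30.0], pristine, (172.0, 197.0))
        assert w[1] == pytest.approx(w[2], rel=1e-12)

    def test_deepest_component_has_largest_weight(self):
        pristine = pristine_for_request(SobpRequest(20.0, 10.0))
        pulls = np.linspace(0.0, 100.0, 20)
        w = flatten_weights(pulls, pristine, (102.0, 197.0))
        assert w[0] == w.max() == 1.0

    def test_plateau_ripple_below_three_percent(self):
        req = SobpRequest(20.0, 10.0)
        pristine = pristine_for_request(req)
        pulls = np.linspace(0.0, 100.0, 40)
        w = flatten_weights(pulls, pristine, (102.0, 197.0))
        grid = np.arange(0.0, 235.0, 0.5)
        from sobplet.curves import pristine_bragg

        base = pristine_bragg(pristine, grid)
        dose = sum(wi * shift_curve(base, p).dose for wi, p in zip(w, pulls))
        sel = (grid >= 125.0) & (grid <= 175.0)  # central 50% of the plateau
        ripple = (dose[sel].max() - dose[sel].min()) / dose[sel].mean()
        assert ripple < 0.03

    def test_empty_interval_raises(self):
        pristine = pristine_for_request(SobpRequest(20.0, 5.0))
        with pytest.raises(ValueError):
            flatten_weights([0.0, 10.0], pristine, (190.0, 150.0))


class TestSynthesizeSobp:
    def test_one_step_sweep_reproduces_pristine_shape(self, wheel1, zero1):
        req = SobpRequest(20.0, 2.5)
        weights = np.zeros(len(wheel1.steps))
        weights[0] = 1.0
        proto = DeliveryProtocol(zero1, 30.0, weights)
        dose, _ = _synthesize_raw(wheel1, proto, req)
        from sobplet.curves import pristine_bragg

        ref = pristine_bragg(pristine_for_request(req), dose.depths)
        np.testing.assert_allclose(dose.dose / dose.dose.max(),
                                   ref.dose / ref.dose.max(), atol=1e-9)

    def test_let_d_bounded_by_component_let(self, wheel1, zero1):
        req = SobpRequest(22.0, 8.0)
        proto = rotation_for_modwidth(wheel1, zero1, req)
        dose, let_d = _synthesize_raw(wheel1, proto, req)
        active = np.flatnonzero(proto.step_weights > 1e-12)
        peak = pristine_for_request(req)
        base_let = pristine_let(peak, dose.depths)
        comp = np.stack([shift_curve(base_let, wheel1.pullbacks[i]).let
                         for i in active])
        sel = dose.dose > 1e-6 * dose.dose.max()
        assert np.all(let_d.let[sel] <= comp.max(axis=0)[sel] + 1e-9)
        assert np.all(let_d.let[sel] >= comp.min(axis=0)[sel] - 1e-9)

    def test_let_rises_from_plateau_center_to_distal_edge(self, table1_sobps):
        for (wheel_no, req), (dose, let_d) in table1_sobps.items():
            at_d80 = np.interp(measure_range(dose), let_d.depths, let_d.let)
            at_center = np.interp(req.range_mm - 0.5 * req.modwidth_mm,
                                  let_d.depths, let_d.let)
            assert at_d80 > at_center

    def test_weight_scaling_linearity(self, wheel1, zero1):
        req = SobpRequest(22.0, 8.0)
        proto = rotation_for_modwidth(wheel1, zero1, req)
        doubled = DeliveryProtocol(proto.zero_angle, proto.rotation_angle,
                                   2.0 * proto.step_weights)
        d1, l1 = _synthesize_raw(wheel1, proto, req)
        d2, l2 = _synthesize_raw(wheel1, doubled, req)
        np.testing.assert_allclose(d2.dose, 2.0 * d1.dose, rtol=1e-12)
        np.testing.assert_allclose(l2.let, l1.let, atol=1e-9)

    def test_sweep_additivity_in_dose(self, wheel1, zero1):
        req = SobpRequest(22.0, 8.0)
        proto = rotation_for_modwidth(wheel1, zero1, req)
        w = proto.step_weights
        active = np.flatnonzero(w > 0)
        half_a, half_b = np.zeros_like(w), np.zeros_like(w)
        half_a[active[::2]] = w[active[::2]]
        half_b[active[1::2]] = w[active[1::2]]
        total, _ = _synthesize_raw(wheel1, proto, req)
        a, _ = _synthesize_raw(wheel1, DeliveryProtocol(zero1, proto.rotation_angle, half_a), req)
        b, _ = _synthesize_raw(wheel1, DeliveryProtocol(zero1, proto.rotation_angle, half_b), req)
        np.testing.assert_allclose(a.dose + b.dose, total.dose, rtol=1e-12)

    def test_all_blocked_sweep_raises(self, wheel1, zero1):
        proto = DeliveryProtocol(zero1, 10.0, np.zeros(len(wheel1.steps)))
        with pytest.raises(ValueError, match="blocked"):
            _synthesize_raw(wheel1, proto, SobpRequest(22.0, 8.0))

    def test_table1_plateau_quality(self, table1_sobps):
        """Every delivery-QA SOBP has <3% plateau ripple and a monotone
        distal falloff."""
        for (wheel_no, req), (dose, _) in table1_sobps.items():
            lo = req.range_mm - 0.75 * req.modwidth_mm
            hi = req.range_mm - 0.25 * req.modwidth_mm
            sel = (dose.depths >= lo) & (dose.depths <= hi)
            ripple = (dose.dose[sel].max() - dose.dose[sel].min()) / dose.dose[sel].mean()
            assert ripple < 0.03
            tail = dose.depths >= measure_range(dose)
            assert np.all(np.diff(dose.dose[tail]) <= 1e-9)
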