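"""Depth-dose primitives: pristine peaks, LET model, shifting, SOBP metrics."""

import numpy as np
import pytest

from conftest import trapezoid_curve
from helpers_oracle import fine_scan_modwidth, fine_scan_range
from sobplet.curves import (
    DepthDoseCurve,
    LetDepthCurve,
    PristinePeak,
    SobpRequest,
    _crossings,
    default_straggle,
    measure_modwidth,
    measure_modwidth_d98,
    measure_range,
    normalize_sobp,
    plateau_level,
    pristine_bragg,
    pristine_let,
    shift_curve,
)

GRID = np.arange(0.0, 130.5, 0.5)


def peak(r80=100.0, sigma=None, slope=3e-4):
    return PristinePeak(r80, default_straggle(r80) if sigma is None else sigma, slope)


class TestPristineBragg:
    def test_distal_d80_pinned_to_r80(self):
        c = pristine_bragg(peak(), GRID)
        d80 = _crossings(c.depths, c.dose, 0.8 * c.dose.max())[-1]
        assert abs(d80 - 100.0) <= 0.5

    def test_single_peaked_and_tail_vanishes(self):
        p = peak()
        c = pristine_bragg(p, GRID)
        i = int(np.argmax(c.dose))
        assert np.all(np.diff(c.dose[: i + 1]) >= -1e-9)
        assert np.all(np.diff(c.dose[i:]) <= 1e-9)
        tail = c.dose[c.depths > p.r80 + 5 * p.sigma_straggle]
        assert np.all(tail < 1e-3 * c.dose.max())

    def test_straggle_widens_distal_falloff(self):
        widths = []
        for s in (1.0, 2.0):
            c = pristine_bragg(peak(sigma=s), GRID)
            x90 = _crossings(c.depths, c.dose, 0.9 * c.dose.max())[-1]
            x10 = _crossings(c.depths, c.dose, 0.1 * c.dose.max())[-1]
            widths.append(x10 - x90)
        assert widths[1] > widths[0]

    def test_scaling_leaves_d80_depth_unchanged(self):
        c = pristine_bragg(peak(), GRID)
        scaled = c.scaled(3.7)
        a = _crossings(c.depths, c.dose, 0.8 * c.dose.max())[-1]
        b = _crossings(scaled.depths, scaled.dose, 0.8 * scaled.dose.max())[-1]
        assert a == pytest.approx(b, abs=1e-12)

    def test_truncated_grid_raises(self):
        with pytest.raises(ValueError, match="truncat"):
            pristine_bragg(peak(), np.arange(0.0, 90.0, 0.5))


class TestPristineLet:
    def test_entrance_below_track_end(self):
        l = pristine_let(peak(), GRID)
        assert l.let[0] < np.interp(100.0, l.depths, l.let)

    def test_monotone_over_second_half(self):
        l = pristine_let(peak(), GRID)
        sel = (l.depths >= 50.0) & (l.depths <= 100.0)
        assert np.all(np.diff(l.let[sel]) >= -1e-12)

    def test_physical_band(self):
        for r80 in (80.0, 150.0, 284.0):
            l = pristine_let(peak(r80), np.arange(0.0, r80 + 25.0, 0.5))
            assert np.all(l.let >= 0.3) and np.all(l.let <= 20.0)

    def test_equal_let_at_equal_residual_range(self):
        la = pristine_let(peak(100.0), GRID)
        lb = pristine_let(peak(150.0), np.arange(0.0, 180.5, 0.5))
        for rr in (10.0, 40.0, 80.0):
            a = np.interp(100.0 - rr, la.depths, la.let)
            b = np.interp(150.0 - rr, lb.depths, lb.let)
            assert a == pytest.approx(b, rel=0.05)


class TestShiftCurve:
    def test_zero_pullback_is_identity(self):
        c = pristine_bragg(peak(), GRID)
        np.testing.assert_array_equal(shift_curve(c, 0.0).dose, c.dose)

    def test_translates_distal_edge(self):
        c = pristine_bragg(peak(), GRID)
        s = shift_curve(c, 10.0)
        a = _crossings(c.depths, c.dose, 0.8 * c.dose.max())[-1]
        b = _crossings(s.depths, s.dose, 0.8 * s.dose.max())[-1]
        assert a - b == pytest.approx(10.0, abs=0.25)

    @pytest.mark.parametrize("p", [5.0, 20.0, 40.0])
    def test_range_shifts_by_pullback(self, p):
        c = pristine_bragg(peak(), GRID)
        s = shift_curve(c, p)
        a = _crossings(c.depths, c.dose, 0.8 * c.dose.max())[-1]
        b = _crossings(s.depths, s.dose, 0.8 * s.dose.max())[-1]
        assert a - b == pytest.approx(p, abs=0.25)

    @pytest.mark.parametrize("a,b", [(2.0, 3.5), (0.5, 10.0), (7.5, 12.5)])
    def test_composition_on_grid_commensurate_shifts(self, a, b):
        c = pristine_bragg(peak(), GRID)
        once = shift_curve(c, a + b)
        twice = shift_curve(shift_curve(c, a), b)
        np.testing.assert_allclose(twice.dose, once.dose, atol=1e-9)

    def test_negative_pullback_raises(self):
        c = pristine_bragg(peak(), GRID)
        with pytest.raises(ValueError):
            shift_curve(c, -1.0)

    def test_works_on_let_curves(self):
        l = pristine_let(peak(), GRID)
        s = shift_curve(l, 10.0)
        assert isinstance(s, LetDepthCurve)
        assert s.let[0] == pytest.approx(np.interp(10.0, l.depths, l.let))


class TestMetrics:
    def test_range_linear_falloff(self):
        c = trapezoid_curve()
        # plateau 100, falls 100 -> 0 over [150, 154]: crossing of 80 at 150.8
        assert measure_range(c) == pytest.approx(150.8, abs=1e-9)

    def test_range_scale_invariant(self):
        c = trapezoid_curve()
        doubled = DepthDoseCurve(c.depths, 2.0 * c.dose)
        assert measure_range(doubled) == pytest.approx(150.8, abs=1e-9)
        assert measure_range(doubled, level=200.0) == pytest.approx(150.8, abs=1e-9)

    def test_range_without_crossing_raises(self):
        flat = DepthDoseCurve(GRID, np.full(GRID.size, 100.0))
        with pytest.raises(ValueError):
            measure_range(flat)

    def test_modwidth_linear_edges(self):
        c = trapezoid_curve()
        # proximal D90 at 49.8, distal D90 at 150.4
        assert measure_modwidth(c) == pytest.approx(100.6, abs=1e-9)

    def test_modwidth_rectangular(self):
        c = trapezoid_curve(spacing=0.1, rise=(49.9, 50.0), flat_until=150.0,
                            fall_until=150.1)
        assert measure_modwidth(c) == pytest.approx(100.0, abs=0.05)
        assert measure_modwidth_d98(c) == pytest.approx(measure_modwidth(c),
                                                        abs=0.05)

    def test_modwidth_requires_two_crossings(self):
        c = pristine_bragg(peak(), GRID)  # no proximal D90 shoulder concept here
        high = DepthDoseCurve(GRID, np.full(GRID.size, 100.0) + 0.01 * GRID)
        with pytest.raises(ValueError):
            measure_modwidth(high)

    def test_d98_width_smaller_on_slow_ramp(self):
        c = trapezoid_curve(rise=(20.0, 60.0))
        assert measure_modwidth_d98(c) < measure_modwidth(c)

    def test_metrics_match_fine_scan_oracle(self, wheel1, zero1, table1_sobps):
        for (wheel_no, req), (dose, _) in table1_sobps.items():
            lvl = plateau_level(dose)
            assert measure_range(dose) == pytest.approx(
                fine_scan_range(dose, lvl), abs=0.5)
            assert measure_modwidth(dose) == pytest.approx(
                fine_scan_modwidth(dose, lvl), abs=0.5)

    def test_random_sobps_match_fine_scan_oracle(self):
        """Superpositions of randomly weighted pulled-back peaks agree with a
        0.01 mm exhaustive scan on both clinical metrics."""
        from sobplet.curves import shift_curve as sh

        rng = np.random.default_rng(12345)
        grid = np.arange(0.0, 240.5, 0.5)
        base = pristine_bragg(peak(200.0), grid)
        n_checked = 0
        for _ in range(100):
            n_comp = rng.integers(8, 30)
            pulls = np.sort(rng.uniform(0.0, 120.0, n_comp))
            w = 0.1 + rng.random(n_comp) * np.linspace(1.0, 0.05, n_comp)
            dose = sum(wi * sh(base, p).dose for wi, p in zip(w, pulls))
            curve = DepthDoseCurve(grid, dose)
            lvl = plateau_level(curve)
            try:
                mw = measure_modwidth(curve, lvl)
            except ValueError:
                continue  # randomly weighted sums need not have a D90 shoulder
            assert measure_range(curve, lvl) == pytest.approx(
                fine_scan_range(curve, lvl), abs=0.5)
            assert mw == pytest.approx(fine_scan_modwidth(curve, lvl), abs=0.5)
            n_checked += 1
        assert n_checked >= 60


class TestNormalizeSobp:
    REQ = SobpRequest(15.0, 10.0)

    def test_flat_window_scales_to_100(self):
        c = trapezoid_curve(level=37.2)
        n = normalize_sobp(c, self.REQ)
        sel = (n.depths >= 60.0) & (n.depths <= 140.0)
        assert np.allclose(n.dose[sel], 100.0)

    def test_idempotent(self):
        c = trapezoid_curve(level=42.0)
        once = normalize_sobp(c, self.REQ)
        twice = normalize_sobp(once, self.REQ)
        np.testing.assert_allclose(twice.dose, once.dose, rtol=1e-12)

    def test_tilted_window_mean_is_100(self):
        c = trapezoid_curve()
        tilt = c.dose * (1.0 + 0.001 * (c.depths - 100.0))
        n = normalize_sobp(DepthDoseCurve(c.depths, np.maximum(tilt, 0.0)),
                           self.REQ)
        d90 = _crossings(n.depths, n.dose, 0.9 * plateau_level(n))[-1]
        center = d90 - 0.5 * self.REQ.modwidth_mm
        sel = (n.depths >= center - 25.0 - 1e-9) & (n.depths <= center + 25.0 + 1e-9)
        assert np.mean(n.dose[sel]) == pytest.approx(100.0, abs=1e-9)

    def test_window_outside_grid_raises(self):
        c = trapezoid_curve(rise=(8.0, 10.0), flat_until=100.0, fall_until=104.0,
                            zmax=130.0)
        with pytest.raises(ValueError, match="window"):
            normalize_sobp(c, SobpRequest(15.0, 14.0))

    def test_metrics_invariant_under_scaling_then_normalizing(self, table1_sobps):
        (_, req), (dose, _) = next(iter(table1_sobps.items()))
        for scale in (0.037, 1.0, 418.0):
            scaled = normalize_sobp(dose.scaled(scale), req)
            assert measure_range(scaled) == pytest.approx(measure_range(dose),
                                                          abs=1e-6)
            assert measure_modwidth(scaled) == pytest.approx(
                measure_modwidth(dose), abs=1e-6)


class TestCurveTypes:
    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            DepthDoseCurve(np.array([0.0, 0.5, 1.5]), np.zeros(3))

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DepthDoseCurve(np.array([0.0, 0.5, 1.0]), np.array([1.0, -0.1, 0.0]))

    def test_invalid_peak_parameters(self):
        with pytest.raises(ValueError):
            PristinePeak(-1.0, 1.0)
        with pytest.raises(ValueError):
            PristinePeak(100.0, 0.0)

    def test_request_ordering_enforced(self):
        with pytest.raises(ValueError):
            SobpRequest(10.0, 11.0)
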