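import numpy as np
import pytest

from sobplet.synthetic import TABLE1_REQUESTS, draw_zero_angle, make_wheel
from sobplet.wheel import rotation_for_modwidth, synthesize_sobp


@pytest.fixture(scope="session")
def wheel1():
    return make_wheel(3)


@pytest.fixture(scope="session")
def wheel2():
    return make_wheel(4)


@pytest.fixture(scope="session")
def zero1(wheel1):
    return draw_zero_angle(wheel1, 8)


@pytest.fixture(scope="session")
def zero2(wheel2):
    return draw_zero_angle(wheel2, 9)


@pytest.fixture(scope="session")
def table1_sobps(wheel1, wheel2, zero1, zero2):
    """Synthesized (dose, LET) curves for the 11 delivery-QA requests."""
    out = {}
    for wheel, zero, wheel_no in ((wheel1, zero1, 1), (wheel2, zero2, 2)):
        for req in TABLE1_REQUESTS[wheel_no]:
            proto = rotation_for_modwidth(wheel, zero, req)
            out[(wheel_no, req)] = synthesize_sobp(wheel, proto, req)
    return out


def trapezoid_curve(spacing=0.5, rise=(48.0, 50.0), flat_until=150.0,
                    fall_until=154.0, level=100.0, zmax=170.0):
    """Piecewise-linear test SOBP: linear rise, flat plateau, linear fall."""
    from sobplet.curves import DepthDoseCurve

    z = np.arange(0.0, zmax + spacing / 2, spacing)
    d = np.zeros_like(z)
    r0, r1 = rise
    d[(z >= r0) & (z < r1)] = level * (z[(z >= r0) & (z < r1)] - r0) / (r1 - r0)
    d[(z >= r1) & (z <= flat_until)] = level
    sel = (z > flat_until) & (z <= fall_until)
    d[sel] = level * (fall_until - z[sel]) / (fall_until - flat_until)
    return DepthDoseCurve(z, d)
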