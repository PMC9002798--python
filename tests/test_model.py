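"""Curve algebra of the extended Scholander-Irving model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from torpormix import (
    InvalidParameterError,
    ThermoParams,
    derive_euthermic_line,
    derive_tt,
    predict_euthermic,
    predict_torpor,
    q10_conforming,
)
from conftest import random_admissible_params


def make_params(**kw):
    base = dict(m_tnz=1.0, t_lc=30.0, t_be=38.0, t_bt=2.0, tmr=0.05, m_r=0.4)
    base.update(kw)
    return ThermoParams(**base)


class TestEuthermicLine:
    def test_two_point_line(self):
        # line through (30, 1) and (38, 0)
        alpha, beta = derive_euthermic_line(make_params())
        assert beta == pytest.approx(-0.125)
        assert alpha == pytest.approx(4.75)

    def test_anchor_conditions(self):
        p = make_params()
        assert predict_euthermic(p.t_lc, p) == pytest.approx(p.m_tnz, abs=1e-12)
        assert predict_euthermic(p.t_be, p) == pytest.approx(0.0, abs=1e-12)

    def test_interpolated_value(self):
        # (38-22)/(38-30) * 1.0, from the two-anchor construction
        assert predict_euthermic(22.0, make_params()) == pytest.approx(2.0)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_euthermic_line(make_params(t_be=29.0))
        with pytest.raises(InvalidParameterError):
            derive_euthermic_line(make_params(t_be=30.0))


class TestTorporCurve:
    def test_breakpoint_location(self):
        # regulated line with slope -0.125 through (2, 0) reaches 0.05 at 1.6
        p = make_params()
        assert p.beta_r == pytest.approx(-0.125)
        assert derive_tt(p) == pytest.approx(1.6)

    def test_breakpoint_second_case(self):
        # slope -0.1 through (10, 0) reaches 1.0 at 0.0
        p = make_params(m_tnz=1.3, t_lc=20.0, t_be=33.0, t_bt=10.0, tmr=1.0,
                        m_r=1.04)
        assert p.beta_r == pytest.approx(-0.1)
        assert derive_tt(p) == pytest.approx(0.0, abs=1e-12)

    def test_breakpoint_matches_bisection_oracle(self, param_rng):
        for _ in range(200):
            p = random_admissible_params(param_rng)
            beta = abs(p.beta_r)
            root = brentq(
                lambda x: beta * (p.t_bt - x) - p.tmr, p.t_bt - 1000, p.t_bt,
                xtol=1e-12,
            )
            assert derive_tt(p) == pytest.approx(root, abs=1e-6)

    def test_anchors_and_continuity(self):
        p = make_params()
        assert predict_torpor(p.t_lc, p) == pytest.approx(p.m_r, abs=1e-12)
        t_t = p.t_t
        below = predict_torpor(t_t - 1e-9, p)
        above = predict_torpor(t_t + 1e-9, p)
        assert abs(below - above) < 1e-9
        assert above == pytest.approx(p.tmr, abs=1e-6)

    def test_conforming_value_from_log_linear_oracle(self):
        # exponential through (1.6, 0.05) and (30, 0.8): log-linear interpolation
        p = make_params(m_r=0.8)
        t_t = p.t_t
        ta = 15.0
        frac = (ta - t_t) / (30.0 - t_t)
        expected = math.exp(
            math.log(0.05) + frac * (math.log(0.8) - math.log(0.05))
        )
        assert expected == pytest.approx(0.18497, abs=1e-5)
        assert predict_torpor(ta, p) == pytest.approx(expected, rel=1e-10)

    def test_invalid_when_mr_below_tmr(self):
        p = make_params(m_r=0.01)
        with pytest.raises(InvalidParameterError):
            predict_torpor(20.0, p)

    def test_flat_conforming_limit(self):
        # m_r == tmr is admissible: conforming branch exactly flat
        p = make_params(tmr=0.4, m_r=0.4)
        assert p.beta_c == 0.0
        assert predict_torpor(20.0, p) == pytest.approx(0.4)


class TestQ10:
    def test_boundary_and_flat(self):
        p = make_params(m_r=0.8)
        assert q10_conforming(make_params(tmr=0.4, m_r=0.4)) == pytest.approx(1.0)
        # ratio of torpor M at two temperatures 10 deg C apart inside the
        # conforming range equals Q10
        lo, hi = 12.0, 22.0
        ratio = predict_torpor(hi, p) / predict_torpor(lo, p)
        assert q10_conforming(p) == pytest.approx(ratio, rel=1e-10)
        assert q10_conforming(p) == pytest.approx(2.654, abs=2e-3)

    def test_validation_rejects_excess_q10(self):
        # conforming span squeezed so hard the implied Q10 exceeds 5
        p = make_params(t_bt=28.0, tmr=0.01, m_r=1.0)
        with pytest.raises(InvalidParameterError):
            p.validate()


@settings(max_examples=150, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_invariants_over_random_admissible_params(seed):
    """Continuity at the breakpoint, anchor conditions, monotonicity and
    state ordering hold over the admissible parameter space."""
    p = random_admissible_params(np.random.default_rng(seed))
    assert predict_euthermic(p.t_lc, p) == pytest.approx(p.m_tnz, abs=1e-10)
    t_t = p.t_t
    assert t_t < p.t_lc and t_t < p.t_bt
    assert abs(predict_torpor(t_t - 1e-9, p) - predict_torpor(t_t + 1e-9, p)) < 1e-8
    ta = np.linspace(p.t_bt - 5.0, p.t_lc, 200)
    m_e = np.asarray(predict_euthermic(ta, p))
    m_t = np.asarray(predict_torpor(ta, p))
    assert np.all(np.diff(m_e) < 0)
    # torpid M falls toward TMR as T_a rises to the breakpoint (regulated
    # defense), then climbs the conforming exponential back up to M_r
    reg, conf = ta < t_t, ta >= t_t
    assert np.all(np.diff(m_t[reg]) < 0)
    assert np.all(np.diff(m_t[conf]) >= 0)  # flat when m_r == tmr
    assert np.all(m_e >= m_t - 1e-9)
    assert q10_conforming(p) <= 5.0 + 1e-9
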