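"""Unit and property tests of the core equations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damsim import core
from damsim.config import DimensionLevels, ModelConstants
from damsim.core import TargetSet
from damsim.rng import ScriptedStream


def levels_av(A_v: float) -> DimensionLevels:
    return DimensionLevels.adapted("avoidance", A_v)


def levels_am(A_m: float) -> DimensionLevels:
    return DimensionLevels.adapted("ambivalence", A_m)


class TestNeed:
    @pytest.mark.parametrize(
        "x, h, expected",
        [
            (0.0, 0.5, 0.0),  # zero drive, zero need
            (1.0, 1.0, 0.5),  # 1/(1+1)
            (1.5, 0.5, 1.5 / (1.5 + 0.5**1.5)),  # 0.809247...
        ],
    )
    def test_closed_form(self, x, h, expected):
        assert core.need(x, h) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("x, h", [(-0.1, 0.5), (1.0, 0.0), (1.0, 1.5), (1.0, -0.2)])
    def test_rejects_bad_domain(self, x, h):
        with pytest.raises(ValueError):
            core.need(x, h)

    def test_monotone_in_drive_and_antimonotone_in_h(self):
        xs = np.linspace(0.0, 10.0, 200)
        for h in (0.1, 0.5, 0.9, 1.0):
            vals = [core.need(x, h) for x in xs]
            assert np.all(np.diff(vals) > 0), f"need not increasing in x at h={h}"
        hs = np.linspace(0.05, 1.0, 50)
        for x in (0.5, 1.0, 2.0, 5.0):
            vals = [core.need(x, h) for h in hs]
            assert np.all(np.diff(vals) <= 1e-15), f"need not non-increasing in h at x={x}"

    @settings(derandomize=True, max_examples=200)
    @given(
        x=st.floats(min_value=0.0, max_value=100.0),
        h=st.floats(min_value=0.05, max_value=1.0),
    )
    def test_range(self, x, h):
        # N in [0,1) mathematically; in floats the bound is attained by
        # rounding once h**x drops below the ULP of x, so strictness is only
        # asserted where the saturation term is representable.
        n = core.need(x, h)
        assert 0.0 <= n <= 1.0
        if h**x > x * 1e-12:
            assert n < 1.0


class TestDrives:
    """Term-by-term oracles of the four coupled drive equations."""

    consts = ModelConstants()

    def test_avoidant_attacher_vanishes_at_full_avoidance(self):
        consts = ModelConstants(c0a_av=0.0)
        lv = levels_av(1.0)
        assert core.drive_avoidant_attacher(K=7, N_G=1.0, S_Ea=42.0, levels=lv, consts=consts) == 0.0

    def test_avoidant_attacher_offset_only(self):
        # K=0 and a fully signaling caregiver leave only the offset.
        lv = levels_av(0.5)
        out = core.drive_avoidant_attacher(K=0, N_G=1.0, S_Ea=80.0, levels=lv, consts=self.consts)
        assert out == pytest.approx(0.49)

    def test_avoidant_attacher_full_substitution(self):
        # (1-0.5)*(0.5*2) + 4*(1-0.75)*(50/100) + 0.49 = 0.5 + 0.5 + 0.49
        lv = levels_av(0.5)
        out = core.drive_avoidant_attacher(K=2, N_G=0.75, S_Ea=50.0, levels=lv, consts=self.consts)
        assert out == pytest.approx(0.5 + 0.5 + 0.49)

    def test_avoidant_caregiver_mirror(self):
        # (1-0.5)*(0.5*2) + 4*(1-0.75)*(50/100) + 0.50
        lv = levels_av(0.5)
        out = core.drive_avoidant_caregiver(K=2, N_R=0.75, S_Ec=50.0, levels=lv, consts=self.consts)
        assert out == pytest.approx(0.5 + 0.5 + 0.50)

    def test_ambivalent_attacher_offset_only(self):
        lv = DimensionLevels(A_m=0.0, U_n=0.0)
        out = core.drive_ambivalent_attacher(K=9, N_G=0.0, D_Pa=70.0, levels=lv, consts=self.consts)
        assert out == pytest.approx(0.2)

    def test_ambivalent_attacher_full_substitution(self):
        # 0.9*(0.5*4) + 2*0.5*(50/100) + 0.2 = 1.8 + 0.5 + 0.2
        lv = levels_am(0.9)
        out = core.drive_ambivalent_attacher(K=4, N_G=0.5, D_Pa=50.0, levels=lv, consts=self.consts)
        assert out == pytest.approx(1.8 + 0.5 + 0.2)

    def test_ambivalent_caregiver_full_substitution(self):
        # (1-0.9)*(0.5*4) + 2*(1-0.5)*(50/100) + 0.5 = 0.2 + 0.5 + 0.5
        lv = levels_am(0.9)
        out = core.drive_ambivalent_caregiver(K=4, N_R=0.5, D_Pc=50.0, levels=lv, consts=self.consts)
        assert out == pytest.approx(0.2 + 0.5 + 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        level=st.floats(min_value=0.0, max_value=1.0),
        K=st.integers(min_value=0, max_value=100),
        other_need=st.floats(min_value=0.0, max_value=1.0),
        percept=st.floats(min_value=0.0, max_value=142.0),
    )
    def test_all_drives_nonnegative(self, level, K, other_need, percept):
        consts = self.consts
        lv_av = levels_av(level)
        lv_am = DimensionLevels(A_m=level, U_n=level)
        for f in (core.drive_avoidant_attacher, core.drive_avoidant_caregiver):
            assert f(K, other_need, percept, lv_av, consts) >= 0.0
        for f in (core.drive_ambivalent_attacher, core.drive_ambivalent_caregiver):
            assert f(K, other_need, percept, lv_am, consts) >= 0.0

    def test_variable_c0_matches_linear_form(self):
        consts = ModelConstants(variable_c0=True)
        for k in range(1, 10):
            A_v = round(0.1 * k, 1)
            c0a, c0c = consts.c0_avoidant(A_v)
            assert c0a == pytest.approx(-0.30 * A_v + 0.60)
            assert c0c == pytest.approx(-0.30 * A_v + 0.59)


class TestThreshold:
    consts = ModelConstants()

    def test_decreasing_at_r0(self):
        rng = ScriptedStream(uniforms=[0.0])
        assert core.update_threshold(True, self.consts, rng) == pytest.approx(0.67)

    def test_increasing_at_r1(self):
        rng = ScriptedStream(uniforms=[1.0])
        assert core.update_threshold(False, self.consts, rng) == pytest.approx(0.91)

    def test_zero_tau_pins_baseline(self):
        consts = ModelConstants(tau=0.0)
        rng = ScriptedStream(uniforms=[0.37, 0.99])
        assert core.update_threshold(True, consts, rng) == 0.75
        assert core.update_threshold(False, consts, rng) == 0.75

    def test_bounds(self):
        rng = np.random.default_rng(0)
        lo, hi = 0.75 - 2 * 0.08, 0.75 + 2 * 0.08
        for _ in range(2000):
            t = core.update_threshold(bool(rng.integers(2)), self.consts, rng)
            assert lo <= t <= hi


class TestBehavioralVariables:
    @pytest.mark.parametrize("N_ex, n, expected", [(0, 10, 0.0), (10, 10, 100.0), (55, 100, 55.0)])
    def test_indifference(self, N_ex, n, expected):
        assert core.indifference(N_ex, n) == expected

    def test_indifference_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            core.indifference(5, 0)
        with pytest.raises(ValueError):
            core.indifference(11, 10)

    @pytest.mark.parametrize(
        "a, c, expected",
        [
            ((9.0, 15.0), (21.0, 15.0), 12.0),  # the dyad's printed starting placement
            ((5.0, 5.0), (5.0, 5.0), 0.0),
            ((0.0, 0.0), (3.0, 4.0), 5.0),
        ],
    )
    def test_distancing(self, a, c, expected):
        assert core.distancing(a, c) == pytest.approx(expected)
        assert core.distancing(c, a) == pytest.approx(expected)


class TestPerceptionUpdates:
    targets_E = TargetSet(T_E=50.0, T_i=55.0)
    targets_P = TargetSet(T_P=90.0, T_d=21.6)

    def test_fixed_point_at_target(self):
        # At-target state is invariant for every noise draw.
        for r in (0.0, 0.25, 1.0):
            rng = ScriptedStream(uniforms=[r])
            out = core.update_emotional_separation(50.0, 55.0, self.targets_E, rng)
            assert out == pytest.approx(50.0)

    def test_zero_noise_freezes_state(self):
        rng = ScriptedStream(uniforms=[0.0, 0.0])
        assert core.update_emotional_separation(37.0, 80.0, self.targets_E, rng) == 37.0
        assert core.update_perceived_distance(37.0, 5.0, self.targets_P, rng) == 37.0

    def test_expectation_identity(self):
        # E[2r] = 1, so the mean update equals the deterministic correction.
        rng = np.random.default_rng(12345)
        prev, i_now = 30.0, 70.0
        n = 200_000
        samples = np.array(
            [core.update_emotional_separation(prev, i_now, self.targets_E, rng) for _ in range(n)]
        )
        closed_form = prev + (i_now - 55.0) - (prev - 50.0)
        assert samples.mean() == pytest.approx(closed_form, abs=0.15)

    def test_emotional_separation_clamped(self):
        rng = ScriptedStream(uniforms=[1.0])
        out = core.update_emotional_separation(95.0, 100.0, TargetSet(T_E=90.0, T_i=99.0), rng)
        assert 0.0 <= out <= 100.0

    def test_perceived_distance_clamped(self):
        rng = ScriptedStream(uniforms=[1.0, 1.0])
        hi = core.update_perceived_distance(140.0, 42.0, TargetSet(T_P=90.0, T_d=2.0), rng)
        assert hi <= core.DP_MAX
        lo = core.update_perceived_distance(1.0, 0.0, TargetSet(T_P=0.0, T_d=40.0), rng)
        assert lo >= 0.0


class TestTargets:
    def test_avoidance_shared_emotional_goal(self):
        lv = levels_av(0.5)
        for role in ("attacher", "caregiver"):
            t = core.compute_targets(lv, role, "avoidance")
            assert t.T_E == 50.0
            assert t.T_i == pytest.approx(55.0)

    def test_ambivalence_opposite_distance_goals(self):
        lv = levels_am(0.9)
        child = core.compute_targets(lv, "attacher", "ambivalence")
        cg = core.compute_targets(lv, "caregiver", "ambivalence")
        assert child.T_P == pytest.approx(10.0)
        assert child.T_d == pytest.approx(2.4)
        assert cg.T_P == pytest.approx(90.0)
        assert cg.T_d == pytest.approx(21.6)

    def test_hill_parameter_is_normalized_goal(self):
        """h tracks the agent's set-goal: steeper need for the hyper-activated side."""
        lv = levels_am(0.9)
        assert core.hill_parameter(lv, "attacher", "ambivalence") == pytest.approx(0.1)
        assert core.hill_parameter(lv, "caregiver", "ambivalence") == pytest.approx(0.9)
        lv2 = levels_av(0.3)
        assert core.hill_parameter(lv2, "attacher", "avoidance") == pytest.approx(0.3)
        assert core.hill_parameter(lv2, "caregiver", "avoidance") == pytest.approx(0.3)
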