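"""Core equations of the Dimensional Attachment Model.

The model couples two agents — an attacher (child) and a caregiver (mother) —
through four scalar state families per dimension:

* **drives** ``a`` (attacher) and ``c`` (caregiver): linear combinations of the
  care clock K, the other agent's signaled need, and the agent's current
  perception (emotional separation S_E for avoidance, perceived distance D_P
  for ambivalence), plus a constant offset;
* **needs** ``N_R`` (need to receive care) and ``N_G`` (need to give care):
  Hill-form saturations of the drives, N(x, h) = x / (x + h^x);
* **thresholds** ``T``: a noisy baseline with hysteresis — lowered while the
  agent's need is falling (prudent re-activation), raised otherwise;
* **perceptions** S_E / D_P: stochastic trackers that pull the psychological
  variable toward its set-goal, driven by the gap between the observable
  behavioral variable (caregiver indifference i, inter-agent distance d) and
  its own target.

Set-goals are linear in the stored dimensional level: both avoidant agents
share T_E = 100*A_v; the ambivalent attacher holds T_P = 100*(1-A_m) while the
unresponsive caregiver holds T_P = 100*U_n, with the behavioral targets
T_i = 1.1*T_E and T_d = 0.24*T_P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .config import Dimension, DimensionLevels, ModelConstants, Role

#: Upper clamp for the perceived distance D_P: the 0-100 perception scale
#: stretched along the lab diagonal.
DP_MAX = 100.0 * math.sqrt(2.0)


@dataclass(frozen=True)
class TargetSet:
    """An agent's set-goals: psychological (T_E or T_P) and behavioral (T_i or T_d)."""

    T_E: Optional[float] = None
    T_i: Optional[float] = None
    T_P: Optional[float] = None
    T_d: Optional[float] = None

    @property
    def psychological(self) -> float:
        """The controlled perception's target (T_E in avoidance, T_P in ambivalence)."""
        val = self.T_E if self.T_E is not None else self.T_P
        assert val is not None
        return val

    @property
    def behavioral(self) -> float:
        """The observable variable's target (T_i in avoidance, T_d in ambivalence)."""
        val = self.T_i if self.T_i is not None else self.T_d
        assert val is not None
        return val


def compute_targets(levels: DimensionLevels, role: Role, dimension: Dimension) -> TargetSet:
    """Set-goals for one agent on one dimension.

    Avoidance: both agents share the emotional-separation goal T_E = 100*A_v
    (= 100*I_n in an adapted dyad).  Ambivalence: the agents hold *opposite*
    distance goals — the attacher T_P = 100*(1-A_m), the caregiver T_P = 100*U_n.
    """
    if dimension == "avoidance":
        level = levels.A_v if role == "attacher" else levels.I_n
        T_E = 100.0 * level
        return TargetSet(T_E=T_E, T_i=1.1 * T_E)
    if role == "attacher":
        T_P = 100.0 * (1.0 - levels.A_m)
    else:
        T_P = 100.0 * levels.U_n
    return TargetSet(T_P=T_P, T_d=0.24 * T_P)


def hill_parameter(levels: DimensionLevels, role: Role, dimension: Dimension) -> float:
    """Hill parameter ``h`` of an agent's need function.

    ``h`` equals the agent's own normalized set-goal (T_E/100 or T_P/100):
    avoidance gives h = A_v (attacher) and h = I_n (caregiver) — the more
    avoidant/insensitive the agent, the shallower the need curve (deactivation);
    ambivalence gives h = 1 - A_m (attacher) and h = U_n (caregiver) — the more
    ambivalent the child, the *steeper* the curve (hyper-activation), while the
    more unresponsive the caregiver, the shallower.
    """
    targets = compute_targets(levels, role, dimension)
    return targets.psychological / 100.0


def need(x: float, h: float) -> float:
    """Hill-form need function N(x, h) = x / (x + h^x).

    Maps a nonnegative drive to an activation level in [0, 1) (the upper bound
    can be attained by rounding once h^x falls below the ULP of x).  Strictly
    increasing in ``x``; for fixed x > 0, increasing ``h`` flattens the curve
    (the agent "feels less" per unit of drive).

    Raises ``ValueError`` for x < 0 or h outside (0, 1] — both signal a
    mis-set dimensional level rather than a recoverable state.
    """
    if x < 0:
        raise ValueError(f"drive must be nonnegative, got {x}")
    if not (0.0 < h <= 1.0):
        raise ValueError(f"Hill parameter must lie in (0, 1], got {h}")
    return x / (x + h**x)


def drive_avoidant_attacher(
    K: float, N_G: float, S_Ea: float, levels: DimensionLevels, consts: ModelConstants
) -> float:
    """Avoidant attachment drive a_av.

    a_av = (1-A_v)*(K/2) + C_f,av*(1-N_G)*(S_Ea/scale) + c0a_av.  Deprivation
    time, the caregiver's *lack* of signaled caregiving, and felt emotional
    separation all push the child to seek care — each damped by avoidance.
    """
    c0a, _ = consts.c0_avoidant(levels.A_v)
    return (
        (1.0 - levels.A_v) * (consts.K_coeff * K)
        + consts.Cf_av * (1.0 - N_G) * (S_Ea / consts.percept_scale)
        + c0a
    )


def drive_avoidant_caregiver(
    K: float, N_R: float, S_Ec: float, levels: DimensionLevels, consts: ModelConstants
) -> float:
    """Insensitive caregiving drive c_av (mirror of the attacher's, with I_n)."""
    _, c0c = consts.c0_avoidant(levels.A_v)
    return (
        (1.0 - levels.I_n) * (consts.K_coeff * K)
        + consts.Cf_av * (1.0 - N_R) * (S_Ec / consts.percept_scale)
        + c0c
    )


def drive_ambivalent_attacher(
    K: float, N_G: float, D_Pa: float, levels: DimensionLevels, consts: ModelConstants
) -> float:
    """Ambivalent attachment drive a_am.

    a_am = A_m*(K/2) + C_f,am*N_G*(D_Pa/scale) + c0a_am.  Here the caregiver's
    signaled need enters with a *positive* sign: an ambivalent child reacts to
    the caregiver's engagement, and perceived distance amplifies the drive.
    """
    return (
        levels.A_m * (consts.K_coeff * K)
        + consts.Cf_am * N_G * (D_Pa / consts.percept_scale)
        + consts.c0a_am
    )


def drive_ambivalent_caregiver(
    K: float, N_R: float, D_Pc: float, levels: DimensionLevels, consts: ModelConstants
) -> float:
    """Unresponsive caregiving drive c_am = (1-U_n)*(K/2) + C_f,am*(1-N_R)*(D_Pc/scale) + c0c_am."""
    return (
        (1.0 - levels.U_n) * (consts.K_coeff * K)
        + consts.Cf_am * (1.0 - N_R) * (D_Pc / consts.percept_scale)
        + consts.c0c_am
    )


def update_threshold(n_decreasing: bool, consts: ModelConstants, rng) -> float:
    """Hysteretic need threshold T = T_bl -/+ tau*(1+r), r ~ U[0,1].

    The minus sign applies while the agent's need is strictly decreasing:
    a deactivating system re-arms readily (lower bar to re-trigger).  The
    result always lies in [T_bl - 2*tau, T_bl + 2*tau].
    """
    r = rng.uniform(0.0, 1.0)
    excursion = consts.tau * (1.0 + r)
    return consts.T_bl - excursion if n_decreasing else consts.T_bl + excursion


def indifference(N_ex: int, n: int) -> float:
    """Caregiver indifference i = 100*N_ex/n: cumulative % of iterations explored."""
    if n < 1:
        raise ValueError(f"iteration index must be >= 1, got {n}")
    if not (0 <= N_ex <= n):
        raise ValueError(f"exploration count {N_ex} outside [0, {n}]")
    return 100.0 * N_ex / n


def distancing(pos_a: tuple, pos_c: tuple) -> float:
    """Euclidean distance d between attacher and caregiver."""
    return math.hypot(pos_a[0] - pos_c[0], pos_a[1] - pos_c[1])


def _percept_update(prev: float, observed: float, t_behavioral: float, t_psych: float, r: float) -> float:
    # CurrentPerception = Previous + 2r * (ObservedDeviation - PreviousDeviation)
    return prev + 2.0 * r * ((observed - t_behavioral) - (prev - t_psych))


def update_emotional_separation(S_E_prev: float, i_now: float, targets: TargetSet, rng) -> float:
    """Stochastic tracker S_E[n] = S_E[n-1] + 2r*[(i - T_i) - (S_E[n-1] - T_E)].

    The noisy step 2r (r ~ U[0,1], mean 1) pulls the felt emotional separation
    toward its set-goal, corrected by how far the caregiver's observed
    indifference sits from its own target.  Clamped to the [0, 100] scale.
    """
    assert targets.T_E is not None and targets.T_i is not None
    r = rng.uniform(0.0, 1.0)
    out = _percept_update(S_E_prev, i_now, targets.T_i, targets.T_E, r)
    return min(max(out, 0.0), 100.0)


def update_perceived_distance(D_P_prev: float, d_now: float, targets: TargetSet, rng) -> float:
    """Mirror tracker for perceived distance, clamped to [0, 100*sqrt(2)]."""
    assert targets.T_P is not None and targets.T_d is not None
    r = rng.uniform(0.0, 1.0)
    out = _percept_update(D_P_prev, d_now, targets.T_d, targets.T_P, r)
    return min(max(out, 0.0), DP_MAX)
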