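"""Time-varying elastance chambers and leaflet valve dynamics.

All four chambers are contractile: E(t) = E_min + E_amp * e(t) with a
normalized activation e in [0, 1] per beat.  Atrial activation opens the
beat (the atrial kick), ventricular activation follows after an AV delay.
Valve leaflets obey an angular momentum balance with four torque terms:
the transvalvular pressure difference, friction from neighbouring tissue,
the dynamic motion of the blood on the leaflet, and the vortex downstream
of the valve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .network import HeartChamber, ValveState

DEFAULT_TIMING = {"atrial_frac": 0.20, "av_delay_frac": 0.15,
                  "vent_frac": 0.40}


def _bump(s: float) -> float:
    """Smooth normalized activation on s in [0, 1]; 0 outside."""
    if 0.0 <= s <= 1.0:
        return 0.5 * (1.0 - math.cos(2.0 * math.pi * s))
    return 0.0


def activation(chamber_id: str, phase: float, timing: dict | None = None
               ) -> float:
    """Normalized activation e(t/RR) in [0, 1] for a chamber.

    ``phase`` is the fraction of the current beat in [0, 1).  Atria are
    active over the first ``atrial_frac`` of the beat; ventricles over
    ``vent_frac`` starting after ``av_delay_frac`` (so the atrial peak
    precedes the ventricular peak: the atrial kick tops up the ventricle
    at end diastole).
    """
    t = dict(DEFAULT_TIMING, **(timing or {}))
    phase = phase % 1.0
    if chamber_id in ("LA", "RA"):
        return _bump(phase / t["atrial_frac"])
    return _bump((phase - t["av_delay_frac"]) / t["vent_frac"])


def elastance(chamber: HeartChamber, t: float, rr: float = 0.8,
              timing: dict | None = None, e_amp_mult: float = 1.0) -> float:
    """E(t) = E_min + E_amp * e(t/RR) [mmHg/ml]; periodic with RR."""
    e = activation(chamber.id, (t / rr) % 1.0, timing)
    return chamber.e_min + chamber.e_amp * e_amp_mult * e


def chamber_pressure(chamber: HeartChamber, v: float, t: float,
                     rr: float = 0.8, timing: dict | None = None,
                     e_amp_mult: float = 1.0) -> float:
    """P = E(t) (V - V0) [mmHg]: increases with V at fixed t and with E at
    fixed V; equals zero transmural pressure at V = V0."""
    return elastance(chamber, t, rr, timing, e_amp_mult) * (v - chamber.v0)


def valve_update(valve: ValveState, dp: float, local_flow: float,
                 dt: float) -> ValveState:
    """Advance the leaflet angle one step.

    d(omega)/dt sums the four torques:
      + k_p * dP * cos(theta)      pressure difference across the valve
      - k_f * omega                friction from neighbouring tissue
      + k_b * Q  * cos(theta)      dynamic motion of the blood on the leaflet
      - k_v * Q  * sin(2 theta)    vortex downstream of the valve
    The angle is clamped to [0, theta_max]; opening maps it to [0, 1].
    """
    th = valve.theta
    domega = (valve.k_p * dp * math.cos(th)
              - valve.k_f * valve.omega
              + valve.k_b * local_flow * math.cos(th)
              - valve.k_v * local_flow * math.sin(2.0 * th))
    omega = valve.omega + dt * domega
    th = th + dt * omega
    if th <= 0.0:
        th, omega = 0.0, 0.0
    elif th >= valve.theta_max:
        th, omega = valve.theta_max, 0.0
    valve.theta = th
    valve.omega = omega
    if valve.opening == 0.0:
        valve.flow = 0.0
    return valve


def valve_flow(valve: ValveState, dp: float) -> float:
    """Flow [ml/s] through the (partially) open valve.

    Orifice law with a small linear series resistance for numerical
    robustness near flow reversal: dP = r_lin Q + Q|Q|/(CQ opening)^2.
    Exactly zero when the valve is closed.
    """
    o = valve.opening
    if o <= 0.0:
        return 0.0
    b = 1.0 / (valve.cq * o) ** 2
    r = valve.r_lin
    q = (-r + math.sqrt(r * r + 4.0 * b * abs(dp))) / (2.0 * b)
    return math.copysign(q, dp)


@dataclass
class HeartModel:
    """Runtime wrapper binding chambers, valves and beat timing."""

    chambers: dict[str, HeartChamber]
    valves: dict[str, ValveState]
    rr: float = 0.8
    timing: dict = field(default_factory=lambda: dict(DEFAULT_TIMING))
    e_amp_mult: dict = field(default_factory=lambda: {"LV": 1.0, "RV": 1.0})

    def elastance_at(self, chamber_id: str, phase: float) -> float:
        ch = self.chambers[chamber_id]
        mult = self.e_amp_mult.get(chamber_id, 1.0)
        e = activation(chamber_id, phase, self.timing)
        return ch.e_min + ch.e_amp * mult * e

    def pressure(self, chamber_id: str, phase: float) -> float:
        ch = self.chambers[chamber_id]
        return self.elastance_at(chamber_id, phase) * (ch.v - ch.v0)
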