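"""Short-term baroregulation.

The afferent branch low-pass filters a weighted aortic--carotid sinus
pressure; the efferent branch drives five effector families through
sigmoidal static curves centred at the setpoint with first-order lags:
heart rate, ventricular elastance amplitudes, peripheral arterial
resistances, venous unstressed volumes, and venous compliances.  All
multipliers equal 1 at setpoint equilibrium, and the signs implement
negative feedback (sensed pressure below setpoint raises HR and
resistance, lowers venous unstressed volume, raises venous compliance).
"""

from __future__ import annotations

import math

from .network import BaroreflexBlock


class BaroreflexConfigError(ValueError):
    """Raised on an invalid reconfiguration (e.g. double 0G application)."""


def afferent_pressure(aortic_p: float, carotid_p: float,
                      filter_state: float | None, dt: float,
                      block: BaroreflexBlock) -> float:
    """Update the low-pass filtered aortic--carotid sinus pressure [mmHg].

    A first-order filter: constant input converges to that constant, and a
    step input is approached monotonically.
    """
    w = block.aortic_weight
    x = w * aortic_p + (1.0 - w) * carotid_p
    if filter_state is None:
        return x
    return filter_state + dt / block.afferent_tau * (x - filter_state)


def effector_targets(block: BaroreflexBlock, afferent: float) -> dict:
    """Static sigmoid targets for the five effector multipliers."""
    dev = (afferent - block.setpoint) / (block.setpoint * block.sigmoid_width)
    s = math.tanh(dev)
    g = block.gains
    return {
        "hr": 1.0 - g["hr"] * s,
        "e_amp": 1.0 - g["e_amp"] * s,
        "r_art": 1.0 - g["r_art"] * s,
        "v0_ven": 1.0 + g["v0_ven"] * s,
        "c_ven": 1.0 + g["c_ven"] * s,
    }


def baroreflex_effectors(afferent: float, block: BaroreflexBlock,
                         dt: float) -> dict:
    """Advance the first-order effector lags one step; returns the
    multipliers (also stored on the block)."""
    targets = effector_targets(block, afferent)
    for key, target in targets.items():
        tau = block.taus[key]
        m = block.multipliers[key]
        block.multipliers[key] = m + dt / tau * (target - m)
    return dict(block.multipliers)


def set_0g_baselines(block: BaroreflexBlock) -> BaroreflexBlock:
    """Long-term weightlessness acts on the baroreflex only through its
    baselines: HR baseline +13%, aortic--carotid setpoint -10%.  Gains and
    time constants are unchanged.  Refuses double application."""
    if block.gravity_tag == "0g":
        raise BaroreflexConfigError(
            "baroreflex block already configured for 0G")
    block.hr_baseline *= 1.13
    block.setpoint *= 0.90
    block.gravity_tag = "0g"
    return block
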