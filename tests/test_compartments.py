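import math

import numpy as np
import pytest

from cardioloop import (InterfaceError, advance_compartments,
                        aortic_root_interface, arteriolar_interface_step,
                        load_network)
from cardioloop.compartments import CompartmentSystem
from cardioloop.network import ArteriolarInterface, ValveState
from cardioloop.units import BLOOD_DENSITY, MMHG_TO_CGS


def rc_doc(units, r=5.0, c=2.0, p0=10.0):
    return {
        "units": units,
        "compartments": [
            {"id": "rc", "class": "vein", "r": r, "c": c, "v0": 50.0,
             "v": 50.0 + c * p0, "downstream": "sink"},
            {"id": "sink", "class": "vein", "r": 0.0, "c": 1000.0,
             "v0": 0.0, "v": 0.001, "fixed_pressure": True,
             "downstream": None},
        ],
    }


class TestRLCDynamics:
    def test_rc_discharge_matches_exponential(self, units):
        r, c, p0 = 5.0, 2.0, 10.0
        net = load_network(rc_doc(units, r, c, p0))
        dt = 1e-4
        t_end = 2.0
        for _ in range(int(t_end / dt)):
            advance_compartments(net, dt)
        p = net.compartments["rc"].p
        expected = p0 * math.exp(-t_end / (r * c))
        assert p == pytest.approx(expected, rel=1e-3)

    def test_resistive_limit_instantaneous(self, units):
        net = load_network(rc_doc(units))
        sys = CompartmentSystem(net)
        p = sys.pressures()
        q = sys.outflows(p, {}, dt=1e-3)
        assert q[0] == pytest.approx((p[0] - p[1]) / 5.0)

    def test_inertial_link_first_order_rise(self, units):
        doc = rc_doc(units)
        doc["compartments"][0]["l"] = 0.01
        net = load_network(doc)
        sys = CompartmentSystem(net)
        p = sys.pressures()
        q1 = sys.outflows(p, {}, dt=1e-4).copy()
        # with inertance the flow cannot jump to the resistive value
        assert 0 < q1[0] < (p[0] - p[1]) / 5.0

    def test_closed_ring_conserves_volume(self, units):
        doc = {
            "units": units,
            "compartments": [
                {"id": "a", "class": "vein", "r": 1.0, "c": 1.0,
                 "v0": 10.0, "v": 16.0, "downstream": "b"},
                {"id": "b", "class": "vein", "r": 2.0, "c": 3.0,
                 "v0": 10.0, "v": 11.0, "downstream": "a"},
            ],
        }
        net = load_network(doc)
        sys = CompartmentSystem(net)
        total0 = sys.total_volume()
        dt = 1e-3
        for _ in range(10_000):
            sys.step(dt, np.zeros(2), {})
            assert abs(sys.total_volume() - total0) < 1e-9 * total0

    def test_external_inflow_bookkeeping_exact(self, units):
        net = load_network(rc_doc(units))
        net.compartments["sink"].fixed_pressure = False
        net.compartments["sink"].downstream = "rc"
        sys = CompartmentSystem(net)
        sys.fixed = np.zeros(2, dtype=bool)
        total0 = sys.total_volume()
        dt = 1e-3
        for _ in range(1000):
            sys.step(dt, np.array([2.0, 0.0]), {})
        assert sys.total_volume() - total0 == pytest.approx(2.0, rel=1e-12)


def terminal_state(a0=0.2, c0=700.0, u=0.0):
    beta = 2.0 * BLOOD_DENSITY * c0 ** 2 * math.sqrt(a0) / MMHG_TO_CGS
    cc = MMHG_TO_CGS * beta / (2.0 * BLOOD_DENSITY * a0)
    c = c0 + u / 4.0
    a = (c * c / cc) ** 2
    return {"A": a, "W1": u + 4.0 * c, "cc": cc, "beta": beta, "a0": a0,
            "pe": 0.0, "c0": c0}


def arteriole_with_pressure(units, p):
    net = load_network({
        "units": units,
        "compartments": [
            {"id": "art", "class": "arteriole", "r": 10.0, "c": 0.05,
             "v0": 5.0, "v": 5.0 + 0.05 * p, "downstream": "sink"},
            {"id": "sink", "class": "vein", "r": 0.0, "c": 100.0,
             "v0": 0.0, "v": 500.0, "fixed_pressure": True,
             "downstream": None},
        ],
    })
    return net.compartments["art"]


class TestArteriolarInterface:
    def test_matched_termination_no_reflection(self, units):
        u_inc = 1.0
        st = terminal_state(u=u_inc)
        zc = BLOOD_DENSITY * st["c0"] / (st["a0"] * MMHG_TO_CGS)
        # arteriole pressure consistent with full transmission
        c = st["c0"] + u_inc / 4.0
        a_inc = (c * c / st["cc"]) ** 2
        p_inc = st["beta"] / st["a0"] * (math.sqrt(a_inc)
                                         - math.sqrt(st["a0"]))
        p_art = p_inc - zc * a_inc * u_inc
        itf = ArteriolarInterface("t", "art", zc)
        out = arteriolar_interface_step(st, itf,
                                        arteriole_with_pressure(units, p_art),
                                        dt=1e-4)
        u_b = out["Q"] / out["A"]
        c_b = math.sqrt(st["cc"] * math.sqrt(out["A"]))
        w2_refl = u_b - 4.0 * c_b + 4.0 * st["c0"]
        assert abs(w2_refl) < 1e-3 * u_inc

    def test_infinite_impedance_closes_the_end(self, units):
        st = terminal_state(u=2.0)
        itf = ArteriolarInterface("t", "art", 1e9)
        out = arteriolar_interface_step(st, itf,
                                        arteriole_with_pressure(units, 50.0),
                                        dt=1e-4)
        assert abs(out["Q"]) < 1e-6

    def test_series_element_law(self, units):
        st = terminal_state(u=1.5)
        zc = 3.0
        p_art = 40.0
        itf = ArteriolarInterface("t", "art", zc)
        out = arteriolar_interface_step(st, itf,
                                        arteriole_with_pressure(units, p_art),
                                        dt=1e-4)
        assert out["P"] - zc * out["Q"] == pytest.approx(p_art, abs=1e-8)

    def test_unresolved_zc_rejected(self, units):
        st = terminal_state()
        itf = ArteriolarInterface("t", "art", "auto")
        with pytest.raises(ValueError):
            arteriolar_interface_step(st, itf,
                                      arteriole_with_pressure(units, 40.0),
                                      dt=1e-4)


def inlet_state(a0=6.5, c0=460.0, u=0.0):
    beta = 2.0 * BLOOD_DENSITY * c0 ** 2 * math.sqrt(a0) / MMHG_TO_CGS
    cc = MMHG_TO_CGS * beta / (2.0 * BLOOD_DENSITY * a0)
    c = c0 - u / 4.0   # backward invariant at rest
    a = a0
    return {"A": a, "W2": u - 4.0 * c0, "cc": cc, "beta": beta, "a0": a0,
            "pe": 0.0}


class TestAorticRoot:
    def test_closed_valve_zero_inflow(self):
        av = ValveState(id="AV", cq=350.0, theta=0.0)
        out = aortic_root_interface(120.0, av, inlet_state())
        assert out["Q"] == 0.0

    def test_open_valve_forward_flow(self):
        av = ValveState(id="AV", cq=350.0, theta=1.309)
        assert av.opening == pytest.approx(1.0)
        out = aortic_root_interface(150.0, av, inlet_state())
        assert out["Q"] > 0

    def test_backflow_when_ventricle_below_aorta(self):
        av = ValveState(id="AV", cq=350.0, theta=0.6)
        st = inlet_state()
        # aortic side at rest pressure 0, LV below it
        out = aortic_root_interface(-30.0, av, st)
        assert out["Q"] < 0
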