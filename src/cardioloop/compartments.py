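"""Lumped (0D) RLC compartments and both 1D <-> 0D interfaces.

Every compartment obeys V = V0 + C P identically; its outflow toward the
downstream element passes through a resistance R (and inertance L where
L > 0).  The 1D -> 0D interface sits at the arteriolar level: a
characteristic impedance Z_c in series before each arteriole honours the
incident characteristic of the feeding terminal artery.  The 0D -> 1D
interface is at the aortic valve: the ascending-aorta inlet flow equals the
valve flow, and a closed valve reflects the incoming characteristic.
"""

from __future__ import annotations

import math

import numpy as np

from .network import CardiovascularNetwork, Compartment0D


class InterfaceError(RuntimeError):
    """Newton iteration on a 1D/0D interface failed to converge."""


class CompartmentStepError(RuntimeError):
    """A compartment update produced an invalid state."""


# ---------------------------------------------------------------------------
# Vectorized compartment system (used by the driver and the public op)


class CompartmentSystem:
    """All 0D compartments of a network packed into flat arrays.

    The update is explicit and staggered with the 1D scheme: outflows are
    computed from the current pressures, then volumes are advanced with the
    same fluxes on both sides of every link, which keeps the volume
    bookkeeping exact.
    """

    def __init__(self, net: CardiovascularNetwork):
        comps = list(net.compartments.values())
        self.net = net
        self.comps = comps
        self.ids = [c.id for c in comps]
        self.index = {c.id: k for k, c in enumerate(comps)}
        n = len(comps)
        self.V = np.array([c.v for c in comps])
        self.V0 = np.array([c.v0 for c in comps])
        self.C = np.array([c.c for c in comps])
        self.R = np.array([c.r for c in comps])
        self.L = np.array([c.l for c in comps])
        self.Q = np.array([c.q_out for c in comps])
        self.fixed = np.array([c.fixed_pressure for c in comps])
        self.rectify = np.array([c.rectify for c in comps])
        self.has_l = self.L > 0
        self.down = np.full(n, -1, dtype=np.intp)
        self.down_chamber = np.full(n, "", dtype=object)
        for k, c in enumerate(comps):
            if c.downstream in self.index:
                self.down[k] = self.index[c.downstream]
            elif c.downstream in net.chambers:
                self.down_chamber[k] = c.downstream
        self.to_comp = self.down >= 0
        self.to_ra = self.down_chamber == "RA"
        self.to_la = self.down_chamber == "LA"
        self.P_fixed = (self.V - self.V0) / self.C
        # runtime-adjustable multipliers (baroreflex effectors)
        self.r_mult = np.ones(n)
        self.v0_mult = np.ones(n)
        self.c_mult = np.ones(n)

    def pressures(self) -> np.ndarray:
        p = (self.V - self.V0 * self.v0_mult) / (self.C * self.c_mult)
        if self.fixed.any():
            p[self.fixed] = self.P_fixed[self.fixed]
        return p

    def outflows(self, p: np.ndarray, chamber_p: dict[str, float],
                 dt: float) -> np.ndarray:
        p_down = np.zeros_like(p)
        p_down[self.to_comp] = p[self.down[self.to_comp]]
        if self.to_ra.any():
            p_down[self.to_ra] = chamber_p.get("RA", 0.0)
        if self.to_la.any():
            p_down[self.to_la] = chamber_p.get("LA", 0.0)
        dp = p - p_down
        r_eff = self.R * self.r_mult
        q = np.where(r_eff > 0, dp / np.where(r_eff > 0, r_eff, 1.0), self.Q)
        if self.has_l.any():
            # semi-implicit in R to tolerate stiff inertial links
            i = self.has_l
            q[i] = ((self.Q[i] + dt * dp[i] / self.L[i])
                    / (1.0 + dt * r_eff[i] / self.L[i]))
        if self.rectify.any():
            q[self.rectify] = np.maximum(q[self.rectify], 0.0)
        return q

    def step(self, dt: float, inflow_ext: np.ndarray,
             chamber_p: dict[str, float]) -> dict[str, float]:
        """Advance one step; returns the flows delivered to RA and LA."""
        p = self.pressures()
        q = self.outflows(p, chamber_p, dt)
        routed = np.bincount(self.down[self.to_comp],
                             weights=q[self.to_comp],
                             minlength=self.V.size)
        dv = dt * (inflow_ext + routed - q)
        self.V += np.where(self.fixed, 0.0, dv)
        self.Q = q
        if not np.all(np.isfinite(self.V)):
            k = int(np.argmin(np.isfinite(self.V)))
            raise CompartmentStepError(
                f"non-finite volume in compartment '{self.ids[k]}'")
        return {"RA": float(q[self.to_ra].sum()),
                "LA": float(q[self.to_la].sum())}

    def sync_to_network(self) -> None:
        p = self.pressures()
        for k, c in enumerate(self.comps):
            c.v = float(self.V[k])
            c.v0 = float(self.V0[k] * self.v0_mult[k])
            c.c = float(self.C[k] * self.c_mult[k])
            c.r = float(self.R[k] * self.r_mult[k])
            c.q_out = float(self.Q[k])
            # keep V = V0 + C P identically
            if c.fixed_pressure:
                c.v = c.v0 + c.c * float(p[k])

    def total_volume(self) -> float:
        return float(self.V.sum())


def advance_compartments(net: CardiovascularNetwork, dt: float,
                         inflows: dict[str, float] | None = None,
                         chamber_p: dict[str, float] | None = None
                         ) -> CardiovascularNetwork:
    """Advance all lumped compartments of ``net`` one explicit step.

    ``inflows`` maps compartment ids to external inflow [ml/s] (terminal
    arteries, valves); ``chamber_p`` supplies RA/LA pressures for venous
    return links.  Volume bookkeeping is exact: the sum of compartment
    volume changes equals the net external flux times dt.
    """
    sys = CompartmentSystem(net)
    ext = np.zeros(len(sys.ids))
    for cid, q in (inflows or {}).items():
        ext[sys.index[cid]] += q
    sys.step(dt, ext, chamber_p or {})
    sys.sync_to_network()
    return net


# ---------------------------------------------------------------------------
# 1D -> 0D arteriolar interface


def solve_terminal_interfaces(A_guess, W1, cc, beta, a0, pe, zc, p_arteriole,
                              tol: float = 1e-11, max_iter: int = 60):
    """Couple terminal-artery outlets to their arterioles through Z_c.

    Vectorized Newton solve over all terminals for the boundary area A with
    u = W1 - 4 c(A) (the outgoing characteristic is honoured) and the
    series-impedance law  P(A) - Z_c * A u = P_arteriole.

    Returns (A, Q, P) at the boundary.
    """
    A = np.array(A_guess, dtype=float)
    scale = 1.0 + np.asarray(zc, dtype=float)   # residual is in mmHg but
    for _ in range(max_iter):                   # grows linearly with Z_c
        c = np.sqrt(cc * np.sqrt(A))
        u = W1 - 4.0 * c
        P = pe + beta / a0 * (np.sqrt(A) - np.sqrt(a0))
        g = P - zc * A * u - p_arteriole
        if np.max(np.abs(g) / scale) < tol:
            break
        dPdA = beta / (2.0 * a0 * np.sqrt(A))
        dg = dPdA - zc * (u - c)
        A = A - g / dg
        if np.any(A <= 0):
            raise InterfaceError("arteriolar interface produced A <= 0")
    else:
        raise InterfaceError(
            f"arteriolar interface Newton did not converge "
            f"(max residual {np.max(np.abs(g)):g} mmHg)")
    c = np.sqrt(cc * np.sqrt(A))
    u = W1 - 4.0 * c
    P = pe + beta / a0 * (np.sqrt(A) - np.sqrt(a0))
    return A, A * u, P


def arteriolar_interface_step(terminal_state: dict, interface,
                              arteriole: Compartment0D, dt: float) -> dict:
    """One coupled boundary evaluation for a single terminal artery.

    ``terminal_state`` needs ``A`` (guess), ``W1`` (outgoing invariant
    u + 4c), ``cc``, ``beta``, ``a0`` and optionally ``pe``.  Returns the
    boundary ``A``, ``Q`` and ``P``; mass continuity across the interface
    is exact because the same Q feeds the arteriole.
    """
    zc = interface.zc
    if zc == "auto":
        raise ValueError("interface Z_c must be resolved before stepping")
    A, Q, P = solve_terminal_interfaces(
        np.atleast_1d(float(terminal_state["A"])),
        np.atleast_1d(float(terminal_state["W1"])),
        np.atleast_1d(float(terminal_state["cc"])),
        np.atleast_1d(float(terminal_state["beta"])),
        np.atleast_1d(float(terminal_state["a0"])),
        np.atleast_1d(float(terminal_state.get("pe", 0.0))),
        np.atleast_1d(float(zc)),
        np.atleast_1d(arteriole.p),
    )
    return {"A": float(A[0]), "Q": float(Q[0]), "P": float(P[0])}


# ---------------------------------------------------------------------------
# 0D -> 1D aortic root interface


def aortic_root_interface(lv_pressure: float, aortic_valve, inlet_state: dict,
                          tol: float = 1e-8, max_iter: int = 120) -> dict:
    """Inlet boundary data for the ascending aorta.

    ``inlet_state`` needs ``A`` (guess), ``W2`` (outgoing invariant u - 4c
    extrapolated at the inlet), ``cc``, ``beta``, ``a0``, ``pe``.  The
    valve is an orifice whose effective coefficient scales with the leaflet
    opening; a closed valve gives zero inlet flow and pure reflection of
    the incoming characteristic (u = 0).

    Returns ``{"A", "Q", "P"}`` at the inlet.
    """
    cc = float(inlet_state["cc"])
    beta = float(inlet_state["beta"])
    a0 = float(inlet_state["a0"])
    pe = float(inlet_state.get("pe", 0.0))
    w2 = float(inlet_state["W2"])
    opening = aortic_valve.opening if hasattr(aortic_valve, "opening") \
        else float(aortic_valve)

    def pressure(A):
        return pe + beta / a0 * (math.sqrt(A) - math.sqrt(a0))

    if opening < 1e-5:
        c = max(-w2 / 4.0, 1e-12)
        A = (c * c / cc) ** 2
        return {"A": A, "Q": 0.0, "P": pressure(A)}

    cq_eff = aortic_valve.cq * opening
    b = 1.0 / (cq_eff * cq_eff)      # mmHg / (ml/s)^2
    r_lin = getattr(aortic_valve, "r_lin", 0.0)
    A = float(inlet_state["A"])
    for _ in range(max_iter):
        c = math.sqrt(cc * math.sqrt(A))
        u = w2 + 4.0 * c
        q = A * u
        g = lv_pressure - pressure(A) - b * q * abs(q) - r_lin * q
        if abs(g) < tol:
            break
        dPdA = beta / (2.0 * a0 * math.sqrt(A))
        dg = -dPdA - (2.0 * b * abs(q) + r_lin) * (u + c)
        step = g / dg
        # damped Newton keeps the iterate in the physical branch
        A_next = A - step
        if A_next <= 0:
            A_next = 0.5 * A
        A = A_next
    else:
        raise InterfaceError(
            f"aortic root interface did not converge (residual {g:g} mmHg)")
    c = math.sqrt(cc * math.sqrt(A))
    u = w2 + 4.0 * c
    return {"A": A, "Q": A * u, "P": pressure(A)}
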