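"""1D pulse-wave solver for the arterial tree.

Mass and momentum balance in one dimension with a Poiseuille-type
dissipation term and blood inertia, closed by a nonlinear elastic tube law
with an optional Kelvin--Voigt viscoelastic wall stress:

    P(A, x, t) = P_ext + beta(x)/A0(x) * (sqrt(A) - sqrt(A0))
                 + Gamma(x)/(A0(x) sqrt(A)) * dA/dt

The hyperbolic core is advanced with the explicit two-step MacCormack
scheme on a uniform per-segment grid.  The mass update is written in flux
form with half-cell finite-volume updates at the two boundary nodes, so the
discrete lumen volume of every segment changes by exactly ``dt * (Q_in -
Q_out)`` per step: the closed loop then conserves blood volume to round-off
once the 0D side integrates the same interface fluxes.

Bifurcations are closed by mass conservation plus continuity of total
pressure, solved by Newton iteration on the boundary areas while preserving
the outgoing characteristic of every adjoining segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Artery1DSegment
from .units import BLOOD_DENSITY, BLOOD_VISCOSITY, MMHG_TO_CGS


class CollapseError(RuntimeError):
    """A vessel area reached zero (simulation aborts; signals a bad setup)."""


class StabilityError(RuntimeError):
    """The time step violates the CFL condition of the explicit scheme."""


class JunctionSolveError(RuntimeError):
    """Newton iteration on a junction failed to converge."""


# ---------------------------------------------------------------------------
# Tube law


@dataclass
class WallLaw:
    """Wall model of one segment sampled on its axial grid."""

    a0: np.ndarray          # cm^2, unstressed area profile
    beta: np.ndarray        # mmHg cm, elastic coefficient
    gamma: np.ndarray | float = 0.0   # mmHg s cm, viscoelastic coefficient
    external_pressure: float = 0.0    # mmHg
    density: float = BLOOD_DENSITY    # g/ml


def tube_law_pressure(A, dA_dt, wall: WallLaw):
    """Transmural + external pressure [mmHg] for area A and rate dA/dt.

    The elastic part vanishes at A = A0; the viscous part vanishes when
    dA/dt = 0.  Raises :class:`CollapseError` for non-positive areas.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0.0):
        raise CollapseError("tube law evaluated at non-positive area")
    elastic = wall.beta / wall.a0 * (np.sqrt(A) - np.sqrt(wall.a0))
    viscous = np.asarray(wall.gamma) / (wall.a0 * np.sqrt(A)) * np.asarray(dA_dt)
    return wall.external_pressure + elastic + viscous


def wave_speed(A, wall: WallLaw):
    """Local wave speed c = sqrt(A/rho * dP/dA) [cm/s] of the elastic law."""
    A = np.asarray(A, dtype=float)
    cc = MMHG_TO_CGS * wall.beta / (2.0 * wall.density * wall.a0)
    return np.sqrt(cc * np.sqrt(A))


# ---------------------------------------------------------------------------
# Packed multi-segment state


class Packed1D:
    """All 1D segments concatenated into flat node arrays.

    Attributes
    ----------
    A, Q, P : node arrays (P includes the viscoelastic stress, lagged one
        step; characteristics always use the elastic part only).
    starts, ends : first/last node index of each segment, in input order.
    """

    def __init__(self, segments: list[Artery1DSegment],
                 density: float = BLOOD_DENSITY,
                 viscosity: float = BLOOD_VISCOSITY,
                 dx_target: float = 0.25):
        self.segments = segments
        self.ids = [s.id for s in segments]
        self.index = {s.id: k for k, s in enumerate(segments)}
        self.density = density
        self.viscosity = viscosity
        starts, ends, dx_seg = [], [], []
        xs, a0s, betas, gammas, zetas, pes = [], [], [], [], [], []
        pos = 0
        for seg in segments:
            if seg.x is None:
                seg.build_grid(dx_target)
            n = seg.x.size
            starts.append(pos)
            ends.append(pos + n - 1)
            dx_seg.append(seg.x[1] - seg.x[0])
            xs.append(seg.x)
            a0s.append(seg.a0_profile(seg.x))
            betas.append(seg.beta_profile(seg.x, density))
            gammas.append(np.full(n, seg.wall_visc))
            zetas.append(np.full(n, seg.friction_zeta))
            pes.append(np.full(n, seg.external_pressure))
            pos += n
        self.n_nodes = pos
        self.starts = np.asarray(starts, dtype=np.intp)
        self.ends = np.asarray(ends, dtype=np.intp)
        self.dx_seg = np.asarray(dx_seg)
        self.a0 = np.concatenate(a0s)
        self.beta = np.concatenate(betas)
        self.gamma = np.concatenate(gammas)
        self.zeta = np.concatenate(zetas)
        self.pe = np.concatenate(pes)
        # per-node helpers
        self.dxn = np.empty(self.n_nodes)
        for k in range(len(segments)):
            self.dxn[self.starts[k]:self.ends[k] + 1] = self.dx_seg[k]
        self.cc = MMHG_TO_CGS * self.beta / (2.0 * density * self.a0)
        self.kr = MMHG_TO_CGS / density
        self._sqrt_a0 = np.sqrt(self.a0)
        self._beta_a0 = self.beta / self.a0
        self._gamma_a0 = self.gamma / self.a0
        self.A = np.concatenate([s.A.astype(float) for s in segments])
        self.Q = np.concatenate([s.Q.astype(float) for s in segments])
        self.P = self.elastic_pressure(self.A)
        self._fric = 2.0 * (self.zeta + 2.0) * np.pi * viscosity / density
        self._has_visc = bool(np.any(self.gamma > 0))
        self._dAdt = np.zeros(self.n_nodes)

    # -- local laws ---------------------------------------------------------

    def elastic_pressure(self, A):
        return self.pe + self._beta_a0 * (np.sqrt(A) - self._sqrt_a0)

    def full_pressure(self, A, dA_dt):
        sqA = np.sqrt(A)
        return (self.pe + self._beta_a0 * (sqA - self._sqrt_a0)
                + self._gamma_a0 / sqA * dA_dt)

    def speed(self, A):
        return np.sqrt(self.cc * np.sqrt(A))

    def speed_at(self, idx, A):
        return np.sqrt(self.cc[idx] * np.sqrt(A))

    # -- bookkeeping ----------------------------------------------------------

    def segment_slice(self, sid: str) -> slice:
        k = self.index[sid]
        return slice(self.starts[k], self.ends[k] + 1)

    def volumes(self) -> np.ndarray:
        """Trapezoidal lumen volume per segment [ml]."""
        out = np.empty(len(self.ids))
        for k in range(len(self.ids)):
            sl = slice(self.starts[k], self.ends[k] + 1)
            a = self.A[sl]
            out[k] = self.dx_seg[k] * (a.sum() - 0.5 * (a[0] + a[-1]))
        return out

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def sync_to_segments(self) -> None:
        for k, seg in enumerate(self.segments):
            sl = slice(self.starts[k], self.ends[k] + 1)
            seg.A = self.A[sl].copy()
            seg.Q = self.Q[sl].copy()
            seg.P = self.P[sl].copy()

    # -- characteristics ------------------------------------------------------

    def boundary_invariants(self, dt: float):
        """Outgoing Riemann invariants at each segment's two ends.

        Returns ``(W1_out, W2_in)``: W1 = u + 4c extrapolated at the distal
        end, W2 = u - 4c at the proximal end, both interpolated at the foot
        of the outgoing characteristic.
        """
        A, Q = self.A, self.Q
        ie, ie1 = self.ends, self.ends - 1
        u_e, u_e1 = Q[ie] / A[ie], Q[ie1] / A[ie1]
        c_e, c_e1 = self.speed_at(ie, A[ie]), self.speed_at(ie1, A[ie1])
        frac = np.clip((u_e + c_e) * dt / self.dx_seg, 0.0, 1.0)
        w1_e = u_e + 4.0 * c_e
        w1 = w1_e - frac * (w1_e - (u_e1 + 4.0 * c_e1))

        i_s, i_s1 = self.starts, self.starts + 1
        u_s, u_s1 = Q[i_s] / A[i_s], Q[i_s1] / A[i_s1]
        c_s, c_s1 = self.speed_at(i_s, A[i_s]), self.speed_at(i_s1, A[i_s1])
        frac2 = np.clip(-(u_s - c_s) * dt / self.dx_seg, 0.0, 1.0)
        w2_s = u_s - 4.0 * c_s
        w2 = w2_s + frac2 * ((u_s1 - 4.0 * c_s1) - w2_s)
        return w1, w2

    # -- time stepping --------------------------------------------------------

    def min_dx_over_speed(self) -> float:
        c = self.speed(self.A)
        u = np.abs(self.Q) / self.A
        return float(np.min(self.dxn / (u + c)))

    def advance(self, dt: float, q_in: np.ndarray, q_out: np.ndarray,
                check_cfl: bool = True) -> None:
        """One MacCormack step for every segment, with boundary fluxes
        ``q_in``/``q_out`` (ml/s, one per segment) applied conservatively.
        """
        if check_cfl and dt > self.min_dx_over_speed():
            raise StabilityError(
                f"dt={dt:g} s violates the CFL condition "
                f"(limit {self.min_dx_over_speed():g} s)")
        A, Q, P = self.A, self.Q, self.P
        dxn = self.dxn
        ends, starts = self.ends, self.starts
        r = dt / dxn
        kr = self.kr

        F2 = Q * Q / A
        fric = self._fric / A * Q

        # predictor (forward differences; garbage at segment-last nodes is
        # overwritten below and never used)
        dQ = np.empty_like(Q)
        dQ[:-1] = Q[1:] - Q[:-1]
        dF = np.empty_like(Q)
        dF[:-1] = F2[1:] - F2[:-1]
        dP = np.empty_like(Q)
        dP[:-1] = P[1:] - P[:-1]
        for arr in (dQ, dF, dP):
            arr[-1] = 0.0
            arr[ends] = 0.0
        As = A - r * dQ
        Qs = Q - r * dF - r * kr * A * dP - dt * fric
        bad = As <= 0
        if np.any(bad):
            k = int(np.argmax(bad))
            raise CollapseError(self._collapse_msg(k))
        if self._has_visc:
            Ps = self.full_pressure(As, (As - A) / dt)
        else:
            Ps = self.elastic_pressure(As)
        F2s = Qs * Qs / As
        frics = self._fric / As * Qs

        # corrector (backward differences of the starred state)
        dQs = np.empty_like(Q)
        dQs[1:] = Qs[1:] - Qs[:-1]
        dFs = np.empty_like(Q)
        dFs[1:] = F2s[1:] - F2s[:-1]
        dPs = np.empty_like(Q)
        dPs[1:] = Ps[1:] - Ps[:-1]
        for arr in (dQs, dFs, dPs):
            arr[0] = 0.0
            arr[starts] = 0.0

        A_new = 0.5 * (A + As - r * dQs)
        Q_new = 0.5 * (Q + Qs - r * dFs - r * kr * As * dPs - dt * frics)

        # half-cell finite-volume mass update at the boundary nodes; the
        # interface flux between nodes i and i+1 is (Q*_i + Q^n_{i+1})/2,
        # so the per-segment volume change telescopes to dt*(q_in - q_out).
        f_in = 0.5 * (Qs[starts] + Q[starts + 1])
        f_out = 0.5 * (Qs[ends - 1] + Q[ends])
        A_new[starts] = A[starts] + 2.0 * r[starts] * (q_in - f_in)
        A_new[ends] = A[ends] + 2.0 * r[ends] * (f_out - q_out)
        Q_new[starts] = q_in
        Q_new[ends] = q_out

        bad = A_new <= 0
        if np.any(bad):
            k = int(np.argmax(bad))
            raise CollapseError(self._collapse_msg(k))

        dAdt = (A_new - A) / dt
        self.A = A_new
        self.Q = Q_new
        self.P = (self.full_pressure(A_new, dAdt) if self._has_visc
                  else self.elastic_pressure(A_new))
        self._dAdt = dAdt

    def _collapse_msg(self, node: int) -> str:
        k = int(np.searchsorted(self.ends, node))
        sid = self.ids[k]
        xloc = (node - self.starts[k]) * self.dx_seg[k]
        return f"vessel collapse (A <= 0) in segment '{sid}' at x={xloc:.2f} cm"


# ---------------------------------------------------------------------------
# Junction coupling


def _port_u(W, A, cc, s):
    """Velocity from the fixed outgoing invariant: u = W - s*4c."""
    c = np.sqrt(cc * np.sqrt(A))
    return W - s * 4.0 * c, c


def solve_junctions(A_guess, W, cc, beta, a0, pe, s, density,
                    tol: float = 1e-11, max_iter: int = 50, active=None):
    """Solve a batch of junctions by Newton iteration.

    Parameters are (m, n) arrays: column 0 is the parent's distal end,
    columns 1..n-1 the daughters' proximal ends.  ``s`` is +1 for the
    parent port and -1 for daughters.  Junctions of smaller arity can be
    padded to a common width with ``active`` (1/0 mask; column 0 always
    active).  Unknowns are the port areas; the constraints are exact mass
    conservation and continuity of total pressure, with each segment's
    outgoing characteristic preserved.  The arrow-shaped Jacobian is
    inverted in closed form.

    Returns (A, Q, P_total) per port; raises :class:`JunctionSolveError`
    on non-convergence.
    """
    A = np.array(A_guess, dtype=float)
    m, n = A.shape
    rho_k = density / MMHG_TO_CGS
    sgn = np.full(n, -1.0)
    sgn[0] = 1.0
    beta_a0 = beta / a0
    sqrt_a0 = np.sqrt(a0)
    act_d = None if active is None else np.asarray(active, float)[:, 1:]
    prev_resid = np.inf
    for it in range(max_iter):
        sqA = np.sqrt(A)
        c = np.sqrt(cc * sqA)
        u = W - s * 4.0 * c
        Pt = pe + beta_a0 * (sqA - sqrt_a0) + 0.5 * rho_k * u * u
        q = sgn * A * u
        rk = Pt[:, :1] - Pt[:, 1:]
        if act_d is not None:
            q[:, 1:] *= act_d
            rk *= act_d
        r0 = q.sum(axis=1)
        resid = max(np.abs(r0).max(), np.abs(rk).max())
        if resid < tol:
            break
        if resid >= prev_resid and resid < 1e-9:
            break       # stagnated at round-off, well inside tolerance
        prev_resid = resid
        cu = c / A
        dptda = rho_k * cu * (c - s * u)         # d(P + rho u^2/2K)/dA
        a_row = sgn * (u - s * c)                # mass-balance row
        ratio = a_row[:, 1:] / dptda[:, 1:]
        if act_d is not None:
            ratio *= act_d
        denom = a_row[:, 0] + dptda[:, 0] * ratio.sum(axis=1)
        x0 = (r0 + (ratio * rk).sum(axis=1)) / denom
        xk = (dptda[:, :1] * x0[:, None] - rk) / dptda[:, 1:]
        if act_d is not None:
            xk *= act_d
        A[:, 0] -= x0
        A[:, 1:] -= xk
        if np.any(A <= 0):
            raise CollapseError("junction solve produced non-positive area")
    else:
        raise JunctionSolveError(
            f"junction Newton did not converge in {max_iter} iterations "
            f"(max residual {resid:g})")
    u, _ = _port_u(W, A, cc, s)
    P = pe + beta_a0 * (np.sqrt(A) - sqrt_a0)
    return A, A * u, P + 0.5 * rho_k * u * u


def solve_junction(parent_state: dict, daughter_states: list[dict],
                   density: float = BLOOD_DENSITY):
    """Couple one parent outlet to >= 1 daughter inlets.

    Each state dict needs ``A`` (guess), ``W`` (outgoing invariant:
    u + 4c for the parent, u - 4c for daughters), ``cc``, ``beta``, ``a0``
    and optionally ``pe``.  Returns per-port dicts with converged
    ``A``, ``Q`` [ml/s] and total pressure ``Pt`` [mmHg].
    """
    if not daughter_states:
        raise ValueError("junction needs at least one daughter")
    ports = [parent_state] + list(daughter_states)
    n = len(ports)

    def col(key, default=None):
        return np.array([[p.get(key, default) if default is not None
                          else p[key] for p in ports]])

    A0g = col("A")
    W = col("W")
    cc = col("cc")
    beta = col("beta")
    a0 = col("a0")
    pe = col("pe", 0.0)
    s = np.full((1, n), -1.0)
    s[0, 0] = 1.0
    A, Q, Pt = solve_junctions(A0g, W, cc, beta, a0, pe, s, density)
    return [{"A": float(A[0, j]), "Q": float(Q[0, j]), "Pt": float(Pt[0, j])}
            for j in range(n)]


# ---------------------------------------------------------------------------
# Public operations on single segments


def _packed_for(segment: Artery1DSegment, density, viscosity) -> Packed1D:
    cached = getattr(segment, "_packed", None)
    if cached is None or cached.segments[0] is not segment:
        cached = Packed1D([segment], density=density, viscosity=viscosity,
                          dx_target=(segment.x[1] - segment.x[0]
                                     if segment.x is not None else 0.25))
        segment._packed = cached
    return cached


def advance_segment(segment: Artery1DSegment, boundary_data: tuple,
                    dt: float, density: float = BLOOD_DENSITY,
                    viscosity: float = BLOOD_VISCOSITY) -> Artery1DSegment:
    """Advance a single segment one step with prescribed boundary fluxes
    ``boundary_data = (q_in, q_out)`` [ml/s]."""
    q_in, q_out = boundary_data
    packed = _packed_for(segment, density, viscosity)
    packed.advance(dt, np.array([q_in], dtype=float),
                   np.array([q_out], dtype=float))
    packed.sync_to_segments()
    return segment


def stable_timestep(net_or_packed, cfl_number: float = 0.9) -> float:
    """dt = cfl * min over grid cells of dx / (|u| + c)."""
    if not 0.0 < cfl_number <= 1.0:
        raise ValueError("cfl_number must be in (0, 1]")
    packed = net_or_packed
    if not isinstance(packed, Packed1D):
        packed = Packed1D(list(net_or_packed.segments.values()),
                          density=net_or_packed.blood_density,
                          viscosity=net_or_packed.blood_viscosity)
    return cfl_number * packed.min_dx_over_speed()
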