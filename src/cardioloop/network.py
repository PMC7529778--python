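"""Data model for the closed-loop circulation.

The network couples a 1D arterial tree (nonlinear elastic/viscoelastic
tapered vessels) to a lumped-parameter (RLC) description of the remaining
circulation: arterioles, capillaries, venules, veins, venae cavae, the
pulmonary circulation, four contractile heart chambers and four valves,
plus a short-term baroreflex block.

Internal units are fixed to mmHg, ml, s and cm (see :mod:`cardioloop.units`).
Parameter documents are structured YAML; :func:`load_network` /
:func:`serialize_network` round-trip every parameter bit-exactly.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .units import BLOOD_DENSITY, BLOOD_VISCOSITY, MMHG_TO_CGS, M_PER_S_TO_CM_PER_S

REGION_TAGS = ("cerebral", "cardio-thoracic", "abdominal", "lower-limbs")
SHIFT_REGIONS = ("head-arms", "cardiac-thoracic", "upper-abdomen",
                 "lower-abdomen", "legs")
VIP_SIDES = ("upper", "lower")
UPPER_SHIFT_REGIONS = ("head-arms", "cardiac-thoracic", "upper-abdomen")
COMPARTMENT_CLASSES = ("arteriole", "capillary", "venule", "vein",
                       "vena-cava", "pulmonary-artery", "pulmonary-vein")
CHAMBER_IDS = ("LA", "LV", "RA", "RV")
VALVE_IDS = ("MV", "AV", "TV", "PV")


class NetworkLoadError(ValueError):
    """Raised when a parameter document violates the schema or an invariant."""


class ConsistencyError(ValueError):
    """Raised when the dynamic state contradicts a model identity."""


@dataclass
class Artery1DSegment:
    """One tapered 1D arterial segment.

    Geometry is a linear radius taper from ``r_prox`` to ``r_dist`` over
    ``length`` cm; the elastic tube-law coefficient is derived from the
    reference pulse-wave velocity ``pwv`` (m/s) at the unstressed area.
    State arrays (``x``, ``A``, ``Q``, ``P``) exist only after
    :meth:`build_grid`.
    """

    id: str
    name: str
    length: float                    # cm
    r_prox: float                    # cm
    r_dist: float                    # cm
    pwv: float                       # m/s, reference wave speed at A0
    wall_visc: float = 0.0           # Kelvin-Voigt coefficient Gamma [mmHg s cm]
    friction_zeta: float = 9.0       # velocity-profile coefficient
    external_pressure: float = 0.0   # mmHg
    region_tag: str = "cardio-thoracic"
    shift_region: str = "cardiac-thoracic"
    vip_side: str = "upper"
    area_scale: float = 1.0          # multiplicative A0 scale (gravity config)
    # state (built lazily)
    x: np.ndarray | None = None
    A: np.ndarray | None = None
    Q: np.ndarray | None = None
    P: np.ndarray | None = None

    def a0_profile(self, x: np.ndarray) -> np.ndarray:
        r = self.r_prox + (self.r_dist - self.r_prox) * (x / self.length)
        return self.area_scale * math.pi * r * r

    def beta_profile(self, x: np.ndarray, density: float) -> np.ndarray:
        """Elastic tube-law coefficient beta(x) [mmHg cm]."""
        c0 = self.pwv * M_PER_S_TO_CM_PER_S
        a0 = self.a0_profile(x)
        return 2.0 * density * c0 * c0 * np.sqrt(a0) / MMHG_TO_CGS

    def build_grid(self, dx_target: float = 0.25) -> None:
        n = max(3, int(round(self.length / dx_target)) + 1)
        self.x = np.linspace(0.0, self.length, n)
        a0 = self.a0_profile(self.x)
        self.A = a0.copy()
        self.Q = np.zeros(n)
        self.P = np.full(n, self.external_pressure)

    def rest_volume(self) -> float:
        """Volume [ml] of the unstressed lumen (analytic, taper-aware)."""
        rp, rd = self.r_prox, self.r_dist
        return (self.area_scale * math.pi * self.length
                * (rp * rp + rp * rd + rd * rd) / 3.0)

    def volume(self) -> float:
        if self.A is None:
            return self.rest_volume()
        return float(np.trapezoid(self.A, self.x))


@dataclass
class Compartment0D:
    """Lumped RLC compartment obeying V = V0 + C P.

    ``r``/``l`` are the resistance/inertance of the *outflow* link toward
    ``downstream`` (a compartment id, or the receiving chamber ``RA``/``LA``).
    """

    id: str
    name: str
    compartment_class: str
    r: float                         # mmHg s / ml (outflow)
    c: float                         # ml / mmHg
    v0: float                        # ml
    v: float                         # ml
    l: float = 0.0                   # mmHg s^2 / ml
    downstream: str | None = None
    region_tag: str = "cardio-thoracic"
    shift_region: str = "cardiac-thoracic"
    vip_side: str = "upper"
    fixed_pressure: bool = False     # fixture sink: P held constant
    rectify: bool = False            # flow-rectifying (venous valve) outflow
    q_out: float = 0.0               # state (inertial links)

    @property
    def p(self) -> float:
        return (self.v - self.v0) / self.c

    def set_pressure(self, p: float) -> None:
        self.v = self.v0 + self.c * p


@dataclass
class HeartChamber:
    """Time-varying elastance chamber: P = E(t) (V - V0)."""

    id: str
    e_min: float                     # mmHg/ml
    e_amp: float                     # mmHg/ml
    v0: float                        # ml
    v: float                         # ml
    region_tag: str = "cardio-thoracic"
    shift_region: str = "cardiac-thoracic"
    vip_side: str = "upper"


@dataclass
class ValveState:
    """Leaflet valve driven by four torque terms (pressure, friction,
    blood motion, downstream vortex); opening maps the leaflet angle
    to [0, 1]."""

    id: str
    cq: float                        # ml/s/mmHg^0.5 at full opening
    r_lin: float = 0.002             # small series resistance [mmHg s/ml]
    k_p: float = 18000.0             # pressure torque [rad/s^2/mmHg]
    k_f: float = 50.0                # frictional damping [1/s]
    k_b: float = 30.0                # blood-motion torque [rad/s^2 per ml/s]
    k_v: float = 7.0                 # vortex torque [rad/s^2 per ml/s]
    theta_max: float = 1.309         # rad (75 deg)
    theta: float = 0.0               # rad, state
    omega: float = 0.0               # rad/s, state
    flow: float = 0.0                # ml/s, state

    @property
    def opening(self) -> float:
        num = (1.0 - math.cos(self.theta)) ** 2
        den = (1.0 - math.cos(self.theta_max)) ** 2
        return min(1.0, max(0.0, num / den))


@dataclass
class BaroreflexBlock:
    """Short-term baroregulation: afferent aortic-carotid pressure sensing
    with sigmoidal static effector curves and first-order effector lags."""

    setpoint: float                  # mmHg
    hr_baseline: float               # bpm
    gains: dict = field(default_factory=lambda: {
        "hr": 0.08, "e_amp": 0.3, "r_art": 0.3, "v0_ven": 0.15, "c_ven": 0.08})
    taus: dict = field(default_factory=lambda: {
        "hr": 3.0, "e_amp": 6.0, "r_art": 6.0, "v0_ven": 8.0, "c_ven": 8.0})
    sigmoid_width: float = 0.12      # relative pressure scale of the sigmoid
    afferent_tau: float = 2.0        # s, low-pass of the sensed pressure
    aortic_weight: float = 0.5
    gravity_tag: str = "1g"
    # state
    afferent: float | None = None
    multipliers: dict = field(default_factory=lambda: {
        "hr": 1.0, "e_amp": 1.0, "r_art": 1.0, "v0_ven": 1.0, "c_ven": 1.0})


@dataclass
class ArteriolarInterface:
    """1D -> 0D coupling: characteristic impedance in series before the
    arteriole fed by a terminal artery."""

    artery: str
    arteriole: str
    zc: float | str = "auto"         # mmHg s/ml, or "auto" from the tube law


@dataclass
class InflowSource:
    """Fixture-only prescribed inflow (replaces the heart in toy networks).

    q(t) = q_mean + q_pulse * sin(2 pi t / period) into ``target`` (a segment
    inlet or a compartment).
    """

    target: str
    q_mean: float
    q_pulse: float = 0.0
    period: float = 0.8


@dataclass
class CardiovascularNetwork:
    """Full closed-loop topology plus parameters."""

    blood_density: float = BLOOD_DENSITY
    blood_viscosity: float = BLOOD_VISCOSITY
    gravity_tag: str = "1g"
    rr: float = 0.8                  # s, reference beating period at baseline HR
    heart_timing: dict = field(default_factory=lambda: {
        "atrial_frac": 0.20, "av_delay_frac": 0.15, "vent_frac": 0.40})
    segments: dict[str, Artery1DSegment] = field(default_factory=dict)
    compartments: dict[str, Compartment0D] = field(default_factory=dict)
    chambers: dict[str, HeartChamber] = field(default_factory=dict)
    valves: dict[str, ValveState] = field(default_factory=dict)
    junctions: list[tuple[str, list[str]]] = field(default_factory=list)
    interfaces: list[ArteriolarInterface] = field(default_factory=list)
    root_segment: str | None = None  # fed by the aortic valve
    baroreflex: BaroreflexBlock | None = None
    source: InflowSource | None = None

    # ---- topology helpers -------------------------------------------------

    def parents(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for parent, daughters in self.junctions:
            for d in daughters:
                out[d] = parent
        return out

    def terminal_segments(self) -> list[str]:
        with_daughters = {p for p, _ in self.junctions}
        return [s for s in self.segments if s not in with_daughters]

    def interface_for(self, artery: str) -> ArteriolarInterface | None:
        for itf in self.interfaces:
            if itf.artery == artery:
                return itf
        return None

    def upstream_compartments(self) -> dict[str, list[str]]:
        ups: dict[str, list[str]] = {c: [] for c in self.compartments}
        for c in self.compartments.values():
            if c.downstream in ups:
                ups[c.downstream].append(c.id)
        return ups

    # ---- volume accounting ------------------------------------------------

    def check_state_consistency(self) -> None:
        """Pressure is derived from volume, so V = V0 + C P holds by
        construction; what can go wrong is an unphysical stored state."""
        for c in self.compartments.values():
            if c.c <= 0:
                raise ConsistencyError(f"compartment {c.id}: non-positive C")
            if not math.isfinite(c.v) or c.v <= 0:
                raise ConsistencyError(
                    f"compartment {c.id}: unphysical volume {c.v!r} ml")
        for s in self.segments.values():
            if s.A is not None and (not np.all(np.isfinite(s.A))
                                    or np.any(s.A <= 0)):
                raise ConsistencyError(
                    f"segment {s.id}: unphysical area state")

    def total_blood_volume(self) -> float:
        """Sum of compartment, chamber and 1D-lumen volumes [ml]."""
        self.check_state_consistency()
        vol = sum(c.v for c in self.compartments.values())
        vol += sum(ch.v for ch in self.chambers.values())
        vol += sum(s.volume() for s in self.segments.values())
        if vol <= 0:
            raise ConsistencyError("total blood volume is not positive")
        return vol

    def vip_volumes(self) -> dict[str, float]:
        """Volume held above/below the volume indifference point."""
        out = {"upper": 0.0, "lower": 0.0}
        for c in self.compartments.values():
            out[c.vip_side] += c.v
        for ch in self.chambers.values():
            out[ch.vip_side] += ch.v
        for s in self.segments.values():
            out[s.vip_side] += s.volume()
        return out

    def shift_region_volumes(self) -> dict[str, float]:
        out = {r: 0.0 for r in SHIFT_REGIONS}
        for c in self.compartments.values():
            out[c.shift_region] += c.v
        for ch in self.chambers.values():
            out[ch.shift_region] += ch.v
        for s in self.segments.values():
            out[s.shift_region] += s.volume()
        return out

    def copy(self) -> "CardiovascularNetwork":
        return copy.deepcopy(self)

    def config_hash(self) -> str:
        doc = serialize_network(self)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Document I/O


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise NetworkLoadError(f"{where}: missing required field '{key}'")
    return mapping[key]


def load_network(document) -> CardiovascularNetwork:
    """Build and validate a network from a YAML document.

    ``document`` may be a mapping, a YAML string, or a path to a YAML file.
    Raises :class:`NetworkLoadError` naming the offending element on any
    schema or invariant violation.
    """
    if isinstance(document, dict):
        doc = document
    else:
        text = str(document)
        if "\n" not in text and (text.endswith(".yaml") or text.endswith(".yml")):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise NetworkLoadError("document root must be a mapping")
    units = doc.get("units")
    if units is None:
        raise NetworkLoadError("document: missing 'units' declaration")
    expected = {"pressure": "mmHg", "volume": "ml", "time": "s", "length": "cm"}
    for k, v in expected.items():
        if units.get(k) != v:
            raise NetworkLoadError(
                f"document units: expected {k}={v}, got {units.get(k)!r}")

    net = CardiovascularNetwork(
        blood_density=float(doc.get("blood", {}).get("density", BLOOD_DENSITY)),
        blood_viscosity=float(doc.get("blood", {}).get("viscosity", BLOOD_VISCOSITY)),
        gravity_tag=doc.get("gravity", "1g"),
        rr=float(doc.get("heart", {}).get("rr", 0.8)),
    )
    heart = doc.get("heart", {})
    if "timing" in heart:
        net.heart_timing = {k: float(v) for k, v in heart["timing"].items()}

    for seg_doc in doc.get("segments", []) or []:
        sid = _require(seg_doc, "id", "segment")
        seg = Artery1DSegment(
            id=sid,
            name=seg_doc.get("name", sid),
            length=float(_require(seg_doc, "length", f"segment {sid}")),
            r_prox=float(_require(seg_doc, "r_prox", f"segment {sid}")),
            r_dist=float(_require(seg_doc, "r_dist", f"segment {sid}")),
            pwv=float(_require(seg_doc, "pwv", f"segment {sid}")),
            wall_visc=float(seg_doc.get("wall_visc", 0.0)),
            friction_zeta=float(seg_doc.get("friction_zeta", 9.0)),
            external_pressure=float(seg_doc.get("external_pressure", 0.0)),
            region_tag=seg_doc.get("region_tag", "cardio-thoracic"),
            shift_region=seg_doc.get("shift_region", "cardiac-thoracic"),
            vip_side=seg_doc.get("vip_side", "upper"),
            area_scale=float(seg_doc.get("area_scale", 1.0)),
        )
        if seg.length <= 0:
            raise NetworkLoadError(f"segment {sid}: length must be > 0 "
                                   f"(got {seg.length})")
        if seg.r_prox <= 0 or seg.r_dist <= 0:
            raise NetworkLoadError(f"segment {sid}: radii must be > 0")
        if seg.pwv <= 0:
            raise NetworkLoadError(f"segment {sid}: pwv must be > 0")
        if seg.region_tag not in REGION_TAGS:
            raise NetworkLoadError(f"segment {sid}: unknown region_tag "
                                   f"{seg.region_tag!r}")
        if seg.shift_region not in SHIFT_REGIONS:
            raise NetworkLoadError(f"segment {sid}: unknown shift_region "
                                   f"{seg.shift_region!r}")
        if sid in net.segments:
            raise NetworkLoadError(f"segment {sid}: duplicate id")
        net.segments[sid] = seg

    for c_doc in doc.get("compartments", []) or []:
        cid = _require(c_doc, "id", "compartment")
        comp = Compartment0D(
            id=cid,
            name=c_doc.get("name", cid),
            compartment_class=_require(c_doc, "class", f"compartment {cid}"),
            r=float(_require(c_doc, "r", f"compartment {cid}")),
            l=float(c_doc.get("l", 0.0)),
            c=float(_require(c_doc, "c", f"compartment {cid}")),
            v0=float(_require(c_doc, "v0", f"compartment {cid}")),
            v=float(_require(c_doc, "v", f"compartment {cid}")),
            downstream=c_doc.get("downstream"),
            region_tag=c_doc.get("region_tag", "cardio-thoracic"),
            shift_region=c_doc.get("shift_region", "cardiac-thoracic"),
            vip_side=c_doc.get("vip_side", "upper"),
            fixed_pressure=bool(c_doc.get("fixed_pressure", False)),
            rectify=bool(c_doc.get("rectify", False)),
        )
        if comp.r < 0 or comp.l < 0:
            raise NetworkLoadError(f"compartment {cid}: R and L must be >= 0")
        if comp.c <= 0:
            raise NetworkLoadError(f"compartment {cid}: C must be > 0")
        if comp.v0 < 0:
            raise NetworkLoadError(f"compartment {cid}: V0 must be >= 0")
        if comp.compartment_class not in COMPARTMENT_CLASSES:
            raise NetworkLoadError(f"compartment {cid}: unknown class "
                                   f"{comp.compartment_class!r}")
        if cid in net.compartments:
            raise NetworkLoadError(f"compartment {cid}: duplicate id")
        net.compartments[cid] = comp

    for ch_doc in doc.get("chambers", []) or []:
        chid = _require(ch_doc, "id", "chamber")
        if chid not in CHAMBER_IDS:
            raise NetworkLoadError(f"chamber {chid}: id must be one of "
                                   f"{CHAMBER_IDS}")
        ch = HeartChamber(
            id=chid,
            e_min=float(_require(ch_doc, "e_min", f"chamber {chid}")),
            e_amp=float(_require(ch_doc, "e_amp", f"chamber {chid}")),
            v0=float(_require(ch_doc, "v0", f"chamber {chid}")),
            v=float(_require(ch_doc, "v", f"chamber {chid}")),
            region_tag=ch_doc.get("region_tag", "cardio-thoracic"),
            shift_region=ch_doc.get("shift_region", "cardiac-thoracic"),
            vip_side=ch_doc.get("vip_side", "upper"),
        )
        if ch.e_min <= 0 or ch.e_amp < 0:
            raise NetworkLoadError(f"chamber {chid}: need E_min > 0, E_amp >= 0")
        net.chambers[chid] = ch

    for v_doc in doc.get("valves", []) or []:
        vid = _require(v_doc, "id", "valve")
        if vid not in VALVE_IDS:
            raise NetworkLoadError(f"valve {vid}: id must be one of {VALVE_IDS}")
        net.valves[vid] = ValveState(
            id=vid,
            cq=float(_require(v_doc, "cq", f"valve {vid}")),
            r_lin=float(v_doc.get("r_lin", 0.002)),
            k_p=float(v_doc.get("k_p", 18000.0)),
            k_f=float(v_doc.get("k_f", 50.0)),
            k_b=float(v_doc.get("k_b", 30.0)),
            k_v=float(v_doc.get("k_v", 7.0)),
            theta_max=float(v_doc.get("theta_max", 1.309)),
            theta=float(v_doc.get("theta", 0.0)),
        )

    for j_doc in doc.get("junctions", []) or []:
        parent = _require(j_doc, "parent", "junction")
        daughters = _require(j_doc, "daughters", f"junction {parent}")
        if parent not in net.segments:
            raise NetworkLoadError(f"junction: unknown parent segment {parent}")
        for d in daughters:
            if d not in net.segments:
                raise NetworkLoadError(
                    f"junction {parent}: unknown daughter segment {d}")
        if not daughters:
            raise NetworkLoadError(f"junction {parent}: needs >= 1 daughter")
        net.junctions.append((parent, list(daughters)))

    for i_doc in doc.get("interfaces", []) or []:
        artery = _require(i_doc, "artery", "interface")
        arteriole = _require(i_doc, "arteriole", "interface")
        if artery not in net.segments:
            raise NetworkLoadError(f"interface: unknown artery {artery}")
        if arteriole not in net.compartments:
            raise NetworkLoadError(
                f"interface {artery}: unknown arteriole {arteriole}")
        zc = i_doc.get("zc", "auto")
        if zc != "auto":
            zc = float(zc)
            if zc <= 0:
                raise NetworkLoadError(f"interface {artery}: Zc must be > 0")
        net.interfaces.append(ArteriolarInterface(artery, arteriole, zc))

    net.root_segment = doc.get("root_segment")

    if "baroreflex" in doc and doc["baroreflex"] is not None:
        b = doc["baroreflex"]
        net.baroreflex = BaroreflexBlock(
            setpoint=float(_require(b, "setpoint", "baroreflex")),
            hr_baseline=float(_require(b, "hr_baseline", "baroreflex")),
            gains={k: float(v) for k, v in b.get("gains", {}).items()} or
            BaroreflexBlock.__dataclass_fields__["gains"].default_factory(),
            taus={k: float(v) for k, v in b.get("taus", {}).items()} or
            BaroreflexBlock.__dataclass_fields__["taus"].default_factory(),
            sigmoid_width=float(b.get("sigmoid_width", 0.12)),
            afferent_tau=float(b.get("afferent_tau", 2.0)),
            aortic_weight=float(b.get("aortic_weight", 0.5)),
            gravity_tag=b.get("gravity_tag", doc.get("gravity", "1g")),
        )

    if "source" in doc and doc["source"] is not None:
        s = doc["source"]
        net.source = InflowSource(
            target=_require(s, "target", "source"),
            q_mean=float(_require(s, "q_mean", "source")),
            q_pulse=float(s.get("q_pulse", 0.0)),
            period=float(s.get("period", 0.8)),
        )

    problems = validate_network(net)
    if problems:
        raise NetworkLoadError("invalid network:\n  " + "\n  ".join(problems))
    return net


def serialize_network(net: CardiovascularNetwork) -> str:
    """Serialize to a YAML document; floats use repr so the round-trip is
    bit-exact."""
    doc: dict = {
        "version": 1,
        "units": {"pressure": "mmHg", "volume": "ml", "time": "s",
                  "length": "cm"},
        "gravity": net.gravity_tag,
        "blood": {"density": net.blood_density,
                  "viscosity": net.blood_viscosity},
        "heart": {"rr": net.rr, "timing": dict(net.heart_timing)},
    }
    doc["segments"] = [{
        "id": s.id, "name": s.name, "length": s.length, "r_prox": s.r_prox,
        "r_dist": s.r_dist, "pwv": s.pwv, "wall_visc": s.wall_visc,
        "friction_zeta": s.friction_zeta,
        "external_pressure": s.external_pressure, "region_tag": s.region_tag,
        "shift_region": s.shift_region, "vip_side": s.vip_side,
        "area_scale": s.area_scale,
    } for s in net.segments.values()]
    doc["compartments"] = [{
        "id": c.id, "name": c.name, "class": c.compartment_class, "r": c.r,
        "l": c.l, "c": c.c, "v0": c.v0, "v": c.v, "downstream": c.downstream,
        "region_tag": c.region_tag, "shift_region": c.shift_region,
        "vip_side": c.vip_side, "fixed_pressure": c.fixed_pressure,
        "rectify": c.rectify,
    } for c in net.compartments.values()]
    doc["chambers"] = [{
        "id": ch.id, "e_min": ch.e_min, "e_amp": ch.e_amp, "v0": ch.v0,
        "v": ch.v, "region_tag": ch.region_tag,
        "shift_region": ch.shift_region, "vip_side": ch.vip_side,
    } for ch in net.chambers.values()]
    doc["valves"] = [{
        "id": v.id, "cq": v.cq, "r_lin": v.r_lin, "k_p": v.k_p,
        "k_f": v.k_f, "k_b": v.k_b, "k_v": v.k_v,
        "theta_max": v.theta_max, "theta": v.theta,
    } for v in net.valves.values()]
    doc["junctions"] = [{"parent": p, "daughters": list(d)}
                        for p, d in net.junctions]
    doc["interfaces"] = [{"artery": i.artery, "arteriole": i.arteriole,
                          "zc": i.zc} for i in net.interfaces]
    doc["root_segment"] = net.root_segment
    if net.baroreflex is not None:
        b = net.baroreflex
        doc["baroreflex"] = {
            "setpoint": b.setpoint, "hr_baseline": b.hr_baseline,
            "gains": dict(b.gains), "taus": dict(b.taus),
            "sigmoid_width": b.sigmoid_width, "afferent_tau": b.afferent_tau,
            "aortic_weight": b.aortic_weight, "gravity_tag": b.gravity_tag,
        }
    if net.source is not None:
        doc["source"] = {"target": net.source.target,
                         "q_mean": net.source.q_mean,
                         "q_pulse": net.source.q_pulse,
                         "period": net.source.period}

    class _Dumper(yaml.SafeDumper):
        pass

    _Dumper.add_representer(
        float, lambda dumper, value: dumper.represent_scalar(
            "tag:yaml.org,2002:float", repr(float(value))))
    return yaml.dump(doc, Dumper=_Dumper, sort_keys=False)


def validate_network(net: CardiovascularNetwork) -> list[str]:
    """Return a diagnostics report: one entry per violated invariant.

    An empty list means the network is valid. Never raises.
    """
    report: list[str] = []

    for s in net.segments.values():
        if s.length <= 0:
            report.append(f"segment {s.id}: length {s.length} <= 0")
        if s.r_prox <= 0 or s.r_dist <= 0:
            report.append(f"segment {s.id}: non-positive radius")
        if s.x is not None:
            if np.any(np.diff(s.x) <= 0):
                report.append(f"segment {s.id}: grid not strictly increasing")
            if np.any(s.A <= 0):
                report.append(f"segment {s.id}: non-positive area in state")

    for c in net.compartments.values():
        if c.r < 0 or c.l < 0 or c.c <= 0 or c.v0 < 0:
            report.append(f"compartment {c.id}: invalid R/L/C/V0")
        if c.downstream is None and not c.fixed_pressure:
            report.append(f"compartment {c.id}: no downstream connection")
        elif (c.downstream is not None
              and c.downstream not in net.compartments
              and c.downstream not in net.chambers):
            report.append(f"compartment {c.id}: unknown downstream "
                          f"{c.downstream!r}")

    # 1D topology: rooted tree
    parents = net.parents()
    for child, parent in parents.items():
        if child == net.root_segment:
            report.append(f"segment {child}: root segment has a parent")
    if net.segments:
        roots = [s for s in net.segments if s not in parents]
        if net.root_segment is None:
            report.append("network with 1D segments but no root_segment")
        elif net.root_segment not in net.segments:
            report.append(f"root_segment {net.root_segment!r} unknown")
        if len(roots) != 1:
            report.append(f"1D tree must have exactly one root, found {roots}")
        seen: set[str] = set()
        for parent, daughters in net.junctions:
            for d in daughters:
                if d in seen:
                    report.append(f"segment {d}: multiple parents")
                seen.add(d)
        # every terminal has exactly one arteriolar interface
        itf_count: dict[str, int] = {}
        for itf in net.interfaces:
            itf_count[itf.artery] = itf_count.get(itf.artery, 0) + 1
        for t in net.terminal_segments():
            n = itf_count.get(t, 0)
            if n != 1 and net.source is None:
                report.append(f"terminal segment {t}: has {n} arteriolar "
                              f"interfaces (needs exactly 1)")
        for itf in net.interfaces:
            if itf.artery in {p for p, _ in net.junctions}:
                report.append(f"interface on non-terminal artery {itf.artery}")

    # heart completeness
    if net.chambers and set(net.chambers) != set(CHAMBER_IDS):
        report.append(f"chambers incomplete: {sorted(net.chambers)}")
    if net.chambers and set(net.valves) != set(VALVE_IDS):
        report.append(f"valves incomplete: {sorted(net.valves)}")
    for v in net.valves.values():
        if not (0.0 <= v.opening <= 1.0):
            report.append(f"valve {v.id}: opening outside [0, 1]")
        if v.opening == 0.0 and v.flow != 0.0:
            report.append(f"valve {v.id}: closed but flow {v.flow} != 0")

    # closed loop: every compartment chain must reach a chamber or cycle back
    for cid in net.compartments:
        cur = cid
        hops = 0
        while True:
            comp = net.compartments[cur]
            if comp.fixed_pressure:
                break
            nxt = comp.downstream
            if nxt is None:
                break  # already reported
            if nxt in net.chambers:
                break
            if nxt not in net.compartments:
                break  # already reported
            cur = nxt
            hops += 1
            if cur == cid:
                break  # closed ring (legal degenerate loop)
            if hops > len(net.compartments):
                report.append(f"compartment {cid}: downstream chain does not "
                              f"close the loop (open circulation)")
                break

    # chambers need a venous return if present
    if net.chambers and net.compartments:
        returns = {c.downstream for c in net.compartments.values()}
        if "RA" not in returns:
            report.append("open loop: no compartment returns to RA "
                          "(missing vena cava return)")
        if "LA" not in returns:
            report.append("open loop: no compartment returns to LA "
                          "(missing pulmonary venous return)")

    # VIP partition covers every volume-holding element
    for group in (net.segments.values(), net.compartments.values(),
                  net.chambers.values()):
        for el in group:
            if el.vip_side not in VIP_SIDES:
                report.append(f"element {el.id}: vip_side {el.vip_side!r} "
                              f"not in {VIP_SIDES}")
            if el.shift_region not in SHIFT_REGIONS:
                report.append(f"element {el.id}: shift_region "
                              f"{el.shift_region!r} not in {SHIFT_REGIONS}")

    return report


def packaged_document(name: str) -> str:
    """Return the text of a parameter document shipped with the package."""
    ref = importlib.resources.files("cardioloop.data").joinpath(name)
    return ref.read_text()


def load_packaged_network(name: str = "supine_1g_synthetic.yaml"
                          ) -> CardiovascularNetwork:
    return load_network(yaml.safe_load(packaged_document(name)))
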