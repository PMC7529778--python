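"""Long-term weightlessness configurator.

Transforms a supine-1G network into the chronic-0G adaptation point by
applying, in a fixed order, the deconditioning change set: upward blood
shift between five body regions, total blood volume reduction, cardiac
function changes, vascular compliance/resistance changes, and baroreflex
baseline shifts.  Blood shift conserves total volume; the volume reduction
is exactly multiplicative; both preserve each zone's V0/V ratio to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .baroreflex import set_0g_baselines
from .network import (CardiovascularNetwork, SHIFT_REGIONS,
                      packaged_document)


class GravityConfigError(ValueError):
    """Invalid or mis-ordered gravity reconfiguration."""


@dataclass
class GravityConfigDelta:
    """The chronic-0G change set (defaults: long-term spaceflight without
    dedicated countermeasures)."""

    blood_shift_ml: dict = field(default_factory=lambda: {
        "legs": -235.0, "lower-abdomen": -234.0, "head-arms": 133.0,
        "cardiac-thoracic": 202.0, "upper-abdomen": 134.0})
    volume_reduction_fraction: float = 0.115
    ventricular_e_amp_factor: float = 0.73
    ventricular_e_min_factor: float = 1.03
    pulmonary_artery_c_factor: float = 1.04
    pulmonary_vein_c_factor: float = 1.05
    chamber_v0_factor: float = 0.10
    legs_venous_c_factor: float = 1.27
    vertebral_carotid_r_factor: float = 1.10
    lower_body_r_factor: float = 0.90
    hr_baseline_factor: float = 1.13
    setpoint_factor: float = 0.90

    def validate(self) -> None:
        missing = set(SHIFT_REGIONS) - set(self.blood_shift_ml)
        if missing:
            raise GravityConfigError(f"blood shift missing regions {missing}")
        total = sum(self.blood_shift_ml.values())
        if abs(total) > 1e-9:
            raise GravityConfigError(
                f"regional blood shifts must sum to 0 ml (got {total:g})")
        if not 0.0 <= self.volume_reduction_fraction < 1.0:
            raise GravityConfigError("reduction fraction must be in [0, 1)")
        for name in ("ventricular_e_amp_factor", "ventricular_e_min_factor",
                     "pulmonary_artery_c_factor", "pulmonary_vein_c_factor",
                     "chamber_v0_factor", "legs_venous_c_factor",
                     "vertebral_carotid_r_factor", "lower_body_r_factor",
                     "hr_baseline_factor", "setpoint_factor"):
            if getattr(self, name) <= 0:
                raise GravityConfigError(f"{name} must be > 0")


def load_delta(document=None) -> GravityConfigDelta:
    """Load a gravity delta document (YAML mapping, string or path);
    ``None`` loads the packaged chronic-0G set."""
    if document is None:
        doc = yaml.safe_load(packaged_document("gravity_0g.yaml"))
    elif isinstance(document, dict):
        doc = document
    else:
        text = str(document)
        if "\n" not in text and (text.endswith(".yaml")
                                 or text.endswith(".yml")):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    flat: dict = {}
    flat.update({"blood_shift_ml": doc.get("blood_shift_ml", {})})
    if "volume_reduction_fraction" in doc:
        flat["volume_reduction_fraction"] = float(
            doc["volume_reduction_fraction"])
    for group in ("cardiac", "vascular", "baroreflex"):
        for k, v in doc.get(group, {}).items():
            flat[k] = float(v)
    delta = GravityConfigDelta(**flat)
    delta.validate()
    return delta


# ---------------------------------------------------------------------------
# Zone helpers: every volume-holding element is one "zone"


def _zones(net: CardiovascularNetwork):
    for c in net.compartments.values():
        yield ("compartment", c)
    for ch in net.chambers.values():
        yield ("chamber", ch)
    for s in net.segments.values():
        yield ("segment", s)


def _zone_volume(kind, el) -> float:
    if kind == "segment":
        return el.volume()
    return el.v


def _scale_zone(kind, el, factor: float, report: list) -> None:
    """Scale a zone's total volume by ``factor`` preserving V0/V."""
    if kind == "segment":
        before = el.volume()
        el.area_scale *= factor
        if el.A is not None:
            el.A = el.A * factor
        report.append({"element": el.id, "parameter": "volume",
                       "before": before, "after": before * factor})
    else:
        report.append({"element": el.id, "parameter": "volume",
                       "before": el.v, "after": el.v * factor})
        el.v *= factor
        el.v0 *= factor


def apply_blood_shift(net: CardiovascularNetwork,
                      delta: GravityConfigDelta,
                      report: list | None = None) -> CardiovascularNetwork:
    """Shift the stated millilitres between the five body regions.

    Within each region every zone's total volume V scales proportionally
    to its share in the incoming configuration, and V0 is rescaled so
    V0/V is unchanged.  Total blood volume is conserved exactly.
    """
    if net.gravity_tag != "1g":
        raise GravityConfigError("blood shift requires a 1G-tagged network")
    if getattr(net, "_shift_applied", False):
        raise GravityConfigError("blood shift already applied")
    delta.validate()
    report = report if report is not None else []
    totals = net.shift_region_volumes()
    for region, dv in delta.blood_shift_ml.items():
        tot = totals.get(region, 0.0)
        if tot <= 0 and dv != 0:
            raise GravityConfigError(
                f"region {region}: no shiftable volume for {dv} ml")
        if dv == 0:
            continue
        factor = (tot + dv) / tot
        if factor <= 0:
            raise GravityConfigError(
                f"region {region}: shift {dv} ml exceeds the regional "
                f"volume {tot:.1f} ml")
        for kind, el in _zones(net):
            if el.shift_region == region:
                _scale_zone(kind, el, factor, report)
    net._shift_applied = True
    return net


def apply_volume_reduction(net: CardiovascularNetwork,
                           fraction: float = 0.115,
                           report: list | None = None
                           ) -> CardiovascularNetwork:
    """Reduce every zone's volume by ``fraction`` (of the post-shift
    configuration), preserving V0/V.  Must follow the blood shift."""
    if not getattr(net, "_shift_applied", False):
        raise GravityConfigError(
            "volume reduction must be applied after the blood shift")
    if not 0.0 <= fraction < 1.0:
        raise GravityConfigError("reduction fraction must be in [0, 1)")
    report = report if report is not None else []
    factor = 1.0 - fraction
    if fraction == 0.0:
        return net
    for kind, el in _zones(net):
        _scale_zone(kind, el, factor, report)
    return net


def apply_cardiac_changes(net: CardiovascularNetwork,
                          delta: GravityConfigDelta,
                          report: list | None = None
                          ) -> CardiovascularNetwork:
    """Reduced contractility and cardiac volume; stiffer baseline
    ventricles; more compliant pulmonary vessels."""
    report = report if report is not None else []

    def _set(el, attr, factor, label=None):
        before = getattr(el, attr)
        setattr(el, attr, before * factor)
        report.append({"element": el.id, "parameter": label or attr,
                       "before": before, "after": before * factor})

    for chid in ("LV", "RV"):
        ch = net.chambers[chid]
        _set(ch, "e_amp", delta.ventricular_e_amp_factor)
        _set(ch, "e_min", delta.ventricular_e_min_factor)
    for ch in net.chambers.values():
        _set(ch, "v0", delta.chamber_v0_factor)
    for c in net.compartments.values():
        if c.compartment_class == "pulmonary-artery":
            _set(c, "c", delta.pulmonary_artery_c_factor, "C")
        elif c.compartment_class == "pulmonary-vein":
            _set(c, "c", delta.pulmonary_vein_c_factor, "C")
    return net


def apply_vascular_changes(net: CardiovascularNetwork,
                           delta: GravityConfigDelta,
                           report: list | None = None
                           ) -> CardiovascularNetwork:
    """Leg venous compliance up; cerebral (vertebral/carotid) arteriolar
    resistance up; all lower-body arteriolar resistance down."""
    report = report if report is not None else []
    for c in net.compartments.values():
        if not c.region_tag or not c.vip_side:
            raise GravityConfigError(f"compartment {c.id}: missing tags")
        if (c.shift_region == "legs"
                and c.compartment_class in ("vein", "venule")):
            before = c.c
            c.c *= delta.legs_venous_c_factor
            report.append({"element": c.id, "parameter": "C",
                           "before": before, "after": c.c})
        if c.compartment_class == "arteriole":
            factor = None
            if c.region_tag == "cerebral":
                factor = delta.vertebral_carotid_r_factor
            elif c.vip_side == "lower":
                factor = delta.lower_body_r_factor
            if factor is not None:
                before = c.r
                c.r *= factor
                report.append({"element": c.id, "parameter": "R",
                               "before": before, "after": c.r})
    return net


def configure_0g(net: CardiovascularNetwork,
                 delta: GravityConfigDelta | None = None
                 ) -> tuple[CardiovascularNetwork, list]:
    """Full 1G -> 0G pipeline, in the required order: blood shift, volume
    reduction, cardiac changes, vascular changes, baroreflex baselines.

    Returns the configured network (tagged 0G) and a report of every
    parameter changed with before/after values.  Refuses to run twice.
    """
    if net.gravity_tag == "0g":
        raise GravityConfigError("network already configured for 0G")
    if net.gravity_tag != "1g":
        raise GravityConfigError(f"unknown gravity tag {net.gravity_tag!r}")
    delta = delta or load_delta()
    delta.validate()
    report: list = []
    apply_blood_shift(net, delta, report)
    apply_volume_reduction(net, delta.volume_reduction_fraction, report)
    apply_cardiac_changes(net, delta, report)
    apply_vascular_changes(net, delta, report)
    if net.baroreflex is not None:
        b = net.baroreflex
        before_hr, before_sp = b.hr_baseline, b.setpoint
        # delta factors are authoritative; the baroreflex op guards the tag
        b.hr_baseline = before_hr * delta.hr_baseline_factor / 1.13
        b.setpoint = before_sp * delta.setpoint_factor / 0.90
        set_0g_baselines(b)
        report.append({"element": "baroreflex", "parameter": "hr_baseline",
                       "before": before_hr, "after": b.hr_baseline})
        report.append({"element": "baroreflex", "parameter": "setpoint",
                       "before": before_sp, "after": b.setpoint})
    net.gravity_tag = "0g"
    return net, report
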