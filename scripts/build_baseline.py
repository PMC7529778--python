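"""Construct the supine-1G baseline parameter document.

The document is synthetic: it is assembled from standard human
arterial-tree geometry and lumped-parameter values of the physiological
modeling literature, with terminal and venous resistances chosen so the
1G operating point (mean pressures, regional flow distribution, total
blood volume) sits at textbook supine values.  Run from the repo root:

    python scripts/build_baseline.py

writes src/cardioloop/data/supine_1g_synthetic.yaml.
"""

import math
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from cardioloop.network import (Artery1DSegment, BaroreflexBlock,  # noqa: E402
                                CardiovascularNetwork, Compartment0D,
                                HeartChamber, ValveState,
                                load_network, serialize_network)
from cardioloop.network import ArteriolarInterface  # noqa: E402

# id, name, L [cm], r_prox, r_dist [cm], pwv [m/s], region, shift_region
SEGMENTS = [
    ("asc_aorta", "ascending aorta", 4.0, 1.44, 1.40, 4.6, "cardio-thoracic", "cardiac-thoracic"),
    ("arch_a", "aortic arch A", 2.0, 1.35, 1.30, 4.8, "cardio-thoracic", "cardiac-thoracic"),
    ("brachioceph", "brachiocephalic", 3.4, 0.70, 0.70, 5.0, "cardio-thoracic", "cardiac-thoracic"),
    ("r_common_carotid", "right common carotid", 17.0, 0.37, 0.37, 5.5, "cerebral", "head-arms"),
    ("r_int_carotid", "right internal carotid", 17.0, 0.25, 0.20, 7.0, "cerebral", "head-arms"),
    ("r_ext_carotid", "right external carotid", 17.0, 0.20, 0.15, 7.5, "cerebral", "head-arms"),
    ("r_subclavian", "right subclavian", 3.4, 0.42, 0.42, 5.5, "cardio-thoracic", "head-arms"),
    ("r_vertebral", "right vertebral", 14.8, 0.19, 0.19, 7.0, "cerebral", "head-arms"),
    ("r_brachial", "right brachial", 42.2, 0.40, 0.25, 6.0, "cardio-thoracic", "head-arms"),
    ("arch_b", "aortic arch B", 3.9, 1.30, 1.25, 4.8, "cardio-thoracic", "cardiac-thoracic"),
    ("l_common_carotid", "left common carotid", 20.8, 0.37, 0.37, 5.5, "cerebral", "head-arms"),
    ("l_int_carotid", "left internal carotid", 17.0, 0.25, 0.20, 7.0, "cerebral", "head-arms"),
    ("l_ext_carotid", "left external carotid", 17.0, 0.20, 0.15, 7.5, "cerebral", "head-arms"),
    ("l_subclavian", "left subclavian", 3.4, 0.42, 0.42, 5.5, "cardio-thoracic", "head-arms"),
    ("l_vertebral", "left vertebral", 14.8, 0.19, 0.19, 7.0, "cerebral", "head-arms"),
    ("l_brachial", "left brachial", 42.2, 0.40, 0.25, 6.0, "cardio-thoracic", "head-arms"),
    ("thoracic_aorta", "thoracic aorta", 15.6, 1.25, 1.00, 5.0, "cardio-thoracic", "cardiac-thoracic"),
    ("intercostals", "intercostal trunk", 7.3, 0.30, 0.25, 6.0, "cardio-thoracic", "cardiac-thoracic"),
    ("celiac", "celiac trunk", 2.0, 0.39, 0.39, 5.5, "abdominal", "upper-abdomen"),
    ("gastric", "gastric", 7.1, 0.18, 0.18, 7.0, "abdominal", "upper-abdomen"),
    ("splenic_hepatic", "splenic-hepatic", 6.3, 0.28, 0.28, 6.5, "abdominal", "upper-abdomen"),
    ("abd_aorta_a", "abdominal aorta A", 5.3, 0.95, 0.90, 5.2, "abdominal", "upper-abdomen"),
    ("l_renal", "left renal", 3.2, 0.26, 0.26, 6.5, "abdominal", "lower-abdomen"),
    ("r_renal", "right renal", 3.2, 0.26, 0.26, 6.5, "abdominal", "lower-abdomen"),
    ("mesenteric", "superior mesenteric", 5.9, 0.43, 0.43, 6.0, "abdominal", "lower-abdomen"),
    ("abd_aorta_e", "abdominal aorta E", 10.6, 0.75, 0.65, 5.5, "abdominal", "lower-abdomen"),
    ("l_common_iliac", "left common iliac", 5.8, 0.45, 0.40, 6.5, "lower-limbs", "legs"),
    ("r_common_iliac", "right common iliac", 5.8, 0.45, 0.40, 6.5, "lower-limbs", "legs"),
    ("l_inner_iliac", "left inner iliac", 5.0, 0.20, 0.20, 7.5, "lower-limbs", "legs"),
    ("r_inner_iliac", "right inner iliac", 5.0, 0.20, 0.20, 7.5, "lower-limbs", "legs"),
    ("l_ext_iliac", "left external iliac", 14.4, 0.38, 0.34, 7.0, "lower-limbs", "legs"),
    ("r_ext_iliac", "right external iliac", 14.4, 0.38, 0.34, 7.0, "lower-limbs", "legs"),
    ("l_deep_femoral", "left deep femoral", 12.6, 0.26, 0.26, 7.5, "lower-limbs", "legs"),
    ("r_deep_femoral", "right deep femoral", 12.6, 0.26, 0.26, 7.5, "lower-limbs", "legs"),
    ("l_femoral", "left femoral", 44.3, 0.30, 0.24, 7.5, "lower-limbs", "legs"),
    ("r_femoral", "right femoral", 44.3, 0.30, 0.24, 7.5, "lower-limbs", "legs"),
    ("l_ant_tibial", "left anterior tibial", 34.3, 0.15, 0.13, 8.5, "lower-limbs", "legs"),
    ("r_ant_tibial", "right anterior tibial", 34.3, 0.15, 0.13, 8.5, "lower-limbs", "legs"),
    ("l_post_tibial", "left posterior tibial", 32.1, 0.20, 0.17, 8.5, "lower-limbs", "legs"),
    ("r_post_tibial", "right posterior tibial", 32.1, 0.20, 0.17, 8.5, "lower-limbs", "legs"),
]

JUNCTIONS = [
    ("asc_aorta", ["brachioceph", "arch_a"]),
    ("arch_a", ["l_common_carotid", "arch_b"]),
    ("arch_b", ["l_subclavian", "thoracic_aorta"]),
    ("brachioceph", ["r_common_carotid", "r_subclavian"]),
    ("r_common_carotid", ["r_int_carotid", "r_ext_carotid"]),
    ("l_common_carotid", ["l_int_carotid", "l_ext_carotid"]),
    ("r_subclavian", ["r_vertebral", "r_brachial"]),
    ("l_subclavian", ["l_vertebral", "l_brachial"]),
    ("thoracic_aorta", ["intercostals", "celiac", "abd_aorta_a"]),
    ("celiac", ["gastric", "splenic_hepatic"]),
    ("abd_aorta_a", ["l_renal", "r_renal", "mesenteric", "abd_aorta_e"]),
    ("abd_aorta_e", ["l_common_iliac", "r_common_iliac"]),
    ("l_common_iliac", ["l_ext_iliac", "l_inner_iliac"]),
    ("r_common_iliac", ["r_ext_iliac", "r_inner_iliac"]),
    ("l_ext_iliac", ["l_femoral", "l_deep_femoral"]),
    ("r_ext_iliac", ["r_femoral", "r_deep_femoral"]),
    ("l_femoral", ["l_ant_tibial", "l_post_tibial"]),
    ("r_femoral", ["r_ant_tibial", "r_post_tibial"]),
]

# terminal artery -> (bed, target flow [ml/s], arteriolar pressure [mmHg])
TERMINALS = {
    "r_int_carotid": ("cerebral", 2.16, 80.40),
    "l_int_carotid": ("cerebral", 2.16, 80.40),
    "r_ext_carotid": ("cerebral", 2.34, 80.37),
    "l_ext_carotid": ("cerebral", 2.34, 80.37),
    "r_vertebral": ("cerebral", 1.60, 70.60),
    "l_vertebral": ("cerebral", 1.60, 70.60),
    "r_brachial": ("arms", 4.29, 80.00),
    "l_brachial": ("arms", 4.29, 80.00),
    "intercostals": ("intercostal", 9.93, 85.39),
    "gastric": ("upper-abdomen", 4.92, 48.88),
    "splenic_hepatic": ("upper-abdomen", 5.25, 60.00),
    "l_renal": ("lower-abdomen", 8.50, 66.18),
    "r_renal": ("lower-abdomen", 8.50, 66.18),
    "mesenteric": ("lower-abdomen", 12.93, 60.00),
    "l_inner_iliac": ("legs", 2.20, 78.65),
    "r_inner_iliac": ("legs", 2.20, 78.65),
    "l_deep_femoral": ("legs", 3.08, 68.12),
    "r_deep_femoral": ("legs", 3.08, 68.12),
    "l_ant_tibial": ("legs", 2.01, 38.20),
    "r_ant_tibial": ("legs", 2.01, 38.20),
    "l_post_tibial": ("legs", 1.22, 64.36),
    "r_post_tibial": ("legs", 1.22, 64.36),
}

# bed -> (capillary P, venule P, vein id, region_tag, shift_region, vip)
BEDS = {
    "cerebral": (25.0, 12.0, "ha_veins", "cerebral", "head-arms", "upper"),
    "arms": (25.0, 12.0, "ha_veins", "cardio-thoracic", "head-arms", "upper"),
    "intercostal": (25.0, 13.0, "ivc", "cardio-thoracic", "cardiac-thoracic",
                    "upper"),
    "upper-abdomen": (20.0, 12.94, "uabd_veins", "abdominal",
                      "upper-abdomen", "upper"),
    "lower-abdomen": (18.0, 12.98, "labd_veins", "abdominal",
                      "lower-abdomen", "lower"),
    "legs": (27.13, 15.0, "legs_veins", "lower-limbs", "legs", "lower"),
}

# vein id -> (P, C, V, downstream, region_tag, shift_region, vip)
VEINS = {
    "ha_veins": (6.94, 9.0, 380.0, "svc", "cerebral", "head-arms", "upper"),
    "uabd_veins": (9.00, 14.0, 480.0, "ivc", "abdominal", "upper-abdomen",
                   "upper"),
    "labd_veins": (9.00, 26.0, 850.0, "ivc", "abdominal", "lower-abdomen",
                   "lower"),
    "legs_veins": (7.68, 20.0, 550.0, "ivc", "lower-limbs", "legs", "lower"),
}

VC_PRESSURES = {"svc": 6.48, "ivc": 6.50}
TARGET_TOTAL_VOLUME = 5300.0   # ml
R_CAL = 1.15      # arteriolar-resistance calibration to the target CO


def bed_flow(bed):
    return sum(q for b, q, _ in TERMINALS.values() if b == bed)


def build() -> CardiovascularNetwork:
    net = CardiovascularNetwork(rr=0.8)
    for sid, name, L, rp, rd, pwv, region, shift in SEGMENTS:
        vip = "upper" if shift in ("head-arms", "cardiac-thoracic",
                                   "upper-abdomen") else "lower"
        a0_mean = math.pi * ((rp + rd) / 2.0) ** 2
        net.segments[sid] = Artery1DSegment(
            id=sid, name=name, length=L, r_prox=rp, r_dist=rd, pwv=pwv,
            wall_visc=round(0.01 * math.sqrt(a0_mean), 6),
            region_tag=region, shift_region=shift, vip_side=vip)
    net.junctions = [(p, list(d)) for p, d in JUNCTIONS]
    net.root_segment = "asc_aorta"

    def add(cid, name, cls, r, c, v0, v, downstream, region, shift, vip,
            l=0.0):
        net.compartments[cid] = Compartment0D(
            id=cid, name=name, compartment_class=cls, r=round(r, 6), l=l,
            c=round(c, 6), v0=round(v0, 4), v=round(v, 4),
            downstream=downstream, region_tag=region, shift_region=shift,
            vip_side=vip)

    # one arteriole per terminal artery
    for tid, (bed, q, p_art) in TERMINALS.items():
        p_cap = BEDS[bed][0]
        region, shift, vip = BEDS[bed][3], BEDS[bed][4], BEDS[bed][5]
        c = 0.0025 * q + 0.004
        v0 = 3.0 * q
        add(f"{tid}_art", f"{tid} arterioles", "arteriole",
            R_CAL * (p_art - p_cap) / q, c, v0, v0 + c * p_art,
            f"{bed}_cap", region, shift, vip)
        net.interfaces.append(
            ArteriolarInterface(artery=tid, arteriole=f"{tid}_art",
                                zc="auto"))

    # per-bed capillary and venule compartments
    for bed, (p_cap, p_ven, vein, region, shift, vip) in BEDS.items():
        q = bed_flow(bed)
        p_down = (VC_PRESSURES[vein] if vein in VC_PRESSURES
                  else VEINS[vein][0])
        c_cap = 0.012 * q + 0.10
        v_cap = 3.5 * q
        add(f"{bed}_cap", f"{bed} capillaries", "capillary",
            (p_cap - p_ven) / q, c_cap, v_cap - c_cap * p_cap, v_cap,
            f"{bed}_ven", region, shift, vip)
        c_ven = 0.25 * q
        v_ven = 7.0 * q
        add(f"{bed}_ven", f"{bed} venules", "venule",
            (p_ven - p_down) / q, c_ven, v_ven - c_ven * p_ven, v_ven,
            vein, region, shift, vip)

    # region veins
    vein_flow = {
        "ha_veins": bed_flow("cerebral") + bed_flow("arms"),
        "uabd_veins": bed_flow("upper-abdomen"),
        "labd_veins": bed_flow("lower-abdomen"),
        "legs_veins": bed_flow("legs"),
    }
    for vid, (p, c, v, down, region, shift, vip) in VEINS.items():
        p_down = VC_PRESSURES[down]
        add(vid, vid.replace("_", " "), "vein",
            (p - p_down) / vein_flow[vid], c, v - c * p, v, down,
            region, shift, vip)

    # venae cavae
    add("svc", "superior vena cava", "vena-cava", 0.010, 1.5,
        80.0 - 1.5 * 6.48, 80.0, "RA", "cardio-thoracic",
        "cardiac-thoracic", "upper")
    add("ivc", "inferior vena cava", "vena-cava", 0.004, 3.0,
        150.0 - 3.0 * 6.50, 150.0, "RA", "abdominal", "lower-abdomen",
        "lower")

    # pulmonary circulation
    add("pulm_art", "pulmonary arteries", "pulmonary-artery", 0.080, 2.0,
        110.0 - 2.0 * 15.42, 110.0, "pulm_vein", "cardio-thoracic",
        "cardiac-thoracic", "upper", l=0.0003)
    add("pulm_vein", "pulmonary veins", "pulmonary-vein", 0.012, 9.0,
        340.0 - 9.0 * 8.39, 340.0, "LA", "cardio-thoracic",
        "cardiac-thoracic", "upper")

    # heart
    for chid, emin, eamp, v0, v in (("LA", 0.18, 0.13, 20.0, 62.0),
                                    ("LV", 0.10, 2.28, 5.0, 120.0),
                                    ("RA", 0.15, 0.10, 18.0, 61.0),
                                    ("RV", 0.05, 0.55, 6.0, 128.0)):
        net.chambers[chid] = HeartChamber(
            id=chid, e_min=emin, e_amp=eamp, v0=v0, v=v,
            region_tag="cardio-thoracic", shift_region="cardiac-thoracic",
            vip_side="upper")
    for vid, cq in (("MV", 400.0), ("AV", 350.0), ("TV", 400.0),
                    ("PV", 350.0)):
        net.valves[vid] = ValveState(id=vid, cq=cq)

    net.baroreflex = BaroreflexBlock(setpoint=95.2, hr_baseline=75.0)

    # pad the venous reservoirs so the total blood volume hits the target
    # (added to both V and V0, so pressures are unchanged)
    total = (sum(c.v for c in net.compartments.values())
             + sum(ch.v for ch in net.chambers.values())
             + sum(s.rest_volume() for s in net.segments.values()))
    deficit = TARGET_TOTAL_VOLUME - total
    pads = ["ha_veins", "uabd_veins", "labd_veins", "legs_veins", "ivc"]
    pad_tot = sum(net.compartments[p].v for p in pads)
    for pid in pads:
        c = net.compartments[pid]
        share = deficit * c.v / pad_tot
        c.v = round(c.v + share, 4)
        c.v0 = round(c.v0 + share, 4)
    return net


def main():
    net = build()
    text = serialize_network(net)
    header = (
        "# Supine-1G baseline parameter document (synthetic).\n"
        "# Assembled from standard human arterial-tree geometry and\n"
        "# lumped-parameter values of the physiological modeling\n"
        "# literature; terminal resistances set the textbook supine\n"
        "# operating point. Regenerate with scripts/build_baseline.py.\n")
    out = (pathlib.Path(__file__).resolve().parents[1]
           / "src" / "cardioloop" / "data" / "supine_1g_synthetic.yaml")
    out.write_text(header + text)
    # round-trip sanity check
    net2 = load_network(str(out))
    assert serialize_network(net2) == text
    vol = net2.total_blood_volume()
    print(f"wrote {out} ({len(net2.segments)} segments, "
          f"{len(net2.compartments)} compartments, total volume "
          f"{vol:.1f} ml)")


if __name__ == "__main__":
    main()
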