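import numpy as np
import pytest

from cardioloop import (GravityConfigDelta, GravityConfigError,
                        apply_blood_shift, apply_cardiac_changes,
                        apply_vascular_changes, apply_volume_reduction,
                        configure_0g, load_delta, load_network,
                        load_packaged_network)


@pytest.fixture
def delta():
    return load_delta()


def two_zone_region_net(units):
    """One region with two zones of 100 ml and 300 ml (all other regions
    empty of volume is not allowed, so they hold a token zone each)."""
    comps = [
        {"id": "z1", "class": "vein", "r": 1.0, "c": 10.0, "v0": 80.0,
         "v": 100.0, "downstream": "z2", "shift_region": "legs",
         "vip_side": "lower", "region_tag": "lower-limbs"},
        {"id": "z2", "class": "vein", "r": 1.0, "c": 30.0, "v0": 240.0,
         "v": 300.0, "downstream": "z1", "shift_region": "legs",
         "vip_side": "lower", "region_tag": "lower-limbs"},
    ]
    for i, region in enumerate(("head-arms", "cardiac-thoracic",
                                "upper-abdomen", "lower-abdomen")):
        comps.append({"id": f"pad{i}", "class": "vein", "r": 1.0,
                      "c": 10.0, "v0": 160.0, "v": 200.0,
                      "downstream": f"pad{(i + 1) % 4}",
                      "shift_region": region,
                      "vip_side": "upper" if i < 3 else "lower",
                      "region_tag": "cardio-thoracic"})
    return load_network({"units": units, "compartments": comps})


class TestDelta:
    def test_packaged_delta_zero_sum(self, delta):
        assert sum(delta.blood_shift_ml.values()) == 0.0
        assert delta.volume_reduction_fraction == 0.115
        assert delta.ventricular_e_amp_factor == 0.73
        assert delta.chamber_v0_factor == 0.10
        assert delta.legs_venous_c_factor == 1.27

    def test_non_zero_sum_rejected(self, delta):
        delta.blood_shift_ml["legs"] += 5.0
        with pytest.raises(GravityConfigError, match="sum to 0"):
            delta.validate()

    def test_negative_factor_rejected(self, delta):
        delta.legs_venous_c_factor = -1.0
        with pytest.raises(GravityConfigError):
            delta.validate()


class TestBloodShift:
    def test_proportional_split_within_region(self, units, delta):
        net = two_zone_region_net(units)
        delta.blood_shift_ml = {"legs": 40.0, "lower-abdomen": -40.0,
                                "head-arms": 0.0, "cardiac-thoracic": 0.0,
                                "upper-abdomen": 0.0}
        apply_blood_shift(net, delta)
        assert net.compartments["z1"].v == pytest.approx(110.0, rel=1e-12)
        assert net.compartments["z2"].v == pytest.approx(330.0, rel=1e-12)

    def test_total_volume_conserved(self, baseline_net, delta):
        before = baseline_net.total_blood_volume()
        apply_blood_shift(baseline_net, delta)
        assert baseline_net.total_blood_volume() == pytest.approx(
            before, rel=1e-12)

    def test_v0_over_v_preserved(self, baseline_net, delta):
        ratios = {c.id: c.v0 / c.v
                  for c in baseline_net.compartments.values()}
        apply_blood_shift(baseline_net, delta)
        for c in baseline_net.compartments.values():
            assert c.v0 / c.v == pytest.approx(ratios[c.id], abs=1e-12)

    def test_excessive_shift_rejected(self, units, delta):
        net = two_zone_region_net(units)
        delta.blood_shift_ml = {"legs": -500.0, "lower-abdomen": 500.0,
                                "head-arms": 0.0, "cardiac-thoracic": 0.0,
                                "upper-abdomen": 0.0}
        with pytest.raises(GravityConfigError, match="exceeds"):
            apply_blood_shift(net, delta)


class TestVolumeReduction:
    def test_requires_prior_shift(self, baseline_net):
        with pytest.raises(GravityConfigError, match="after the blood"):
            apply_volume_reduction(baseline_net, 0.115)

    def test_exact_multiplicative_reduction(self, baseline_net, delta):
        apply_blood_shift(baseline_net, delta)
        before = baseline_net.total_blood_volume()
        apply_volume_reduction(baseline_net, 0.115)
        assert baseline_net.total_blood_volume() == pytest.approx(
            0.885 * before, rel=1e-12)

    def test_fraction_zero_is_identity(self, baseline_net, delta):
        apply_blood_shift(baseline_net, delta)
        vols = {c.id: c.v for c in baseline_net.compartments.values()}
        apply_volume_reduction(baseline_net, 0.0)
        for c in baseline_net.compartments.values():
            assert c.v == vols[c.id]

    def test_v0_over_v_preserved(self, baseline_net, delta):
        apply_blood_shift(baseline_net, delta)
        ratios = {c.id: c.v0 / c.v
                  for c in baseline_net.compartments.values()}
        apply_volume_reduction(baseline_net, 0.115)
        for c in baseline_net.compartments.values():
            assert c.v0 / c.v == pytest.approx(ratios[c.id], abs=1e-12)


class TestCardiacVascularChanges:
    def test_cardiac_factors_exact(self, baseline_net, delta):
        e_amp = {c: baseline_net.chambers[c].e_amp for c in ("LV", "RV")}
        e_min = {c: baseline_net.chambers[c].e_min for c in ("LV", "RV")}
        v0 = {c: ch.v0 for c, ch in baseline_net.chambers.items()}
        c_pa = next(c.c for c in baseline_net.compartments.values()
                    if c.compartment_class == "pulmonary-artery")
        c_pv = next(c.c for c in baseline_net.compartments.values()
                    if c.compartment_class == "pulmonary-vein")
        apply_cardiac_changes(baseline_net, delta)
        for cid in ("LV", "RV"):
            assert baseline_net.chambers[cid].e_amp == pytest.approx(
                0.73 * e_amp[cid], rel=1e-12)
            assert baseline_net.chambers[cid].e_min == pytest.approx(
                1.03 * e_min[cid], rel=1e-12)
        for cid, ch in baseline_net.chambers.items():
            assert ch.v0 == pytest.approx(0.10 * v0[cid], rel=1e-12)
        assert next(c.c for c in baseline_net.compartments.values()
                    if c.compartment_class == "pulmonary-artery") == \
            pytest.approx(1.04 * c_pa, rel=1e-12)
        assert next(c.c for c in baseline_net.compartments.values()
                    if c.compartment_class == "pulmonary-vein") == \
            pytest.approx(1.05 * c_pv, rel=1e-12)

    def test_vascular_factors_and_scope(self, baseline_net, delta):
        before_c = {c.id: c.c for c in baseline_net.compartments.values()}
        before_r = {c.id: c.r for c in baseline_net.compartments.values()}
        apply_vascular_changes(baseline_net, delta)
        for c in baseline_net.compartments.values():
            if (c.shift_region == "legs"
                    and c.compartment_class in ("vein", "venule")):
                assert c.c == pytest.approx(1.27 * before_c[c.id],
                                            rel=1e-12)
            else:
                assert c.c == before_c[c.id]
            if c.compartment_class == "arteriole":
                if c.region_tag == "cerebral":
                    assert c.r == pytest.approx(1.10 * before_r[c.id],
                                                rel=1e-12)
                elif c.vip_side == "lower":
                    assert c.r == pytest.approx(0.90 * before_r[c.id],
                                                rel=1e-12)
                else:
                    assert c.r == before_r[c.id]
            else:
                assert c.r == before_r[c.id]


class TestFullPipeline:
    def test_total_volume_is_0_885_of_baseline(self, baseline_net):
        before = baseline_net.total_blood_volume()
        net, report = configure_0g(baseline_net)
        assert net.gravity_tag == "0g"
        assert net.total_blood_volume() == pytest.approx(0.885 * before,
                                                         rel=1e-12)
        assert report

    def test_rerun_rejected(self, baseline_net):
        net, _ = configure_0g(baseline_net)
        with pytest.raises(GravityConfigError, match="already"):
            configure_0g(net)

    def test_baroreflex_baselines_shifted(self, baseline_net):
        h0 = baseline_net.baroreflex.hr_baseline
        s0 = baseline_net.baroreflex.setpoint
        net, _ = configure_0g(baseline_net)
        assert net.baroreflex.hr_baseline == pytest.approx(1.13 * h0)
        assert net.baroreflex.setpoint == pytest.approx(0.90 * s0)

    def test_change_report_families_closed(self, baseline_net):
        _, report = configure_0g(baseline_net)
        families = {entry["parameter"] for entry in report}
        assert families <= {"volume", "e_amp", "e_min", "v0", "C", "R",
                            "hr_baseline", "setpoint"}
        # every family named by the change set appears
        assert {"volume", "e_amp", "e_min", "v0", "C", "R",
                "hr_baseline", "setpoint"} <= families

    def test_order_enforced(self, baseline_net):
        with pytest.raises(GravityConfigError):
            apply_volume_reduction(baseline_net, 0.115)

    def test_1d_segments_participate_in_volume_scaling(self, baseline_net):
        seg_vol = {s.id: s.volume() for s in baseline_net.segments.values()}
        net, _ = configure_0g(baseline_net)
        changed = [s.id for s in net.segments.values()
                   if abs(s.volume() - seg_vol[s.id]) > 1e-9]
        assert changed  # arterial lumens were rescaled per region
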