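# Chronic microgravity (long-term spaceflight, no dedicated
# countermeasures) change set applied to the supine-1G baseline.
# Regional blood shifts sum to zero; the volume reduction acts on the
# post-shift configuration; V0/V ratios are preserved by both.
blood_shift_ml:
  legs: -235.0
  lower-abdomen: -234.0
  head-arms: 133.0
  cardiac-thoracic: 202.0
  upper-abdomen: 134.0
volume_reduction_fraction: 0.115
cardiac:
  ventricular_e_amp_factor: 0.73     # contractility amplitude -27%
  ventricular_e_min_factor: 1.03     # baseline ventricular stiffness +3%
  pulmonary_artery_c_factor: 1.04
  pulmonary_vein_c_factor: 1.05
  chamber_v0_factor: 0.10            # cardiac volume change via V0 -90%
vascular:
  legs_venous_c_factor: 1.27
  vertebral_carotid_r_factor: 1.10
  lower_body_r_factor: 0.90
baroreflex:
  hr_baseline_factor: 1.13
  setpoint_factor: 0.90
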