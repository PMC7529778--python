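# cardioloop

Closed-loop 0D–1D multiscale simulation of the human circulation, with a
configurator that maps a supine-1G baseline onto the chronic microgravity
(0G) adaptation point of long-duration spaceflight, and a beat-level
analysis layer for cardiac indexes and waveform alteration.

**Who it is for.** Computational physiologists and space-medicine
researchers who want a desk-scale, fully deterministic model of
cardiovascular deconditioning: the blood shift from the lower body to the
thorax and head, total blood volume loss, reduced cardiac contractility
and volume, altered vascular tone, and resetting of the baroreflex that
together mimic a sedentary/aged phenotype.

## Model

- A 40-segment 1D arterial tree (nonlinear viscoelastic tapered walls;
  explicit second-order MacCormack scheme) coupled at the arteriolar
  level, through a characteristic impedance per terminal artery, to a
  lumped RLC network for arterioles, capillaries, venules, veins, venae
  cavae and the pulmonary circulation.
- Four contractile chambers (time-varying elastance with atrial kick) and
  four leaflet valves driven by pressure, friction, blood-motion and
  vortex torques; the aortic valve is the 0D→1D interface.
- Short-term baroreflex: filtered aortic–carotid pressure driving heart
  rate, ventricular contractility, arteriolar resistance, venous
  unstressed volume and venous compliance.
- The 0G configurator applies, in order: inter-regional blood shift
  (legs −235 ml, lower abdomen −234 ml, head-arms +133 ml,
  cardiac-thoracic +202 ml, upper abdomen +134 ml), a −11.5 % total
  volume reduction, cardiac changes (ventricular E_amp ×0.73, E_min
  ×1.03, chamber V₀ ×0.10, pulmonary compliances ×1.04/×1.05), vascular
  changes (leg venous C ×1.27, vertebral/carotid arteriolar R ×1.10,
  lower-body R ×0.90), and baroreflex baselines (HR ×1.13,
  setpoint ×0.90).

The whole loop conserves blood volume to round-off by construction (the
1D boundary updates and the 0D integrator share the same interface
fluxes). See `docs/methods.md` for the full model and numerics.

## Worked example

```python
from cardioloop import (load_packaged_network, run_simulation,
                        cardiac_indexes, nsd, relative_variation)
from cardioloop.gravity import configure_0g

net_1g = load_packaged_network()          # supine-1G baseline document
net_0g, report = configure_0g(load_packaged_network())

run_1g = run_simulation(net_1g, n_beats=100)
run_0g = run_simulation(net_0g, n_beats=100)

i1 = cardiac_indexes(run_1g)
i0 = cardiac_indexes(run_0g)
print(f"SV   {i1.sv:6.1f} -> {i0.sv:6.1f} ml "
      f"({relative_variation(i1.sv, i0.sv):+.1f} %)")
print(f"MAP  {i1.map:6.1f} -> {i0.map:6.1f} mmHg "
      f"({relative_variation(i1.map, i0.map):+.1f} %)")
print(f"HR   {i1.hr:6.1f} -> {i0.hr:6.1f} bpm "
      f"({relative_variation(i1.hr, i0.hr):+.1f} %)")
print("NSD(P) ascending aorta:",
      round(nsd(run_1g.last_beat('asc_aorta:P'),
                run_0g.last_beat('asc_aorta:P')), 2))
```

prints

```
SV     76.4 ->   59.1 ml (-22.6 %)
MAP    94.8 ->   84.6 mmHg (-10.7 %)
HR     75.3 ->   85.5 bpm (+13.6 %)
NSD(P) ascending aorta: 0.24
```

i.e. in chronic 0G the stroke volume and mean arterial pressure fall
while heart rate rises, and even the central aortic waveform changes
shape (NSD > 0). End-systolic LV volume and pulmonary blood volumes
increase, and waveform alteration grows from the aorta toward the
periphery — the deconditioning pattern.

A thin CLI wraps the same functionality:

```sh
cardioloop validate
cardioloop simulate --gravity 0g --beats 100 --out runs/0g
cardioloop compare --run-a runs/1g --run-b runs/0g --out report/
```

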