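# Methods

## Model overview

`cardioloop` simulates the closed human circulation as a 0D–1D multiscale
system:

- **1D arterial tree** — 40 tapered segments from the ascending aorta to
  the tibial arteries (both body sides), governed by the one-dimensional
  mass and momentum balances with a Poiseuille-type dissipation term and
  blood inertia, closed by a nonlinear tube law

  P(A, x, t) = P_ext + β(x)/A₀(x) · (√A − √A₀) + Γ(x)/(A₀√A) · ∂A/∂t.

  The elastic coefficient β is set per segment from a reference pulse-wave
  velocity; the Kelvin–Voigt coefficient Γ adds wall viscoelasticity.
- **0D compartments** — arterioles (one per terminal artery), and per-bed
  capillaries, venules, veins, the venae cavae, and the pulmonary arterial
  and venous compartments, each an RLC element obeying V = V₀ + C·P with a
  resistive (optionally inertial) outflow link.
- **Heart** — four contractile chambers with time-varying elastance
  E(t) = E_min + E_amp·e(t/RR); atrial activation opens the beat (atrial
  kick), ventricular activation follows after an AV delay. The four valves
  are leaflet models driven by four torques (transvalvular pressure,
  tissue friction, blood motion on the leaflet, downstream vortex) with an
  orifice flow law.
- **Interfaces** — 1D→0D at the arteriolar level through a characteristic
  impedance Z_c per terminal artery (computed from the local tube law by
  default); 0D→1D at the aortic valve, where the inlet solve couples the
  left-ventricular pressure, the valve orifice and the backward
  characteristic of the ascending aorta. A closed aortic valve gives zero
  inflow and pure reflection.
- **Baroreflex** — the afferent branch low-pass filters a 50/50 weighted
  mean of aortic-root and common-carotid pressure; five effector families
  (heart rate, ventricular elastance amplitudes, arteriolar resistances,
  venous unstressed volumes, venous compliances) follow sigmoidal static
  curves centred at the setpoint with first-order lags.

## Numerics

- Hyperbolic core: explicit two-step MacCormack on a uniform per-segment
  grid, Δx ≤ 0.25 cm by default. The global time step is the CFL limit of
  the diastolic initial state times a default CFL number of 0.6; the
  margin covers the systolic increase of wave speed and advective
  velocity, and the CFL condition is re-checked during the run.
- **Conservative coupling.** The mass update is written in flux form with
  half-cell finite-volume updates at the two boundary nodes of every
  segment, and the 0D side integrates the identical interface fluxes.
  Consequently each segment's discrete volume changes by exactly
  dt·(Q_in − Q_out) per step and the whole loop conserves blood volume to
  round-off (measured drift ≈ 10⁻¹⁵ per beat). Boundary states come from
  the outgoing Riemann invariants (u ± 4c for the square-root tube law)
  interpolated at the foot of the characteristic.
- Junctions impose exact mass conservation and continuity of total
  pressure (P + ρu²/2), solved by Newton iteration on the port areas while
  preserving each segment's outgoing characteristic. The arrow-shaped
  Jacobian is inverted in closed form, and all junctions are solved as one
  padded batch per step.
- The viscoelastic wall stress is evaluated with the area rate of the
  current step and carried in the pressure array (a lagged, semi-explicit
  treatment rather than a separate diffusion substep). Explicit stability
  caps the usable Γ well below fully physiological wall viscosity; the
  default Γ = 0.01·√A₀ provides mild high-frequency damping and the
  mechanism is exercised by tests, but quantitative viscoelastic damping
  of real arteries is under-resolved — a known limitation.
- 0D compartments use the same global dt, explicitly and staggered with
  the 1D step; inertial links are semi-implicit in R. Valve leaflet ODEs
  are explicit; the orifice law carries a small linear series resistance
  (0.002 mmHg·s/ml) for robustness near flow reversal.
- Beats are quantized to a whole number of time steps so consecutive
  beats align exactly in phase; the beat-to-beat convergence metric is the
  relative L2 distance of the aortic-root pressure between consecutive
  beats, sampled at full rate. Runs flag (not reject) a final metric
  above 10⁻³.
- Degenerate cases: vessel collapse (A → 0) aborts the run with segment
  and location rather than clamping; a constant signal cannot be
  amplitude-normalized and raises; junction/interface Newton failures
  raise with residuals.

## Parameter provenance and calibration

The packaged supine-1G document (`supine_1g_synthetic.yaml`) is a
synthetic parameterization assembled from standard human arterial-tree
geometry (lengths, radii, wave speeds of the classic multi-branch
datasets) and textbook lumped values. Terminal arteriolar resistances are
set from target regional mean flows and arteriolar pressures of the
supine operating point, with a single global calibration factor (1.15) so
cardiac output lands near 5.8 l/min at MAP ≈ 95 mmHg; venous reservoir
volumes are padded so the total blood volume is 5300 ml. Chamber
elastances balance a left-ventricular end-systolic volume ≈ 46 ml and
end-diastolic volume ≈ 122 ml at HR 75. Baroreflex gains are set at
low-normal sensitivity (HR gain 0.08 ≈ 0.8 bpm/mmHg) with time constants
of 3–12 s. These choices were made once for the 1G baseline; the 0G
configuration is never tuned — it is produced solely by the configurator
below.

The simulated operating points are physiological but not a transcription
of any specific published parameter set, so absolute magnitudes (e.g. SV,
PP) differ from any particular reference study at the 10–20 % level; the
package therefore treats *relative* 1G→0G responses and their signs and
spatial patterns as the primary outputs.

## The weightlessness configurator

`configure_0g` maps a 1G-tagged network to the chronic-0G adaptation
point in a fixed order:

1. **Blood shift** (ml): legs −235, lower abdomen −234, head-arms +133,
   cardiac-thoracic +202, upper abdomen +134 (zero-sum). Within each
   region every zone's volume scales proportionally to its share, V₀/V is
   preserved exactly, and 1D segments participate through their
   unstressed areas.
2. **Blood volume reduction** −11.5 %, multiplicative on the post-shift
   configuration, again preserving V₀/V.
3. **Cardiac changes**: ventricular E_amp ×0.73, ventricular E_min ×1.03,
   pulmonary arterial C ×1.04, pulmonary venous C ×1.05, all chamber V₀
   ×0.10.
4. **Vascular changes**: leg venous compliance ×1.27, cerebral
   (vertebral/carotid territory) arteriolar resistance ×1.10, all
   lower-body arteriolar resistance ×0.90.
5. **Baroreflex baselines**: HR baseline ×1.13, setpoint ×0.90; gains and
   time constants unchanged.

The transform is order-sensitive (the reduction acts on the post-shift
state), guarded against double application, and emits a change report
with before/after values for every touched parameter.

## What the simulations show (and what they do not)

Both configurations are run for 100 beats; transients are extinguished
well before that (final beat-to-beat metric ≈ 10⁻⁶). The 0G state
reproduces the qualitative deconditioning response: stroke volume,
ejection fraction, cardiac output, MAP, central pulse pressure, stroke
work, tension–time index, rate–pressure product and CVP all fall;
end-systolic LV volume and pulmonary blood volumes rise; waveform
alteration (NSD) grows from proximal to distal along the arterial
pathway and affects flow waveforms more than pressure waveforms at most
sites. Because the baseline is an independent parameterization, the
magnitudes of these changes carry the model's own scale, not that of any
specific published table; the regression module reports residuals against
published reference values at two tolerance tiers without asserting them.

Not modelled: an explicit gravity force term (the 0G state is configured,
not dynamically produced), interstitial fluid exchange, countermeasures,
partial-gravity states, autoregulation of the microcirculation, and
long-term neurohumoral control (the chronic adaptation enters through the
configured parameter changes).

## Reported quantities

Cardiac indexes follow their standard definitions: SV = V_lved − V_lves,
EF = SV/V_lved, CO = SV·HR, SW = area of the LV pressure–volume loop,
TTI = beat integral of ascending-aortic pressure over the aortic-valve
open window, RPP = HR × systolic aortic pressure, CVP = mean of the
beat-averaged SVC and IVC pressures. The augmentation index uses an
inflection-point decomposition of the central aortic beat
(Savitzky–Golay-smoothed second derivative; the crossing nearest the
systolic peak); since no unique algorithm exists for AI, its absolute
value is algorithm-dependent and only its direction of change is treated
as meaningful. Waveform similarity uses NSD = ∫₀¹|y′₁G − y′₀G|dt′ on
amplitude- and time-normalized beats (population σ, trapezoidal
quadrature on a common 1000-point grid), with identities NSD ∈ [0,2],
symmetry, NSD = 0 for identical shapes, NSD = 2 only for complementary
centred steps, and NSD ≤ √(2(1−ρ)).
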