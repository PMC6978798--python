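# Methods

## Circuit model

A myelinated fiber is discretized into compartments along the morphology.
Unmyelinated compartments (soma, dendrites, AIS, nodes, cut end) carry the
usual parallel R_m/C_m membrane to the bath. Myelinated compartments
(internodes, paranodes) carry **two stacked layers**:

- axolemma (R_m, C_m) between the core and the periaxonal rail,
- myelin sheath (R_my, C_my) between the periaxonal rail and the bath.

Both rails are longitudinally resistive: the core through the axoplasm
(R_i, Ω·cm over the core cross-section) and the periaxonal rail through the
submyelin annulus (r_pa, Ω/cm in internodes; r_pn in the tighter paranodal
gaps). At the outer paranodal edges the periaxonal rail contacts the bath
(`SolverConfig.ground_myelin_ends`). The state vector holds absolute core and
periaxonal potentials; derived observables are

```
V_m   = core − periaxonal      (transaxonal)
V_my  = periaxonal             (transmyelin, bath = 0)
V_mym = core                   (transfiber), so V_mym = V_m + V_my
```

Single-cable mode (`mode="SC"`) merges the two layers in series per
compartment and drops the periaxonal unknowns; `DC_no_rpn` removes the
distinct paranodal axial resistance.

### Units

mV, ms, nA, µS, nF internally. Parameters: R_i in Ω·cm; R_m, R_my in
kΩ·cm²; C_m, C_my in µF/cm²; r_pa, r_pn in Ω/cm; lengths in µm, widths in
nm. Resting potential −75 mV; the periaxonal rail rests at 0 mV (bath).

## Ultrastructure algebra

For a core of diameter d wrapped at periaxonal width δ_pa, the annulus
cross-section gives `r_pa = R_pa / (π δ_pa (d + δ_pa))` with R_pa the fluid
resistivity; the same relation inverts to width or resistivity. The sheath of
n_my lamellae (2·n_my membranes) has `R_my = 2 n_my R_mm` and
`C_my = C_mm / (2 n_my)` for per-membrane values R_mm, C_mm, so an apparent
C_my measured electrically converts to a lamellae count via
`n_my = C_m / (2 C_my)` when C_mm = C_m. The optical resolving distance
`1.22 λ / (NA_obj + NA_cond)` bounds what light microscopy can say about
these widths. Sub-nanometer periaxonal widths are rejected (below the ~0.78 nm
Debye screening scale the continuum resistivity model is meaningless).

## Numerics

- **Discretization**: d_lambda rule — compartment length ≤ `d_lambda` times
  the AC length constant at the fastest membrane time constant
  (`tau_min_ms`), per section.
- **Time stepping**: sparse backward Euler (default, L-stable) or
  Crank–Nicolson (second order). Stimuli are piecewise-constant per step,
  evaluated at the step midpoint. Dirichlet voltage clamps by row
  substitution.
- **Exact route** (`method="eigen"`): the passive system
  `M dx/dt = −G x + b(t)` with symmetric positive semidefinite G and diagonal
  M is solved by the generalized symmetric eigendecomposition
  `eigh(G, M)` exactly per piecewise-constant stimulus segment. Used for
  synthetic data generation and fitting (thousands of forward evaluations).
- **Verification**: a dense matrix-exponential oracle reproduces
  Crank–Nicolson at dt = 1 µs to < 1 µV on ≤ 20-compartment two-layer
  systems (backward Euler's first-order error leaves ~6 µV and is why the
  oracle test uses CN); an optional per-step Kirchhoff residual check
  (`check_balance`) stays < 10⁻⁹ relative. The eigen and stepping routes
  cross-check in tests, and the sealed double cable (r_pa, r_pn at the upper
  fit bound, paranodal grounds removed) matches the single cable to < 0.5 %
  of signal range — the single cable nests inside the double-cable parameter
  space.
- **Pipette**: an optional explicit electrode — a tapered chain of
  compartments with wall capacitance from the coaxial-dielectric formula and
  a bridge-balance series resistance.

## Active channels

Generic Boltzmann/cosh HH-style kinetics for Nav, Kv1, Kv7, HCN with Q10
scaling, assigned per axonal domain (node, internode, AIS, soma, dendrite
with a proximal→distal Nav gradient, cut end). Gates advance by exponential
Euler staggered with a backward-Euler voltage step. These are *generic*
kinetics chosen to give a ~1 ms cortical-style AP: sign relations
(node-vs-internode amplitudes, CV trends with C_my, δ_pa, internodal Nav)
are robust to the kinetics, but exact thresholds — e.g. the internodal-Nav
multiplier at which regenerative internodal spiking first appears — are
kinetics-dependent and not calibrated.

### Conduction velocity

Onset markers: first prominent peak of d³V/dt³ (model traces; a height floor
at 50 % of the largest third derivative rejects the electrotonic foot of
upstream activity), a 3×noise dV/dt threshold clipped to 60–120 V/s
(recorded-style traces), or the time of maximal dV/dt with parabolic
refinement (`upstroke_peak`; most jitter-robust, used in parameter sweeps).
With ≥ 3 sites CV comes from a least-squares regression of onset on path
distance.

Structural sweeps (`sensitivity_sweep`) treat the submyelin space as one
continuous annulus whose paranodal stretch differs in *resistivity*, not
width: a δ_pa sweep rescales the paranodal gap by the same factor and
re-derives both r_pa and r_pn at fixed fluid resistivities. Widening δ_pa to
1 µm collapses CV to the unmyelinated comparator's.

## Fitting

- **Preprocessing**: per level/site, trials are baselined over the late
  pre-pulse window; a trial is rejected when sustained excursions
  (≥ 0.1 ms) beyond mean ± 2 SD exceed 5 % of samples; survivors are
  averaged and per-site noise floors recorded.
- **Windows**: injecting electrodes are scored from 0.5 ms after the pulse
  (uncompensated pipette artifacts); recording-only electrodes from pulse
  onset — their artifact-free rising phase carries most of the
  myelin-parameter information.
- **Objective**: mean over traces of windowed MSE (mV²).
- **Search**: per mode, free parameters live in normalized log space with
  physically derived bounds. `optimize` runs `n_runs` independent
  evolutionary searches (tournament selection, uniform crossover, Gaussian
  mutation annealed 10× over the run, elitism), stops a run after 5
  consecutive generations improving by less than the target's noise floor,
  then refines the best candidate with Powell's direction-set method. All
  returned solutions are in bounds; dispersion across solutions flags
  unidentifiable parameters.
- **Circuit comparison**: `compare_circuits` fits each mode (SC, SC with
  R_my/C_my tied to 20·R_m / 0.05·C_m, per-internode SC, split-R_m SC, DC,
  DC without r_pn) to the same targets and ranks best MSE.

### Identifiability of R_my (known limitation)

For a 1.1 µm axon with 110 µm internodes, the myelin conductive shunt per
internode is ~16 pS (R_my = 240 kΩ·cm² over 3.8×10⁻⁶ cm²) in parallel with a
~2 nS escape through the paranodal periaxonal pathway to ground. Changing
R_my ±30 % moves somatic/axonal step responses by ~0.002 mV — an order of
magnitude below the effective noise of trial-averaged recordings
(0.08 mV/√30 ≈ 0.015 mV). R_my therefore cannot be recovered from this
protocol at realistic noise (fits drift to a bound), while C_my survives
through the fast charge-redistribution transient and r_pa/r_pn through the
periaxonal discharge pathway. This is a property of the physics, not of the
optimizer; imaging under the sheath or protocols that isolate the myelin DC
leak would be needed to pin R_my.

## Synthetic world

The generator builds a stylized pyramidal cell: soma, two equivalent-cylinder
dendrites, 45 µm AIS, then a 1.1 µm axon with a heminode flush at the start,
6 internodes (L = 100 µm per µm of diameter; the first two halved),
2.3 µm paranodes, 1 µm nodes, and an unmyelinated cut end. Ground truth
follows the ultrastructural laws: n_my = round(10.5·d), R_my = 2·n_my·R_mm,
C_my = C_mm/(2·n_my), r_pa/r_pn from (δ_pa = 12.3 nm, R_pa = 53.7 Ω·cm;
δ_pn = 7.4 nm, R_pn = 550 Ω·cm). Recordings: 2 ms current steps
(±300…±600 pA) in 100 ms sweeps at 50 kHz, 4-pole Bessel-shaped noise,
30 trials/level, optional square artifacts for the rejection machinery; all
seeded. EM-like tables draw δ_pa from a truncated normal matching the
reported mean/range. Dye traces get hidden per-site gains and offsets plus a
calibration step attenuated by `exp(−x/k)`; calibration cancels the gain
exactly.

## Tolerances used in the acceptance tests

Worked ultrastructure values to 3 significant figures; solver oracle < 1 µV
at dt = 1 µs with charge residual < 10⁻⁹; SC nesting < 0.5 % of range;
temporal saltation strict inequalities (DC) vs ≤ one time step (SC);
recovery within 10 % (R_i, R_m, C_m), 30 % (R_my, C_my — R_my is expected to
fail, see above), 2× (r_pa); DC ranked first in ≥ 95 % of 20 seeds; sign
checks qualitative; dye round trip within generator noise and e⁻¹
attenuation exact at x = k.
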