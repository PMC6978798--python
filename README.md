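# periaxon

Double-cable biophysics of myelinated axons: simulation, ultrastructure
algebra, evolutionary circuit fitting, and saltation analysis.

## The science

Textbook models treat the myelin sheath and the axolemma beneath it as a
single merged membrane, so the potential across the axolemma under the myelin
is not even representable. `periaxon` models the myelinated axon as **two
coupled cables**: the axon core and the nanometer-scale **periaxonal space**
between the axolemma and the innermost myelin membrane. The periaxonal space
is a long (~100 µm per internode), extremely thin (~12 nm) conductive annulus
that reaches the extracellular bath only through the even thinner paranodal
gaps at each end. Its longitudinal resistance is enormous (~10¹¹ Ω/cm), which
makes three distinct potentials physically meaningful and experimentally
observable:

- **V_m** — transaxonal: across the axolemma (core minus periaxonal),
- **V_my** — transmyelin: across the sheath (periaxonal minus bath),
- **V_mym** — transfiber: across the whole fiber (core minus bath).

The double cable predicts **temporal saltation**: as a nodal action potential
spreads passively under the myelin, the transaxonal depolarization arrives at
the *next node* before it peaks in the *middle of the internode* it crossed —
the AP appears to jump from node to node, while the transfiber potential
advances smoothly. A single-cable model cannot produce this. The double cable
also explains why apparent myelin capacitance measured from the soma
understates the anatomical lamellae count, and why conduction velocity
collapses as the periaxonal space widens.

### What's in the box

| module | contents |
| --- | --- |
| `periaxon.ultrastructure` | closed-form algebra linking circuit parameters to EM anatomy: periaxonal width ↔ axial resistance ↔ fluid resistivity, lamellae count ↔ sheath capacitance, g-ratio, optical resolving distance |
| `periaxon.morphology` | sections/trees, axon domain annotation (nodes, paranodes, internodes), SWC and YAML I/O, validation |
| `periaxon.cable_core` | two-layer compartment graphs, sparse implicit solvers (backward Euler, Crank–Nicolson) plus an exact eigendecomposition route, AP voltage clamp, explicit pipette model |
| `periaxon.channels` | generic HH-style channels (Nav, Kv1, Kv7, HCN), per-domain density tables, active simulation, conduction-velocity estimators, structural sensitivity sweeps |
| `periaxon.fitting` | trial preprocessing, windowed MSE objective, seeded evolutionary search with Powell refinement, circuit-mode comparison (single cable, tied single cable, per-internode, double cable, …) |
| `periaxon.saltation` | onset latencies, spatial latency profiles, saltation advancement, voltage-sensitive-dye calibration |
| `periaxon.synthetic` | fully synthetic world: stylized cell generator, noisy multi-trial recordings, EM-like measurement tables, dye fluorescence with hidden gains |
| `periaxon.cli` | `periaxon synth / simulate / apclamp / fit / compare / sweep / analyze / calc` |

## Worked example

```python
import numpy as np

from periaxon import periaxonal_resistivity, lamellae_from_sheath
from periaxon.synthetic import SynthConfig, make_l5_morphology
from periaxon.cable_core import SolverConfig, discretize, ap_clamp, axon_record_sites
from periaxon.saltation import spatial_profile, saltation_advancement

# ultrastructure algebra: periaxonal fluid resistivity and lamellae count
print("R_pa  =", round(periaxonal_resistivity(125e9, 1.1, 12.3), 1), "Ohm*cm")
print("n_my  =", lamellae_from_sheath(C_m=1.0, C_my=0.05))

# a stylized myelinated axon (6 internodes) with its ground-truth parameters
cell = make_l5_morphology(SynthConfig(seed=0))

# drive the first node with an AP-like voltage command and map onset
# latencies of the transaxonal potential along the axon
cfg = SolverConfig(dt_ms=0.005, t_stop_ms=6.0, d_lambda=0.05)
graph = discretize(cell.morph, cell.params, cfg, mode="DC")
cfg.record = axon_record_sites(graph)
t = np.arange(0.0, 6.0, 0.005)
wave = -75.0 + 100.0 * np.exp(-((t - 1.0) ** 2) / (2 * 0.15**2))
node0 = [s.id for s in cell.morph.sections if s.kind == "node"][0]
profile = spatial_profile(ap_clamp(graph, node0, wave, cfg), potential="V_m")

for pos in [s for s in cell.morph.sections if s.kind == "node"][1:4]:
    p = cell.morph.path_distance(pos.id, 0.5)
    adv = saltation_advancement(profile, p, offset_um=5.0)
    print(f"node at {p:6.1f} um: onset leads its flanks by {adv*1e3:5.1f} us")
```

Output:

```
R_pa  = 53.7 Ohm*cm
n_my  = 10.0
node at  121.5 um: onset leads its flanks by  64.7 us
node at  177.5 um: onset leads its flanks by  61.9 us
node at  288.5 um: onset leads its flanks by  51.9 us
```

Every node's transaxonal onset leads the surrounding internodal axolemma by
50–65 µs — temporal saltation. Rebuild the graph with `mode="SC"` (single
cable) and the advancement collapses to below one solver time step.

The same pipeline from the command line:

```sh
periaxon synth --seed 0 --out work/synth            # cell + noisy recordings
periaxon apclamp --morphology work/synth/morphology.yaml --out work/clamp
periaxon calc periaxonal-resistivity --r-pa 125e9 --d 1.1 --delta-pa 12.3
```

Each subcommand writes a `summary.json` (sorted keys, config hash, no
timestamps): the same seed and config give byte-identical summaries.

## Fitting circuits to recordings

```python
from periaxon.fitting import FitProblem, OptBudget, optimize, preprocess_trials
from periaxon.synthetic import SynthConfig, make_l5_morphology, make_recording_set

cfg = SynthConfig(seed=0, noise_sd_mV=0.08)
cell = make_l5_morphology(cfg)
raw = make_recording_set(cell.morph, cell.params, cfg)   # 240 noisy trials
target = preprocess_trials(raw)                          # reject, baseline, average
best = optimize(FitProblem(cell.morph, target, mode="DC"), OptBudget(), seed=0)[0]
```

On this synthetic ground truth the fit recovers R_i, R_m, C_m essentially
exactly, C_my within ~12 %, and the periaxonal resistances within a factor
≲ 1.2; R_my itself is structurally unidentifiable from somatic/axonal step
responses at realistic noise (see `docs/methods.md`), which is itself a
prediction of the circuit. `compare_circuits` fits single-cable variants to
the same targets and consistently ranks the double cable first on
double-cable-generated data.

## Reproduction

```sh
pip install --no-build-isolation -e ".[test]"
pytest                                    # full suite, incl. acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script writes the headline closed-form values as JSON. All
randomness is seeded; tests derandomize hypothesis and use fixed generator
seeds. `docs/methods.md` documents the model, units, numerics and known
limitations.
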