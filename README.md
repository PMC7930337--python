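# wormcpg

A neuromechanical model of *C. elegans* forward locomotion driven by a
chain of **network** rhythmic-pattern generators in the ventral nerve
cord (VNC) — no stretch-receptor feedback, no pacemaker neurons, no
descending input.

The model couples three layers:

1. **Circuit** — seven identical repeating VNC units (motorneuron
   classes AS, DA, DB, DD, VD, VA, VB; 49 CTRNN neurons), with chemical
   synapses, self-connections and gap junctions,

       tau_i dV_i/dt = -V_i + Σ_j w_ji σ(V_j + θ_j) + Σ_j g_ji (V_j − V_i)

   Adjacent units couple only through DB→DD⁺¹, VA⁺¹→DD and the gap
   junctions DA⊣⊢AS⁺¹, VB⊣⊢DB⁺¹, AS⊣⊢VA⁺¹.
2. **Muscles** — 24 dorsal + 24 ventral leaky-integrator muscles
   (τ_M = 100 ms) driven by I_m^k = Σ_i γ_m q_i S_i with an evolvable
   anterior-posterior efficacy gradient γ_m = 0.7(1 − (m−1)F/24), and
   Hill force-length/velocity scaling.
3. **Body & environment** — a 2D cross-section body of 50 variable-width
   segments (51 rigid rods, 153 DOF) joined by damped-spring lateral and
   diagonal elements, crawling overdamped on agar under anisotropic
   linear drag (C∥ = 3.2×10⁻³ kg/s, C⊥ = 128×10⁻³ kg/s per rod).

The 44 unknown parameters (28 class parameters, 15 connection strengths,
1 muscle gain) are found by a two-stage genetic algorithm: stage 1
evolves an isolated unit to oscillate at the worm's bending frequency
(fitness F1, target f_a = 0.44 Hz), stage 2 embodies the chain and
evolves it to crawl at the worm's speed (fitness F1·F2, target
V_a = 0.22 mm/s). An analysis suite applies the behavioral filters used
to select worm-like solutions and the circuit-dissection experiments
(regional paralysis, gap-junction overexpression, subcircuit isolation,
interunit necessity/sufficiency, entrainment, phase shifts).

Who this is for: computational neuroscientists and systems biologists
studying central pattern generation and undulatory locomotion, and
anyone needing a compact, fully scriptable worm neuromechanics testbed.

See `docs/methods.md` for the model's assumptions, parameter tables and
the design choices made where the published description is open.

## Worked example

The package ships two demo genotypes produced by its own evolutionary
search (`scripts/make_demo_genotypes.py`): an isolated-unit oscillator
and an embodied locomotor. Characterizing the locomotor:

```python
from wormcpg import SimConfig, run_embodied
from wormcpg.analysis import (ap_curvature_slope, body_wavelength,
                              interunit_phase_shifts, trace_kymograph)
from wormcpg.fitness import estimate_frequency, fitness_f2, mean_velocity
from wormcpg.fixtures import demo_locomotor_genotype

genotype = demo_locomotor_genotype()
trace = run_embodied(genotype, SimConfig(duration=30.0, transient=5.0))
post = trace.post_transient()

speed = mean_velocity(post.com, post.dt)
freq, _ = estimate_frequency(post.neuron(3, "DB"), post.dt)
kym = trace_kymograph(post)
wavelength, _ = body_wavelength(kym)
slope, _ = ap_curvature_slope(kym)
shift = interunit_phase_shifts(post, "DB", units=(2, 3))
```

which prints

```
mean speed          : 0.193 mm/s  (F2 = 0.875)
DB bend frequency   : 0.447 Hz
body wavelength     : 0.88 body lengths
A-P curvature slope : -951.2 (negative = anterior-dominant)
interunit DB phase  : 58.9 degrees (unit 3 -> 4)
```

The model worm crawls at 88% of the target speed, bends at the worm's
0.44 Hz, propagates a posterior-traveling wave of 0.88 body lengths with
anterior-dominant curvature (all three worm-likeness filters pass), and
adjacent units lock ~59° apart — the phase gradient that turns seven
local rhythms into one traveling wave.

## Command line

```bash
wormcpg evolve --stage 1 --seed 3 --out runs/s1            # evolve an oscillator
wormcpg evolve --stage 2 --seed-genotype runs/s1/best_genotype.json \
               --seed 11 --out runs/s2                     # embody and evolve speed
wormcpg simulate --genotype runs/s2/best_genotype.json --out trace.h5 \
                 --silence-units 1:3                       # anterior paralysis
wormcpg analyze filter --genotype runs/s2/best_genotype.json
wormcpg fixtures --seed 1 --out fixtures/
wormcpg report runs/s2
```

Every run directory contains a manifest (config snapshot, seeds,
checksums) sufficient to re-derive it.

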