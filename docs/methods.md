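# Methods

This note documents the model implemented by `wormcpg`, the choices made
where the design was open, and what the shipped tests do and do not
establish.

## The scientific question

Forward crawling in *C. elegans* requires generating a dorsoventral
bending rhythm at ~0.44 Hz and propagating it head-to-tail. Two
mechanisms dominate the experimental literature: stretch-receptor
feedback and pacemaker neurons. `wormcpg` implements the third
possibility: a chain of *network* rhythm generators — oscillations
emerging from interactions among non-oscillatory ventral-nerve-cord
(VNC) motorneurons — coordinated unit-to-unit by electrical synapses.
The model deliberately excludes stretch-receptor feedback, pacemaker
dynamics, and descending input from command interneurons, so that
anything it achieves is attributable to the VNC network alone.

## Neural model

The VNC is modeled as seven identical repeating units, one neuron per
motorneuron class (AS, DA, DB, DD, VD, VA, VB), 49 neurons in total.
Each neuron follows continuous-time recurrent (CTRNN) dynamics

    tau_i dV_i/dt = -V_i + sum_j w_ji sigma(V_j + theta_j)
                         + sum_j g_ji (V_j - V_i),

with V measured relative to rest (so rest is V = 0 everywhere),
sigma(x) = 1/(1+e^-x) the graded synaptic release function, theta a
sensitivity offset, w chemical weights and g >= 0 symmetric gap-junction
conductances. Self-connections w_ii stand in for active membrane
conductances; depending on their strength a neuron is smoothly graded or
bistable, but never intrinsically oscillatory — rhythm can only be a
network property.

Wiring per unit: chemical synapses AS→DA, AS→VD, DA→DB, DB→AS, VD→VA,
VD→VB, DA→DD, VB→DD, VA→DD; gap junction VD⊣⊢DD. Between adjacent
units: chemical DB→DD⁺¹ and VA⁺¹→DD, and gap junctions DA⊣⊢AS⁺¹,
VB⊣⊢DB⁺¹, AS⊣⊢VA⁺¹. End units simply drop edges that would reference a
missing neighbor. (Descriptions of this circuit occasionally name a
"VD⊣⊢DB⁺¹" junction; that is inconsistent with the interunit set above
and is read as a misprint of VB⊣⊢DB⁺¹ throughout this package.)

## Muscles

24 dorsal + 24 ventral muscles lie along the cuticle. Muscle m of side
k integrates its drive leakily, dA/dt = (I - A)/tau_M with tau_M =
100 ms, where

    I_m^k = sum_{i in N^k} gamma_m q_i S_i,

N^D = {AS, DA, DB, DD}, N^V = {VA, VB, VD} of the innervating unit;
q_i is the NMJ weight, positive for cholinergic classes (AS, A, B) and
negative for GABAergic D classes; gamma_m = 0.7 (1 - (m-1) F / 24) is a
linearly decreasing anterior-posterior efficacy gradient with evolvable
gain F in [0, 1].

Unit-to-muscle assignment: three muscles per unit would cover only 21
of 24, and "four muscles for each end unit" still totals 23; we assign
unit 1 → muscles 1–4, units 2–6 → three each (5–19), and unit 7 →
muscles 20–24, covering all 24 with end-unit expansion. This allocation
is this package's documented choice.

Each muscle spans four consecutive lateral body elements, staggered by
two, with uniform weights normalized per muscle, so neighboring muscles
overlap and superpose on shared elements. Active tension is
A × F_max × FL × FV with a parabolic force–length factor (zero beyond
±50% strain of the element rest length) and a Hill force–velocity
factor that falls from 1 at zero shortening speed to 0 at v_max
(lengthening is clamped at the isometric value; the small eccentric
force enhancement of real muscle is ignored). Negative activations
(net GABAergic drive) produce extension forces symmetrically.

## Body and environment

The ~1 mm body is a 2D cross-section: 51 rigid rods (50 segments), each
rod with (x, y, phi) — 153 degrees of freedom. Neighboring rod
endpoints are joined by damped-spring *lateral* elements (cuticle
stretch resistance, the elements muscles contract) and cross-linked by
damped-spring *diagonal* elements (internal-pressure compression
resistance). Rod half-widths taper toward head and tail,
w_i = 40 µm · sqrt(1 - ((i-25)/26.5)²).

Crawling on agar is low-Reynolds-number motion: inertia is dropped and
the medium exerts linear drag F = -Cv with C∥ = 3.2×10⁻³ kg/s along the
local body-midline tangent and C⊥ = 128×10⁻³ kg/s normal to it (ratio
40), applied per rod, split equally between the rod's two endpoints so
that rotation is damped as well. The equations of motion are the
instantaneous force balance drag(v) = elastic + muscle forces.

The stiffness/damping constants and the muscle force scale shipped in
`data/body.yaml` are this package's own calibration (the historical
constant tables of the antecedent body model are not restated in
available sources): k_lateral = 24 N/m, k_diagonal = 12 N/m, c_lateral
= 3×10⁻³ kg/s, c_diagonal = 1.5×10⁻³ kg/s, F_max = 2×10⁻⁴ N per
element. These were chosen so that (i) body shape relaxes in a few
milliseconds, quasi-static relative to the 2.3 s bending period, (ii)
physiological activations (|A| ≈ 1–5) bend the body to mid-body
curvature of ~3–10 /mm, and (iii) an imposed worm-like traveling wave
(amplitude ≈ 6 /mm, wavelength 0.6–0.9 L, 0.44 Hz) propels the body at
0.15–0.22 mm/s. Within that regime the evolutionary search, not the
calibration, decides the operating point. Any mismatch with the
original body model's constants is a fidelity risk of this
re-implementation and is confined to this one config file.

Self-intersection is neither prevented nor penalized; a geometric
overlap check can flag it (`check_self_intersection`), matching the
source model's behavior for extreme genotypes.

## Integration

Neural and muscle states advance by Forward Euler at dt = 0.5 ms; the
body advances by a semi-implicit backward-Euler scheme at dt = 0.1 ms,
five body substeps per neural step, with muscle activations frozen
across the substeps (neural step → muscle step → body substeps). The
body solve treats drag, element damping and the dominant (axial)
elastic stiffness implicitly — the system matrix is symmetric positive
definite and block-tridiagonal (3×3 blocks), solved by a block Thomas
algorithm — and the remaining geometric nonlinearity explicitly. The
scheme is first-order convergent (verified by dt-halving in the tests),
keeps an exactly resting body exactly at rest, and is stable at the
default steps for all stiffness values in the shipped config. Because
the circuit receives no feedback from the body, neural trajectories are
identical with and without the body; purely neural analyses exploit
this.

All runs start from rest (V = 0, A = 0, straight posture). A seeded
Gaussian perturbation of V is available (`SimConfig.init_noise`) to
break symmetric fixed points but is off by default; every simulation is
bit-reproducible given (genotype, config, masks).

## Parameters and search

44 free parameters, normalized to [-1, 1] and mapped linearly onto
ranges held in `data/ranges.yaml`: per class, bias θ ∈ [-15, 15], time
constant τ ∈ [0.05, 2] s (the lower bound keeps 0.5 ms Euler stable),
self-weight ∈ [-15, 15], NMJ magnitude ∈ [0, 15] (sign fixed by
transmitter class); 9 + 2 chemical weights ∈ [-15, 15]; 1 + 3 gap
conductances ∈ [0, 2.5]; muscle gain F ∈ [0, 1]. These are standard
CTRNN evolutionary-search ranges.

The genetic algorithm is real-valued with linear-ranking selection
(pressure 1.8), uniform recombination with probability 0.5, sparse
per-slot Gaussian mutation (each slot mutated with probability 0.25,
sigma 0.1, reflected at the bounds) and elitism 1. Sparse mutation
matters: mutating every slot each time stalls stage-1 runs near fitness
0.95, below the 0.99 gate.

Fitness is staged. Stage 1 integrates a single isolated unit and scores
the B-class outputs:

    F1 = prod_{j in {DB,VB}} min(1, TV_j / (4 A f_a T)) ·
                              max(0, 1 - |f_j - f_a| / f_a),

with TV_j the total variation of S_j over the scoring window, A = 0.5
and f_a = 0.44 Hz. The normalizer makes a sinusoid of amplitude A at
f_a score exactly 1, the value at which the amplitude term is capped —
the normalization is chosen precisely so that the cap coincides with
the threshold-amplitude oscillation. Frequency is estimated from mean
intervals
between rising mean-crossings (sub-sample interpolated), with a
periodogram cross-check available; fewer than two crossings flags the
trace non-oscillatory and scores 0. Stage 2 embodies the circuit and
scores F1·F2 with

    F2 = max(0, 1 - |V̄ - V_a| / V_a),   V_a = 0.22 mm/s,

where V̄ is the magnitude of the net center-of-mass displacement over
the scoring window divided by its duration — net displacement, so
wiggling or spinning in place scores ≈ 0. For the embodied model F1 is
the mean over the seven units of the per-unit B-class score.

Evaluation windows: the paper-level characterization protocol is 50 s
with the first 10 s discarded (≈18 retained cycles). GA evaluations use
shorter windows — 22 s/2 s for stage 1, 18 s/3 s for stage 2 — chosen
as the smallest windows giving stable frequency and velocity estimates
(≈9 and ≈6.6 cycles); stage-1 winners are re-verified on the full
protocol. Stage 2 seeds its population with a stage-1 winner plus
mutated copies.

## Analyses

* **Kymograph**: signed local curvature (dorsal positive) along the
  midline per frame, from finite differences of the tangent angle with
  a 5-point moving-average smoothing window along the body.
* **Body wavelength**: first minimum of the frame-averaged unbiased
  spatial autocorrelation of the centered curvature profile (parabolic
  sub-sample refinement), times two; an FFT peak serves as cross-check
  and fallback. Filter passes for 0.4–0.9 body lengths.
* **A-P curvature profile**: least-squares slope of time-mean
  |curvature| versus body coordinate; filter requires a negative slope
  (bending more pronounced anteriorly).
* **Trajectory curvature radius**: arc length of the low-pass-filtered
  COM path divided by its net heading rotation (exact for circles,
  saturating at 1 m for straight paths); filter requires > 1 mm.
* **NMJ role filter**: velocity with all A-class NMJs suppressed must
  exceed 20% of V_a while velocity with B-class NMJs suppressed must
  fall below it.
* **Regional silencing**: either all neurons of a unit range are
  clamped to rest with zero synaptic output ("neurons") or only their
  NMJs are zeroed ("nmj"); bending amplitude is reported per body third
  as the sum over body points of peak-to-peak curvature across the
  post-transient window (a disclosed operationalization of "total
  bending amplitude").
* **Gap-junction overexpression**: the evolved VB⊣⊢DB⁺¹ conductance is
  multiplied by a factor ≥ 1, and homologous DB⊣⊢DB⁺¹ / VB⊣⊢VB⁺¹
  channels are added at (factor−1) times the evolved reference, so
  factor 1 reproduces the baseline exactly and larger factors
  strengthen all three B-class couplings together.
* **Subcircuit oscillation score**: a 3-neuron subcircuit (AS-DA-DB,
  VD-VA-DD or VD-VB-DD) is isolated with only its internal connections;
  each member receives compensatory tonic input centered on the mean
  synaptic drive it lost (estimated from a full-unit reference run) and
  swept ±3 over a 9-point grid per neuron. The score is the grid
  maximum of time-mean |dS/dt| normalized by the threshold-oscillation
  rate 4·A·f_a and clipped to [0, 1]; fixed points score 0.
* **Necessity/sufficiency**: each of the five interunit connection
  types is ablated alone (necessity) or retained alone (sufficiency);
  performance is F2. A connection is necessary/sufficient relative to
  0.5× the baseline score; solutions are *simple* (some connection both
  necessary and sufficient), *redundant* (sufficient connections exist
  but none is singly necessary) or *complex* (no single connection
  sufficient). The 0.5 threshold quantizes a qualitative published
  categorization and is configurable.
* **Entrainment**: the chain is integrated to its limit cycle, one end
  unit's neurons are replaced by their own state from a chosen fraction
  of a cycle earlier (state substitution on the limit cycle, not input
  injection — the chosen mechanism where the source is silent), and the
  phase shift each unit adopts relative to an unperturbed continuation
  is measured. Purely neural (no body needed).
* **Phase markers**: the per-cycle phase of a neuron is the midpoint
  between the times of maximum and minimum dS/dt within a cycle; shifts
  between traces are circular means over cycles, reported in
  (−180°, 180°].

## Synthetic data and demo genotypes

`wormcpg.fixtures` generates analytic traveling-wave kymographs (chosen
wavelength, frequency, amplitude gradient, travel direction), midline
series that reproduce them exactly (heading integration), and
circular/straight COM paths. These validate every estimator against
known ground truth, but they are noiseless, perfectly periodic and
perfectly sampled: passing them shows estimator correctness, not
robustness to tracking noise or posture occlusion in real video data.

The committed demo genotypes are actual products of the package's own
search (`scripts/make_demo_genotypes.py`): `demo_oscillator.json` is a
stage-1 winner; `demo_locomotor.json` is the best individual of a
stage-2 run seeded from it (population 32; a scaled-down setting chosen
to keep regeneration to about an hour of CPU). The locomotor is, by
construction, a solution that passes all three worm-likeness filters —
continuing the same lineage raises raw fitness but drifts it out of the
filtered ensemble (its thrust comes to depend on A-class NMJs), which
is exactly why ensemble filtering exists: evolved solutions are not
automatically worm-like. They are fixtures in the sense of being
archived outputs, not hand-crafted inputs.

## Known limitations

* Forward crawling on agar only: no backward locomotion, turns,
  variable-viscosity environments, or 3D body.
* No stretch-receptor feedback, pacemaker dynamics or command-interneuron
  input — by design, to isolate the network-oscillator mechanism.
* Body constants are a calibrated re-implementation, not the original
  tables; absolute forces should not be over-interpreted.
* Ensemble-level statistics (success rates over large batches of
  searches, the size and composition of a filtered ensemble, its
  phase-shift distributions) depend on search hyperparameters that are
  not pinned down by the model itself; the package reproduces the
  pipeline and per-solution phenotypes, not any particular ensemble's
  numbers.
* Electrical coupling between muscle cells is omitted (weak in vivo);
  muscle calcium dynamics are not modeled.
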