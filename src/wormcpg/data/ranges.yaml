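# Search ranges for the 44 evolvable parameters.
# Each genotype slot in [-1, 1] maps linearly onto [lo, hi].
# Gap-junction conductances and neuromuscular-junction magnitudes are
# constrained non-negative; NMJ signs are fixed by transmitter class
# (cholinergic excitatory, GABAergic inhibitory) and are not evolved.
schema: 1
bias: [-15.0, 15.0]          # dimensionless potential offset theta
time_constant: [0.05, 2.0]   # seconds; lower bound keeps 0.5 ms Euler stable
self_weight: [-15.0, 15.0]   # self-connection strength
nmj_weight: [0.0, 15.0]      # NMJ magnitude |q|; sign applied from class
chemical_weight: [-15.0, 15.0]
gap_conductance: [0.0, 2.5]
muscle_gain: [0.0, 1.0]      # anterior-posterior gain F
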