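# Mechanical constants of the 2D rod-and-spring body and agar environment.
# This file is the single source of truth for the body model; the solver
# reads everything from here.
#
# The drag coefficients are the published agar values. The cuticle
# stiffness/damping constants and muscle force scale are this package's
# own calibration, chosen so that (i) the body is quasi-static on the
# bending time scale (shape relaxation of a few ms << 2.3 s bending
# period), (ii) physiological muscle drive can bend the body to curvature
# of order 5 /mm against drag, and (iii) crawling speeds of ~0.2 mm/s are
# reachable. They are not the original constant tables of the prior body
# model, which are not restated in the literature available here.
schema: 1

n_seg: 50
body_length: 1.0e-3        # m
half_width_max: 40.0e-6    # m, maximum rod half-width
half_width_taper: 26.5     # w_i = w_max * sqrt(1 - ((i - n/2)/taper)^2)

# Agar drag, per rod (split equally between the rod's two endpoints)
drag_tangential: 3.2e-3    # kg/s
drag_normal: 128.0e-3      # kg/s

# Damped-spring structural elements
k_lateral: 24.0            # N/m, cuticle stretch resistance
c_lateral: 3.0e-3          # kg/s
k_diagonal: 12.0           # N/m, internal-pressure compression resistance
c_diagonal: 1.5e-3         # kg/s

# Muscles
n_muscles_per_side: 24
muscle_span_elements: 4    # lateral elements intersected by one muscle
muscle_stagger: 2          # element offset between consecutive muscles
f_max: 2.0e-4              # N, maximum isometric tension per lateral element
fl_width: 0.5              # force-length: FL = 1 - ((l - l0)/(fl_width*l0))^2
fv_vmax: 1.0e-4            # m/s, maximum shortening velocity
fv_curvature: 3.0          # Hill force-velocity shape factor
tau_muscle: 0.1            # s, muscle activation time constant
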