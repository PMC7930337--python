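"""Body-wall muscles: 24 dorsal + 24 ventral leaky-integrator actuators.

Motorneuron outputs drive the muscles through neuromuscular junctions,

    I_m^k = sum_{i in N^k} gamma_m * q_i * S_i,

where N^D = {AS, DA, DB, DD} and N^V = {VA, VB, VD} of the unit
innervating muscle m, q_i is the signed NMJ weight (D-class inhibitory),
and gamma_m = 0.7 * (1 - (m-1)*F/M) is a linearly decreasing
anterior-posterior efficacy gradient with evolvable gain F. Activation
relaxes toward the drive with time constant tau_M = 100 ms. Active force
follows simplified Hill force-length / force-velocity scaling and is
distributed over the lateral elements each muscle intersects.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .circuit import (
    CLASS_INDEX,
    DORSAL_CLASSES,
    N_CLASSES,
    VENTRAL_CLASSES,
    CircuitWiring,
)
from .config import BodyConstants, ConfigError, load_body_constants

N_MUSCLES = 24


def ap_gain(m: np.ndarray | int, F: float, n_muscles: int = N_MUSCLES) -> np.ndarray | float:
    """Anterior-posterior NMJ efficacy gamma_m = 0.7*(1 - (m-1)*F/M).

    m is 1-based muscle position; gamma_1 = 0.7 for any F.
    """
    m = np.asarray(m, dtype=float)
    gamma = 0.7 * (1.0 - ((m - 1.0) * F) / n_muscles)
    return gamma if gamma.ndim else float(gamma)


def unit_of_muscle(n_units: int = 7, n_muscles: int = N_MUSCLES) -> np.ndarray:
    """Assignment of each muscle (0-based index) to its innervating unit.

    Three muscles per unit, except the most anterior and most posterior
    units which take the extra muscles needed to cover all 24: unit 0 ->
    muscles 1-4 and unit 6 -> muscles 20-24 (1-based).
    """
    if n_units != 7 or n_muscles != 24:
        # proportional fallback for non-default configurations
        return np.minimum((np.arange(n_muscles) * n_units) // n_muscles, n_units - 1)
    units = np.empty(n_muscles, dtype=np.int64)
    units[:4] = 0
    for u in range(1, 6):
        units[4 + 3 * (u - 1): 4 + 3 * u] = u
    units[19:] = 6
    return units


@dataclasses.dataclass
class MuscleMap:
    """Static wiring from neurons to muscles and muscles to body elements."""

    n_units: int
    gain_F: float
    unit_to_muscle: np.ndarray        # (n_muscles,) innervating unit per muscle
    drive_matrix: np.ndarray          # (2*n_muscles, n_neurons): I = drive @ S
    element_weights: np.ndarray       # (n_seg, n_muscles): per-side overlap weights

    @property
    def n_muscles(self) -> int:
        return len(self.unit_to_muscle)


def build_drive_matrix(
    wiring: CircuitWiring,
    gain_F: float,
    nmj_mask: np.ndarray | None = None,
    n_muscles: int = N_MUSCLES,
) -> np.ndarray:
    """(2*n_muscles, n_neurons) matrix mapping outputs S to drives I.

    Rows 0..23 are dorsal muscles, rows 24..47 ventral. ``nmj_mask``
    (per neuron, False = suppressed junction) zeroes a neuron's column.
    """
    n = wiring.n_neurons
    units = unit_of_muscle(wiring.n_units, n_muscles)
    gamma = ap_gain(np.arange(1, n_muscles + 1), gain_F, n_muscles)
    if np.any(gamma <= 0):
        raise ConfigError("gamma_m must stay positive for all muscles (check gain F)")
    M = np.zeros((2 * n_muscles, n))
    mask = np.ones(n, dtype=bool) if nmj_mask is None else np.asarray(nmj_mask, dtype=bool)
    for m in range(n_muscles):
        u = units[m]
        if u < 0 or u >= wiring.n_units:
            raise ConfigError(f"muscle {m + 1} has no assigned unit")
        for c in DORSAL_CLASSES:
            j = u * N_CLASSES + CLASS_INDEX[c]
            M[m, j] = gamma[m] * wiring.nmj[j] * mask[j]
        for c in VENTRAL_CLASSES:
            j = u * N_CLASSES + CLASS_INDEX[c]
            M[n_muscles + m, j] = gamma[m] * wiring.nmj[j] * mask[j]
    return M


def build_element_weights(constants: BodyConstants | None = None) -> np.ndarray:
    """(n_seg, n_muscles) overlap weights from muscles onto lateral elements.

    Muscle m spans ``muscle_span_elements`` consecutive lateral elements
    starting at element ``muscle_stagger * m``; its weight is uniform over
    the span and normalized to sum to 1 per muscle, so overlapping
    muscles superpose on shared elements.
    """
    c = constants or load_body_constants()
    Wme = np.zeros((c.n_seg, c.n_muscles_per_side))
    for m in range(c.n_muscles_per_side):
        start = c.muscle_stagger * m
        stop = min(start + c.muscle_span_elements, c.n_seg)
        if stop <= start:
            raise ConfigError(f"muscle {m + 1} intersects no lateral element")
        Wme[start:stop, m] = 1.0 / (stop - start)
    return Wme


def build_muscle_map(
    wiring: CircuitWiring,
    gain_F: float,
    constants: BodyConstants | None = None,
    nmj_mask: np.ndarray | None = None,
) -> MuscleMap:
    c = constants or load_body_constants()
    return MuscleMap(
        n_units=wiring.n_units,
        gain_F=gain_F,
        unit_to_muscle=unit_of_muscle(wiring.n_units, c.n_muscles_per_side),
        drive_matrix=build_drive_matrix(wiring, gain_F, nmj_mask, c.n_muscles_per_side),
        element_weights=build_element_weights(c),
    )


@dataclasses.dataclass
class MuscleState:
    """Activation A and drive I, dorsal rows then ventral (2*n_muscles)."""

    activation: np.ndarray
    drive: np.ndarray

    @classmethod
    def rest(cls, n_muscles: int = N_MUSCLES) -> "MuscleState":
        return cls(activation=np.zeros(2 * n_muscles), drive=np.zeros(2 * n_muscles))


def muscle_input(S: np.ndarray, muscle_map: MuscleMap) -> np.ndarray:
    """Instantaneous drive I = drive_matrix @ S (dorsal block then ventral)."""
    return muscle_map.drive_matrix @ np.asarray(S, dtype=float)


def muscle_activation_step(
    state: MuscleState, I: np.ndarray, dt: float, tau_m: float = 0.1
) -> MuscleState:
    """Forward-Euler update of dA/dt = (I - A) / tau_M (tau_M = 100 ms)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    A = state.activation + dt * (I - state.activation) / tau_m
    return MuscleState(activation=A, drive=np.asarray(I, dtype=float).copy())


def force_length(length: np.ndarray, rest: np.ndarray, width: float = 0.5):
    """Parabolic Hill force-length factor, 1 at rest length, 0 beyond +-width."""
    strain = (np.asarray(length) - rest) / (width * rest)
    return np.clip(1.0 - strain**2, 0.0, None)


def force_velocity(dldt: np.ndarray, v_max: float = 1e-4, shape: float = 3.0):
    """Hill force-velocity factor: 1 when not shortening, 0 at v_max shortening."""
    u = np.clip(-np.asarray(dldt), 0.0, None)  # shortening speed
    fv = np.where(u >= v_max, 0.0, (1.0 - u / v_max) / (1.0 + shape * u / v_max))
    return fv


def muscle_force(
    activation: np.ndarray,
    element_length: np.ndarray,
    element_velocity: np.ndarray,
    geometry_rest: np.ndarray,
    element_weights: np.ndarray,
    constants: BodyConstants | None = None,
) -> np.ndarray:
    """Active contractile tension per lateral element for one body side.

    tension_j = F_max * (sum_m w_jm A_m) * FL(l_j) * FV(dl_j/dt); positive
    values contract the element. The two sides are independent.
    """
    c = constants or load_body_constants()
    act = element_weights @ np.asarray(activation, dtype=float)
    fl = force_length(element_length, geometry_rest, c.fl_width)
    fv = force_velocity(element_velocity, c.fv_vmax, c.fv_curvature)
    return c.f_max * act * fl * fv
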