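"""Clocked simulation protocols: isolated neural unit and embodied worm.

The neural chain is integrated by Forward Euler at dt_neural (0.5 ms);
the body by a semi-implicit backward-Euler scheme at dt_body (0.1 ms),
five body substeps per neural step. Per macro step the order is: neural
step -> muscle-drive computation and muscle activation step -> body
substeps with frozen activations. The circuit receives no feedback from
the body (no stretch receptors), so neural trajectories are identical
with or without the body.

All runs start from rest (V = 0, A = 0, straight posture) unless a
seeded initial perturbation is requested, and are bit-reproducible given
(genotype, config, masks).
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels
from .body import BodyGeometry, BodyState, EnvironmentDrag
from .circuit import (
    CLASS_INDEX,
    N_CLASSES,
    CircuitWiring,
    Genotype,
    build_circuit,
    decode_genotype,
)
from .config import BodyConstants, load_body_constants
from .muscles import build_drive_matrix, build_element_weights


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Timing and recording parameters of a simulation run."""

    duration: float = 50.0          # s
    transient: float = 10.0         # s discarded by downstream metrics
    dt_neural: float = 5e-4         # s
    dt_body: float = 1e-4           # s
    record_stride: int = 20         # neural steps between recorded frames
    seed: int = 0
    init_noise: float = 0.0         # amplitude of seeded initial V perturbation

    def __post_init__(self):
        n_sub = self.dt_neural / self.dt_body
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("dt_neural must be an integer multiple of dt_body")
        if self.duration <= self.transient:
            raise ValueError("duration must exceed the transient")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_sub(self) -> int:
        return int(round(self.dt_neural / self.dt_body))

    @property
    def n_macro(self) -> int:
        return int(round(self.duration / self.dt_neural))

    @property
    def dt_record(self) -> float:
        return self.dt_neural * self.record_stride


@dataclasses.dataclass
class Masks:
    """Experimental manipulations applied to a simulation run.

    ``alive`` False silences a neuron (V clamped to rest, no synaptic or
    gap output); ``nmj`` False suppresses only the neuron's muscle
    output. Both default to all-enabled.
    """

    alive: np.ndarray
    nmj: np.ndarray

    @classmethod
    def none(cls, n_neurons: int = 49) -> "Masks":
        return cls(np.ones(n_neurons, dtype=bool), np.ones(n_neurons, dtype=bool))

    def silence_units(self, units) -> "Masks":
        m = self.alive.copy()
        for u in units:
            m[u * N_CLASSES: (u + 1) * N_CLASSES] = False
        return Masks(m, self.nmj.copy())

    def suppress_nmj_units(self, units) -> "Masks":
        m = self.nmj.copy()
        for u in units:
            m[u * N_CLASSES: (u + 1) * N_CLASSES] = False
        return Masks(self.alive.copy(), m)

    def suppress_nmj_classes(self, class_labels) -> "Masks":
        m = self.nmj.copy()
        n_units = len(m) // N_CLASSES
        for c in class_labels:
            idx = CLASS_INDEX[c]
            for u in range(n_units):
                m[u * N_CLASSES + idx] = False
        return Masks(self.alive.copy(), m)


@dataclasses.dataclass
class SimulationTrace:
    """Uniformly sampled recordings with a shared time base."""

    times: np.ndarray                 # (n_rec,)
    outputs: np.ndarray               # (n_rec, n_neurons) synaptic outputs S
    n_units: int
    muscle_activation: np.ndarray | None = None   # (n_rec, 48)
    midline: np.ndarray | None = None             # (n_rec, n_rod, 2)
    potentials: np.ndarray | None = None          # (n_rec, n_neurons) V
    config: SimConfig | None = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def neuron(self, unit: int, class_label: str) -> np.ndarray:
        return self.outputs[:, unit * N_CLASSES + CLASS_INDEX[class_label]]

    @property
    def com(self) -> np.ndarray:
        """(n_rec, 2) center-of-mass trajectory (requires midline)."""
        if self.midline is None:
            raise ValueError("trace has no midline recording")
        return self.midline.mean(axis=1)

    def window(self, t_start: float | None = None, t_stop: float | None = None) -> "SimulationTrace":
        """Sub-trace restricted to [t_start, t_stop]."""
        t0 = self.times[0] if t_start is None else t_start
        t1 = self.times[-1] if t_stop is None else t_stop
        sel = (self.times >= t0 - 1e-12) & (self.times <= t1 + 1e-12)
        return SimulationTrace(
            times=self.times[sel],
            outputs=self.outputs[sel],
            n_units=self.n_units,
            muscle_activation=None if self.muscle_activation is None else self.muscle_activation[sel],
            midline=None if self.midline is None else self.midline[sel],
            potentials=None if self.potentials is None else self.potentials[sel],
            config=self.config,
        )

    def post_transient(self) -> "SimulationTrace":
        t0 = self.config.transient if self.config is not None else 0.0
        return self.window(t_start=t0)


def _initial_potentials(n: int, config: SimConfig) -> np.ndarray:
    V = np.zeros(n)
    if config.init_noise > 0:
        rng = np.random.default_rng(config.seed)
        V += config.init_noise * rng.standard_normal(n)
    return V


def simulate_neural(
    wiring: CircuitWiring,
    config: SimConfig,
    masks: Masks | None = None,
    V0: np.ndarray | None = None,
    external_input: np.ndarray | None = None,
    record_potentials: bool = False,
) -> tuple[SimulationTrace, np.ndarray]:
    """Integrate the circuit alone; returns (trace, final potentials)."""
    n = wiring.n_neurons
    masks = masks or Masks.none(n)
    V = np.array(V0, dtype=float) if V0 is not None else _initial_potentials(n, config)
    ext = np.zeros(n) if external_input is None else np.asarray(external_input, dtype=float)
    n_macro = config.n_macro
    n_rec = (n_macro + config.record_stride - 1) // config.record_stride
    S_rec = np.zeros((n_rec, n))
    V_rec = np.zeros((n_rec, n)) if record_potentials else None
    alive = masks.alive.astype(np.float64)
    _kernels.neural_steps(
        V, wiring.chemical, wiring.gap, wiring.bias, wiring.tau, alive, ext,
        config.dt_neural, n_macro, config.record_stride, S_rec, 0, V_rec,
    )
    if not np.all(np.isfinite(V)):
        raise SimulationError("non-finite neural state")
    times = np.arange(n_rec) * config.dt_record
    trace = SimulationTrace(times=times, outputs=S_rec, n_units=wiring.n_units,
                            potentials=V_rec, config=config)
    return trace, V


def run_isolated_unit(genotype: Genotype | np.ndarray, config: SimConfig | None = None) -> SimulationTrace:
    """Stage-1 protocol: one 7-neuron unit, no interunit edges, no body."""
    config = config or SimConfig()
    params, connectome, _ = decode_genotype(genotype)
    wiring = build_circuit(params, connectome, n_units=1)
    trace, _ = simulate_neural(wiring, config)
    return trace


@dataclasses.dataclass
class EmbodiedModel:
    """Fully assembled neuromechanical model ready to simulate.

    Separating assembly from integration lets analysis code edit the
    wiring (connection ablations, gap-junction overexpression) or masks
    and re-run without re-decoding the genotype.
    """

    wiring: CircuitWiring
    gain_F: float
    constants: BodyConstants
    geometry: BodyGeometry

    @classmethod
    def from_genotype(
        cls,
        genotype: Genotype | np.ndarray,
        constants: BodyConstants | None = None,
    ) -> "EmbodiedModel":
        params, connectome, gain_F = decode_genotype(genotype)
        wiring = build_circuit(params, connectome, n_units=7)
        c = constants or load_body_constants()
        return cls(wiring=wiring, gain_F=gain_F, constants=c,
                   geometry=BodyGeometry.from_constants(c))

    def simulate(
        self,
        config: SimConfig,
        masks: Masks | None = None,
        drag: EnvironmentDrag | None = None,
    ) -> SimulationTrace:
        w = self.wiring
        geom = self.geometry
        c = self.constants
        masks = masks or Masks.none(w.n_neurons)
        drag = drag or EnvironmentDrag(c.drag_tangential, c.drag_normal)

        V = _initial_potentials(w.n_neurons, config)
        Mmap = build_drive_matrix(w, self.gain_F, nmj_mask=masks.nmj,
                                  n_muscles=c.n_muscles_per_side)
        ME = build_element_weights(c)
        A = np.zeros(2 * c.n_muscles_per_side)
        act_d = np.zeros(geom.n_seg)
        act_v = np.zeros(geom.n_seg)
        body = BodyState.straight(geom)

        n_macro = config.n_macro
        n_rec = (n_macro + config.record_stride - 1) // config.record_stride
        S_rec = np.zeros((n_rec, w.n_neurons))
        A_rec = np.zeros((n_rec, 2 * c.n_muscles_per_side))
        mid_rec = np.zeros((n_rec, geom.n_rod, 2))
        alive = masks.alive.astype(np.float64)
        ext = np.zeros(w.n_neurons)

        status = _kernels.embodied_steps(
            V, w.chemical, w.gap, w.bias, w.tau, alive, ext,
            config.dt_neural, n_macro,
            Mmap, A, c.tau_muscle,
            ME, act_d, act_v,
            body.x, body.y, body.phi, body.vx, body.vy, body.vphi,
            geom.half_width,
            geom.elem_rod, geom.elem_side_a, geom.elem_side_b,
            geom.elem_k, geom.elem_c, geom.elem_rest, geom.elem_kind,
            c.f_max, c.fl_width, c.fv_vmax, c.fv_curvature,
            drag.c_par, drag.c_perp, config.dt_body, config.n_sub,
            config.record_stride, S_rec, A_rec, mid_rec, 0,
        )
        if status != 0:
            t_fail = n_macro * config.dt_neural
            raise SimulationError(
                f"body integration failed (code {status}) before t={t_fail:.3f}s"
            )
        if not (np.all(np.isfinite(V)) and np.all(np.isfinite(body.x))):
            raise SimulationError("non-finite simulation state")
        times = np.arange(n_rec) * config.dt_record
        return SimulationTrace(
            times=times, outputs=S_rec, n_units=w.n_units,
            muscle_activation=A_rec, midline=mid_rec, config=config,
        )


def run_embodied(
    genotype: Genotype | np.ndarray,
    config: SimConfig | None = None,
    masks: Masks | None = None,
    constants: BodyConstants | None = None,
) -> SimulationTrace:
    """Stage-2 protocol: full 7-unit circuit driving the body on agar."""
    config = config or SimConfig()
    model = EmbodiedModel.from_genotype(genotype, constants)
    return model.simulate(config, masks=masks)
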