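"""Ventral-nerve-cord motorneuron circuit: seven identical repeating units.

Each unit contains one neuron of each of the seven motorneuron classes
(AS, DA, DB, DD, VD, VA, VB). Neurons are continuous-time recurrent
(CTRNN) nodes,

    tau_i dV_i/dt = -V_i + sum_j w_ji * sigma(V_j + theta_j)
                         + sum_j g_ji * (V_j - V_i) + I_ext_i

with membrane potential V measured relative to rest, sigmoidal graded
synaptic output S_i = sigma(V_i + theta_i), chemical weights w, and
bidirectional ohmic gap junctions g (g_ji = g_ij >= 0). Self-connections
stand in for active membrane conductances, letting single neurons be
smoothly graded or bistable without intrinsic (pacemaker) oscillation.

The wiring repeats the statistically supported VNC unit: nine intraunit
chemical synapses, the VD-DD gap junction, two interunit chemical
synapses onto DD, and three interunit gap junctions (DA-AS+1, VB-DB+1,
AS-VA+1) that couple adjacent units. Units at the chain boundary simply
drop edges that would reference a missing neighbor.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.special import expit

from .config import ParameterRanges, load_ranges

CLASSES = ("AS", "DA", "DB", "DD", "VD", "VA", "VB")
N_CLASSES = 7
CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: NMJ sign per class: cholinergic (AS, A, B) excite muscle, GABAergic (D) inhibit.
NMJ_SIGN = {"AS": +1, "DA": +1, "DB": +1, "DD": -1, "VD": -1, "VA": +1, "VB": +1}

#: Motorneuron classes innervating dorsal / ventral body-wall muscles.
DORSAL_CLASSES = ("AS", "DA", "DB", "DD")
VENTRAL_CLASSES = ("VA", "VB", "VD")

#: Intraunit chemical synapses (pre, post).
INTRAUNIT_CHEMICAL = (
    ("AS", "DA"), ("AS", "VD"), ("DA", "DB"), ("DB", "AS"),
    ("VD", "VA"), ("VD", "VB"), ("DA", "DD"), ("VB", "DD"), ("VA", "DD"),
)
#: Intraunit gap junctions (unordered pair).
INTRAUNIT_GAP = (("VD", "DD"),)
#: Interunit chemical synapses (pre, post, unit offset of post wrt pre).
#: DB -> DD of the next unit; VA of the next unit -> DD (offset -1 on post).
INTERUNIT_CHEMICAL = (("DB", "DD", +1), ("VA", "DD", -1))
#: Interunit gap junctions (class in unit u, class in unit u+1).
INTERUNIT_GAP = (("DA", "AS"), ("VB", "DB"), ("AS", "VA"))

N_UNITS_DEFAULT = 7
GENOTYPE_LENGTH = 44


def sigmoid(x):
    """Logistic synaptic activation sigma(x) = 1 / (1 + exp(-x))."""
    return expit(x)


def _genotype_slots() -> tuple[tuple[str, str], ...]:
    """Ordered (slot_name, range_kind) pairs defining the 44-slot layout."""
    slots: list[tuple[str, str]] = []
    for c in CLASSES:
        slots.append((f"bias_{c}", "bias"))
    for c in CLASSES:
        slots.append((f"tau_{c}", "time_constant"))
    for c in CLASSES:
        slots.append((f"self_{c}", "self_weight"))
    for c in CLASSES:
        slots.append((f"nmj_{c}", "nmj_weight"))
    for pre, post in INTRAUNIT_CHEMICAL:
        slots.append((f"w_{pre}_{post}", "chemical_weight"))
    for a, b in INTRAUNIT_GAP:
        slots.append((f"g_{a}_{b}", "gap_conductance"))
    for pre, post, off in INTERUNIT_CHEMICAL:
        tag = f"{pre}_{post}p1" if off > 0 else f"{pre}p1_{post}"
        slots.append((f"w_{tag}", "chemical_weight"))
    for a, b in INTERUNIT_GAP:
        slots.append((f"g_{a}_{b}p1", "gap_conductance"))
    slots.append(("muscle_gain_F", "muscle_gain"))
    return tuple(slots)


GENOTYPE_SLOTS = _genotype_slots()
SLOT_INDEX = {name: i for i, (name, _) in enumerate(GENOTYPE_SLOTS)}
assert len(GENOTYPE_SLOTS) == GENOTYPE_LENGTH


@dataclasses.dataclass
class Genotype:
    """44 normalized reals in [-1, 1] with a fixed named-slot layout."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GENOTYPE_LENGTH,):
            raise ValueError(
                f"genotype must have exactly {GENOTYPE_LENGTH} values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype values must be finite")

    def __getitem__(self, slot: str) -> float:
        return float(self.values[SLOT_INDEX[slot]])

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema": 1,
            "layout": "wormcpg-44",
            "slots": {name: float(v) for (name, _), v in zip(GENOTYPE_SLOTS, self.values)},
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Genotype":
        s = str(source)
        looks_like_path = isinstance(source, Path) or ("\n" not in s and len(s) < 1000)
        text = Path(s).read_text() if looks_like_path and Path(s).exists() else s
        doc = json.loads(text)
        if doc.get("layout") != "wormcpg-44":
            raise ValueError(f"unknown genotype layout {doc.get('layout')!r}")
        slots = doc["slots"]
        missing = [name for name, _ in GENOTYPE_SLOTS if name not in slots]
        if missing:
            raise ValueError(f"genotype file missing slots: {missing}")
        return cls(np.array([slots[name] for name, _ in GENOTYPE_SLOTS]))


@dataclasses.dataclass
class NeuronClassParams:
    """Per-class intrinsic parameters, identical across all 7 units."""

    class_label: str
    bias: float
    time_constant: float
    self_weight: float
    nmj_weight: float

    @property
    def nmj_sign(self) -> int:
        return NMJ_SIGN[self.class_label]

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.time_constant <= 0:
            raise ValueError("time constant must be positive")
        if self.nmj_weight < 0:
            raise ValueError("NMJ magnitude must be non-negative")


@dataclasses.dataclass
class UnitConnectome:
    """The 15 connection strengths of one repeating unit (+ its neighbors)."""

    intraunit_chemical: dict[tuple[str, str], float]
    intraunit_gap: dict[tuple[str, str], float]
    interunit_chemical: dict[tuple[str, str, int], float]
    interunit_gap: dict[tuple[str, str], float]

    def __post_init__(self):
        n = (len(self.intraunit_chemical) + len(self.intraunit_gap)
             + len(self.interunit_chemical) + len(self.interunit_gap))
        if n != 15:
            raise ValueError(f"unit connectome must hold exactly 15 values, got {n}")
        for table in (self.intraunit_gap, self.interunit_gap):
            for pair, g in table.items():
                if g < 0:
                    raise ValueError(f"gap conductance {pair} must be non-negative")


def _lin(v: float, lo: float, hi: float) -> float:
    return lo + (v + 1.0) * 0.5 * (hi - lo)


def _lin_inv(p: float, lo: float, hi: float) -> float:
    return (p - lo) / (hi - lo) * 2.0 - 1.0


def decode_genotype(
    genotype: Genotype | np.ndarray, ranges: ParameterRanges | None = None
) -> tuple[dict[str, NeuronClassParams], UnitConnectome, float]:
    """Map a normalized 44-vector onto circuit parameters.

    Every slot maps linearly from [-1, 1] onto its range; NMJ slots carry
    magnitude only (the sign is fixed by transmitter class) and gap slots
    map onto non-negative ranges.
    """
    if not isinstance(genotype, Genotype):
        genotype = Genotype(np.asarray(genotype, dtype=float))
    if ranges is None:
        ranges = load_ranges()
    vals = genotype.values
    dec = {
        name: _lin(v, *getattr(ranges, kind))
        for (name, kind), v in zip(GENOTYPE_SLOTS, vals)
    }
    params = {
        c: NeuronClassParams(
            class_label=c,
            bias=dec[f"bias_{c}"],
            time_constant=dec[f"tau_{c}"],
            self_weight=dec[f"self_{c}"],
            nmj_weight=dec[f"nmj_{c}"],
        )
        for c in CLASSES
    }
    connectome = UnitConnectome(
        intraunit_chemical={(a, b): dec[f"w_{a}_{b}"] for a, b in INTRAUNIT_CHEMICAL},
        intraunit_gap={(a, b): dec[f"g_{a}_{b}"] for a, b in INTRAUNIT_GAP},
        interunit_chemical={
            (a, b, off): dec[f"w_{a}_{b}p1" if off > 0 else f"w_{a}p1_{b}"]
            for a, b, off in INTERUNIT_CHEMICAL
        },
        interunit_gap={(a, b): dec[f"g_{a}_{b}p1"] for a, b in INTERUNIT_GAP},
    )
    return params, connectome, dec["muscle_gain_F"]


def encode_genotype(
    params: dict[str, NeuronClassParams],
    connectome: UnitConnectome,
    muscle_gain: float,
    ranges: ParameterRanges | None = None,
) -> Genotype:
    """Inverse of :func:`decode_genotype` on the fixed slot layout."""
    if ranges is None:
        ranges = load_ranges()
    dec: dict[str, float] = {}
    for c in CLASSES:
        p = params[c]
        dec[f"bias_{c}"] = p.bias
        dec[f"tau_{c}"] = p.time_constant
        dec[f"self_{c}"] = p.self_weight
        dec[f"nmj_{c}"] = p.nmj_weight
    for (a, b), w in connectome.intraunit_chemical.items():
        dec[f"w_{a}_{b}"] = w
    for (a, b), g in connectome.intraunit_gap.items():
        dec[f"g_{a}_{b}"] = g
    for (a, b, off), w in connectome.interunit_chemical.items():
        dec[f"w_{a}_{b}p1" if off > 0 else f"w_{a}p1_{b}"] = w
    for (a, b), g in connectome.interunit_gap.items():
        dec[f"g_{a}_{b}p1"] = g
    dec["muscle_gain_F"] = muscle_gain
    vals = np.array([
        _lin_inv(dec[name], *getattr(ranges, kind)) for name, kind in GENOTYPE_SLOTS
    ])
    return Genotype(vals)


@dataclasses.dataclass
class CircuitWiring:
    """Instantiated chain: dense weight/conductance tables for n_units*7 neurons.

    ``chemical[i, j]`` is the weight from neuron j onto neuron i;
    ``gap[i, j] = gap[j, i] >= 0`` is the gap conductance between i and j.
    """

    n_units: int
    chemical: np.ndarray
    gap: np.ndarray
    bias: np.ndarray
    tau: np.ndarray
    nmj: np.ndarray  # signed NMJ weight per neuron

    @property
    def n_neurons(self) -> int:
        return self.n_units * N_CLASSES

    def neuron_id(self, unit: int, class_label: str) -> int:
        if not (0 <= unit < self.n_units):
            raise IndexError(f"unit {unit} out of range")
        return unit * N_CLASSES + CLASS_INDEX[class_label]


def build_circuit(
    params: dict[str, NeuronClassParams],
    connectome: UnitConnectome,
    n_units: int = N_UNITS_DEFAULT,
) -> CircuitWiring:
    """Instantiate the repeating unit ``n_units`` times along the chain.

    Interunit edges are created only where the neighboring unit exists
    (no wraparound); the gap table is symmetric by construction.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    n = n_units * N_CLASSES
    W = np.zeros((n, n))
    G = np.zeros((n, n))

    def nid(u, c):
        return u * N_CLASSES + CLASS_INDEX[c]

    for u in range(n_units):
        for c in CLASSES:
            W[nid(u, c), nid(u, c)] = params[c].self_weight
        for (pre, post), w in connectome.intraunit_chemical.items():
            W[nid(u, post), nid(u, pre)] = w
        for (a, b), g in connectome.intraunit_gap.items():
            G[nid(u, a), nid(u, b)] = g
            G[nid(u, b), nid(u, a)] = g
        for (pre, post, off), w in connectome.interunit_chemical.items():
            pu = u + off
            if 0 <= pu < n_units:
                W[nid(pu, post), nid(u, pre)] = w
        for (a, b), g in connectome.interunit_gap.items():
            if u + 1 < n_units:
                G[nid(u, a), nid(u + 1, b)] = g
                G[nid(u + 1, b), nid(u, a)] = g

    bias = np.tile([params[c].bias for c in CLASSES], n_units)
    tau = np.tile([params[c].time_constant for c in CLASSES], n_units)
    nmj = np.tile([params[c].nmj_sign * params[c].nmj_weight for c in CLASSES], n_units)
    return CircuitWiring(n_units=n_units, chemical=W, gap=G, bias=bias, tau=tau, nmj=nmj)


@dataclasses.dataclass
class CircuitState:
    """Membrane potentials plus experiment masks.

    ``ablation_mask`` False silences a neuron: V clamped at rest (0) and
    synaptic output forced to 0. ``nmj_mask`` False suppresses a neuron's
    muscle output only, leaving its dynamics intact. Connection-level
    ablations are expressed by editing the wiring tables (see
    :func:`wormcpg.analysis.mask_connections`).
    """

    potentials: np.ndarray
    ablation_mask: np.ndarray
    nmj_mask: np.ndarray

    @classmethod
    def rest(cls, n_neurons: int) -> "CircuitState":
        return cls(
            potentials=np.zeros(n_neurons),
            ablation_mask=np.ones(n_neurons, dtype=bool),
            nmj_mask=np.ones(n_neurons, dtype=bool),
        )


def synaptic_output(state: CircuitState, wiring: CircuitWiring) -> np.ndarray:
    """S_i = sigma(V_i + theta_i); silenced neurons emit 0."""
    S = sigmoid(state.potentials + wiring.bias)
    return np.where(state.ablation_mask, S, 0.0)


def neural_step(
    state: CircuitState,
    wiring: CircuitWiring,
    external_input: np.ndarray | float = 0.0,
    dt: float = 5e-4,
) -> CircuitState:
    """One Forward-Euler update of the CTRNN chain.

    Silenced neurons are held at rest and contribute no synaptic or gap
    current. Emits a warning-level error if dt is too large for the
    fastest time constant.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt >= 2.0 * np.min(wiring.tau):
        import warnings

        warnings.warn(
            f"dt={dt} close to instability for min tau={np.min(wiring.tau)}",
            RuntimeWarning,
            stacklevel=2,
        )
    V = state.potentials
    alive = state.ablation_mask
    S = synaptic_output(state, wiring)
    Gm = wiring.gap * np.outer(alive, alive)  # dead neurons conduct nothing
    chem = wiring.chemical @ S
    gap = Gm @ V - Gm.sum(axis=1) * V
    dV = (-V + chem + gap + external_input) / wiring.tau
    Vn = V + dt * dV
    Vn = np.where(alive, Vn, 0.0)
    return CircuitState(potentials=Vn, ablation_mask=alive.copy(), nmj_mask=state.nmj_mask.copy())
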