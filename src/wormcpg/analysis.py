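"""Behavioral metrics, ensemble filters and circuit-dissection experiments.

Everything here operates on simulation traces (or synthetic stand-ins):

* kinematics — curvature kymographs, body wavelength, anterior-posterior
  curvature profile, trajectory curvature radius;
* ensemble filters — the three criteria used to select worm-like
  solutions (relative A/B-class NMJ roles, body curvature, trajectory
  straightness);
* manipulations — regional silencing/paralysis, B-class gap-junction
  overexpression;
* coordination — subcircuit oscillation scores, necessity/sufficiency
  of interunit connections, entrainment directionality, interunit phase
  shifts.

Because the circuit receives no proprioceptive feedback, purely neural
analyses (entrainment, phase shifts, subcircuit scores) run on the
chain alone; performance scores and kinematics use the embodied model.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .circuit import (
    CLASS_INDEX,
    N_CLASSES,
    CircuitWiring,
    build_circuit,
    decode_genotype,
)
from .fitness import FitnessConstants, estimate_frequency, fitness_f2, mean_velocity
from .simulation import (
    EmbodiedModel,
    Masks,
    SimConfig,
    SimulationTrace,
    simulate_neural,
)

#: The five interunit connection types of the repeating circuit.
INTERUNIT_CONNECTIONS = ("DB->DD+1", "VA+1->DD", "DA-AS+1", "VB-DB+1", "AS-VA+1")

#: Default simulation protocol for analysis runs (long enough for ~11
#: bending cycles after the transient).
ANALYSIS_EVAL = SimConfig(duration=30.0, transient=5.0)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Kymograph:
    """Signed body curvature over (body coordinate, time), dorsal positive."""

    curvature: np.ndarray   # (n_body, n_time), 1/m
    body_coord: np.ndarray  # (n_body,) in [0, 1], head -> tail
    times: np.ndarray       # (n_time,), s

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


def midline_curvature(midline: np.ndarray, smooth_window: int = 5) -> np.ndarray:
    """Signed curvature d(theta)/ds at interior points of one midline.

    Positive curvature bends toward the dorsal side (the +y side of the
    straight rest posture; the relation is preserved by continuity).
    """
    pts = np.asarray(midline, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("midline needs at least 3 points")
    seg = np.diff(pts, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    if np.any(ds < 1e-12):
        raise ValueError("degenerate midline (repeated points)")
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    kappa = np.diff(theta) / (0.5 * (ds[:-1] + ds[1:]))
    if smooth_window > 1 and len(kappa) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(kappa, pad, mode="edge")
        kappa = np.convolve(padded, kernel, mode="valid")[: len(kappa)]
    return kappa


def curvature_kymograph(
    midlines: np.ndarray,
    times: np.ndarray | None = None,
    smooth_window: int = 5,
) -> Kymograph:
    """Kymograph from a (n_frames, n_points, 2) midline time series."""
    mids = np.asarray(midlines, dtype=float)
    if mids.ndim != 3 or mids.shape[1] < 3:
        raise ValueError("midlines must be (n_frames, n_points>=3, 2)")
    kap = np.stack([midline_curvature(m, smooth_window) for m in mids], axis=1)
    n_body = kap.shape[0]
    body_coord = (np.arange(n_body) + 1.0) / (mids.shape[1] - 1)
    t = np.arange(mids.shape[0], dtype=float) if times is None else np.asarray(times, float)
    return Kymograph(curvature=kap, body_coord=body_coord, times=t)


def trace_kymograph(trace: SimulationTrace, smooth_window: int = 5) -> Kymograph:
    if trace.midline is None:
        raise ValueError("trace has no midline recording")
    return curvature_kymograph(trace.midline, trace.times, smooth_window)


def body_wavelength(kym: Kymograph) -> tuple[float, bool]:
    """Dominant spatial wavelength of the curvature wave, in body lengths.

    Per frame, the spatial autocorrelation of the mean-centered curvature
    profile is computed; the averaged autocorrelation's first local
    minimum at lag > 0 marks half the wavelength. A spectral estimate is
    used as cross-check and fallback. Returns ``(wavelength, oscillatory)``.
    """
    kap = kym.curvature - kym.curvature.mean(axis=0, keepdims=True)
    n_body = kap.shape[0]
    if np.max(np.ptp(kap, axis=0)) < 1e-12:
        return 0.0, False
    ds = float(kym.body_coord[1] - kym.body_coord[0])
    acf = np.zeros(n_body)
    for j in range(kap.shape[1]):
        prof = kap[:, j]
        c = np.correlate(prof, prof, mode="full")[n_body - 1:]
        acf += c
    acf /= np.arange(n_body, 0, -1)  # unbiased: normalize by overlap count
    if acf[0] <= 0:
        return 0.0, False
    acf /= acf[0]
    minima = sp_signal.argrelmin(acf)[0]
    if len(minima):
        m = int(minima[0])
        lag = float(m)
        if 0 < m < len(acf) - 1:
            # parabolic interpolation around the discrete minimum
            denom = acf[m - 1] - 2 * acf[m] + acf[m + 1]
            if denom > 0:
                lag = m + 0.5 * (acf[m - 1] - acf[m + 1]) / denom
        lam_acf = 2.0 * lag * ds
    else:
        lam_acf = np.nan
    # spectral cross-check: dominant spatial frequency of the mean spectrum
    spec = np.abs(np.fft.rfft(kap, n=4 * n_body, axis=0)) ** 2
    mean_spec = spec.mean(axis=1)
    freqs = np.fft.rfftfreq(4 * n_body, d=ds)
    k_peak = freqs[np.argmax(mean_spec[1:]) + 1]
    lam_fft = 1.0 / k_peak if k_peak > 0 else np.nan
    lam = lam_acf if np.isfinite(lam_acf) else lam_fft
    if not np.isfinite(lam):
        return 0.0, False
    return float(lam), True


def ap_curvature_slope(kym: Kymograph) -> tuple[float, int]:
    """Least-squares slope of mean |curvature| vs body coordinate.

    A negative slope means bending is more pronounced anteriorly, as in
    crawling worms. Returns (slope, sign).
    """
    profile = np.mean(np.abs(kym.curvature), axis=1)
    res = sp_stats.linregress(kym.body_coord, profile)
    return float(res.slope), int(np.sign(res.slope))


def trajectory_curvature_radius(
    com_path: np.ndarray,
    dt: float | None = None,
    smooth_time: float | None = None,
    max_radius: float = 1.0,
) -> tuple[float, bool]:
    """Characteristic radius of curvature of the center-of-mass path (m).

    The path is low-pass filtered (to suppress the per-cycle wiggle),
    then radius = arc length / |net heading change|. Straight paths
    saturate at ``max_radius`` (1 m, effectively infinite for a 1 mm
    worm). Returns ``(radius, moving)``; stationary paths are flagged.
    """
    path = np.asarray(com_path, dtype=float)
    if path.ndim != 2 or len(path) < 3:
        raise ValueError("need an (n, 2) path with at least 3 points")
    if smooth_time and dt:
        win = max(1, int(round(smooth_time / dt)))
        if win > 1 and win < len(path):
            kernel = np.ones(win) / win
            path = np.column_stack([
                np.convolve(path[:, 0], kernel, mode="valid"),
                np.convolve(path[:, 1], kernel, mode="valid"),
            ])
    seg = np.diff(path, axis=0)
    ds = np.linalg.norm(seg, axis=1)
    keep = ds > 1e-12
    if keep.sum() < 2:
        return 0.0, False
    seg = seg[keep]
    ds = ds[keep]
    headings = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    total_turn = abs(headings[-1] - headings[0])
    arc = float(ds.sum())
    if arc < 1e-9:
        return 0.0, False
    radius = arc / total_turn if total_turn > 1e-9 else np.inf
    return float(min(radius, max_radius)), True


# ---------------------------------------------------------------------------
# ensemble filters
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilterReport:
    """Outcome of the three worm-likeness filters for one solution."""

    velocity_no_a_frac: float       # velocity with A-class NMJs off, / V_a
    velocity_no_b_frac: float       # velocity with B-class NMJs off, / V_a
    wavelength_bl: float            # body lengths
    ap_slope: float
    trajectory_radius_m: float
    nmj_pass: bool
    curvature_pass: bool
    trajectory_pass: bool

    @property
    def overall_pass(self) -> bool:
        return self.nmj_pass and self.curvature_pass and self.trajectory_pass


def _as_model(model_or_genotype) -> EmbodiedModel:
    if isinstance(model_or_genotype, EmbodiedModel):
        return model_or_genotype
    return EmbodiedModel.from_genotype(model_or_genotype)


def _post_velocity(trace: SimulationTrace) -> float:
    post = trace.post_transient()
    return mean_velocity(post.com, post.dt)


def nmj_ablation_filter(
    model_or_genotype,
    config: SimConfig | None = None,
    constants: FitnessConstants | None = None,
) -> dict:
    """Criterion (a): B-class NMJs necessary, A-class NMJs not.

    Runs the embodied model with all A-class (DA, VA) NMJs suppressed and
    with all B-class (DB, VB) NMJs suppressed. Passes iff velocity
    without A exceeds 20% of the target velocity and velocity without B
    falls below it.
    """
    cfg = config or ANALYSIS_EVAL
    k = constants or FitnessConstants()
    model = _as_model(model_or_genotype)
    n = model.wiring.n_neurons
    v = {}
    for label, classes in (("no_A", ("DA", "VA")), ("no_B", ("DB", "VB"))):
        masks = Masks.none(n).suppress_nmj_classes(classes)
        v[label] = _post_velocity(model.simulate(cfg, masks=masks))
    frac_a = v["no_A"] / k.target_velocity
    frac_b = v["no_B"] / k.target_velocity
    return {
        "velocity_no_a_frac": frac_a,
        "velocity_no_b_frac": frac_b,
        "pass": bool(frac_a > 0.2 and frac_b < 0.2),
    }


def locomotion_filter_report(
    model_or_genotype,
    config: SimConfig | None = None,
    constants: FitnessConstants | None = None,
    baseline_trace: SimulationTrace | None = None,
) -> FilterReport:
    """Apply all three ensemble filters to one solution."""
    cfg = config or ANALYSIS_EVAL
    model = _as_model(model_or_genotype)
    trace = baseline_trace or model.simulate(cfg)
    post = trace.post_transient()
    kym = trace_kymograph(post)
    lam, _ = body_wavelength(kym)
    slope, _ = ap_curvature_slope(kym)
    radius, _ = trajectory_curvature_radius(
        post.com, post.dt, smooth_time=1.0 / FitnessConstants().target_frequency
    )
    nmj = nmj_ablation_filter(model, cfg, constants)
    return FilterReport(
        velocity_no_a_frac=nmj["velocity_no_a_frac"],
        velocity_no_b_frac=nmj["velocity_no_b_frac"],
        wavelength_bl=lam,
        ap_slope=slope,
        trajectory_radius_m=radius,
        nmj_pass=nmj["pass"],
        curvature_pass=bool(0.4 <= lam <= 0.9 and slope < 0),
        trajectory_pass=bool(radius > 1e-3),
    )


# ---------------------------------------------------------------------------
# manipulation experiments
# ---------------------------------------------------------------------------

def bending_amplitudes_by_third(kym: Kymograph) -> dict[str, float]:
    """Total bending amplitude per body third.

    Amplitude per body point = peak-to-peak curvature over the window;
    the reported value is its sum over the points of each third.
    """
    ptp = np.ptp(kym.curvature, axis=1)
    n = len(ptp)
    thirds = np.array_split(np.arange(n), 3)
    return {
        name: float(ptp[idx].sum())
        for name, idx in zip(("head", "mid", "tail"), thirds)
    }


def region_silencing_experiment(
    model_or_genotype,
    region: tuple[int, int] | None,
    mode: str = "neurons",
    config: SimConfig | None = None,
) -> dict:
    """Silence a contiguous range of units and measure regional bending.

    ``region`` is an inclusive (first, last) 0-based unit range (None =
    no manipulation); ``mode`` 'neurons' silences all neural activity in
    those units, 'nmj' suppresses only their neuromuscular junctions
    (paralysis with intact dynamics). Returns bending amplitude per body
    third plus the mean speed.
    """
    cfg = config or ANALYSIS_EVAL
    model = _as_model(model_or_genotype)
    n = model.wiring.n_neurons
    masks = Masks.none(n)
    if region is not None:
        lo, hi = region
        if not (0 <= lo <= hi < model.wiring.n_units):
            raise ValueError(f"region {region} outside unit range")
        units = range(lo, hi + 1)
        if mode == "neurons":
            masks = masks.silence_units(units)
        elif mode == "nmj":
            masks = masks.suppress_nmj_units(units)
        else:
            raise ValueError("mode must be 'neurons' or 'nmj'")
    trace = model.simulate(cfg, masks=masks)
    post = trace.post_transient()
    kym = trace_kymograph(post)
    out = bending_amplitudes_by_third(kym)
    out["speed"] = _post_velocity(trace)
    return out


def _bclass_gap_overexpressed(wiring: CircuitWiring, factor: float) -> CircuitWiring:
    """Scale B-class interunit gap junctions by ``factor``.

    The evolved wiring carries VB-DB+1; overexpression additionally
    couples homologous B neurons (DB-DB+1, VB-VB+1) at (factor - 1)
    times the evolved VB-DB+1 conductance, so factor 1 reproduces the
    baseline exactly and larger factors strengthen all three channels.
    """
    if factor < 1:
        raise ValueError("overexpression factors must be >= 1")
    W = wiring.chemical.copy()
    G = wiring.gap.copy()
    nu = wiring.n_units
    g_ref = 0.0
    for u in range(nu - 1):
        i = wiring.neuron_id(u, "VB")
        j = wiring.neuron_id(u + 1, "DB")
        g_ref = max(g_ref, G[i, j])
    for u in range(nu - 1):
        i = wiring.neuron_id(u, "VB")
        j = wiring.neuron_id(u + 1, "DB")
        G[i, j] *= factor
        G[j, i] = G[i, j]
        for cls in ("DB", "VB"):
            a = wiring.neuron_id(u, cls)
            b = wiring.neuron_id(u + 1, cls)
            G[a, b] += (factor - 1.0) * g_ref
            G[b, a] = G[a, b]
    return dataclasses.replace(wiring, chemical=W, gap=G)


def gj_overexpression_sweep(
    model_or_genotype,
    factors,
    config: SimConfig | None = None,
) -> list[dict]:
    """Speed and regional bending vs B-class gap-junction strength."""
    cfg = config or ANALYSIS_EVAL
    model = _as_model(model_or_genotype)
    rows = []
    for factor in factors:
        wiring = _bclass_gap_overexpressed(model.wiring, float(factor))
        m = dataclasses.replace(model, wiring=wiring)
        trace = m.simulate(cfg)
        post = trace.post_transient()
        kym = trace_kymograph(post)
        row = {"factor": float(factor), "speed": _post_velocity(trace)}
        row.update(bending_amplitudes_by_third(kym))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# rhythm generation and coordination
# ---------------------------------------------------------------------------

SUBCIRCUITS = {
    "AS-DA-DB": ("AS", "DA", "DB"),
    "VD-VA-DD": ("VD", "VA", "DD"),
    "VD-VB-DD": ("VD", "VB", "DD"),
}


def _single_unit_wiring(genotype) -> CircuitWiring:
    params, connectome, _ = decode_genotype(genotype)
    return build_circuit(params, connectome, n_units=1)


def subcircuit_oscillation_score(
    genotype,
    subcircuit: str,
    tonic_steps: int = 9,
    tonic_span: float = 3.0,
    config: SimConfig | None = None,
    constants: FitnessConstants | None = None,
) -> float:
    """Capacity of a 3-neuron subcircuit to oscillate in isolation.

    The subcircuit keeps only the connections among its members (plus
    their self-connections); every other neuron is removed. Because
    isolation removes synaptic drive, each member receives a
    compensatory tonic input centered on the mean drive it lost
    (estimated from a full-unit reference run) and swept over
    ``tonic_steps`` values spanning +-``tonic_span``. The score is the
    maximum over the grid of the time-averaged |dS/dt| normalized by the
    threshold-oscillation rate 4*A*f_a, clipped to [0, 1]; it is 0 iff
    every grid point converges to a fixed point.
    """
    if subcircuit not in SUBCIRCUITS:
        raise ValueError(f"unknown subcircuit {subcircuit!r}")
    members = SUBCIRCUITS[subcircuit]
    cfg = config or SimConfig(duration=20.0, transient=5.0)
    k = constants or FitnessConstants()
    unit = _single_unit_wiring(genotype)
    member_ids = np.array([CLASS_INDEX[c] for c in members])
    keep = np.zeros(N_CLASSES, dtype=bool)
    keep[member_ids] = True

    # reference run of the full unit for the mean lost drive
    ref, _ = simulate_neural(unit, cfg)
    S_mean = ref.post_transient().outputs.mean(axis=0)
    lost = np.zeros(N_CLASSES)
    for i in range(N_CLASSES):
        for j in range(N_CLASSES):
            if keep[i] and not keep[j] and i != j:
                lost[i] += unit.chemical[i, j] * S_mean[j]

    # restricted wiring: zero all edges touching removed neurons
    W = unit.chemical * np.outer(keep, keep)
    G = unit.gap * np.outer(keep, keep)
    sub = dataclasses.replace(unit, chemical=W, gap=G)
    masks = Masks(alive=keep.copy(), nmj=np.ones(N_CLASSES, dtype=bool))

    offsets = np.linspace(-tonic_span, tonic_span, tonic_steps)
    norm = 4.0 * k.amplitude_threshold * k.target_frequency
    best = 0.0
    for da in offsets:
        for db in offsets:
            for dc in offsets:
                ext = np.zeros(N_CLASSES)
                ext[member_ids[0]] = lost[member_ids[0]] + da
                ext[member_ids[1]] = lost[member_ids[1]] + db
                ext[member_ids[2]] = lost[member_ids[2]] + dc
                trace, _ = simulate_neural(sub, cfg, masks=masks, external_input=ext)
                post = trace.post_transient()
                dsdt = np.abs(np.diff(post.outputs[:, member_ids], axis=0)) / post.dt
                score = min(1.0, float(dsdt.mean()) / norm)
                if score > best:
                    best = score
    return best


#: Map of connection-type name to its (pre_class, post_class, kind) along
#: the chain; 'gap' entries are symmetric pairs between unit u and u+1.
_INTERUNIT_EDGES = {
    "DB->DD+1": ("DB", "DD", "chem+1"),
    "VA+1->DD": ("VA", "DD", "chem-1"),
    "DA-AS+1": ("DA", "AS", "gap"),
    "VB-DB+1": ("VB", "DB", "gap"),
    "AS-VA+1": ("AS", "VA", "gap"),
}


def mask_connections(wiring: CircuitWiring, remove) -> CircuitWiring:
    """Return a wiring with the named interunit connection types removed."""
    W = wiring.chemical.copy()
    G = wiring.gap.copy()
    nu = wiring.n_units
    for name in remove:
        pre, post, kind = _INTERUNIT_EDGES[name]
        for u in range(nu - 1):
            if kind == "chem+1":
                W[wiring.neuron_id(u + 1, post), wiring.neuron_id(u, pre)] = 0.0
            elif kind == "chem-1":
                W[wiring.neuron_id(u, post), wiring.neuron_id(u + 1, pre)] = 0.0
            else:
                a = wiring.neuron_id(u, pre)
                b = wiring.neuron_id(u + 1, post)
                G[a, b] = 0.0
                G[b, a] = 0.0
    return dataclasses.replace(wiring, chemical=W, gap=G)


@dataclasses.dataclass
class CoordinationReport:
    """Necessity/sufficiency of each interunit connection for locomotion."""

    baseline: float
    necessity: dict[str, float]     # performance with the connection ablated
    sufficiency: dict[str, float]   # performance with only that connection
    category: str                   # simple / redundant / complex
    coordination_threshold: float

    def necessary(self, name: str) -> bool:
        return self.necessity[name] < self.coordination_threshold * self.baseline

    def sufficient(self, name: str) -> bool:
        return self.sufficiency[name] >= self.coordination_threshold * self.baseline


def interunit_necessity_sufficiency(
    model_or_genotype,
    config: SimConfig | None = None,
    constants: FitnessConstants | None = None,
    threshold: float = 0.5,
) -> CoordinationReport:
    """Ablate each interunit connection type alone / keep it alone.

    Performance is the velocity-matching score F2 of the embodied run.
    A connection is *necessary* if its removal drops performance below
    ``threshold`` x baseline and *sufficient* if it alone maintains at
    least that level. Solutions are 'simple' when some connection is
    both, 'redundant' when sufficiency exists without single-connection
    necessity, and 'complex' when no single connection is sufficient.
    """
    cfg = config or ANALYSIS_EVAL
    k = constants or FitnessConstants()
    model = _as_model(model_or_genotype)

    def performance(wiring) -> float:
        m = dataclasses.replace(model, wiring=wiring)
        trace = m.simulate(cfg).post_transient()
        return fitness_f2(trace.com, trace.dt, k)

    baseline = performance(model.wiring)
    necessity = {}
    sufficiency = {}
    for name in INTERUNIT_CONNECTIONS:
        necessity[name] = performance(mask_connections(model.wiring, [name]))
        others = [n for n in INTERUNIT_CONNECTIONS if n != name]
        sufficiency[name] = performance(mask_connections(model.wiring, others))
    rep = CoordinationReport(
        baseline=baseline,
        necessity=necessity,
        sufficiency=sufficiency,
        category="",
        coordination_threshold=threshold,
    )
    nec = {n: rep.necessary(n) for n in INTERUNIT_CONNECTIONS}
    suf = {n: rep.sufficient(n) for n in INTERUNIT_CONNECTIONS}
    if any(nec[n] and suf[n] for n in INTERUNIT_CONNECTIONS):
        rep.category = "simple"
    elif any(suf.values()):
        rep.category = "redundant"
    else:
        rep.category = "complex"
    return rep


# ---------------------------------------------------------------------------
# phase analysis
# ---------------------------------------------------------------------------

def _cycle_phase_markers(trace: np.ndarray, dt: float) -> tuple[np.ndarray, float]:
    """Per-cycle phase markers: midpoint between max and min of dS/dt.

    Cycles are delimited by rising mean-crossings. Returns (marker times,
    period). Raises if the trace is not oscillatory.
    """
    s = np.asarray(trace, dtype=float)
    freq, oscillatory = estimate_frequency(s, dt)
    if not oscillatory or freq <= 0:
        raise ValueError("trace is not oscillatory")
    centered = s - s.mean()
    sign = centered > 0
    rising = np.flatnonzero(~sign[:-1] & sign[1:])
    ds = np.gradient(s, dt)
    markers = []
    for a, b in zip(rising[:-1], rising[1:]):
        if b - a < 4:
            continue
        seg = ds[a:b]
        t_max = (a + np.argmax(seg)) * dt
        t_min = (a + np.argmin(seg)) * dt
        markers.append(0.5 * (t_max + t_min))
    if not markers:
        raise ValueError("no complete cycles in trace")
    return np.array(markers), 1.0 / freq


def _wrap_degrees(x: float) -> float:
    """Map an angle to the reporting interval (-180, 180]."""
    x = (x + 180.0) % 360.0 - 180.0
    return 180.0 if np.isclose(x, -180.0) else float(x)


def phase_shift(trace_a: np.ndarray, trace_b: np.ndarray, dt: float) -> float:
    """Phase of b relative to a, in degrees in (-180, 180].

    Both traces must oscillate at the same frequency (within 10%). The
    per-cycle phase marker is the midpoint between the times of maximum
    and minimum rate of change; the shift is the circular mean over
    cycles of the marker offsets, scaled by the shared period.
    """
    ma, pa = _cycle_phase_markers(trace_a, dt)
    mb, pb = _cycle_phase_markers(trace_b, dt)
    if abs(pa - pb) > 0.1 * pa:
        raise ValueError(f"frequency mismatch: periods {pa:.3f}s vs {pb:.3f}s")
    period = 0.5 * (pa + pb)
    angles = []
    for t in ma:
        j = np.argmin(np.abs(mb - t))
        angles.append(2.0 * np.pi * (mb[j] - t) / period)
    mean_angle = np.angle(np.mean(np.exp(1j * np.array(angles))))
    return _wrap_degrees(np.degrees(mean_angle))


def interunit_phase_shifts(
    trace: SimulationTrace,
    class_label: str = "DB",
    units: tuple[int, int] = (2, 3),
) -> float:
    """Phase shift (degrees) between the same class in adjacent units."""
    a = trace.neuron(units[0], class_label)
    b = trace.neuron(units[1], class_label)
    return phase_shift(a, b, trace.dt)


def entrainment_analysis(
    genotype_or_wiring,
    perturbed_unit: int,
    phase_shift_deg: float,
    config: SimConfig | None = None,
    settle: float = 40.0,
    measure: float = 40.0,
) -> dict[int, float]:
    """Phase shift adopted by every unit after perturbing one unit.

    The chain (neural only; the circuit receives no body feedback) is
    integrated to its limit cycle; the perturbed unit's neurons are then
    replaced by their own state from ``phase_shift_deg`` of a cycle
    earlier (state substitution on the limit cycle), and both the
    perturbed and an unperturbed copy are integrated on. The adopted
    shift per unit is the phase difference of its DB output between the
    two continuations, in degrees.
    """
    cfg = config or SimConfig(duration=settle, transient=5.0, record_stride=4)
    if isinstance(genotype_or_wiring, CircuitWiring):
        wiring = genotype_or_wiring
    else:
        params, connectome, _ = decode_genotype(genotype_or_wiring)
        wiring = build_circuit(params, connectome, n_units=7)
    if not (0 <= perturbed_unit < wiring.n_units):
        raise ValueError("perturbed unit outside the chain")

    settle_trace, V0 = simulate_neural(wiring, cfg)
    post = settle_trace.post_transient()
    freq, oscillatory = estimate_frequency(post.neuron(3, "DB"), post.dt)
    if not oscillatory or freq <= 0:
        raise ValueError("solution is not steadily oscillating")
    period = 1.0 / freq

    # state-substitution source: advance a copy by (period - shift) so the
    # perturbed unit takes its own limit-cycle state from `shift` earlier
    shift_time = (phase_shift_deg % 360.0) / 360.0 * period
    adv = (period - shift_time) % period
    n_adv = int(round(adv / cfg.dt_neural))
    V_shifted = V0.copy()
    if n_adv > 0:
        tiny = SimConfig(
            duration=max(n_adv, 1) * cfg.dt_neural + cfg.dt_neural,
            transient=0.0, dt_neural=cfg.dt_neural, dt_body=cfg.dt_body,
            record_stride=max(n_adv, 1),
        )
        # integrate exactly n_adv steps
        from . import _kernels

        V_shifted = V0.copy()
        _kernels.neural_steps(
            V_shifted, wiring.chemical, wiring.gap, wiring.bias, wiring.tau,
            np.ones(wiring.n_neurons), np.zeros(wiring.n_neurons),
            cfg.dt_neural, n_adv, 0, np.zeros((1, wiring.n_neurons)), 0,
        )
    V_pert = V0.copy()
    sl = slice(perturbed_unit * N_CLASSES, (perturbed_unit + 1) * N_CLASSES)
    V_pert[sl] = V_shifted[sl]

    meas_cfg = SimConfig(
        duration=measure, transient=measure / 2.0,
        dt_neural=cfg.dt_neural, dt_body=cfg.dt_body, record_stride=cfg.record_stride,
    )
    base_trace, _ = simulate_neural(wiring, meas_cfg, V0=V0.copy())
    pert_trace, _ = simulate_neural(wiring, meas_cfg, V0=V_pert)
    base_post = base_trace.post_transient()
    pert_post = pert_trace.post_transient()
    out = {}
    for u in range(wiring.n_units):
        out[u] = phase_shift(base_post.neuron(u, "DB"), pert_post.neuron(u, "DB"), base_post.dt)
    return out
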