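"""Unit tests of the repeating VNC circuit: decoding, wiring, dynamics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from wormcpg.circuit import (
    CLASSES,
    GENOTYPE_SLOTS,
    CircuitState,
    CircuitWiring,
    Genotype,
    build_circuit,
    decode_genotype,
    encode_genotype,
    neural_step,
    sigmoid,
    synaptic_output,
)


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == 0.5

    def test_saturation(self):
        assert sigmoid(500.0) == pytest.approx(1.0)
        assert sigmoid(-500.0) == pytest.approx(0.0)

    @given(st.floats(-30, 30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_complement_identity(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self):
        x = np.linspace(-20, 20, 200)
        assert np.all(np.diff(sigmoid(x)) > 0)


class TestGenotypeDecoding:
    def test_layout_has_44_named_slots(self):
        assert len(GENOTYPE_SLOTS) == 44
        kinds = [k for _, k in GENOTYPE_SLOTS]
        assert kinds.count("bias") == 7
        assert kinds.count("time_constant") == 7
        assert kinds.count("self_weight") == 7
        assert kinds.count("nmj_weight") == 7
        assert kinds.count("chemical_weight") == 11  # 9 intraunit + 2 interunit
        assert kinds.count("gap_conductance") == 4   # 1 intraunit + 3 interunit
        assert kinds.count("muscle_gain") == 1

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="44"):
            Genotype(np.zeros(43))

    def test_zero_vector_decodes_to_range_midpoints(self, ranges):
        params, connectome, F = decode_genotype(np.zeros(44), ranges)
        for c in CLASSES:
            assert params[c].bias == pytest.approx(np.mean(ranges.bias))
            assert params[c].time_constant == pytest.approx(np.mean(ranges.time_constant))
            assert params[c].nmj_weight == pytest.approx(np.mean(ranges.nmj_weight))
        for g in connectome.intraunit_gap.values():
            assert g == pytest.approx(np.mean(ranges.gap_conductance))
        assert F == pytest.approx(np.mean(ranges.muscle_gain))

    def test_nmj_signs_fixed_by_class(self):
        params, _, _ = decode_genotype(np.zeros(44))
        assert all(params[c].nmj_sign == 1 for c in ("AS", "DA", "DB", "VA", "VB"))
        assert all(params[c].nmj_sign == -1 for c in ("DD", "VD"))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_decode_encode_roundtrip(self, seed):
        vec = np.random.default_rng(seed).uniform(-1, 1, 44)
        params, connectome, F = decode_genotype(vec)
        back = encode_genotype(params, connectome, F)
        np.testing.assert_allclose(back.values, vec, atol=1e-12)

    def test_json_roundtrip(self, tmp_path):
        g = Genotype(np.linspace(-1, 1, 44))
        path = tmp_path / "g.json"
        g.to_json(path)
        g2 = Genotype.from_json(path)
        np.testing.assert_array_equal(g.values, g2.values)


@pytest.fixture(scope="module")
def decoded():
    vec = np.random.default_rng(7).uniform(-1, 1, 44)
    return decode_genotype(vec)


class TestBuildCircuit:
    def test_seven_units_means_49_neurons(self, decoded):
        params, conn, _ = decoded
        wiring = build_circuit(params, conn, 7)
        assert wiring.n_neurons == 49

    def test_single_unit_has_no_interunit_edges(self, decoded):
        params, conn, _ = decoded
        w1 = build_circuit(params, conn, 1)
        # intraunit only: 9 chemical + 7 self, 1 gap pair
        assert np.count_nonzero(w1.chemical) == 16
        assert np.count_nonzero(w1.gap) == 2  # symmetric VD-DD entry

    def test_two_units_have_five_interunit_edges(self, decoded):
        params, conn, _ = decoded
        w1 = build_circuit(params, conn, 1)
        w2 = build_circuit(params, conn, 2)
        n_intra_chem = np.count_nonzero(w1.chemical)
        assert np.count_nonzero(w2.chemical) == 2 * n_intra_chem + 2
        assert np.count_nonzero(w2.gap) // 2 == 2 * 1 + 3

    def test_gap_table_symmetric(self, decoded):
        params, conn, _ = decoded
        wiring = build_circuit(params, conn, 7)
        np.testing.assert_array_equal(wiring.gap, wiring.gap.T)
        assert np.all(wiring.gap >= 0)

    def test_invalid_unit_count_rejected(self, decoded):
        params, conn, _ = decoded
        with pytest.raises(ValueError):
            build_circuit(params, conn, 0)


def _simple_wiring(n=1, tau=1.0, bias=0.0, self_w=0.0, gap=0.0):
    W = np.eye(n) * self_w
    G = np.full((n, n), gap) - np.diag(np.full(n, gap))
    return CircuitWiring(
        n_units=1, chemical=W, gap=G,
        bias=np.full(n, bias), tau=np.full(n, tau), nmj=np.zeros(n),
    )


class TestNeuralStep:
    def test_isolated_neuron_decays_exponentially(self):
        # all weights 0 except the leak: V(t) = e^(-t) for tau = 1
        wiring = _simple_wiring(1, tau=1.0, bias=-1e3)  # bias kills synaptic input
        state = CircuitState.rest(1)
        state.potentials[0] = 1.0
        dt = 5e-4
        for _ in range(2000):  # 1 s
            state = neural_step(state, wiring, dt=dt)
        assert state.potentials[0] == pytest.approx(np.exp(-1.0), rel=1e-3)

    def test_self_excited_neuron_settles_at_fixed_point(self):
        w_self, theta = 5.0, -2.0
        wiring = _simple_wiring(1, tau=0.5, bias=theta, self_w=w_self)
        state = CircuitState.rest(1)
        state.potentials[0] = 5.0
        for _ in range(40000):  # 20 s
            state = neural_step(state, wiring, dt=5e-4)
        # independent oracle: upper root of V - w*sigma(V+theta) = 0
        v_star = brentq(lambda v: v - w_self * sigmoid(v + theta), 3.0, 10.0)
        assert state.potentials[0] == pytest.approx(v_star, abs=1e-6)

    def test_gap_coupled_pair_decays_at_known_rate(self):
        # d/dt (V1 - V2) = -(1 + 2g)/tau * (V1 - V2) when only gap-coupled
        g, tau = 0.8, 1.0
        wiring = _simple_wiring(2, tau=tau, bias=-1e3, gap=g)
        state = CircuitState.rest(2)
        state.potentials[:] = [1.0, -1.0]
        dt, t_end = 5e-4, 0.5
        for _ in range(int(t_end / dt)):
            state = neural_step(state, wiring, dt=dt)
        diff = state.potentials[0] - state.potentials[1]
        assert diff == pytest.approx(2.0 * np.exp(-(1 + 2 * g) / tau * t_end), rel=1e-3)

    def test_outputs_bounded_in_unit_interval(self):
        vec = np.random.default_rng(3).uniform(-1, 1, 44)
        params, conn, _ = decode_genotype(vec)
        wiring = build_circuit(params, conn, 7)
        state = CircuitState.rest(49)
        for _ in range(500):
            state = neural_step(state, wiring, dt=5e-4)
            S = synaptic_output(state, wiring)
            assert np.all((S >= 0) & (S < 1))

    def test_gap_current_sums_to_zero(self):
        # with a symmetric conductance table, total gap current vanishes
        vec = np.random.default_rng(5).uniform(-1, 1, 44)
        params, conn, _ = decode_genotype(vec)
        wiring = build_circuit(params, conn, 7)
        rng = np.random.default_rng(0)
        V = rng.normal(0, 3, 49)
        total = 0.0
        for i in range(49):
            total += np.sum(wiring.gap[i] * (V - V[i]))
        assert abs(total) < 1e-12 * np.abs(wiring.gap).sum() * np.abs(V).max()

    def test_halving_dt_halves_trajectory_error(self):
        vec = np.random.default_rng(11).uniform(-1, 1, 44)
        params, conn, _ = decode_genotype(vec)
        wiring = build_circuit(params, conn, 1)

        def run(dt, t_end=10.0):
            state = CircuitState.rest(7)
            state.potentials[:] = 0.1
            for _ in range(int(round(t_end / dt))):
                state = neural_step(state, wiring, dt=dt)
            return state.potentials.copy()

        ref = run(6.25e-5)
        err1 = np.max(np.abs(run(5e-4) - ref))
        err2 = np.max(np.abs(run(2.5e-4) - ref))
        assert err2 < 0.65 * err1  # ~first-order convergence
        assert err1 < 0.05

    def test_silencing_equals_removing_outgoing_edges(self):
        vec = np.random.default_rng(13).uniform(-1, 1, 44)
        params, conn, _ = decode_genotype(vec)
        wiring = build_circuit(params, conn, 2)
        victim = 3  # DD of unit 0

        silenced = CircuitState.rest(14)
        silenced.ablation_mask[victim] = False
        edited = CircuitWiring(
            n_units=2,
            chemical=wiring.chemical.copy(),
            gap=wiring.gap.copy(),
            bias=wiring.bias, tau=wiring.tau, nmj=wiring.nmj,
        )
        edited.chemical[:, victim] = 0.0
        edited.gap[:, victim] = 0.0
        edited.gap[victim, :] = 0.0
        plain = CircuitState.rest(14)
        plain.potentials[:] = silenced.potentials[:] = 0.2

        for _ in range(4000):
            silenced = neural_step(silenced, wiring, dt=5e-4)
            plain = neural_step(plain, edited, dt=5e-4)
        others = np.arange(14) != victim
        np.testing.assert_allclose(
            silenced.potentials[others], plain.potentials[others], atol=1e-12
        )
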