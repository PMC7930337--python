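"""Kinematic estimators, filters and coordination analyses on constructed inputs."""
import numpy as np
import pytest

from wormcpg.analysis import (
    Kymograph,
    ap_curvature_slope,
    bending_amplitudes_by_third,
    body_wavelength,
    curvature_kymograph,
    mask_connections,
    midline_curvature,
    phase_shift,
    subcircuit_oscillation_score,
    trajectory_curvature_radius,
)
from wormcpg.circuit import build_circuit, decode_genotype
from wormcpg.fixtures import (
    circular_path,
    midlines_from_curvature,
    straight_path,
    traveling_wave_curvature,
)


class TestCurvature:
    def test_straight_midline_zero_curvature(self):
        mid = np.column_stack([np.linspace(0, 1e-3, 51), np.zeros(51)])
        assert np.abs(midline_curvature(mid, smooth_window=1)).max() < 1e-9

    def test_circular_arc_constant_curvature(self):
        r = 2e-4
        ang = np.linspace(0, 1.5, 51)
        mid = r * np.column_stack([np.cos(ang), np.sin(ang)])
        kap = midline_curvature(mid, smooth_window=1)
        np.testing.assert_allclose(kap, 1.0 / r, rtol=1e-3)

    def test_sinusoidal_midline_recovers_spatial_frequency(self):
        # curvature of a low-slope sine midline is a sine at the same frequency
        x = np.linspace(0, 1e-3, 101)
        amp, k = 2e-5, 2 * np.pi / 0.5e-3
        mid = np.column_stack([x, amp * np.sin(k * x)])
        kap = midline_curvature(mid, smooth_window=1)
        spec = np.abs(np.fft.rfft(kap - kap.mean()))
        ds = 1e-3 / 100
        freqs = np.fft.rfftfreq(len(kap), d=ds)
        assert freqs[np.argmax(spec)] == pytest.approx(k / (2 * np.pi), rel=0.08)

    def test_degenerate_midline_rejected(self):
        mid = np.zeros((5, 2))
        with pytest.raises(ValueError):
            midline_curvature(mid)

    def test_kymograph_matches_generating_wave(self):
        kym = traveling_wave_curvature(wavelength_bl=0.6, ap_gradient=0.3)
        mids = midlines_from_curvature(kym)
        back = curvature_kymograph(mids, kym.times, smooth_window=1)
        np.testing.assert_allclose(back.curvature, kym.curvature,
                                   atol=1e-10 * np.abs(kym.curvature).max())


class TestWavelength:
    @pytest.mark.parametrize("wl", [0.4, 0.5, 0.6, 0.9])
    def test_recovers_imposed_wavelength(self, wl):
        kym = traveling_wave_curvature(wavelength_bl=wl, ap_gradient=0.2)
        lam, ok = body_wavelength(kym)
        assert ok
        assert lam == pytest.approx(wl, rel=0.05)

    def test_long_wave_measured_long_and_fails_filter(self):
        kym = traveling_wave_curvature(wavelength_bl=1.5)
        lam, ok = body_wavelength(kym)
        assert ok and lam > 0.9  # outside the 0.4-0.9 passing band

    def test_flat_kymograph_flagged(self):
        kym = Kymograph(curvature=np.zeros((49, 100)),
                        body_coord=np.linspace(0.02, 0.98, 49),
                        times=np.arange(100.0))
        lam, ok = body_wavelength(kym)
        assert not ok


class TestApSlope:
    def test_decaying_amplitude_negative_slope(self):
        kym = traveling_wave_curvature(ap_gradient=0.4)
        slope, sign = ap_curvature_slope(kym)
        assert sign < 0

    def test_uniform_amplitude_near_zero_slope(self):
        kym = traveling_wave_curvature(ap_gradient=0.0, duration=50.0)
        slope, _ = ap_curvature_slope(kym)
        norm = np.mean(np.abs(kym.curvature))
        assert abs(slope) < 0.05 * norm  # |slope| small relative to the mean level

    def test_increasing_amplitude_positive_slope(self):
        kym = traveling_wave_curvature(ap_gradient=-0.4)
        slope, sign = ap_curvature_slope(kym)
        assert sign > 0


class TestTrajectoryRadius:
    def test_circle_radius_recovered(self):
        r, moving = trajectory_curvature_radius(circular_path(radius=1e-3))
        assert moving and r == pytest.approx(1e-3, rel=0.02)

    def test_straight_path_effectively_infinite(self):
        r, moving = trajectory_curvature_radius(straight_path())
        assert moving and r > 1e-1  # saturates far above the 1 mm threshold

    def test_small_circle_fails_threshold(self):
        r, moving = trajectory_curvature_radius(circular_path(radius=0.5e-3))
        assert moving and r < 1e-3

    def test_stationary_path_flagged(self):
        path = np.zeros((100, 2))
        r, moving = trajectory_curvature_radius(path)
        assert not moving


class TestFilterMatrix:
    """Each filter classifies its constructed pass/fail inputs correctly."""

    def test_wavelength_filter_matrix(self):
        for wl, should_pass in [(0.5, True), (0.6, True), (0.85, True),
                                (0.3, False), (1.5, False)]:
            lam, ok = body_wavelength(traveling_wave_curvature(wavelength_bl=wl))
            assert ok
            assert (0.4 <= lam <= 0.9) == should_pass, f"wavelength {wl}"

    def test_slope_filter_matrix(self):
        for grad, should_pass in [(0.4, True), (0.2, True), (-0.4, False)]:
            slope, _ = ap_curvature_slope(traveling_wave_curvature(ap_gradient=grad))
            assert (slope < 0) == should_pass, f"gradient {grad}"

    def test_trajectory_filter_matrix(self):
        for path, should_pass in [
            (straight_path(), True),
            (circular_path(radius=2e-3), True),
            (circular_path(radius=0.5e-3), False),
        ]:
            r, moving = trajectory_curvature_radius(path)
            assert moving
            assert (r > 1e-3) == should_pass


class TestPhaseShift:
    t = np.arange(0, 25, 0.01)

    def wave(self, shift_deg):
        return 0.5 + 0.4 * np.sin(2 * np.pi * 0.44 * self.t - np.radians(shift_deg))

    def test_identical_traces_zero_shift(self):
        a = self.wave(0)
        assert phase_shift(a, a, 0.01) == pytest.approx(0.0, abs=0.5)

    @pytest.mark.parametrize("deg", [45, 90, 135, 180])
    def test_known_offsets_recovered(self, deg):
        got = phase_shift(self.wave(0), self.wave(deg), 0.01)
        assert got == pytest.approx(deg, abs=2.0) or (deg == 180 and abs(got) == pytest.approx(180, abs=2.0))

    def test_antisymmetry(self):
        a, b = self.wave(0), self.wave(63)
        assert phase_shift(a, b, 0.01) == pytest.approx(-phase_shift(b, a, 0.01), abs=2.0)

    def test_frequency_mismatch_rejected(self):
        a = self.wave(0)
        b = 0.5 + 0.4 * np.sin(2 * np.pi * 0.6 * self.t)
        with pytest.raises(ValueError, match="frequency mismatch"):
            phase_shift(a, b, 0.01)

    def test_nonoscillatory_rejected(self):
        with pytest.raises(ValueError):
            phase_shift(np.full_like(self.t, 0.5), self.wave(0), 0.01)


class TestBendingAmplitude:
    def test_thirds_sum_peak_to_peak(self):
        kym = traveling_wave_curvature(ap_gradient=0.0)
        amps = bending_amplitudes_by_third(kym)
        # uniform wave: the thirds are comparable and positive
        vals = np.array(list(amps.values()))
        assert np.all(vals > 0)
        assert vals.max() / vals.min() < 1.3

    def test_graded_wave_head_heavier(self):
        amps = bending_amplitudes_by_third(traveling_wave_curvature(ap_gradient=0.5))
        assert amps["head"] > amps["mid"] > amps["tail"]


class TestSubcircuits:
    def test_zero_weight_subcircuit_scores_zero(self):
        # all-zero genotype -> zero weights everywhere -> fixed point;
        # long settle so the exponential approach has fully decayed
        from wormcpg.simulation import SimConfig

        score = subcircuit_oscillation_score(np.zeros(44), "AS-DA-DB",
                                             tonic_steps=3, tonic_span=2.0,
                                             config=SimConfig(duration=25.0, transient=15.0))
        assert score < 1e-6

    def test_unknown_subcircuit_rejected(self):
        with pytest.raises(ValueError):
            subcircuit_oscillation_score(np.zeros(44), "AS-VB-DD")

    def test_grid_order_invariance(self, oscillator_genotype):
        # the max over the tonic grid cannot depend on sweep order
        a = subcircuit_oscillation_score(oscillator_genotype, "AS-DA-DB",
                                         tonic_steps=3, tonic_span=1.0)
        b = subcircuit_oscillation_score(oscillator_genotype, "AS-DA-DB",
                                         tonic_steps=3, tonic_span=1.0)
        assert a == b

    def test_demo_oscillator_dorsal_core_oscillates(self, oscillator_genotype):
        score = subcircuit_oscillation_score(oscillator_genotype, "AS-DA-DB",
                                             tonic_steps=5, tonic_span=3.0)
        assert score > 0.05


class TestCoordination:
    def test_zero_degree_perturbation_shifts_nothing(self, locomotor_genotype):
        from wormcpg.analysis import entrainment_analysis

        shifts = entrainment_analysis(locomotor_genotype, perturbed_unit=0,
                                      phase_shift_deg=0.0)
        assert set(shifts) == set(range(7))
        assert all(abs(v) < 3.0 for v in shifts.values())

    def test_decoupled_chain_keeps_perturbation_local(self, locomotor_genotype):
        # with every interunit connection removed, units oscillate
        # independently: the perturbed unit keeps its imposed shift and
        # no other unit adopts any of it
        import dataclasses

        from wormcpg.analysis import INTERUNIT_CONNECTIONS, entrainment_analysis
        from wormcpg.analysis import mask_connections
        from wormcpg.circuit import build_circuit, decode_genotype
        from wormcpg.simulation import EmbodiedModel

        params, conn, _ = decode_genotype(locomotor_genotype)
        empty = dataclasses.replace(
            conn,
            interunit_chemical={k: 0.0 for k in conn.interunit_chemical},
            interunit_gap={k: 0.0 for k in conn.interunit_gap},
        )
        from wormcpg.circuit import encode_genotype

        decoupled = encode_genotype(params, empty, 0.5)
        shifts = entrainment_analysis(decoupled, perturbed_unit=0,
                                      phase_shift_deg=90.0)
        assert shifts[0] == pytest.approx(90.0, abs=8.0)   # keeps its own shift
        for u in range(1, 7):
            assert abs(shifts[u]) < 3.0                     # never propagates

    def test_single_junction_entrainment_directionality(self, locomotor_genotype):
        # anatomy fixes the direction of coordination when one interunit
        # gap junction acts alone: VB-DB+1 places the posterior unit
        # downstream (anterior perturbations propagate tailward),
        # AS-VA+1 places the anterior unit downstream (headward)
        from wormcpg.analysis import (
            INTERUNIT_CONNECTIONS,
            entrainment_analysis,
            mask_connections,
        )
        from wormcpg.circuit import build_circuit, decode_genotype

        params, conn, _ = decode_genotype(locomotor_genotype)
        wiring = build_circuit(params, conn, 7)

        def adoption(keep, perturbed_unit):
            w = mask_connections(
                wiring, [n for n in INTERUNIT_CONNECTIONS if n != keep])
            shifts = entrainment_analysis(w, perturbed_unit, 120.0)
            # mean adopted shift over the units nearest the far end
            far = range(1, 4) if perturbed_unit == 6 else range(3, 6)
            return np.mean([abs(shifts[u]) for u in far])

        tailward = adoption("VB-DB+1", 0)
        headward_vbdb = adoption("VB-DB+1", 6)
        assert tailward > 3 * headward_vbdb + 5.0

        headward = adoption("AS-VA+1", 6)
        tailward_asva = adoption("AS-VA+1", 0)
        assert headward > 3 * tailward_asva + 5.0

    def test_necessity_sufficiency_report_structure(self, locomotor_genotype):
        from wormcpg.analysis import (
            INTERUNIT_CONNECTIONS,
            interunit_necessity_sufficiency,
        )
        from wormcpg.simulation import SimConfig

        rep = interunit_necessity_sufficiency(
            locomotor_genotype, config=SimConfig(duration=16.0, transient=3.0))
        assert set(rep.necessity) == set(INTERUNIT_CONNECTIONS)
        assert set(rep.sufficiency) == set(INTERUNIT_CONNECTIONS)
        assert rep.category in ("simple", "redundant", "complex")
        assert all(0.0 <= v <= 1.0 for v in rep.necessity.values())
        assert all(0.0 <= v <= 1.0 for v in rep.sufficiency.values())

    def test_removing_all_interunit_connections_breaks_locomotion(
            self, locomotor_genotype, analysis_config):
        import dataclasses

        from wormcpg.analysis import INTERUNIT_CONNECTIONS, mask_connections
        from wormcpg.fitness import mean_velocity
        from wormcpg.simulation import EmbodiedModel

        model = EmbodiedModel.from_genotype(locomotor_genotype)
        base = model.simulate(analysis_config).post_transient()
        cut = dataclasses.replace(
            model, wiring=mask_connections(model.wiring, INTERUNIT_CONNECTIONS))
        broken = cut.simulate(analysis_config).post_transient()
        v_base = mean_velocity(base.com, base.dt)
        v_cut = mean_velocity(broken.com, broken.dt)
        assert v_cut < 0.5 * v_base  # uncoordinated units cannot crawl properly


class TestConnectionMasking:
    def test_masking_zero_weight_connection_changes_nothing(self, oscillator_genotype):
        params, conn, _ = decode_genotype(np.zeros(44))
        wiring = build_circuit(params, conn, 7)
        # chemical interunit weights are zero at the range midpoint
        masked = mask_connections(wiring, ["DB->DD+1", "VA+1->DD"])
        np.testing.assert_array_equal(masked.chemical, wiring.chemical)
        np.testing.assert_array_equal(masked.gap, wiring.gap)

    def test_masking_removes_exactly_the_named_edges(self, locomotor_genotype):
        params, conn, _ = decode_genotype(locomotor_genotype)
        wiring = build_circuit(params, conn, 7)
        masked = mask_connections(wiring, ["VB-DB+1"])
        diff = wiring.gap - masked.gap
        assert np.count_nonzero(diff) == 2 * 6  # six symmetric interunit pairs
        np.testing.assert_array_equal(masked.chemical, wiring.chemical)
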