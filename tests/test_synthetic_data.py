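"""Generator-level checks: closed-form agreement, dominant-negative
mixing, determinism, and the auxiliary profile/alignment fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ikslab.aux_quant import segment_profile
from ikslab.ephys_analysis import VoltageProtocol
from ikslab.synthetic_data import (
    EK_RECORDING_MV,
    WT_GATE,
    DNMixture,
    GateModel,
    SyntheticCellConfig,
    conserved_column,
    dn_fraction_by_enumeration,
    dn_functional_fraction,
    gate_closed_form,
    generate_alignment,
    generate_cell_population,
    generate_intensity_profile,
    nernst_potential,
    simulate_iks_sweeps,
    uniform_column,
)

FAST_GATE = GateModel(v_half=25.0, slope_k=17.0, tau_params=(20.0, 60.0, -10.0, 30.0))


class TestNernst:
    def test_potassium_recording_solutions(self):
        # 140 mM internal / 5.4 mM external K+ at 24 C
        assert nernst_potential(140.0, 5.4, 1, 297.15) == pytest.approx(-83.3, abs=0.1)

    def test_equal_concentrations_zero(self):
        assert nernst_potential(12.0, 12.0) == 0.0

    def test_valence_scaling(self):
        e1 = nernst_potential(10.0, 100.0, valence=1)
        e2 = nernst_potential(10.0, 100.0, valence=2)
        assert e2 == pytest.approx(e1 / 2)

    @pytest.mark.parametrize("cin,cout", [(0.0, 5.4), (140.0, -1.0)])
    def test_nonpositive_concentration_rejected(self, cin, cout):
        with pytest.raises(ValueError):
            nernst_potential(cin, cout)


class TestDominantNegative:
    @pytest.mark.parametrize(
        "f,expected", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.0625)]
    )
    def test_strict_rule_closed_form(self, f, expected):
        assert dn_functional_fraction(DNMixture(f)) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.sampled_from(
        ["all-WT-required", "any-mutant-tolerated-with-scaling"]))
    def test_matches_binomial_enumeration(self, f, rule):
        mix = DNMixture(f, rule)
        assert dn_functional_fraction(mix) == pytest.approx(
            dn_fraction_by_enumeration(mix), abs=1e-12
        )

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)))
    def test_monotone_decreasing_in_mutant_fraction(self, pair):
        lo, hi = sorted(pair)
        assert dn_functional_fraction(DNMixture(hi)) <= dn_functional_fraction(
            DNMixture(lo)
        ) + 1e-12

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            DNMixture(1.5)


class TestSweepSimulation:
    def test_noiseless_matches_closed_form(self, fast_gate_protocol):
        cfg = SyntheticCellConfig(noise_sd_pa=0.0)
        ss = simulate_iks_sweeps(FAST_GATE, fast_gate_protocol, cfg)
        for v, (t, i) in ss.sweeps.items():
            x = gate_closed_form(FAST_GATE, fast_gate_protocol, v, t)
            volts = np.where(
                t < fast_gate_protocol.step_start_ms, fast_gate_protocol.holding_mv,
                np.where(t < fast_gate_protocol.tail_start_ms, v,
                         fast_gate_protocol.tail_mv),
            )
            expected = (cfg.g_density_ns_pf * cfg.capacitance_pf
                        * x ** FAST_GATE.gate_power * (volts - cfg.e_rev_mv))
            scale = np.max(np.abs(expected))
            assert np.max(np.abs(i - expected)) / scale < 1e-6

    def test_end_of_step_current_reaches_steady_state(self, fast_gate_protocol):
        # step duration (2 s) >> tau (<= 80 ms for this gate)
        cfg = SyntheticCellConfig(noise_sd_pa=0.0)
        ss = simulate_iks_sweeps(FAST_GATE, fast_gate_protocol, cfg)
        for v, (t, i) in ss.sweeps.items():
            idx = np.searchsorted(t, fast_gate_protocol.tail_start_ms) - 1
            expected = (cfg.g_density_ns_pf * cfg.capacitance_pf
                        * FAST_GATE.x_inf(v) * (v - cfg.e_rev_mv))
            if abs(expected) > 1e-9:
                assert i[idx] == pytest.approx(expected, rel=1e-3)

    def test_step_at_reversal_potential_carries_no_current(self):
        proto = VoltageProtocol(
            step_potentials_mv=(EK_RECORDING_MV,), step_ms=500.0, tail_ms=200.0
        )
        cfg = SyntheticCellConfig(noise_sd_pa=0.0)
        ss = simulate_iks_sweeps(WT_GATE, proto, cfg)
        t, i = ss.sweeps[EK_RECORDING_MV]
        step = (t >= proto.step_start_ms) & (t < proto.tail_start_ms)
        assert np.max(np.abs(i[step])) < 1e-9

    def test_tail_onset_amplitude_and_single_exponential_decay(
        self, fast_gate_protocol
    ):
        cfg = SyntheticCellConfig(noise_sd_pa=0.0)
        ss = simulate_iks_sweeps(FAST_GATE, fast_gate_protocol, cfg)
        proto = fast_gate_protocol
        v_step = 80.0
        t, i = ss.sweeps[v_step]
        tail = t >= proto.tail_start_ms
        g = cfg.g_density_ns_pf * cfg.capacitance_pf
        x_end = FAST_GATE.x_inf(v_step)  # step >> tau
        onset = g * x_end * (proto.tail_mv - cfg.e_rev_mv)
        assert i[tail][0] == pytest.approx(onset, rel=1e-3)
        # relaxation follows exp(-t/tau(Vtail)) towards the tail steady state
        tau = FAST_GATE.tau_ms(proto.tail_mv)
        ts = t[tail] - proto.tail_start_ms
        x_inf_tail = FAST_GATE.x_inf(proto.tail_mv)
        expected = g * (proto.tail_mv - cfg.e_rev_mv) * (
            x_inf_tail + (x_end - x_inf_tail) * np.exp(-ts / tau)
        )
        assert np.max(np.abs(i[tail] - expected)) / abs(onset) < 1e-3

    def test_nonfinite_gate_rejected(self):
        with pytest.raises(ValueError):
            GateModel(v_half=math.nan, slope_k=17.0)


class TestPopulations:
    def test_same_seed_bit_identical(self, protocol):
        a = generate_cell_population("WT", 3, seed=9, protocol=protocol)
        b = generate_cell_population("WT", 3, seed=9, protocol=protocol)
        for ca, cb in zip(a, b):
            assert ca.capacitance_pf == cb.capacitance_pf
            for v in ca.sweeps:
                assert np.array_equal(ca.sweeps[v][1], cb.sweeps[v][1])

    def test_het_without_mutant_equals_wt(self, protocol):
        het = generate_cell_population(
            "HET", 2, seed=9, protocol=protocol, mixture=DNMixture(f_mut=0.0)
        )
        wt = generate_cell_population("WT", 2, seed=9, protocol=protocol)
        for ch, cw in zip(het, wt):
            for v in cw.sweeps:
                assert np.array_equal(ch.sweeps[v][1], cw.sweeps[v][1])

    def test_hom_mean_tail_density_below_wt(self, small_populations, protocol):
        from ikslab.ephys_analysis import build_tail_iv

        iv = build_tail_iv(
            small_populations["WT"] + small_populations["HOM"], protocol
        )
        assert iv.group_mean("HOM")[-1] < iv.group_mean("WT")[-1]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_population("KO", 2)


class TestIntensityProfile:
    def test_flat_when_peak_equals_plateau(self):
        prof = generate_intensity_profile(50, membrane_peak=2.0, cytosol_level=2.0,
                                          noise_sd=0.0)
        assert np.allclose(prof.intensities, 2.0)

    def test_noiseless_maxima_inside_end_segments(self):
        prof = generate_intensity_profile(100, noise_sd=0.0)
        n_end = 15
        peak_idx = int(np.argmax(prof.intensities))
        assert peak_idx < n_end or peak_idx >= 100 - n_end

    def test_quantifier_recovers_generator_ratio(self):
        prof = generate_intensity_profile(
            120, membrane_peak=3.0, cytosol_level=1.0, noise_sd=0.0
        )
        seg = segment_profile(prof)
        assert seg.membrane_index == pytest.approx(3.0, rel=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_intensity_profile(5)


class TestAlignmentGeneration:
    def test_fully_conserved_columns(self):
        aln = generate_alignment(6, [conserved_column("K")] * 4, seed=0)
        assert all(s == "KKKK" for s in aln.sequences)

    def test_uniform_columns_frequencies(self):
        from scipy.stats import chisquare

        n = 4000
        aln = generate_alignment(n, [uniform_column()], seed=3)
        counts = {}
        for s in aln.sequences:
            counts[s] = counts.get(s, 0) + 1
        assert len(counts) == 20
        stat = chisquare(list(counts.values()))
        assert stat.pvalue > 1e-3  # consistent with multinomial(1/20)

    def test_same_seed_identical(self):
        spec = [uniform_column()] * 5
        a = generate_alignment(8, spec, seed=11)
        b = generate_alignment(8, spec, seed=11)
        assert a.sequences == b.sequences

    def test_bad_distribution_rejected(self):
        with pytest.raises(ValueError):
            generate_alignment(4, [{"K": 0.6, "R": 0.2}])
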