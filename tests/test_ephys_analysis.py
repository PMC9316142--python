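"""Voltage-clamp analysis: tail extraction, I-V assembly, Boltzmann and
exponential fits, checked against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ikslab.ephys_analysis import (
    SweepSet,
    boltzmann,
    build_tail_iv,
    extract_tail_peak,
    fit_boltzmann,
    fit_exponential,
    summarize_group,
    tail_density,
)
from ikslab.synthetic_data import (
    GateModel,
    SyntheticCellConfig,
    generate_cell_population,
    simulate_iks_sweeps,
)

FAST_GATE = GateModel(v_half=25.0, slope_k=17.0, tau_params=(20.0, 60.0, -10.0, 30.0))


def _flat_cell(cell_id, value, protocol, cap=10.0, group="G"):
    t = np.arange(0.0, protocol.total_ms + 0.5, 1.0)
    sweeps = {v: (t, np.full_like(t, float(value)))
              for v in protocol.step_potentials_mv}
    return SweepSet(cell_id=cell_id, capacitance_pf=cap, sweeps=sweeps, group=group)


class TestTailPeak:
    def test_constant_current_returned_as_is(self):
        t = np.arange(0.0, 500.0)
        assert extract_tail_peak(t, np.full(500, 7.5), 300.0) == 7.5

    def test_all_zero_sweep(self):
        t = np.arange(0.0, 500.0)
        assert extract_tail_peak(t, np.zeros(500), 300.0) == 0.0

    def test_window_outside_sweep_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            extract_tail_peak(t, np.zeros(100), 80.0, blank_ms=5.0, window_ms=100.0)

    def test_noiseless_tail_onset_matches_analytic_amplitude(self, fast_gate_protocol):
        cfg = SyntheticCellConfig(noise_sd_pa=0.0)
        ss = simulate_iks_sweeps(FAST_GATE, fast_gate_protocol, cfg)
        proto = fast_gate_protocol
        t, i = ss.sweeps[80.0]
        peak = extract_tail_peak(t, i, proto.tail_start_ms, blank_ms=0.0,
                                 window_ms=100.0, smooth_ms=0.0)
        g = cfg.g_density_ns_pf * cfg.capacitance_pf
        analytic = g * FAST_GATE.x_inf(80.0) * (proto.tail_mv - cfg.e_rev_mv)
        assert peak == pytest.approx(analytic, rel=1e-3)


class TestTailDensity:
    def test_arithmetic(self):
        assert tail_density(100.0, 10.0) == 10.0
        assert tail_density(0.0, 3.7) == 0.0

    def test_capacitance_scaling(self):
        assert tail_density(80.0, 20.0) == tail_density(80.0, 10.0) / 2

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(ValueError):
            tail_density(10.0, 0.0)


class TestTailIV:
    def test_constant_tails_give_constant_iv(self, protocol):
        iv = build_tail_iv([_flat_cell("c1", 20.0, protocol)], protocol)
        assert np.allclose(iv.densities.loc["c1"].to_numpy(), 2.0)

    def test_identical_cells_zero_sem(self, protocol):
        cells = [_flat_cell(f"c{k}", 20.0, protocol) for k in range(4)]
        iv = build_tail_iv(cells, protocol)
        assert np.allclose(iv.summary["sem"].to_numpy(), 0.0)
        assert (iv.summary["n"] == 4).all()

    def test_missing_sweep_error_names_cell_and_potential(self, protocol):
        cell = _flat_cell("bad_cell", 1.0, protocol)
        del cell.sweeps[80.0]
        with pytest.raises(ValueError, match=r"bad_cell.*80"):
            build_tail_iv([cell], protocol)

    def test_invariant_under_joint_capacitance_rescaling(self, protocol):
        base = generate_cell_population("WT", 2, seed=21, protocol=protocol)
        scaled = []
        for cell in base:
            sweeps = {v: (t.copy(), 3.0 * i) for v, (t, i) in cell.sweeps.items()}
            scaled.append(
                SweepSet(cell.cell_id, 3.0 * cell.capacitance_pf, sweeps,
                         group=cell.group)
            )
        iv_a = build_tail_iv(base, protocol)
        iv_b = build_tail_iv(scaled, protocol)
        assert np.allclose(iv_a.densities.to_numpy(), iv_b.densities.to_numpy())

    def test_mutant_groups_shifted_and_reduced(self, small_populations, protocol):
        """Mutant groups: lower densities at depolarised potentials, more
        positive V50 and larger slope factor than WT."""
        cells = sum(small_populations.values(), [])
        iv = build_tail_iv(cells, protocol)
        pots = iv.potentials_mv
        fits = {}
        for grp in ("WT", "HOM", "HET"):
            mean = iv.group_mean(grp)
            fits[grp] = fit_boltzmann(pots, mean)
            if grp != "WT":
                sel = pots >= 20.0
                assert np.all(mean[sel] < iv.group_mean("WT")[sel])
        for grp in ("HOM", "HET"):
            assert fits[grp].v50_mv > fits["WT"].v50_mv
            assert fits[grp].k_mv > fits["WT"].k_mv


class TestBoltzmannFit:
    def test_exact_curve_recovered(self):
        v = np.arange(-60.0, 81.0, 20.0)
        y = boltzmann(v, 10.0, 25.0, 17.0)
        fit = fit_boltzmann(v, y)
        assert fit.success
        assert fit.i_max == pytest.approx(10.0, abs=1e-6)
        assert fit.v50_mv == pytest.approx(25.0, abs=1e-6)
        assert fit.k_mv == pytest.approx(17.0, abs=1e-6)

    def test_value_at_fitted_v50_is_half_imax(self):
        rng = np.random.default_rng(5)
        v = np.arange(-60.0, 81.0, 20.0)
        y = boltzmann(v, 12.0, 10.0, 20.0) + rng.normal(0, 0.2, v.size)
        fit = fit_boltzmann(v, y)
        assert boltzmann(np.array([fit.v50_mv]), fit.i_max, fit.v50_mv,
                         fit.k_mv)[0] == pytest.approx(fit.i_max / 2)

    def test_at_least_as_good_as_grid_search_oracle(self):
        """Dense (V50, k) grid with Imax profiled linearly is the
        independent oracle; the optimizer must land in its confidence
        region (SSE no worse, parameters within a grid cell)."""
        rng = np.random.default_rng(17)
        v = np.arange(-60.0, 81.0, 20.0)
        y = boltzmann(v, 8.0, 22.0, 15.0) + rng.normal(0, 0.3, v.size)
        best = (math.inf, None, None)
        for v50 in np.arange(0.0, 40.01, 0.25):
            for k in np.arange(8.0, 25.01, 0.25):
                b = 1.0 / (1.0 + np.exp((v50 - v) / k))
                imax = float(y @ b / (b @ b))
                sse = float(np.sum((y - imax * b) ** 2))
                if sse < best[0]:
                    best = (sse, v50, k)
        fit = fit_boltzmann(v, y)
        sse_fit = fit.residual_norm ** 2
        assert sse_fit <= best[0] + 1e-9
        assert abs(fit.v50_mv - best[1]) <= 0.5
        assert abs(fit.k_mv - best[2]) <= 0.5

    def test_noiseless_generator_round_trip(self, fast_gate_protocol):
        """Boltzmann fit of noiseless tail densities recovers the
        generator's v_half and slope_k to < 0.01 mV."""
        # fast gates so the step fully equilibrates within the protocol
        cfg = SyntheticCellConfig(noise_sd_pa=0.0)
        ss = simulate_iks_sweeps(FAST_GATE, fast_gate_protocol, cfg)
        # single-sample window: the extremum is exactly the tail onset
        iv = build_tail_iv([ss], fast_gate_protocol, blank_ms=0.0,
                           window_ms=0.5, smooth_ms=0.0)
        fit = fit_boltzmann(iv.potentials_mv, iv.densities.iloc[0].to_numpy())
        assert fit.v50_mv == pytest.approx(FAST_GATE.v_half, abs=0.01)
        assert fit.k_mv == pytest.approx(FAST_GATE.slope_k, abs=0.01)
        # fitted curve: monotone in V, normalised G/Gmax within [0, 1+eps]
        dense = boltzmann(np.linspace(-80, 100, 200), fit.i_max, fit.v50_mv, fit.k_mv)
        assert np.all(np.diff(dense) >= 0)
        g_norm = iv.densities.iloc[0].to_numpy() / fit.i_max
        assert np.all(g_norm >= -1e-6) and np.all(g_norm <= 1.0 + 1e-3)

    def test_too_few_potentials_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([0.0, 20.0, 40.0], [1.0, 2.0, 3.0])


class TestExponentialFit:
    def test_exact_tau_recovered(self):
        t = np.arange(0.0, 3000.0, 5.0)
        y = 2.0 + 8.0 * np.exp(-t / 750.0)
        fit = fit_exponential(t, y)
        assert fit.success
        assert fit.tau_ms == pytest.approx(750.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(8.0, rel=1e-6)
        assert fit.offset == pytest.approx(2.0, rel=1e-6)

    def test_constant_series_flagged(self):
        t = np.arange(0.0, 100.0, 10.0)
        fit = fit_exponential(t, np.full(t.size, 4.0))
        assert not fit.success

    def test_noisy_decay_within_grid_oracle_interval(self):
        """Brute-force tau grid with (amplitude, offset) profiled by
        linear least squares brackets the nonlinear fit."""
        rng = np.random.default_rng(23)
        t = np.arange(0.0, 3000.0, 5.0)
        y = 1.0 + 10.0 * np.exp(-t / 600.0) + rng.normal(0, 0.3, t.size)
        taus = np.arange(100.0, 1500.0, 5.0)
        sses = []
        for tau in taus:
            basis = np.column_stack([np.ones_like(t), np.exp(-t / tau)])
            coef, res, *_ = np.linalg.lstsq(basis, y, rcond=None)
            sses.append(float(np.sum((y - basis @ coef) ** 2)))
        tau_grid = float(taus[int(np.argmin(sses))])
        fit = fit_exponential(t, y)
        assert fit.success
        assert abs(fit.tau_ms - tau_grid) <= 5.0
        assert fit.residual_norm ** 2 <= min(sses) + 1e-9

    def test_strictly_increasing_time_required(self):
        with pytest.raises(ValueError):
            fit_exponential([0.0, 1.0, 1.0, 2.0, 3.0], [1, 2, 3, 4, 5])


class TestSummarizeGroup:
    @pytest.mark.parametrize(
        "values,expected",
        [([2.0, 2.0, 2.0], (2.0, 0.0, 3)), ([0.0, 2.0], (1.0, 1.0, 2))],
    )
    def test_hand_arithmetic(self, values, expected):
        assert summarize_group(values) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_agrees_with_two_pass_oracle(self, values):
        mean, sem, n = summarize_group(values)
        mu = sum(values) / len(values)
        var = sum((x - mu) ** 2 for x in values) / (len(values) - 1)
        assert mean == pytest.approx(mu, abs=1e-9)
        assert sem == pytest.approx(math.sqrt(var / len(values)), abs=1e-9)
        assert n == len(values)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])
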