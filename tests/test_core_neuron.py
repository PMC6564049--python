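"""Single-neuron model: decay semantics, input statistics, spiking rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmnnet import NeuronParams, half_life_to_tau, simulate_single
from vmnnet.core_neuron import (NeuronState, external_input_step,
                                generate_external_input,
                                relative_refractory_estimate, step)
from vmnnet.analysis import iod_range


class TestHalfLifeToTau:
    def test_identity_case(self):
        assert half_life_to_tau(math.log(2.0)) == pytest.approx(1.0)

    def test_psp_half_life(self):
        # 7.5-ms PSP half-life -> tau = 7.5/ln 2
        assert half_life_to_tau(7.5) == pytest.approx(10.8202, abs=1e-4)

    @given(st.floats(min_value=0.01, max_value=1e4))
    @settings(derandomize=True, max_examples=50)
    def test_decay_by_tau_halves(self, lam):
        tau = half_life_to_tau(lam)
        assert math.exp(-lam / tau) == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            half_life_to_tau(bad)


class TestExternalInput:
    def test_zero_rate_is_silent(self, rng):
        p = NeuronParams(i_re=0.0)
        assert all(external_input_step(p, rng) == 0.0 for _ in range(100))

    def test_balanced_rates_cancel_in_mean(self):
        # default drive: E[e_n] = E[i_n] = 0.3 per 1-ms step -> E[I_ext] = 0
        p = NeuronParams(i_re=300.0, i_ratio=1.0)
        draws = generate_external_input(p, 1_000_000, np.random.default_rng(0))
        assert abs(draws.mean()) < 3 * draws.std() / np.sqrt(draws.size)

    def test_unbalanced_rates_net_positive(self):
        # 200 Hz EPSPs, 100 Hz IPSPs, 3-mV amplitudes -> +0.3 mV/step
        p = NeuronParams(i_re=200.0, i_ratio=0.5)
        draws = generate_external_input(p, 1_000_000, np.random.default_rng(1))
        se = draws.std() / np.sqrt(draws.size)
        assert draws.mean() == pytest.approx(0.3, abs=3 * se)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(i_re=-1.0)


class TestStep:
    def test_quiescent_neuron_stays_at_rest(self):
        p = NeuronParams(k_hap=0.0, k_ahp=0.0, k_dap=0.0, init_at_k=False)
        s = NeuronState()
        for t in range(1, 1000):
            s, spiked = step(s, p, 0.0, float(t))
            assert not spiked
        assert s.voltage(p) == pytest.approx(p.v_rest)

    def test_post_spike_hap_drop_and_recovery(self):
        # a spike knocks V down by exactly k_HAP = 30 mV, recovering with
        # the HAP half-life
        p = NeuronParams(exact_decay=True, init_at_k=False)
        s = NeuronState()
        s.v_syn = 20.0  # suprathreshold after one decay step
        s, spiked = step(s, p, 0.0, 1.0)
        assert spiked
        v_pre_increment = p.v_rest + s.v_syn
        assert s.voltage(p) == pytest.approx(v_pre_increment - p.k_hap)
        # free decay: HAP halves after lambda_HAP
        hap0 = s.hap
        for t in range(2, 2 + int(p.lambda_hap)):
            s, _ = step(s, p, 0.0, float(t))
        assert s.hap == pytest.approx(hap0 / 2, rel=1e-9)

    def test_absolute_refractory_blocks_early_spikes(self):
        # V pinned far above threshold: ISIs must still exceed 2 ms
        p = NeuronParams(k_hap=0.0, init_at_k=False)
        s = NeuronState()
        for t in range(1, 50):
            step(s, p, 100.0, float(t))
        isis = np.diff(s.spike_times)
        assert len(s.spike_times) > 3
        assert np.all(isis > p.t_refabs)


class TestSimulateSingle:
    def test_determinism(self, hap_only_defaults):
        a, _ = simulate_single(hap_only_defaults, 20_000.0, seed=5)
        b, _ = simulate_single(hap_only_defaults, 20_000.0, seed=5)
        np.testing.assert_array_equal(a.times, b.times)

    def test_kernel_matches_reference_step(self, hap_only_defaults):
        """Compiled kernel reproduces the scalar reference implementation."""
        p = hap_only_defaults
        n_steps = 5000
        inp = generate_external_input(p, n_steps, np.random.default_rng(3))
        s = NeuronState.initial(p)
        for k in range(n_steps):
            step(s, p, float(inp[k]), (k + 1) * p.dt)
        ref_times = np.array(s.spike_times)

        # drive the compiled path with the identical input sequence
        from vmnnet import _kernels
        from vmnnet.core_neuron import _decay_factors
        d = _decay_factors(p)
        init = NeuronState.initial(p)
        spikes, n_sp, _, _ = _kernels.single_neuron_kernel(
            inp, p.dt, *d, p.k_hap, p.k_ahp, p.k_dap,
            p.v_rest, p.v_thresh, p.t_refabs,
            init.v_syn, init.hap, init.ahp, init.dap, init.t_last_spike,
            0.0, False)
        np.testing.assert_allclose(spikes, ref_times)

    def test_default_neuron_rate_in_random_cell_band(self, hap_only_defaults):
        # defaults behave like an in-vivo "random" cell: 1-10 spikes/s,
        # all ISIs beyond the absolute refractory period
        train, _ = simulate_single(hap_only_defaults, 200_000.0, seed=1)
        assert train.n > 0
        assert 1.0 <= train.rate <= 10.0
        assert train.isis.min() > hap_only_defaults.t_refabs

    def test_no_afterpotentials_gives_poisson_like_output(self):
        """Memoryless regime: no afterpotentials, excitatory-only drive
        where each single EPSP reaches threshold and decays away before the
        refractory period ends.  Output is then the input Poisson process
        (minus rare refractory collisions): exponential ISIs, flat IoD ~ 1.
        """
        from scipy import stats
        p = NeuronParams(i_re=5.0, i_ratio=0.0, e_h=15.0, lambda_syn=1.0,
                         k_hap=0.0, k_ahp=0.0, k_dap=0.0, init_at_k=False)
        train, _ = simulate_single(p, 2_000_000.0, seed=2)
        body = train.crop(5000.0)
        for bw, val in zip((0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
                           iod_range(body).values):
            n_bins = int(body.duration // (bw * 1000.0))
            null_sd = np.sqrt(2.0 / (n_bins - 1))
            assert abs(val - 1.0) < max(0.1, 4 * null_sd), (bw, val)
        # ISIs exponential above the refractory floor
        res = stats.kstest(body.isis - body.isis.min(), "expon",
                           args=(0, body.isis.mean() - body.isis.min()))
        assert res.pvalue > 0.01

    def test_pacemaker_regular_firing(self):
        # resting potential above threshold + slow HAP: near-constant ISIs
        p = NeuronParams(i_re=0.0, v_rest=-45.0, k_hap=30.0, lambda_hap=80.0,
                         init_at_k=False)
        train, _ = simulate_single(p, 200_000.0, seed=3)
        isis = train.crop(5000.0).isis
        assert isis.std() / isis.mean() < 0.05
        iods = iod_range(train.crop(5000.0)).values
        assert np.all(iods < 0.1)

    def test_voltage_trace_recorded_every_step(self, hap_only_defaults):
        train, v = simulate_single(hap_only_defaults, 5_000.0, seed=4,
                                   record_voltage=True)
        assert v.shape == (5000,)
        assert np.all(np.isfinite(v))

    def test_ahp_lowers_iod_dap_raises_it(self):
        """Slow AHP is negative feedback (IoD < 1, falling with binwidth);
        a slow DAP is positive feedback that makes cells burstier (IoD > 1
        at long binwidths, rising).  The DAP arm uses a slow-HAP cell:
        enough activity-dependent inhibition to keep the positive feedback
        out of runaway while the burstiness signature develops."""
        p_ahp = NeuronParams(i_re=300.0, k_hap=30.0, lambda_hap=8.0,
                             k_ahp=2.0, lambda_ahp=500.0)
        p_dap = NeuronParams(i_re=250.0, k_hap=20.0, lambda_hap=40.0,
                             k_dap=0.8, lambda_dap=1000.0)
        iods = {}
        for name, p in [("ahp", p_ahp), ("dap", p_dap)]:
            vals = []
            for seed in (10, 11, 12):
                tr, _ = simulate_single(p, 500_000.0, seed=seed)
                vals.append(iod_range(tr.crop(5000.0)).values)
            iods[name] = np.mean(vals, axis=0)
        assert iods["ahp"][-1] < 1.0 < iods["dap"][-1]
        # opposite trends across the binwidth range
        assert iods["ahp"][-1] < iods["ahp"][0]
        assert iods["dap"][-1] > iods["dap"][0]


class TestDecayExactness:
    def test_exact_mode_tracks_closed_form(self):
        """With exact decay, no input and no spikes, HAP(t) follows
        HAP(0) * 2^(-t/lambda) to 1e-9 relative error."""
        p = NeuronParams(exact_decay=True, init_at_k=True)
        s = NeuronState.initial(p)
        hap0 = s.hap
        for t in range(1, 101):
            # keep V below threshold: no input, HAP only decays
            s, spiked = step(s, p, 0.0, float(t))
            assert not spiked
            expected = hap0 * 2.0 ** (-t / p.lambda_hap)
            assert s.hap == pytest.approx(expected, rel=1e-9)


class TestRelativeRefractory:
    def test_amplitude_within_threshold_gives_zero(self):
        assert relative_refractory_estimate(
            NeuronParams(k_hap=1.0)) == 0.0

    def test_all_zero_amplitudes_give_zero(self):
        assert relative_refractory_estimate(
            NeuronParams(k_hap=0.0, k_ahp=0.0, k_dap=0.0)) == 0.0

    def test_hap_only_closed_form(self):
        # k=30, lambda=8 -> 8*log2(30) ~ 39.25 ms
        est = relative_refractory_estimate(NeuronParams(k_hap=30.0,
                                                        lambda_hap=8.0))
        assert est == pytest.approx(8.0 * math.log2(30.0), abs=0.02)

    def test_broad_cell_estimate(self):
        # mean broad-cell fit (k=20 mV, lambda=22 ms) -> ~95 ms, matching
        # the ~96 ms printed from per-cluster medians to within 5 ms
        est = relative_refractory_estimate(NeuronParams(k_hap=20.0,
                                                        lambda_hap=22.0))
        assert est == pytest.approx(96.0, abs=5.0)

    def test_matches_trace_simulation(self):
        """Closed-form/grid estimate agrees with an explicit voltage-trace
        simulation of the post-spike recovery."""
        p = NeuronParams(k_hap=40.0, lambda_hap=15.0, k_ahp=1.0,
                         lambda_ahp=300.0, exact_decay=True)
        est = relative_refractory_estimate(p)
        # simulate the decay directly at fine resolution
        t = np.arange(0.0, 2000.0, 0.01)
        dev = (p.k_hap * 2.0 ** (-t / p.lambda_hap)
               + p.k_ahp * 2.0 ** (-t / p.lambda_ahp))
        t_cross = t[np.nonzero(dev <= 1.0)[0][0]]
        assert est == pytest.approx(t_cross, abs=0.05)
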