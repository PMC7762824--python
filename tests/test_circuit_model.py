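"""Circuit structure, firing nonlinearity, magnesium switch and equations of motion."""

import numpy as np
import pytest
from scipy.integrate import quad

from tcmodel.circuit_model import (CHANNEL_ORDER, FiringFunction,
                                   ParameterVector, PhysicalModel,
                                   build_cmc, build_tcm, conductance_drive,
                                   firing_rate, gamma_name, mg_switch,
                                   parameter_names, state_derivative)
from tcmodel.exceptions import (InvalidParameterError, NumericalError,
                                StructuralError)


class TestStructure:
    def test_tcm_has_8_populations_56_states(self, tcm_spec):
        assert tcm_spec.n_populations == 8
        assert tcm_spec.n_states == 56
        assert tcm_spec.states_per_population == 7

    def test_cmc_has_4_populations_20_states(self, cmc_spec):
        assert cmc_spec.n_populations == 4
        assert cmc_spec.n_states == 20
        assert cmc_spec.states_per_population == 5
        assert "M" not in cmc_spec.state_channels
        assert "GABA_B" in cmc_spec.state_channels

    def test_tcm_free_connectivity_count_is_41(self, tcm_spec):
        assert tcm_spec.connectivity.n_free == 41

    def test_mh_channels_only_on_tp_and_rl(self, tcm_spec):
        for pop in tcm_spec.populations:
            if pop.name in ("TP", "RL"):
                assert {"M", "H"} <= pop.channels
            else:
                assert not ({"M", "H"} & pop.channels)

    def test_every_population_has_synaptic_channels(self, tcm_spec, cmc_spec):
        for spec in (tcm_spec, cmc_spec):
            for pop in spec.populations:
                assert {"AMPA", "NMDA", "GABA_A", "GABA_B"} <= pop.channels

    def test_significant_pathways_are_free(self, tcm_spec):
        edges = set(tcm_spec.connectivity.free_edges)
        assert ("AMPA", "SI", "SP") in edges
        assert ("NMDA", "SI", "SP") in edges
        assert ("NMDA", "DP", "DP") in edges
        assert ("GABA_A", "DP", "DP") in edges

    def test_gaba_sources_inhibitory_or_diagonal(self, tcm_spec):
        excit = {p.name: p.is_excitatory for p in tcm_spec.populations}
        for ch, tgt, src in tcm_spec.connectivity.free_edges:
            if ch == "GABA_A":
                assert (not excit[src]) or tgt == src

    def test_channel_kinetics_constraints(self, tcm_spec):
        threshold = tcm_spec.firing.threshold
        rest = tcm_spec.leak_reversal
        for kind in ("AMPA", "NMDA"):
            assert tcm_spec.channels[kind].reversal_potential > threshold
        for kind in ("GABA_A", "GABA_B"):
            assert tcm_spec.channels[kind].reversal_potential < rest
        assert len(CHANNEL_ORDER) == 6
        for ch in tcm_spec.channels.values():
            assert ch.rate_constant > 0

    def test_parameter_vector_layout(self, tcm_spec, cmc_spec):
        # 41 weights + 6 rates + 8 C + 8 Sigma + 2 delays + input + scale
        assert len(parameter_names(tcm_spec)) == 67
        # 18 weights + 6 rates + 4 C + 4 Sigma + input + scale
        assert len(parameter_names(cmc_spec)) == 34

    def test_zero_coefficients_give_prior_means(self, tcm_spec, tcm_params):
        model = PhysicalModel(tcm_spec, tcm_params)
        conn = tcm_spec.connectivity
        assert np.allclose(model.G_ampa, conn.gamma["AMPA"])
        assert model.kappa["AMPA"] == pytest.approx(
            tcm_spec.channels["AMPA"].rate_constant)

    def test_log_scaling_positivity(self, tcm_spec, tcm_params):
        p = tcm_params.updated({"kappa:AMPA": -5.0, "input_gain": -5.0})
        model = PhysicalModel(tcm_spec, p)
        assert model.kappa["AMPA"] > 0
        assert model.u.sum() > 0


class TestFiringRate:
    def test_half_activation_at_threshold(self, tcm_spec):
        assert firing_rate(-40.0, tcm_spec.firing, 0) == pytest.approx(0.5)

    def test_limits(self, tcm_spec):
        assert firing_rate(500.0, tcm_spec.firing, 0) == pytest.approx(1.0)
        assert firing_rate(-500.0, tcm_spec.firing, 0) == pytest.approx(0.0)

    def test_one_sd_above_threshold(self, tcm_spec):
        sd = np.sqrt(tcm_spec.firing.dispersion[0])
        assert firing_rate(-40.0 + sd, tcm_spec.firing, 0) == pytest.approx(
            0.8413447460685429, abs=1e-8)

    def test_matches_quadrature_oracle(self, tcm_spec):
        sigma2 = tcm_spec.firing.dispersion[3]

        def gauss(x):
            return np.exp(-0.5 * (x + 40.0) ** 2 / sigma2) / np.sqrt(
                2 * np.pi * sigma2)

        for v in np.linspace(-100.0, 20.0, 13):
            expected, _ = quad(gauss, -200.0, v)
            assert firing_rate(v, tcm_spec.firing, 3) == pytest.approx(
                expected, abs=1e-8)

    def test_monotone(self, tcm_spec):
        grid = np.linspace(-100, 20, 200)
        rates = firing_rate(grid, tcm_spec.firing, 0)
        assert np.all(np.diff(rates) >= 0)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(InvalidParameterError):
            FiringFunction(dispersion=np.array([1.0, -1.0]))


class TestMgSwitch:
    def test_value_at_zero_voltage(self):
        for alpha in (0.01, 0.06, 0.5):
            assert mg_switch(0.0, alpha) == pytest.approx(1 / 1.2)

    def test_limits(self):
        assert mg_switch(-1e4, 0.06) == pytest.approx(0.0, abs=1e-12)
        assert mg_switch(1e4, 0.06) == pytest.approx(1.0)

    def test_strictly_increasing_and_bounded(self):
        v = np.linspace(-120, 60, 500)
        s = mg_switch(v, 0.06)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 1))

    def test_invalid_alpha(self):
        with pytest.raises(InvalidParameterError):
            mg_switch(0.0, 0.0)


class TestConductanceDrive:
    def test_zero_firing_gives_zero_drive(self, tcm_spec, tcm_params):
        drive = conductance_drive(tcm_spec, tcm_params, np.zeros(8))
        for v in drive.values():
            assert np.all(v == 0)

    def test_single_pathway(self, tcm_spec, tcm_params):
        f = np.zeros(8)
        src = tcm_spec.population_names.index("SP")
        f[src] = 0.5
        drive = conductance_drive(tcm_spec, tcm_params, f)
        tgt = tcm_spec.population_names.index("SI")
        w = tcm_spec.connectivity.gamma["AMPA"][tgt, src]
        assert drive["AMPA"][tgt] == pytest.approx(w * 0.5)

    def test_linearity_in_weight(self, tcm_spec, tcm_params):
        f = np.full(8, 0.3)
        base = conductance_drive(tcm_spec, tcm_params, f)
        doubled = conductance_drive(
            tcm_spec, tcm_params.updated(
                {gamma_name("AMPA", "SI", "SP"): np.log(2.0)}), f)
        tgt = tcm_spec.population_names.index("SI")
        src = tcm_spec.population_names.index("SP")
        w = tcm_spec.connectivity.gamma["AMPA"][tgt, src]
        assert doubled["AMPA"][tgt] - base["AMPA"][tgt] == pytest.approx(
            w * 0.3, rel=1e-12)

    def test_gaba_b_tied_to_gaba_a(self, tcm_spec, tcm_params):
        f = np.full(8, 0.4)
        drive = conductance_drive(tcm_spec, tcm_params, f)
        ratio = tcm_spec.connectivity.gaba_b_ratio
        assert np.allclose(drive["GABA_B"], ratio * drive["GABA_A"])

    def test_shape_mismatch(self, tcm_spec, tcm_params):
        with pytest.raises(StructuralError):
            conductance_drive(tcm_spec, tcm_params, np.zeros(5))


class TestStateDerivative:
    def test_wrong_state_length(self, tcm_spec, tcm_params):
        with pytest.raises(StructuralError):
            state_derivative(tcm_spec, tcm_params, np.zeros(10))

    def test_nonfinite_state(self, tcm_spec, tcm_params):
        y = np.zeros(56)
        y[3] = np.nan
        with pytest.raises(NumericalError):
            state_derivative(tcm_spec, tcm_params, y)

    def test_conductance_fixed_point(self, tcm_spec, tcm_params):
        # At g_n equal to its drive, the conductance derivative vanishes.
        model = PhysicalModel(tcm_spec, tcm_params)
        y = np.zeros(56).reshape(8, 7)
        y[:, 0] = -55.0
        f = model.firing(y[:, 0])
        drive = model.synaptic_drive(f)
        y[:, 1] = drive["AMPA"]
        y[:, 3] = drive["NMDA"]
        dy = model.derivative(y.reshape(-1)).reshape(8, 7)
        assert np.allclose(dy[:, 1], 0.0, atol=1e-12)
        assert np.allclose(dy[:, 3], 0.0, atol=1e-12)

    def test_linear_in_input_gain(self, tcm_spec, tcm_params):
        y = np.zeros(56)
        y[::7] = -60.0
        d0 = state_derivative(tcm_spec, tcm_params, y)
        dlog2 = state_derivative(
            tcm_spec, tcm_params.updated({"input_gain": np.log(2.0)}), y)
        rl_v = tcm_spec.voltage_index("RL")
        model = PhysicalModel(tcm_spec, tcm_params)
        u = model.u[tcm_spec.population_names.index("RL")]
        c = model.C[tcm_spec.population_names.index("RL")]
        assert dlog2[rl_v] - d0[rl_v] == pytest.approx(u / c, rel=1e-9)
        others = np.delete(np.arange(56), rl_v)
        assert np.allclose(d0[others], dlog2[others])

    def test_leak_relaxation_matches_closed_form(self, cmc_spec, cmc_params):
        # With all synaptic weights off, V relaxes to the leak reversal with
        # time constant C / g_L.
        p = cmc_params.copy()
        for i, n in enumerate(p.names):
            if n.startswith("gamma:"):
                p.values[i] = -30.0  # effectively zero coupling
        p["input_gain"] = -30.0
        model = PhysicalModel(cmc_spec, p)
        y = np.zeros(20).reshape(4, 5)
        y[:, 0] = -55.0
        tau = model.C[0] / model.g_leak  # ms
        dt = 0.001  # ms, fine Euler
        state = y.reshape(-1).copy()
        for _ in range(2000):
            state = state + dt * model.derivative(state)
        t = 2000 * dt
        expected = model.V_leak + (-55.0 - model.V_leak) * np.exp(-t / tau)
        assert np.allclose(state[::5], expected, atol=1e-3)


def test_resting_state_is_fixed_point_of_zero_input_system(tcm_spec, tcm_params):
    from tcmodel.integrator import resting_state

    model = PhysicalModel(tcm_spec, tcm_params)
    y = resting_state(model)
    dy = model.derivative(y, with_input=False)
    assert np.max(np.abs(dy)) < 1e-8
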