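"""Master-equation kinetics: pmf arithmetic, rate scaling, propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flowflash import (ConfigurationError, PmfState, ReactionScheme,
                       Transition, build_rate_matrix, default_scheme,
                       default_time_grid, pmf, pseudo_first_order_rate,
                       scale_rate_for_pmf, solve_populations,
                       solve_populations_ode)
from flowflash.cycle_kinetics import load_config, nernst_slope

from conftest import random_linear_chain


class TestPmf:
    def test_nernst_slope_at_room_temperature(self):
        assert 59.1 <= nernst_slope(298.15) <= 59.2

    @pytest.mark.parametrize("dpsi, dph, expected", [
        (0.0, 0.0, 0.0),
        (100.0, 0.0, 100.0),
        (100.0, 0.4, 123.7),   # 100 + 59.16*0.4
    ])
    def test_combines_electrical_and_ph_terms(self, dpsi, dph, expected):
        assert pmf(dpsi, dph, 298.15) == pytest.approx(expected, abs=0.05)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pmf(float("nan"), 0.0)
        with pytest.raises(ValueError):
            pmf(0.0, float("inf"))
        with pytest.raises(ValueError):
            pmf(0.0, 0.0, temperature=-1.0)

    def test_pmf_state_derives_same_value(self):
        assert PmfState(100.0, 0.4).pmf == pytest.approx(pmf(100.0, 0.4))


class TestRateScaling:
    def test_non_electrogenic_step_unaffected(self):
        assert scale_rate_for_pmf(2000.0, 0.0, 500.0) == 2000.0

    def test_zero_gradient_unaffected(self):
        assert scale_rate_for_pmf(2000.0, 1.0, 0.0) == 2000.0

    def test_boltzmann_attenuation_at_smp_pmf(self):
        # exp(-123.7/25.69) evaluated independently: k ~ 16.3 s⁻¹, τ ~ 61 ms
        k = scale_rate_for_pmf(2000.0, 1.0, pmf(100.0, 0.4))
        assert k == pytest.approx(16.3, rel=0.01)
        assert 1.0 / k >= 0.050

    def test_rejects_bad_rate_or_charge(self):
        with pytest.raises(ValueError):
            scale_rate_for_pmf(-5.0, 1.0, 100.0)
        with pytest.raises(ValueError):
            scale_rate_for_pmf(100.0, -0.5, 100.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(q=st.floats(0.01, 5), dp1=st.floats(1.0, 300.0),
           delta=st.floats(1.0, 100.0))
    def test_strictly_decreasing_in_pmf_for_positive_charge(self, q, dp1, delta):
        assert (scale_rate_for_pmf(1e3, q, dp1 + delta)
                < scale_rate_for_pmf(1e3, q, dp1) <= 1e3)


class TestOxygenBinding:
    @pytest.mark.parametrize("o2, tau_us", [(1.0e-3, 10.0), (0.5e-3, 20.0)])
    def test_pseudo_first_order_taus(self, o2, tau_us):
        k = pseudo_first_order_rate(1.0e8, o2)
        assert 1.0 / k == pytest.approx(tau_us * 1e-6)

    def test_doubling_o2_halves_tau(self):
        k2 = 3.7e7
        assert (1.0 / pseudo_first_order_rate(k2, 2e-3)
                == pytest.approx(0.5 / pseudo_first_order_rate(k2, 1e-3)))

    def test_rejects_non_positive_concentration(self):
        with pytest.raises(ValueError):
            pseudo_first_order_rate(1e8, 0.0)


class TestRateMatrix:
    def test_o2_entry_at_one_millimolar(self, scheme):
        rm = build_rate_matrix(scheme, 1.0e-3)
        i, j = scheme.index("R"), scheme.index("A")
        assert rm.matrix[j, i] == pytest.approx(1.0e5)

    def test_columns_sum_to_zero(self, scheme, smp_pmf):
        rm = build_rate_matrix(scheme, 0.5e-3, smp_pmf)
        assert np.allclose(rm.matrix.sum(axis=0), 0.0, atol=1e-9)

    def test_pmf_touches_only_electrogenic_step(self, scheme, smp_pmf):
        k0 = build_rate_matrix(scheme, 0.5e-3).matrix
        k1 = build_rate_matrix(scheme, 0.5e-3, smp_pmf).matrix
        i, j = scheme.index("F_R"), scheme.index("O")
        assert k1[j, i] == pytest.approx(16.3, rel=0.01)
        changed = ~np.isclose(k0, k1)
        assert set(zip(*np.nonzero(changed))) == {(j, i), (i, i)}

    def test_unknown_state_rejected(self):
        with pytest.raises(ConfigurationError):
            ReactionScheme(states=("X", "Y"),
                           transitions=(Transition("X", "Z", 1.0),))


class TestSolvePopulations:
    def test_identity_at_origin(self, scheme):
        rm = build_rate_matrix(scheme, 0.5e-3)
        traj = solve_populations(rm, times=np.array([0.0, 1e-5]))
        assert np.allclose(traj.occupancies[0], [1, 0, 0, 0, 0, 0], atol=1e-12)

    def test_two_state_closed_form(self):
        scheme = ReactionScheme(states=("X", "Y"),
                                transitions=(Transition("X", "Y", 100.0),))
        rm = build_rate_matrix(scheme, 1e-3)
        t = np.linspace(1e-4, 0.05, 50)
        traj = solve_populations(rm, times=t)
        assert np.allclose(traj.occupancy("X"), np.exp(-100.0 * t), atol=1e-10)

    def test_conservation_and_terminal_monotonicity(self, scheme):
        rm = build_rate_matrix(scheme, 0.5e-3)
        traj = solve_populations(rm)
        assert np.abs(traj.occupancies.sum(axis=1) - 1).max() <= 1e-9
        o = traj.occupancy("O")
        assert (np.diff(o) >= -1e-12).all()
        assert o[traj.times >= 0.05][0] > 0.99

    def test_matches_ode_oracle_on_default_chain(self, scheme):
        rm = build_rate_matrix(scheme, 0.5e-3)
        a = solve_populations(rm)
        b = solve_populations_ode(rm)
        assert np.abs(a.occupancies - b.occupancies).max() <= 1e-6

    def test_matches_ode_oracle_on_random_chains(self):
        rng = np.random.default_rng(20240901)
        grid = default_time_grid()
        for _ in range(100):
            chain = random_linear_chain(rng)
            rm = build_rate_matrix(chain, 1e-3)
            a = solve_populations(rm, times=grid)
            b = solve_populations_ode(rm, times=grid)
            assert np.abs(a.occupancies - b.occupancies).max() <= 1e-6
            assert np.abs(a.occupancies.sum(axis=1) - 1).max() <= 1e-9

    def test_rejects_bad_initial_vector(self, scheme):
        rm = build_rate_matrix(scheme, 0.5e-3)
        with pytest.raises(ValueError):
            solve_populations(rm, initial=[0.5, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            solve_populations(rm, initial=[2.0, -1.0, 0, 0, 0, 0])


class TestTrajectoryRoundTrip:
    def test_csv_round_trip(self, tmp_path, scheme, smp_pmf):
        rm = build_rate_matrix(scheme, 0.5e-3, smp_pmf)
        traj = solve_populations(rm)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = type(traj).from_csv(path)
        assert back.states == traj.states
        assert np.allclose(back.occupancies, traj.occupancies, atol=1e-9)
        assert back.metadata["delta_psi_mV"] == 100.0


class TestConfigLoading:
    def test_defaults_when_sections_absent(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text("{}")
        cfg = load_config(path)
        assert cfg["scheme"].states == default_scheme().states
        assert cfg["o2_conc"] == pytest.approx(0.5e-3)

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"o2_conc_m": 1e-3, "bogus": 1}')
        with pytest.raises(ConfigurationError):
            load_config(path)

    def test_scheme_and_pmf_parsed(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text("""
        {"scheme": {"states": ["X", "Y"],
                    "transitions": [{"from": "X", "to": "Y", "k0": 50.0}]},
         "pmf": {"delta_psi_mv": 80.0, "delta_ph": 0.2},
         "o2_conc_m": 1e-3}
        """)
        cfg = load_config(path)
        assert cfg["scheme"].states == ("X", "Y")
        assert cfg["pmf"].delta_psi == 80.0
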