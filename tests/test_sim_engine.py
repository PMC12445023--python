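"""Steady-state solving, drug law, Monte Carlo and screen mechanics."""

import numpy as np
import pandas as pd
import pytest

import twinscreen as ts
from twinscreen.errors import ValidationError
from twinscreen.model_core import nominal_parameters, CompiledNetwork
from twinscreen.sim_engine import (DoseGrid, DrugSpec, MonteCarloConfig,
                                   apply_drug, monte_carlo_readouts,
                                   run_dose_response, run_screen,
                                   solve_steady_state, steady_state_model)

from conftest import make_chain_model, make_sk_model, make_twin


class TestSteadyState:
    def test_synthesis_over_degradation_analytic(self, sk_model):
        ss = steady_state_model(sk_model, nominal_parameters(sk_model),
                                clamps={"IN": 0.0})
        ix = sk_model.species_index()["X"]
        assert ss.converged
        assert ss.concentrations[ix] == pytest.approx(2.0, abs=1e-6)

    def test_cascade_matches_brute_force_integration(self):
        """Oracle: long-horizon fixed-step Euler integration of the RHS."""
        model = make_chain_model(n_steps=2, k_act=0.8)
        params = nominal_parameters(model)
        compiled = CompiledNetwork(model)
        theta = compiled.theta_from(params)
        iin = model.species_index()["IN"]

        x = np.zeros(len(model.species))
        x[iin] = 1.0
        dt = 1e-2
        for _ in range(50_000):           # t = 500, time constants are O(1)
            dx = compiled.rates(x, theta)
            dx[iin] = 0.0
            x = np.maximum(x + dt * dx, 0.0)

        ss = steady_state_model(model, params, clamps={"IN": 1.0})
        assert ss.converged
        mask = np.ones(len(x), bool)
        assert np.allclose(ss.concentrations[mask], x[mask], rtol=1e-6,
                           atol=1e-9)

    def test_no_synthesis_collapses_to_zero(self):
        model = make_chain_model(n_steps=1)
        params = nominal_parameters(model)
        for key in list(params.values):
            if key[0].startswith("syn_"):
                params.values[key] = 0.0
        ss = steady_state_model(model, params, clamps={"IN": 0.0},
                                x0=np.zeros(len(model.species)))
        assert ss.converged
        assert np.allclose(ss.concentrations, 0.0)

    def test_twin_clamps_hold_inputs(self, ref_model):
        twin = make_twin(ref_model, activation={"CTNNB1_in": 0.7, "SHH_in": 0.2})
        ss = solve_steady_state(twin)
        idx = ref_model.species_index()
        assert ss.converged
        assert ss.concentrations[idx["CTNNB1_in"]] == pytest.approx(0.7)
        assert (ss.concentrations >= 0).all()


class TestApplyDrug:
    def test_zero_concentration_is_identity(self, ref_model):
        params = nominal_parameters(ref_model)
        drug = DrugSpec("d", (("ERK_a", 50.0),))
        assert apply_drug(params, drug, 0.0) == params

    @pytest.mark.parametrize("conc,phi", [(50.0, 0.5), (450.0, 0.1)])
    def test_occupancy_factor(self, ref_model, conc, phi):
        # oracle: phi = 1/(1 + C/kD) evaluated directly
        params = nominal_parameters(ref_model)
        drug = DrugSpec("d", (("ERK_a", 50.0),))
        perturbed = apply_drug(params, drug, conc)
        key = ("myc_prime_erk", "k_cat")
        assert perturbed[key] == pytest.approx(params[key] * phi)
        untouched = ("myc_bypass", "k_cat")
        assert perturbed[untouched] == params[untouched]

    def test_multi_target_factors_compound(self, ref_model):
        params = nominal_parameters(ref_model)
        drug = DrugSpec("d", (("ERK_a", 50.0), ("FAK_a", 50.0)))
        perturbed = apply_drug(params, drug, 50.0)
        assert perturbed[("myc_prime_erk", "k_cat")] == pytest.approx(
            params[("myc_prime_erk", "k_cat")] * 0.5)
        assert perturbed[("myc_mature_fak", "k_cat")] == pytest.approx(
            params[("myc_mature_fak", "k_cat")] * 0.5)

    def test_absent_target_skipped_with_warning(self, ref_model, caplog):
        params = nominal_parameters(ref_model)
        drug = DrugSpec("d", (("ALK", 30.0),))
        with caplog.at_level("WARNING"):
            perturbed = apply_drug(params, drug, 1e4)
        assert perturbed == params
        assert any("absent" in r.message for r in caplog.records)

    def test_negative_concentration_rejected(self, ref_model):
        with pytest.raises(ValidationError):
            apply_drug(nominal_parameters(ref_model),
                       DrugSpec("d", (("ERK_a", 1.0),)), -1.0)


class TestMonteCarlo:
    def test_zero_sigma_equals_deterministic(self, ref_model):
        twin = make_twin(ref_model, activation={"CTNNB1_in": 1.0, "SHH_in": 0.2})
        mc = MonteCarloConfig(n_runs=5, sigma_log10=0.0, master_seed=7)
        pos, neg, table = monte_carlo_readouts(twin, None, 0.0, mc)
        ss = solve_steady_state(twin)
        idx = ref_model.species_index()
        assert pos == pytest.approx(ss.concentrations[idx["MYC_MAX_nuc"]],
                                    rel=1e-7)
        assert neg == pytest.approx(ss.concentrations[idx["CASP3_act"]],
                                    rel=1e-7)

    def test_fixed_seed_reproducible(self, ref_model):
        twin = make_twin(ref_model, activation={"CTNNB1_in": 1.0, "SHH_in": 0.2})
        drug = DrugSpec("d", (("ERK_a", 50.0),))
        mc = MonteCarloConfig(n_runs=20, sigma_log10=0.1, master_seed=3)
        a = monte_carlo_readouts(twin, drug, 100.0, mc)
        b = monte_carlo_readouts(twin, drug, 100.0, mc)
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_perturbed_median_tracks_lognormal_oracle(self):
        """s/k toy: median of s*10^z1 / (k*10^z2) estimated by direct sampling."""
        model = make_sk_model(k_syn=2.0, k_deg=1.0)
        twin = make_twin(model, activation={"IN": 0.0})
        mc = MonteCarloConfig(n_runs=1000, sigma_log10=0.1, master_seed=11)
        pos, _neg, _ = monte_carlo_readouts(twin, None, 0.0, mc)
        rng = np.random.default_rng(0)
        z = rng.normal(0.0, 0.1, (100_000, 2))
        oracle = np.median(2.0 * 10.0 ** z[:, 0] / 10.0 ** z[:, 1])
        assert pos == pytest.approx(oracle, rel=0.02)


class TestDoseResponse:
    def test_absent_target_curve_is_flat_unity(self, ref_model):
        twin = make_twin(ref_model, activation={"CTNNB1_in": 1.0, "SHH_in": 0.2})
        drug = DrugSpec("ghost", (("ALK", 30.0),))
        mc = MonteCarloConfig(n_runs=10, sigma_log10=0.1, master_seed=5)
        curve = run_dose_response(twin, drug, DoseGrid(), mc)
        assert np.allclose(curve.viability, 1.0)

    def test_control_anchored_at_unity(self, ref_model):
        twin = make_twin(ref_model, activation={"CTNNB1_in": 1.0, "SHH_in": 0.2})
        drug = DrugSpec("d", (("ERK_a", 50.0),))
        mc = MonteCarloConfig(n_runs=1, sigma_log10=0.0, master_seed=0)
        curve = run_dose_response(twin, drug, DoseGrid(), mc)
        pos0, neg0 = curve.control_readouts
        assert ts.viability_score(pos0, neg0, pos0, neg0) == 1.0

    def test_doses_returned_ascending(self, ref_model):
        twin = make_twin(ref_model, activation={"CTNNB1_in": 1.0, "SHH_in": 0.2})
        drug = DrugSpec("d", (("ERK_a", 50.0),))
        mc = MonteCarloConfig(n_runs=1, sigma_log10=0.0, master_seed=0)
        curve = run_dose_response(twin, drug, DoseGrid(), mc)
        assert np.all(np.diff(curve.concentrations) > 0)

    @pytest.mark.parametrize("n_steps", [1, 2, 3])
    def test_viability_monotone_on_activating_chain(self, n_steps):
        model = make_chain_model(n_steps=n_steps, k_act=0.5)
        twin = make_twin(model, activation={"IN": 1.0})
        drug = DrugSpec("d", ((f"K{n_steps}_a", 10.0),))
        mc = MonteCarloConfig(n_runs=1, sigma_log10=0.0, master_seed=0)
        curve = run_dose_response(twin, drug, DoseGrid(), mc, lam=0.0)
        assert np.all(np.diff(curve.viability) <= 1e-6)

    @pytest.mark.parametrize("kd", [0.1, 10.0, 1000.0])
    def test_ec50_recovers_target_kd_on_linear_chain(self, kd):
        """Zero-basal single-target chain: viability(C) = 1/(1 + C/kD)."""
        model = make_chain_model(n_steps=1, k_act=0.01)
        twin = make_twin(model, activation={"IN": 1.0})
        drug = DrugSpec("d", (("K1_a", kd),))
        mc = MonteCarloConfig(n_runs=1, sigma_log10=0.0, master_seed=0)
        curve = run_dose_response(twin, drug, DoseGrid(), mc, lam=0.0)
        at_kd = int(np.argmin(np.abs(curve.concentrations - kd)))
        assert curve.viability[at_kd] == pytest.approx(0.5, abs=0.02)
        summary = ts.summarize_curve(curve)
        assert abs(np.log10(summary.ec50 / kd)) <= 1.0


class TestRunScreen:
    def _small_screen(self, ref_model, twins=None, seed=0):
        twins = twins or [
            make_twin(ref_model, "T1", "tumor",
                      {"TCF_LEF_i": 8.0, "MYC_pre": 8.0},
                      {"CTNNB1_in": 1.0, "SHH_in": 0.2}),
            make_twin(ref_model, "N1", "normal", {},
                      {"CTNNB1_in": 0.2, "SHH_in": 0.2}),
        ]
        panel = [DrugSpec("a", (("ERK_a", 50.0),)),
                 DrugSpec("b", (("AKT_a", 50.0),)),
                 DrugSpec("c", (("ALK", 30.0),))]
        mc = MonteCarloConfig(n_runs=5, sigma_log10=0.1, master_seed=seed)
        return run_screen(twins, panel, DoseGrid(), mc), twins, panel

    def test_one_row_per_twin_drug_pair(self, ref_model):
        result, twins, panel = self._small_screen(ref_model)
        assert len(result.table) == len(twins) * len(panel)

    def test_screen_deterministic_and_order_invariant(self, ref_model):
        result1, twins, panel = self._small_screen(ref_model)
        result2 = run_screen(list(reversed(twins)), panel, DoseGrid(),
                             MonteCarloConfig(n_runs=5, sigma_log10=0.1,
                                              master_seed=0))
        pd.testing.assert_frame_equal(result1.table, result2.table)
        assert result1.manifest["config_hash"] == result2.manifest["config_hash"]

    def test_empty_inputs_rejected(self, ref_model):
        with pytest.raises(ValidationError):
            run_screen([], [DrugSpec("a", (("ERK_a", 1.0),))])
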