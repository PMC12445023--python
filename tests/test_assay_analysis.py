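"""Plate analytics: ladders, 4PL, AUC, z-scores, TWS, Bliss, morphometry."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from twinscreen.assay_analysis import (PlateAssay, bliss_synergy,
                                       build_dilution_ladder,
                                       circularity_index, compute_auc,
                                       fit_4pl, four_pl, positive_fraction,
                                       therapeutic_window, tumor_volume,
                                       wound_closure, zscore_auc)
from twinscreen.errors import (DegeneratePanelError, ValidationError,
                               ZeroTumorAucError)
from twinscreen.synthetic_data import generate_plate, generate_synergy_grid


class TestDilutionLadder:
    def test_bench_default_gives_ten_doses(self):
        # 100 uM top, 1:3 serial dilution, 5 nM floor
        doses = build_dilution_ladder(1e5, 3.0, 5.0)
        assert len(doses) == 10
        assert doses[-1] == pytest.approx(1e5)
        assert np.all(np.diff(doses) > 0)

    def test_top_equal_floor_single_dose(self):
        assert len(build_dilution_ladder(5.0, 3.0, 5.0)) == 1

    def test_decade_ladder_enumeration(self):
        doses = build_dilution_ladder(1000.0, 10.0, 1.0)
        assert np.allclose(doses, [1.0, 10.0, 100.0, 1000.0])

    def test_top_below_floor_rejected(self):
        with pytest.raises(ValidationError):
            build_dilution_ladder(1.0, 3.0, 5.0)

    @given(st.floats(min_value=1.5, max_value=10.0),
           st.integers(min_value=0, max_value=12))
    def test_every_dose_within_bounds(self, ratio, steps):
        top = 1e5
        floor = top / ratio ** steps * 0.999999
        doses = build_dilution_ladder(top, ratio, floor)
        assert len(doses) == steps + 1
        assert doses.min() >= floor * (1 - 1e-9) and doses.max() == top


class TestFourPl:
    def test_noiseless_recovery_within_one_percent(self):
        plate, truth = generate_plate(50.0, hill=1.5, noise_sd=0.0)
        fit = fit_4pl(plate)
        assert fit.converged
        assert fit.ic50 == pytest.approx(truth["ic50"], rel=0.01)
        assert fit.hill == pytest.approx(truth["hill"], rel=0.05)

    def test_noisy_recovery_within_fifteen_percent(self):
        plate, truth = generate_plate(50.0, hill=1.5, noise_sd=0.05,
                                      n_replicates=3, seed=7)
        fit = fit_4pl(plate)
        assert fit.ic50 == pytest.approx(truth["ic50"], rel=0.15)

    def test_flat_plate_flags_no_inhibition(self):
        doses = build_dilution_ladder(1e5, 3.0, 5.0)
        plate = PlateAssay(doses=doses, viability=np.ones((2, len(doses))))
        with pytest.warns(UserWarning):
            fit = fit_4pl(plate)
        assert fit.warning == "no_inhibition"
        assert fit.ic50 == pytest.approx(doses.max() * 10.0)


class TestAuc:
    def test_flat_viability_levels(self):
        doses = np.logspace(0, 4, 10)
        for level in (1.0, 0.0, 0.37):
            plate = PlateAssay(doses=doses,
                               viability=np.full((1, 10), level))
            assert compute_auc(plate) == pytest.approx(level)

    def test_linear_descent_gives_half(self):
        doses = np.logspace(0, 4, 9)
        v = np.linspace(1.0, 0.0, 9)      # linear in log10(dose)
        plate = PlateAssay(doses=doses, viability=v[None, :])
        assert compute_auc(plate) == pytest.approx(0.5)

    def test_bounded_by_viability_range(self):
        rng = np.random.default_rng(1)
        doses = np.logspace(0, 3, 8)
        v = rng.uniform(0.1, 1.1, (3, 8))
        plate = PlateAssay(doses=doses, viability=v)
        mean = plate.mean_viability()
        assert mean.min() <= compute_auc(plate) <= mean.max()


class TestZScores:
    def test_one_two_three(self):
        z = zscore_auc({"a": 1.0, "b": 2.0, "c": 3.0})
        assert z == {"a": pytest.approx(-1.0), "b": pytest.approx(0.0),
                     "c": pytest.approx(1.0)}

    def test_mean_zero_unit_sd(self):
        rng = np.random.default_rng(2)
        aucs = {f"m{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 12))}
        z = np.array(list(zscore_auc(aucs).values()))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_panel_rejected(self):
        with pytest.raises(DegeneratePanelError):
            zscore_auc({"a": 0.5, "b": 0.5})

    @given(st.floats(min_value=0.01, max_value=10.0),
           st.floats(min_value=-5.0, max_value=5.0))
    def test_affine_invariance(self, a, b):
        aucs = {"x": 0.2, "y": 0.5, "z": 0.9}
        z1 = zscore_auc(aucs)
        z2 = zscore_auc({k: a * v + b for k, v in aucs.items()})
        for k in aucs:
            assert z2[k] == pytest.approx(z1[k], abs=1e-9)


class TestTherapeuticWindow:
    def test_ratio_of_means(self):
        assert therapeutic_window([0.7, 0.9], [0.3, 0.5]) == pytest.approx(2.0)

    def test_equal_means_give_unity(self):
        assert therapeutic_window([0.6], [0.6]) == pytest.approx(1.0)

    def test_zero_tumor_auc_rejected(self):
        with pytest.raises(ZeroTumorAucError):
            therapeutic_window([0.5], [0.0])


class TestBliss:
    def test_independent_combination_zero_excess(self):
        grid = generate_synergy_grid("independent", margins_a=(0.5,),
                                     margins_b=(0.5,),
                                     doses_a=(0.0, 1.0), doses_b=(0.0, 1.0))
        result = bliss_synergy(grid.doses_a, grid.doses_b, grid.inhibition)
        assert result.inhibition[1, 1] == pytest.approx(0.75)
        assert result.score == pytest.approx(0.0, abs=1e-12)

    def test_observed_above_expectation(self):
        inhibition = np.array([[0.0, 0.5], [0.5, 0.9]])
        result = bliss_synergy([0.0, 1.0], [0.0, 1.0], inhibition)
        assert result.bliss_excess[1, 1] == pytest.approx(0.15)
        assert result.score == pytest.approx(15.0)

    def test_margins_have_zero_excess(self):
        grid = generate_synergy_grid("synergistic", delta=0.2)
        result = bliss_synergy(grid.doses_a, grid.doses_b, grid.inhibition)
        assert np.allclose(result.bliss_excess[0, :], 0.0)
        assert np.allclose(result.bliss_excess[:, 0], 0.0)

    @pytest.mark.parametrize("mode,delta,expected", [
        ("independent", 0.15, 0.0),
        ("synergistic", 0.15, 15.0),
        ("antagonistic", 0.10, -10.0),
    ])
    def test_generator_modes_score_by_construction(self, mode, delta, expected):
        grid = generate_synergy_grid(mode, delta=delta, noise_sd=0.0)
        result = bliss_synergy(grid.doses_a, grid.doses_b, grid.inhibition)
        assert result.score == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_inhibition_warns(self):
        inhibition = np.array([[0.0, 0.5], [0.5, 1.2]])
        with pytest.warns(UserWarning):
            bliss_synergy([0.0, 1.0], [0.0, 1.0], inhibition)


class TestMorphometry:
    @pytest.mark.parametrize("gap0,gap1,expected",
                             [(100.0, 40.0, 60.0), (80.0, 80.0, 0.0),
                              (50.0, 0.0, 100.0)])
    def test_wound_closure(self, gap0, gap1, expected):
        assert wound_closure(gap0, gap1) == pytest.approx(expected)

    def test_circularity_of_reference_shapes(self):
        assert circularity_index(math.pi, 2.0 * math.pi) == pytest.approx(1.0)
        assert circularity_index(1.0, 4.0) == pytest.approx(math.pi / 4.0)
        elongated = circularity_index(10.0, 22.0)    # 10x1 rectangle
        assert elongated == pytest.approx(40.0 * math.pi / 484.0)
        assert elongated < math.pi / 4.0

    def test_tumor_volume(self):
        assert tumor_volume(10.0, 5.0) == pytest.approx(125.0)
        assert tumor_volume(2.0, 2.0) == pytest.approx(4.0)

    def test_tumor_volume_swaps_axes_with_warning(self):
        with pytest.warns(UserWarning):
            assert tumor_volume(5.0, 10.0) == pytest.approx(125.0)

    @pytest.mark.parametrize("pos,total,expected",
                             [(30, 100, 0.30), (0, 50, 0.0), (50, 50, 1.0)])
    def test_positive_fraction(self, pos, total, expected):
        assert positive_fraction(pos, total) == pytest.approx(expected)

    def test_positive_fraction_bounds(self):
        with pytest.raises(ValidationError):
            positive_fraction(5, 4)
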