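import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from membpka.errors import FitError
from membpka.functional_analysis import (
    DoseResponseCurve,
    MutantRecord,
    batch_property_regression,
    classify_effect,
    delta_ph50,
    fit_hill,
    load_property_scales,
    mutant_cycle_coupling,
    property_regression,
)
from membpka.synthetic_data import (
    hill_response,
    simulate_dose_response,
    simulate_mutant_panel,
)

PH_GRID = np.linspace(7.4, 5.0, 9)


class TestHillFit:
    def test_noiseless_recovery_to_1e6(self):
        curve = simulate_dose_response(6.2, 1.5, 1.0, PH_GRID, noise_sd=0.0)
        fit = fit_hill(curve)
        assert fit.converged
        assert fit.ph50 == pytest.approx(6.2, abs=1e-6)
        assert fit.n_h == pytest.approx(1.5, abs=1e-6)
        assert fit.i_max == pytest.approx(1.0, abs=1e-6)

    def test_midpoint_identity(self):
        assert hill_response(6.2, 6.2, 1.5, 1.0) == pytest.approx(0.5)

    def test_ssd_curve_mirrored(self):
        curve = simulate_dose_response(7.0, 2.0, 1.0, np.linspace(7.6, 6.2, 8),
                                       transition="ssd")
        fit = fit_hill(curve)
        assert fit.transition == "ssd"
        assert fit.ph50 == pytest.approx(7.0, abs=1e-6)
        # availability falls as conditioning pH falls
        assert curve.response[0] > curve.response[-1]

    def test_monte_carlo_recovery(self):
        """2% Gaussian noise: |pH50 error| < 0.05 in at least 95/100 seeds."""
        hits = 0
        for seed in range(100):
            curve = simulate_dose_response(6.2, 1.5, 1.0, PH_GRID,
                                           noise_sd=0.02, seed=seed)
            fit = fit_hill(curve)
            if fit.converged and abs(fit.ph50 - 6.2) < 0.05:
                hits += 1
        assert hits >= 95

    def test_rescaling_invariance(self):
        """Uniform response rescaling changes I_max only."""
        curve = simulate_dose_response(6.4, 1.2, 1.0, PH_GRID)
        scaled = DoseResponseCurve(ph=curve.ph, response=curve.response * 0.37)
        f1, f2 = fit_hill(curve), fit_hill(scaled)
        assert f2.ph50 == pytest.approx(f1.ph50, abs=1e-6)
        assert f2.n_h == pytest.approx(f1.n_h, abs=1e-6)
        assert f2.i_max == pytest.approx(0.37 * f1.i_max, abs=1e-6)

    def test_flat_curve_is_error(self):
        with pytest.raises(FitError):
            fit_hill(DoseResponseCurve(ph=PH_GRID, response=np.full(9, 0.5)))

    def test_few_points_warns(self):
        with pytest.warns(UserWarning):
            fit_hill(DoseResponseCurve(ph=np.array([7.0, 6.5, 6.0, 5.5]),
                                       response=hill_response(
                                           np.array([7.0, 6.5, 6.0, 5.5]), 6.2, 1.5, 1.0)))


class TestDeltaPh50:
    def test_identical_fits_zero(self):
        curve = simulate_dose_response(6.2, 1.5, 1.0, PH_GRID)
        fit = fit_hill(curve)
        d, se = delta_ph50(fit, fit)
        assert d == 0.0

    def test_difference_and_quadrature(self):
        f1 = fit_hill(simulate_dose_response(6.0, 1.5, 1.0, PH_GRID))
        f2 = fit_hill(simulate_dose_response(6.3, 1.5, 1.0, PH_GRID))
        d, _ = delta_ph50(f1, f2)
        assert d == pytest.approx(-0.3, abs=1e-6)
        f1.se_ph50 = f2.se_ph50 = 0.02
        _, se = delta_ph50(f1, f2)
        assert se == pytest.approx(math.sqrt(2) * 0.02, abs=1e-6)

    def test_unconverged_input_rejected(self):
        good = fit_hill(simulate_dose_response(6.2, 1.5, 1.0, PH_GRID))
        bad = fit_hill(simulate_dose_response(6.2, 1.5, 1.0, PH_GRID))
        bad.converged = False
        with pytest.raises(FitError):
            delta_ph50(bad, good)


class TestEffectClass:
    @pytest.mark.parametrize(
        "delta,expected",
        [(-0.55, "strong"), (-0.10, "weak"), (0.0, "none"),
         (0.08, "weak"), (0.2, "moderate"), (0.3, "strong"),
         (-0.25, "moderate")],
    )
    def test_bins_with_closed_lower_edges(self, delta, expected):
        assert classify_effect(delta_ph50=delta).bin == expected

    def test_functional_importance_rules(self):
        assert not classify_effect(delta_ph50=-0.10).functionally_important
        assert classify_effect(delta_ph50=-0.25).functionally_important
        assert classify_effect(delta_ph50=0.0, delta_phd50=-0.16).functionally_important
        assert not classify_effect(delta_ph50=0.0, delta_phd50=-0.10).functionally_important

    def test_requires_some_input(self):
        with pytest.raises(ValueError):
            classify_effect()


class TestMutantCycle:
    def test_additive_case(self):
        a = MutantRecord("A", delta_ph50=-0.2, sem=0.0)
        b = MutantRecord("B", delta_ph50=-0.3, sem=0.0)
        ab = MutantRecord("AB", delta_ph50=-0.5, sem=0.0)
        res = mutant_cycle_coupling(a, b, ab)
        assert res.coupling == pytest.approx(0.0)
        assert not res.non_additive

    def test_nonzero_coupling_and_quadrature(self):
        a = MutantRecord("A", delta_ph50=-0.2, sem=0.03)
        b = MutantRecord("B", delta_ph50=-0.3, sem=0.03)
        ab = MutantRecord("AB", delta_ph50=-0.25, sem=0.03)
        res = mutant_cycle_coupling(a, b, ab)
        assert res.coupling == pytest.approx(0.25)
        assert res.se == pytest.approx(math.sqrt(3) * 0.03, abs=1e-9)
        assert res.non_additive

    def test_symmetry_in_singles(self):
        a = MutantRecord("A", delta_ph50=-0.2, sem=0.02)
        b = MutantRecord("B", delta_ph50=0.1, sem=0.05)
        ab = MutantRecord("AB", delta_ph50=-0.4, sem=0.03)
        r1 = mutant_cycle_coupling(a, b, ab)
        r2 = mutant_cycle_coupling(b, a, ab)
        assert r1.coupling == r2.coupling
        assert r1.se == r2.se

    def test_missing_delta_rejected(self):
        a = MutantRecord("A", delta_ph50=-0.2)
        b = MutantRecord("B")
        ab = MutantRecord("AB", delta_ph50=-0.5)
        with pytest.raises(ValueError):
            mutant_cycle_coupling(a, b, ab)


class TestPropertyScales:
    def test_twelve_scales_of_twenty_residues(self):
        scales = load_property_scales()
        assert len(scales) == 12
        for s in scales.values():
            assert len(s.values) == 20


class TestPropertyRegression:
    def test_collinear_panel_r2_one(self):
        scales = load_property_scales()
        panel = simulate_mutant_panel(374, list("ACDEFGH"), scales["hydropathy"],
                                      slope=0.05, intercept=6.0, noise_sd=0.0, seed=1)
        res = property_regression(panel, scales["hydropathy"])
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.slope == pytest.approx(0.05, abs=1e-9)
        assert res.p_value < 1e-6
        assert res.n == 7

    def test_null_pvalues_uniform(self):
        """With slope 0 the regression p-values are ~Uniform(0,1)
        (KS test over 500 simulated panels, alpha = 0.01)."""
        scales = load_property_scales()
        scale = scales["polarity"]
        pvals = []
        for seed in range(500):
            panel = simulate_mutant_panel(374, list("ACDEFGHI"), scale,
                                          slope=0.0, intercept=6.0,
                                          noise_sd=0.1, seed=seed)
            pvals.append(property_regression(panel, scale).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_variants_refused(self):
        scales = load_property_scales()
        panel = pd.DataFrame({"substitution": list("ACD"), "ph50": [6.0, 6.1, 6.2]})
        with pytest.raises(ValueError, match="at least 4"):
            property_regression(panel, scales["size"])

    def test_degenerate_predictor_refused(self):
        scales = load_property_scales()
        # alanine/glycine/valine/isoleucine all have zero H-bond donors
        panel = pd.DataFrame({"substitution": list("AGVI"),
                              "ph50": [6.0, 6.1, 6.2, 6.3]})
        with pytest.raises(ValueError, match="zero variance"):
            property_regression(panel, scales["hydrogen_donor"])

    def test_batch_runs_all_scales_same_n(self):
        scales = load_property_scales()
        panel = simulate_mutant_panel(211, list("ACDEFKL"), scales["size"],
                                      slope=0.02, intercept=6.0, noise_sd=0.05, seed=3)
        df = batch_property_regression(panel)
        assert len(df) == 12
        assert df["n"].nunique() == 1
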