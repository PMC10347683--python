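"""Cohort generation and the 14-compartment PBPK model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from comornet.pbpk import (
    COMPARTMENTS,
    PBPKError,
    _rate_matrix,
    default_parameters,
    fit_absorption_clearance,
    oral_bioavailability,
    pbpk_simulate,
    scale_to_patient,
)
from comornet.virtual_patients import (
    CohortError,
    CohortSpec,
    adult_default_spec,
    generate_cohort,
    pediatric_default_spec,
)


class TestCohorts:
    def test_default_spec_yields_100_patients(self):
        assert len(generate_cohort(adult_default_spec(seed=1))) == 100

    def test_below_minimum_size_raises(self):
        with pytest.raises(CohortError, match="minimum population size"):
            adult_default_spec(n=70)

    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(pediatric_default_spec(seed=11))
        b = generate_cohort(pediatric_default_spec(seed=11))
        assert a == b

    def test_age_ranges_respected(self):
        adults = generate_cohort(adult_default_spec(seed=3))
        children = generate_cohort(pediatric_default_spec(seed=3))
        assert all(p.age >= 18 for p in adults)
        assert all(6 <= p.age < 18 for p in children)

    def test_marginals_match_spec_within_three_standard_errors(self):
        spec = adult_default_spec(n=100, seed=5)
        cohort = generate_cohort(spec)
        for attr, mean, sd in [
            ("age", spec.age_mean, spec.age_sd),
            ("weight", spec.weight_mean, spec.weight_sd),
            ("height", spec.height_mean, spec.height_sd),
        ]:
            values = np.array([getattr(p, attr) for p in cohort])
            # truncation shifts the mean slightly; 3 SE of the untruncated sd
            assert abs(values.mean() - mean) < 3 * sd / np.sqrt(spec.n) + 0.05 * sd

    def test_marginal_means_converge_at_large_n(self):
        spec = adult_default_spec(n=5000, seed=8)
        cohort = generate_cohort(spec)
        weights = np.array([p.weight for p in cohort])
        assert abs(weights.mean() - spec.weight_mean) < 0.05 * spec.weight_mean

    def test_inconsistent_range_and_mean_raises(self):
        with pytest.raises(CohortError, match="outside its range"):
            CohortSpec(label="adult", weight_mean=500.0)

    def test_pediatric_label_enforces_age_window(self):
        with pytest.raises(CohortError):
            CohortSpec(label="pediatric-adolescent", age_range=(6.0, 25.0))


class TestPBPKStructure:
    def test_rate_matrix_columns_sum_to_zero(self):
        a = _rate_matrix(default_parameters())
        assert np.allclose(a.sum(axis=0), 0.0, atol=1e-12)

    def test_flow_balance(self):
        params = default_parameters()
        assert params.cardiac_output == pytest.approx(312.0)

    def test_scaling_is_allometric(self):
        params = default_parameters()
        small = scale_to_patient(params, 35.0)
        assert small.volumes["brain"] == pytest.approx(params.volumes["brain"] * 0.5)
        assert small.flows["brain"] == pytest.approx(params.flows["brain"] * 0.5**0.75)


class TestPBPKSimulation:
    def test_mass_balance_oral_and_iv(self):
        params = default_parameters()
        for route in ("oral", "iv"):
            res = pbpk_simulate(None, params, 70.0, route=route)
            assert res.mass_balance_error() < 1e-6

    def test_no_clearance_conserves_dose_in_body(self):
        from dataclasses import replace

        params = replace(default_parameters(), cl_renal=0.0, k_gut_loss=0.0)
        res = pbpk_simulate(None, params, 50.0, t_end_h=200.0, dt_h=0.5)
        in_body = res.amounts[-1, : len(COMPARTMENTS)].sum()
        assert in_body == pytest.approx(50.0, rel=1e-9)

    def test_linearity_in_dose(self):
        params = default_parameters()
        one = pbpk_simulate(None, params, 35.0)
        two = pbpk_simulate(None, params, 70.0)
        np.testing.assert_allclose(
            2 * one.brain.concentrations, two.brain.concentrations, rtol=1e-9
        )

    def test_brain_curve_single_peak(self):
        res = pbpk_simulate(None, default_parameters(), 70.0)
        c = res.brain.concentrations
        peak = int(np.argmax(c))
        assert 0 < peak < len(c) - 1
        assert np.all(np.diff(c[:peak]) > 0) and np.all(np.diff(c[peak:]) < 0)

    def test_matches_independent_stiff_solver(self):
        """Matrix-exponential propagation against an independent BDF run at
        tight tolerance."""
        params = default_parameters()
        a = _rate_matrix(params)
        x0 = np.zeros(a.shape[0])
        x0[COMPARTMENTS.index("gut_lumen")] = 70.0
        res = pbpk_simulate(None, params, 70.0, t_end_h=24.0, dt_h=0.5)
        ivp = solve_ivp(
            lambda t, x: a @ x, (0, 24.0), x0, t_eval=res.times, method="BDF",
            rtol=1e-10, atol=1e-12,
        )
        np.testing.assert_allclose(res.amounts.T, ivp.y, rtol=5e-6, atol=1e-8)

    @settings(max_examples=15, deadline=None)
    @given(
        ka=st.floats(0.2, 3.0),
        clr=st.floats(2.0, 60.0),
        weight=st.floats(20.0, 120.0),
        dose=st.floats(10.0, 200.0),
    )
    def test_mass_balance_property_over_random_parameters(self, ka, clr, weight, dose):
        params = default_parameters(ka=ka, cl_renal=clr)
        params = scale_to_patient(params, weight)
        res = pbpk_simulate(None, params, dose, t_end_h=24.0, dt_h=0.5)
        assert res.mass_balance_error() < 1e-6
        for curve in res.curves.values():
            assert np.all(curve.concentrations >= 0)

    def test_non_positive_dose_raises(self):
        with pytest.raises(PBPKError):
            pbpk_simulate(None, default_parameters(), 0.0)


class TestBioavailability:
    def test_default_parameters_hit_calibration_target(self):
        assert oral_bioavailability(default_parameters()) == pytest.approx(0.964, abs=0.005)

    def test_complete_absorption_no_loss_gives_unity(self):
        from dataclasses import replace

        params = replace(default_parameters(), k_gut_loss=0.0)
        assert oral_bioavailability(params) == pytest.approx(1.0, abs=1e-9)

    def test_zero_absorption_gives_zero(self):
        from dataclasses import replace

        params = replace(default_parameters(), ka=0.0)
        assert oral_bioavailability(params) == pytest.approx(0.0, abs=1e-12)

    def test_no_elimination_raises(self):
        from dataclasses import replace

        params = replace(default_parameters(), cl_renal=0.0, k_gut_loss=0.0, ka=0.0)
        with pytest.raises(PBPKError, match="non-convergent"):
            oral_bioavailability(params)


class TestParameterRecovery:
    def test_ka_and_clearance_recovered_from_noisy_self_data(self):
        """Fitting ka and renal clearance to 5%-noise curves generated by the
        model itself recovers both within 10% relative error."""
        params = default_parameters()
        truth = pbpk_simulate(None, params, 70.0, t_end_h=36.0, dt_h=0.5)
        rng = np.random.default_rng(99)
        noisy = {}
        for tissue in ("venous_blood", "brain"):
            curve = truth.curves[tissue]
            noise = 1.0 + 0.05 * rng.standard_normal(curve.concentrations.shape)
            noisy[tissue] = type(curve)(
                tissue=tissue,
                times=curve.times,
                concentrations=np.clip(curve.concentrations * noise, 0, None),
            )
        ka_hat, clr_hat = fit_absorption_clearance(noisy, params, 70.0)
        assert abs(ka_hat - params.ka) / params.ka < 0.10
        assert abs(clr_hat - params.cl_renal) / params.cl_renal < 0.10
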