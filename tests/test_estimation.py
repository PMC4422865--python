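"""Estimation tests: censored likelihood, MAP fits, model comparison, variants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adcpk import model
from adcpk.design import Arm, StudyDesign, build_monkey_study, generate_dataset
from adcpk.estimate import (
    FitSettings,
    ModelVariant,
    build_variant,
    compare_models,
    compare_nonnested,
    fit_individual,
    fit_population,
    observation_loglik,
)
from adcpk.params import default_dar_distribution


class TestObservationLoglik:
    def test_censored_at_prediction_is_log_half(self):
        assert observation_loglik(None, 0.195, 0.257, lloq=0.195, censored=True) == pytest.approx(
            math.log(0.5)
        )

    def test_density_at_mean(self):
        expected = math.log(1.0 / (math.sqrt(2 * math.pi) * 2.0))
        assert observation_loglik(10.0, 10.0, 0.2) == pytest.approx(expected)

    def test_censored_two_sd_below(self):
        got = observation_loglik(None, 0.10, 0.25, lloq=0.05, censored=True)
        assert got == pytest.approx(float(stats.norm.logcdf(-2.0)))

    def test_nonpositive_prediction_rejected(self):
        with pytest.raises(ValueError):
            observation_loglik(1.0, 0.0, 0.2)


class TestCompareModels:
    class _Fake:
        def __init__(self, ofv, n_params, bic=None):
            self.ofv = ofv
            self.n_params = n_params
            self.bic = bic if bic is not None else ofv

    @pytest.mark.parametrize(
        "dofv, expected_p",
        [(10.83, 0.00100), (10.3, 0.00133), (0.0, 1.0)],
    )
    def test_lrt_p_values(self, dofv, expected_p):
        full = self._Fake(ofv=100.0, n_params=10)
        red = self._Fake(ofv=100.0 + dofv, n_params=9)
        out = compare_models(full, red)
        assert out["df"] == 1
        assert out["p_value"] == pytest.approx(expected_p, rel=5e-3)

    def test_self_comparison(self):
        fit = self._Fake(ofv=50.0, n_params=5)
        out = compare_models(fit, fit, df=1)
        assert out["delta_ofv"] == 0.0
        assert out["p_value"] == 1.0

    def test_negative_dofv_warns(self):
        full = self._Fake(ofv=100.0, n_params=10)
        red = self._Fake(ofv=99.0, n_params=9)
        with pytest.warns(UserWarning):
            compare_models(full, red)

    def test_bic_comparison(self):
        a = self._Fake(ofv=0, n_params=0, bic=100.0)
        b = self._Fake(ofv=0, n_params=0, bic=110.0)
        assert compare_nonnested(a, b) == pytest.approx(-10.0)


class TestBuildVariant:
    def test_default_variant_matches_core_rhs(self, adc, mmae):
        vm = build_variant(ModelVariant())
        rng = np.random.default_rng(0)
        y = np.abs(rng.standard_normal(model.N_STATES))
        ref = model.derivatives(y, 0.0, adc, mmae)
        got = vm.derivatives(y, 0.0, adc, mmae)
        assert np.allclose(got, ref, rtol=1e-14, atol=0)

    def test_constant_rate_zero_equals_no_deconjugation(self, adc, mmae):
        vm = build_variant(ModelVariant(deconjugation_rate="constant"))
        y = np.abs(np.random.default_rng(1).standard_normal(model.N_STATES))
        got = vm.derivatives(y, 0.0, adc, mmae, extra={"k_dec": 0.0})
        none = model.derivatives(y, 0.0, adc.replace(k_ref=0.0), mmae)
        assert np.allclose(got, none, rtol=1e-14, atol=0)

    def test_dar_dependent_gamma_zero_reduces_to_default(self, adc, mmae):
        vm = build_variant(ModelVariant(proteolysis="dar_dependent"))
        y = np.abs(np.random.default_rng(2).standard_normal(model.N_STATES))
        got = vm.derivatives(y, 0.0, adc, mmae, extra={"gamma": 0.0})
        ref = model.derivatives(y, 0.0, adc, mmae)
        assert np.allclose(got, ref, rtol=1e-14, atol=0)

    def test_peripheral_deconjugation_moves_peripheral_mass(self, adc, mmae):
        vm = build_variant(ModelVariant(deconjugation_site="central_and_peripheral"))
        y = np.zeros(model.N_STATES)
        y[9 + 8] = 1.0  # DAR8 species, peripheral only
        dy = vm.derivatives(y, 0.0, adc, mmae)
        k8 = model.deconjugation_rate(8, adc)
        assert dy[9 + 7] == pytest.approx(8 * k8)  # zero under the default map
        # with a mapping where DAR8 sheds, peripheral loss appears
        adc2 = adc.replace(dar_mapping="9-n")
        dy2 = vm.derivatives(y, 0.0, adc2, mmae)
        assert dy2[9 + 7] > 0
        assert dy2[model.IDX_AMD] > 0

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError):
            ModelVariant(proteolysis="magic")


def _single_subject_dataset(pop, eta, arm, seed=5, sigma=0.02):
    from adcpk.simulate import apply_residual_and_censor, simulate_individual

    quiet = pop.replace(sigma={"tab": sigma, "acmmae": sigma, "mmae": sigma})
    adc_i, mm_i = pop.individual(eta)
    prof = simulate_individual(
        arm.regimen(), adc_i, mm_i, arm.simulation_grid(), dist=default_dar_distribution()
    )
    obs = apply_residual_and_censor(
        prof, arm.schedule, quiet.sigma, rng=np.random.default_rng(seed)
    )
    obs.insert(0, "SUBJ", 1)
    obs.insert(1, "ARM", arm.name)
    obs["DOSE_MGKG"] = arm.dose_level
    obs["CMPD"] = arm.compound
    obs["BW_KG"] = arm.body_weight
    obs["OCC"] = 1
    return obs, quiet


class TestFitIndividual:
    def test_zero_eta_recovered_with_tiny_noise(self, pop):
        arm = build_monkey_study().arm("adc-single-3")
        obs, quiet = _single_subject_dataset(pop, np.zeros(6), arm, sigma=1e-6)
        eta_hat, ok = fit_individual(obs, quiet)
        assert ok
        assert np.allclose(eta_hat, 0.0, atol=5e-3)

    def test_rich_data_recovers_informed_etas(self, pop):
        arm = build_monkey_study().arm("adc-single-3")
        eta = np.array([0.2, -0.1, 0.3, 0.0, -0.2, 0.0])
        obs, quiet = _single_subject_dataset(pop, eta, arm, sigma=0.02)
        eta_hat, _ = fit_individual(obs, quiet)
        # emax, vc and vp are well informed by a rich three-analyte arm
        # (clm is not: after conjugate dosing free-MMAE kinetics are
        # formation-rate-limited, so its random effect stays shrunken)
        for j in (0, 1, 2):
            assert eta_hat[j] == pytest.approx(eta[j], abs=max(0.1 * abs(eta[j]), 0.02))

    def test_all_bloq_subject_shrinks_to_prior_mode(self, pop):
        # a dose so small that every prediction sits far below the LLOQ:
        # the censored records are then uninformative and the prior keeps
        # the random effects at the mode
        full = build_monkey_study()
        a = full.arm("adc-single-0.3")
        arm = Arm(
            name="tiny-dose", compound=a.compound, dose_level=1e-6,
            n_subjects=1, dose_times=list(a.dose_times),
            schedule={k: list(v) for k, v in a.schedule.items()},
        )
        obs, quiet = _single_subject_dataset(pop, np.zeros(6), arm)
        obs["BLOQ"] = 1
        obs["DV"] = np.nan
        eta_hat, _ = fit_individual(obs, quiet)
        assert np.all(np.abs(eta_hat) < 1e-2)

    def test_mmae_only_subject_estimates_clm_vmp_only(self, pop):
        arm = build_monkey_study().arm("mmae-0.03")
        eta = np.array([0.0, 0.0, 0.0, 0.0, 0.4, -0.2])
        obs, quiet = _single_subject_dataset(pop, eta, arm, sigma=0.02)
        eta_hat, _ = fit_individual(obs, quiet)
        assert np.all(eta_hat[:4] == 0.0)  # uninformed effects stay at the mode
        assert eta_hat[4] == pytest.approx(0.4, abs=0.04)
        assert eta_hat[5] == pytest.approx(-0.2, abs=0.06)


@pytest.fixture(scope="module")
def tiny_study():
    """A reduced design: cheap but informative for smoke-level fitting."""
    full = build_monkey_study()
    a1 = full.arm("adc-single-3")
    a2 = full.arm("mmae-0.063")
    arms = [
        Arm(
            name=a1.name, compound=a1.compound, dose_level=a1.dose_level,
            n_subjects=3, dose_times=list(a1.dose_times),
            schedule={k: list(v) for k, v in a1.schedule.items()},
        ),
        Arm(
            name=a2.name, compound=a2.compound, dose_level=a2.dose_level,
            n_subjects=3, dose_times=list(a2.dose_times),
            schedule={k: list(v) for k, v in a2.schedule.items()},
        ),
    ]
    return StudyDesign(arms=arms)


class TestFitPopulation:
    def test_ofv_trace_non_increasing_and_structure(self, tiny_study, pop):
        ds = generate_dataset(tiny_study, pop, seed=21)
        settings = FitSettings(outer_max=3, inner_maxfun=25, struct_maxfun=20)
        fit = fit_population(ds, pop, settings=settings)
        assert np.all(np.diff(fit.trace) <= 0.1)  # EM-style monotonicity
        assert np.isfinite(fit.ofv)
        assert fit.bic == pytest.approx(fit.ofv + fit.n_params * np.log(fit.n_obs))
        assert set(fit.eta.columns) == {"SUBJ", *pop.omega_sq}
        assert fit.n_obs == len(ds)

    def test_requires_two_subjects(self, tiny_study, pop):
        ds = generate_dataset(tiny_study, pop, seed=21)
        one = ds[ds.SUBJ == 1]
        with pytest.raises(ValueError):
            fit_population(one, pop)

    def test_monte_carlo_estep_close_to_map_estep(self, tiny_study, pop):
        """The importance-sampling E-step refines, not replaces, the MAP fit.

        With everything structural fixed, the MC-E-step fit must produce
        finite, reproducible results in the neighbourhood of the MAP fit.
        """
        ds = generate_dataset(tiny_study, pop, seed=23)
        fix = (
            "emax", "km", "vc", "cld", "vp", "weibull_lambda",
            "weibull_kappa", "fmp", "fmd", "clm", "vm", "clmd", "vmp",
        )
        settings_map = FitSettings(outer_max=2, inner_maxfun=30, fix=fix)
        settings_mc = FitSettings(
            outer_max=2, inner_maxfun=30, fix=fix, mc_samples=15, seed=5
        )
        f_map = fit_population(ds, pop, settings=settings_map)
        f_mc = fit_population(ds, pop, settings=settings_mc)
        f_mc2 = fit_population(ds, pop, settings=settings_mc)
        assert np.isfinite(f_mc.ofv)
        assert f_mc.ofv == pytest.approx(f_mc2.ofv, abs=1e-9)  # seeded draws
        for name in pop.omega_sq:
            assert f_mc.population.omega_sq[name] == pytest.approx(
                f_map.population.omega_sq[name], rel=1.0, abs=0.5
            )

    def test_weibull_beats_constant_rate_on_weibull_data(self, tiny_study, pop):
        """Schwarz-criterion selection recovers the DAR-dependent rate law.

        Data simulated under the Weibull deconjugation model should give
        the Weibull fit a lower BIC than the single-shared-rate fit when
        everything else is held at the generating values.
        """
        ds = generate_dataset(tiny_study, pop, seed=31)
        fix = (
            "emax", "km", "vc", "cld", "vp", "fmp", "fmd",
            "clm", "vm", "clmd", "vmp",
        )
        settings = FitSettings(
            outer_max=2, inner_maxfun=30, struct_maxfun=60,
            warmup_maxfun=40, estimate_sigma=True, fix=fix,
        )
        fit_w = fit_population(ds, pop, variant=ModelVariant(), settings=settings)
        fit_c = fit_population(
            ds, pop, variant=ModelVariant(deconjugation_rate="constant"),
            settings=settings,
        )
        assert compare_nonnested(fit_w, fit_c) < 0

    def test_dropping_bloq_biases_mmae_clearance_down(self, pop):
        """Discarding censored records flattens the observed terminal phase.

        With the low tail censored away, the remaining quantifiable values
        overstate late concentrations, so a fit without the M3 terms
        estimates a lower clearance than the censored-likelihood fit.
        """
        full = build_monkey_study()
        a = full.arm("mmae-0.03")
        arm = Arm(
            name=a.name, compound=a.compound, dose_level=a.dose_level,
            n_subjects=6, dose_times=list(a.dose_times),
            schedule={k: list(v) for k, v in a.schedule.items()},
        )
        ds = generate_dataset(StudyDesign(arms=[arm]), pop, seed=41)
        assert ds.BLOQ.sum() > 0
        fix = (
            "emax", "km", "vc", "cld", "vp", "weibull_lambda",
            "weibull_kappa", "fmp", "fmd", "vm", "clmd",
        )
        settings = FitSettings(
            outer_max=3, inner_maxfun=40, struct_maxfun=80,
            warmup_maxfun=60, estimate_sigma=False, fix=fix,
        )
        fit_m3 = fit_population(ds, pop, settings=settings)
        fit_drop = fit_population(
            ds[ds.BLOQ == 0].reset_index(drop=True), pop, settings=settings
        )
        assert fit_drop.population.mmae.clm < fit_m3.population.mmae.clm

    def test_fisher_standard_errors_for_rich_parameters(self, tiny_study, pop):
        """Numerical-information %RSE is finite and small for Vm and CLmd.

        Both are pinned down by the rich IV-MMAE profiles, so their
        relative standard errors should be well under 50%.
        """
        from adcpk.estimate import fisher_standard_errors

        ds = generate_dataset(tiny_study, pop, seed=51)
        fix = (
            "emax", "km", "vc", "cld", "vp", "weibull_lambda",
            "weibull_kappa", "fmp", "fmd", "clm", "vm", "clmd", "vmp",
        )
        settings = FitSettings(outer_max=2, inner_maxfun=30, fix=fix)
        fit = fit_population(ds, pop, settings=settings)
        se = fisher_standard_errors(fit, ds, names=("vm", "clmd"))
        for name in ("vm", "clmd"):
            assert np.isfinite(se[name]["rse_percent"])
            assert 0 < se[name]["rse_percent"] < 50

    def test_final_ofv_invariant_to_subject_order(self, tiny_study, pop):
        # with the shared structural parameters held fixed the fit is a
        # per-subject computation, so the OFV must not depend on how the
        # subjects are labelled/ordered
        ds = generate_dataset(tiny_study, pop, seed=22)
        fix = (
            "emax", "km", "vc", "cld", "vp", "weibull_lambda",
            "weibull_kappa", "fmp", "fmd", "clm", "vm", "clmd", "vmp",
        )
        settings = FitSettings(outer_max=2, inner_maxfun=30, fix=fix, warmup_maxfun=0)
        f1 = fit_population(ds, pop, settings=settings)
        relabel = {1: 6, 2: 5, 3: 4, 4: 3, 5: 2, 6: 1}
        ds2 = ds.copy()
        ds2["SUBJ"] = ds2["SUBJ"].map(relabel)
        ds2 = ds2.sort_values(["SUBJ", "ANALYTE", "TIME_H"], kind="stable").reset_index(drop=True)
        f2 = fit_population(ds2, pop, settings=settings)
        # equal to within optimizer stopping precision
        assert f1.ofv == pytest.approx(f2.ofv, abs=0.01)
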