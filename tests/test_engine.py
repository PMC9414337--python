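"""PBPK engine: closed forms, conservation, linearity, inactivation, populations."""

import numpy as np
import pytest

from pbpkdgi import engine, physiology
from pbpkdgi.engine import (
    ClearanceProcess,
    CompoundProperties,
    DosingRegimen,
    InactivationProcess,
    NonStationaryWarning,
    VariabilitySpec,
    build_model,
    mass_balance_error,
    simulate,
    simulate_population,
    steady_state_window_auc,
)
from pbpkdgi.errors import DomainError, ValidationError
from pbpkdgi.metrics import auc_last
from pbpkdgi.physiology import one_compartment, reference_adult

from conftest import make_one_compartment_linear

MW = 300.0


def iv_bolus(dose_mg, **kw):
    return DosingRegimen(route="iv_infusion", dose=dose_mg, infusion_duration=0.0, **kw)


class TestBuildModel:
    def test_minimal_model_state_dimension(self):
        m = build_model(one_compartment(), [CompoundProperties("d", MW, 1.0)], [])
        assert m.state_dimension == 1

    def test_whole_body_dimension_counts_enzyme_states(self):
        phys = reference_adult()
        cpd = CompoundProperties("d", MW, 0.1)
        inact = InactivationProcess("d", "CYP2D6", kinact=1.0, ki=1.0)
        mm = ClearanceProcess("michaelis_menten", "d", "mm", enzyme_label="CYP2D6", kcat=1.0, km=1.0)
        m = build_model(phys, [cpd], [mm], [inact])
        assert m.state_dimension == 9 + 1

    @pytest.mark.parametrize(
        "bad_kwargs",
        [
            dict(compound="ghost"),  # dangling compound
            dict(enzyme_label="CYP9Z9"),  # enzyme without a pool
        ],
    )
    def test_dangling_references_rejected(self, bad_kwargs):
        kwargs = dict(
            kind="michaelis_menten", compound="d", name="mm",
            enzyme_label="CYP2D6", kcat=1.0, km=1.0,
        )
        kwargs.update(bad_kwargs)
        with pytest.raises(ValidationError):
            build_model(one_compartment(), [CompoundProperties("d", MW, 1.0)],
                        [ClearanceProcess(**kwargs)])

    def test_duplicate_process_names_rejected(self):
        proc = ClearanceProcess("glomerular_filtration", "d", "p")
        with pytest.raises(ValidationError):
            build_model(one_compartment(), [CompoundProperties("d", MW, 1.0)], [proc, proc])

    def test_unknown_metabolite_link_rejected(self):
        proc = ClearanceProcess(
            "michaelis_menten", "d", "mm", enzyme_label="CYP2D6", kcat=1.0, km=1.0,
            product_links=(("ghost", 0.5),),
        )
        with pytest.raises(ValidationError):
            build_model(one_compartment(), [CompoundProperties("d", MW, 1.0)], [proc])


class TestClosedForms:
    def test_one_compartment_iv_bolus_matches_exponential(self, one_comp_linear):
        V, CL, D = 40.0, 5.0, 100.0
        res = simulate(one_comp_linear, iv_bolus(D), duration=24.0, grid=0.25)
        c = res.plasma_concentration("drug")
        expected = (D * 1000 / MW) / V * np.exp(-CL / V * res.times)
        assert np.max(np.abs(c - expected) / expected) < 1e-6

    def test_iv_infusion_auc_equals_dose_over_clearance(self, one_comp_linear):
        D = 100.0
        reg = DosingRegimen(route="iv_infusion", dose=D, infusion_duration=2.0)
        res = simulate(one_comp_linear, reg, duration=120.0, grid=0.25)
        prof = res.profile("drug", units="umol_per_L")
        auc = auc_last(prof.times, prof.concentrations)
        assert auc == pytest.approx(D * 1000 / MW / 5.0, rel=1e-3)
        assert mass_balance_error(res, "drug") < 1e-8

    def test_oral_first_order_absorption_bateman(self):
        m = make_one_compartment_linear(volume=40.0, cl=5.0)
        ka, ke, V = 1.0, 5.0 / 40.0, 40.0
        reg = DosingRegimen(route="oral_solution", dose=100.0, ka=ka)
        res = simulate(m, reg, duration=48.0, grid=0.25)
        d = 100.0 * 1000 / MW
        t = res.times
        expected = d * ka / (V * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        got = res.plasma_concentration("drug")
        assert np.max(np.abs(got[1:] - expected[1:])) < 1e-6 * expected.max()


class TestConservationAndLinearity:
    @pytest.mark.parametrize("phys", [one_compartment(), reference_adult()])
    def test_closed_system_conserves_mass(self, phys):
        cpd = CompoundProperties("d", MW, 0.1, lipophilicity=2.0)
        m = build_model(phys, [cpd], [])
        reg = DosingRegimen(route="oral_tablet", dose=50.0, n_doses=2, interval=24.0, ka=0.8)
        res = simulate(m, reg, duration=48.0, grid=0.5)
        total = res.total_amount("d")
        administered = res.administered("d")
        assert np.max(np.abs(total - administered)) / administered.max() < 1e-8

    def test_dose_proportionality_of_linear_model(self, one_comp_linear):
        aucs = []
        for dose in (50.0, 100.0):
            res = simulate(one_comp_linear, iv_bolus(dose), duration=96.0, grid=0.5)
            p = res.profile("drug")
            aucs.append(auc_last(p.times, p.concentrations))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=1e-6)

    def test_superposition_of_shifted_single_doses(self, one_comp_linear):
        reg_multi = DosingRegimen(route="oral_solution", dose=100.0, n_doses=3, interval=24.0, ka=1.2)
        reg_single = DosingRegimen(route="oral_solution", dose=100.0, ka=1.2)
        grid = 0.5
        multi = simulate(one_comp_linear, reg_multi, duration=96.0, grid=grid)
        single = simulate(one_comp_linear, reg_single, duration=96.0, grid=grid)
        c1 = single.plasma_concentration("drug")
        t = multi.times
        shift = int(24.0 / grid)
        super_c = c1.copy()
        for k in (1, 2):
            shifted = np.zeros_like(c1)
            shifted[k * shift :] = c1[: len(c1) - k * shift]
            super_c += shifted
        cm = multi.plasma_concentration("drug")
        mask = super_c > 1e-3 * super_c.max()
        assert np.max(np.abs(cm[mask] - super_c[mask]) / super_c[mask]) < 1e-3

    def test_accumulation_ratio_matches_analytic(self, one_comp_linear):
        k, tau = 5.0 / 40.0, 24.0
        reg = DosingRegimen(route="iv_infusion", dose=100.0, n_doses=6, interval=tau)
        res = simulate(one_comp_linear, reg, duration=6 * tau, grid=0.1)
        p = res.profile("drug")
        auc_first = auc_last(p.times, p.concentrations, 0.0, tau)
        auc_ss = auc_last(p.times, p.concentrations, 5 * tau, 6 * tau)
        assert auc_ss / auc_first == pytest.approx(1.0 / (1 - np.exp(-k * tau)), rel=1e-2)


class TestMichaelisMenten:
    @staticmethod
    def _mm_model(kcat_per_min=0.01, km=1.0):
        phys = one_compartment(volume=40.0)
        cpd = CompoundProperties("d", MW, 1.0)
        mm = ClearanceProcess(
            "michaelis_menten", "d", "mm", enzyme_label="CYP2D6", kcat=kcat_per_min, km=km
        )
        return build_model(phys, [cpd], [mm]), phys

    def test_low_concentration_limit_matches_linear_model(self):
        # peak substrate concentration K_M/1000: AUC deviation from the
        # first-order limit is S0/(2 K_M) = 0.05%
        km, V = 1.0, 40.0
        model, phys = self._mm_model(km=km)
        e0 = phys.enzyme_pools["CYP2D6"].reference_concentration * V
        cl_int = 0.01 * 60 * e0 / km  # L/h
        c0 = km / 1000
        dose_mg = c0 * V * MW / 1000
        res = simulate(model, iv_bolus(dose_mg), duration=40.0, grid=0.1)
        p = res.profile("d", units="umol_per_L")
        auc_mm = auc_last(p.times, p.concentrations)
        auc_lin = c0 * V / cl_int
        assert abs(auc_mm / auc_lin - 1) < 1e-3

    def test_moderate_concentration_deviation_matches_mm_closed_form(self):
        # at S0 = K_M/100 the exact MM AUC exceeds the linear one by S0/(2 K_M)
        km, V = 1.0, 40.0
        model, phys = self._mm_model(km=km)
        e0 = phys.enzyme_pools["CYP2D6"].reference_concentration * V
        vmax = 0.01 * 60 * e0  # µmol/h
        c0 = km / 100
        dose_mg = c0 * V * MW / 1000
        res = simulate(model, iv_bolus(dose_mg), duration=60.0, grid=0.1)
        p = res.profile("d", units="umol_per_L")
        auc_sim = auc_last(p.times, p.concentrations)
        auc_exact = V * (km * c0 + c0**2 / 2) / vmax
        assert auc_sim == pytest.approx(auc_exact, rel=1e-3)
        auc_lin = c0 * V * km / vmax
        assert auc_exact / auc_lin - 1 == pytest.approx(c0 / (2 * km), rel=1e-3)

    def test_saturation_raises_auc_beyond_dose_proportionality(self):
        model, _ = self._mm_model(km=0.5)
        aucs = {}
        for dose in (24.0, 48.0):  # peak S of 2 and 4 µM: well above K_M
            res = simulate(model, iv_bolus(dose), duration=400.0, grid=0.5)
            p = res.profile("d", units="umol_per_L")
            aucs[dose] = auc_last(p.times, p.concentrations)
        assert aucs[48.0] / aucs[24.0] > 2.2


class TestInactivation:
    @staticmethod
    def _inact_model(cl=0.0, kinact=0.5, ki=1.0):
        phys = one_compartment(volume=40.0)
        cpd = CompoundProperties("i", MW, 1.0)
        procs = []
        if cl > 0:
            procs.append(ClearanceProcess("first_order_hepatic", "i", "cl", cl_linear=cl))
        inact = InactivationProcess("i", "CYP2D6", kinact=kinact, ki=ki)
        return build_model(phys, [cpd], procs, [inact]), phys

    def test_constant_inhibitor_reaches_analytic_steady_state(self):
        model, phys = self._inact_model()
        pool = phys.enzyme_pools["CYP2D6"]
        e0 = pool.reference_concentration * 40.0
        c0 = 2.0  # µmol/L, constant (no clearance)
        res = simulate(model, iv_bolus(c0 * 40.0 * MW / 1000), duration=80.0, grid=0.5)
        hazard = 0.5 * c0 / (1.0 + c0)
        e_ss = e0 * pool.turnover_kdeg / (pool.turnover_kdeg + hazard)
        e_end = res.enzyme_amount("CYP2D6")[-1]
        assert abs(e_end / e_ss - 1) < 1e-3
        assert np.all(res.enzyme_amount("CYP2D6") >= 0)

    def test_washout_recovery_at_turnover_rate(self):
        model, phys = self._inact_model(cl=200.0)  # inhibitor gone within hours
        pool = phys.enzyme_pools["CYP2D6"]
        e0 = pool.reference_concentration * 40.0
        res = simulate(model, iv_bolus(50.0), duration=300.0, grid=1.0)
        e = res.enzyme_amount("CYP2D6")
        t = res.times
        i1, i2 = np.searchsorted(t, [100.0, 200.0])
        k_obs = np.log((e0 - e[i1]) / (e0 - e[i2])) / 100.0
        assert k_obs == pytest.approx(pool.turnover_kdeg, rel=0.05)
        assert e[-1] == pytest.approx(e0, rel=1e-3)


class TestPopulation:
    def test_zero_variability_reproduces_base_individual(self, one_comp_linear):
        spec = VariabilitySpec(parameter_cvs={"processes.CL.cl_linear": 0.0}, seed=1)
        pop = simulate_population(one_comp_linear, iv_bolus(100.0), 3, spec, duration=24.0, grid=0.5)
        base = simulate(one_comp_linear, iv_bolus(100.0), 24.0, grid=0.5)
        assert pop.mean["drug"].concentrations == pytest.approx(
            base.profile("drug").concentrations, rel=1e-12
        )
        # identical replicates: SD is zero up to summation round-off
        assert max(pop.sd["drug"].concentrations) < 1e-10 * max(
            pop.mean["drug"].concentrations
        )

    def test_single_individual_sd_is_zero(self, one_comp_linear):
        spec = VariabilitySpec(parameter_cvs={"processes.CL.cl_linear": 0.5}, seed=2)
        pop = simulate_population(one_comp_linear, iv_bolus(100.0), 1, spec, duration=24.0, grid=1.0)
        assert max(pop.sd["drug"].concentrations) == 0.0

    def test_clearance_cv_propagates_to_auc_cv(self, one_comp_linear):
        spec = VariabilitySpec(parameter_cvs={"processes.CL.cl_linear": 0.3}, seed=42)
        pop = simulate_population(
            one_comp_linear, iv_bolus(100.0), 500, spec, duration=72.0, grid=1.0,
            rtol=1e-6, atol=1e-9,
        )
        aucs = np.array(
            [auc_last(ind.times, ind.plasma_concentration("drug")) for ind in pop.individuals]
        )
        cv = aucs.std(ddof=1) / aucs.mean()
        assert cv == pytest.approx(0.3, rel=0.2)

    def test_deterministic_given_seed(self, one_comp_linear):
        spec = VariabilitySpec(parameter_cvs={"processes.CL.cl_linear": 0.3}, seed=7)
        a = simulate_population(one_comp_linear, iv_bolus(100.0), 5, spec, duration=12.0, grid=1.0)
        b = simulate_population(one_comp_linear, iv_bolus(100.0), 5, spec, duration=12.0, grid=1.0)
        assert a.mean["drug"].concentrations == b.mean["drug"].concentrations

    def test_empty_population_rejected(self, one_comp_linear):
        with pytest.raises(DomainError):
            simulate_population(
                one_comp_linear, iv_bolus(1.0), 0, VariabilitySpec(seed=0), duration=1.0
            )


class TestSteadyStateWindowAuc:
    def _ss_profile(self, n_doses=30, cl=5.0):
        m = make_one_compartment_linear(volume=40.0, cl=cl)
        reg = DosingRegimen(route="oral_solution", dose=100.0, n_doses=n_doses, interval=24.0, ka=1.5)
        res = simulate(m, reg, duration=n_doses * 24.0, grid=0.25, rtol=1e-8, atol=1e-10)
        return res.profile("drug", units="umol_per_L")

    def test_window_auc_equals_dose_over_clearance_per_interval(self):
        prof = self._ss_profile()
        auc = steady_state_window_auc(prof, (24 * 24.0, 28 * 24.0))
        expected = 4 * (100.0 * 1000 / MW) / 5.0  # 4 intervals of F*D/CL
        assert auc == pytest.approx(expected, rel=1e-2)

    def test_window_equals_sum_of_identical_intervals(self):
        prof = self._ss_profile()
        auc4 = steady_state_window_auc(prof, (24 * 24.0, 28 * 24.0))
        auc1 = steady_state_window_auc(prof, (27 * 24.0, 28 * 24.0))
        assert auc4 == pytest.approx(4 * auc1, rel=1e-3)

    def test_non_stationary_window_warns(self):
        prof = self._ss_profile(n_doses=8, cl=0.4)  # half-life ~69 h: day 4-8 far from SS
        with pytest.warns(NonStationaryWarning):
            steady_state_window_auc(prof, (4 * 24.0, 8 * 24.0))

    def test_window_outside_range_rejected(self):
        prof = self._ss_profile(n_doses=2)
        with pytest.raises(DomainError):
            steady_state_window_auc(prof, (24.0, 96.0))


class TestRegimenValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(route="oral_solution", dose=0.0),
            dict(route="oral_solution", dose=1.0, n_doses=0),
            dict(route="snorted", dose=1.0),
            dict(route="oral_solution", dose=1.0, ka=0.0),
        ],
    )
    def test_invalid_regimens_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DosingRegimen(**kwargs)

    def test_duration_must_cover_doses(self, one_comp_linear):
        reg = DosingRegimen(route="oral_solution", dose=1.0, n_doses=3, interval=24.0, ka=1.0)
        with pytest.raises(DomainError):
            simulate(one_comp_linear, reg, duration=24.0)
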