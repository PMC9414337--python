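"""Drug templates, activity-score application, and the steady-state DGI run."""

import numpy as np
import pytest

from pbpkdgi import drugs, engine, scaling
from pbpkdgi.drugs import (
    DGIScenario,
    apply_activity_score,
    load_template,
    make_drug_model,
    model_for_cyp2d6_status,
    run_dgi_scenario,
    standard_regimen,
)
from pbpkdgi.engine import ClearanceProcess, CompoundProperties, DosingRegimen, build_model
from pbpkdgi.errors import ValidationError
from pbpkdgi.metrics import auc_last
from pbpkdgi.physiology import one_compartment


def _process_signature(model):
    return sorted(
        (p.kind, p.enzyme_label or "", p.compound) for p in model.processes
    )


class TestTemplates:
    def test_paroxetine_topology(self):
        m = make_drug_model("paroxetine")
        assert _process_signature(m) == [
            ("first_order_hepatic", "", "paroxetine"),
            ("glomerular_filtration", "", "paroxetine"),
            ("michaelis_menten", "CYP2D6", "paroxetine"),
            ("michaelis_menten", "CYP3A4", "paroxetine"),
        ]
        assert {i.target_enzyme_label for i in m.inactivations} == {"CYP2D6", "CYP3A4"}

    def test_atomoxetine_topology(self):
        m = make_drug_model("atomoxetine")
        assert _process_signature(m) == [
            ("glomerular_filtration", "", "atomoxetine"),
            ("michaelis_menten", "CYP2C19", "atomoxetine"),
            ("michaelis_menten", "CYP2D6", "atomoxetine"),
        ]
        assert not m.inactivations

    def test_risperidone_parent_metabolite_structure(self):
        m = make_drug_model("risperidone")
        assert "9-hydroxyrisperidone" in m.compound_names
        mm_2d6 = [p for p in m.processes if p.enzyme_label == "CYP2D6"]
        mm_3a4 = [p for p in m.processes if p.enzyme_label == "CYP3A4"]
        assert len(mm_2d6) == len(mm_3a4) == 2
        # one pathway per enzyme forms the active metabolite
        forms_9hr = [
            p for p in mm_2d6 + mm_3a4
            if any(met == "9-hydroxyrisperidone" for met, _ in p.product_links)
        ]
        assert len(forms_9hr) == 2
        hep = [p for p in m.processes if p.kind == "first_order_hepatic"]
        assert [p.compound for p in hep] == ["9-hydroxyrisperidone"]

    def test_template_baselines_match_published_as2_kcats(self):
        assert make_drug_model("paroxetine").cyp2d6_baselines == {"PAR_CYP2D6": 4.09}
        assert make_drug_model("atomoxetine").cyp2d6_baselines == {"ATO_CYP2D6": 103.82}
        assert make_drug_model("risperidone").cyp2d6_baselines == {
            "RIS_CYP2D6_9HR": 3.19,
            "RIS_CYP2D6_other": 1.94,
        }

    def test_parameter_override_is_applied(self):
        m = make_drug_model("atomoxetine", {"processes": {"ATO_CYP2D6": {"km": 3.5}}})
        assert m.process("ATO_CYP2D6").km == 3.5

    def test_unknown_override_rejected(self):
        with pytest.raises(ValidationError):
            make_drug_model("atomoxetine", {"processes": {"GHOST": {"km": 3.5}}})

    def test_empty_config_rejected(self):
        with pytest.raises(ValidationError):
            drugs._build_from_config({"name": "empty"}, None)

    def test_missing_required_parameter_names_the_pathway(self):
        cfg = load_template("atomoxetine")
        del cfg["processes"][0]["compound"]
        with pytest.raises(ValidationError, match="missing required parameter"):
            drugs._build_from_config(cfg, None)

    def test_topology_check_rejects_missing_pathway(self):
        cfg = load_template("atomoxetine")
        cfg["processes"] = [p for p in cfg["processes"] if p["name"] != "ATO_GFR"]
        m = drugs._build_from_config(cfg, None)
        with pytest.raises(ValidationError, match="glomerular_filtration"):
            drugs._check_topology("atomoxetine", m)

    def test_unknown_drug_rejected(self):
        with pytest.raises(ValidationError):
            make_drug_model("ibuprofen")


class TestApplyActivityScore:
    def test_score_two_leaves_model_unchanged(self, curve):
        m = make_drug_model("atomoxetine")
        m2 = apply_activity_score(m, curve, 2.0)
        assert m2.process("ATO_CYP2D6").kcat == m.process("ATO_CYP2D6").kcat

    def test_score_zero_silences_all_cyp2d6(self, curve):
        m = apply_activity_score(make_drug_model("risperidone"), curve, 0.0)
        assert m.process("RIS_CYP2D6_9HR").kcat == 0.0
        assert m.process("RIS_CYP2D6_other").kcat == 0.0
        assert m.process("RIS_CYP3A4_9HR").kcat > 0

    def test_risperidone_as1_matches_printed_values(self, curve):
        m = apply_activity_score(make_drug_model("risperidone"), curve, 1.0)
        assert m.process("RIS_CYP2D6_9HR").kcat == pytest.approx(1.22, rel=0.02)
        assert m.process("RIS_CYP2D6_other").kcat == pytest.approx(0.74, rel=0.02)

    def test_km_and_other_parameters_untouched(self, curve):
        base = make_drug_model("paroxetine")
        m = apply_activity_score(base, curve, 0.5)
        assert m.process("PAR_CYP2D6").km == base.process("PAR_CYP2D6").km
        assert m.process("PAR_CYP3A4").kcat == base.process("PAR_CYP3A4").kcat
        assert m.process("PAR_CLhep").cl_linear == base.process("PAR_CLhep").cl_linear
        assert m.physiology.enzyme_pools == base.physiology.enzyme_pools

    def test_idempotent_and_invertible_via_reference_score(self, curve):
        base = make_drug_model("atomoxetine")
        once = apply_activity_score(base, curve, 0.5)
        twice = apply_activity_score(once, curve, 0.5)
        assert once.process("ATO_CYP2D6").kcat == twice.process("ATO_CYP2D6").kcat
        back = apply_activity_score(once, curve, 2.0)
        assert back.process("ATO_CYP2D6").kcat == base.process("ATO_CYP2D6").kcat

    def test_model_without_cyp2d6_rejected(self, curve):
        m = build_model(
            one_compartment(),
            [CompoundProperties("d", 300.0, 1.0)],
            [ClearanceProcess("first_order_hepatic", "d", "cl", cl_linear=1.0)],
        )
        with pytest.raises(ValidationError):
            apply_activity_score(m, curve, 1.0)

    def test_em_status_uses_reduced_as125_kcat(self, curve):
        base = make_drug_model("atomoxetine")
        em = model_for_cyp2d6_status(base, curve, "EM", em_reduction_fraction=0.30)
        expected = curve.scale_kcat(103.82, 1.25) * 0.70
        assert em.process("ATO_CYP2D6").kcat == pytest.approx(expected, rel=1e-12)
        pm = model_for_cyp2d6_status(base, curve, "PM")
        assert pm.process("ATO_CYP2D6").kcat == 0.0

    def test_unknown_status_label_rejected(self, curve):
        with pytest.raises(ValidationError):
            model_for_cyp2d6_status(make_drug_model("atomoxetine"), curve, "XY")


class TestDgiScenario:
    def test_reference_only_scenario_gives_unit_ratio(self, curve):
        scenario = DGIScenario(
            drug="atomoxetine",
            regimen=standard_regimen("atomoxetine", n_doses=8),
            activity_scores=(2.0,),
        )
        res = run_dgi_scenario(
            scenario, curve, duration=4 * 24.0, window=(2 * 24.0, 4 * 24.0), grid=1.0
        )
        assert res.ratio(2.0) == 1.0

    def test_reference_score_must_be_included(self):
        with pytest.raises(ValidationError):
            DGIScenario(
                drug="atomoxetine",
                regimen=standard_regimen("atomoxetine"),
                activity_scores=(0.0, 1.0),
            )

    def test_one_compartment_reduction_matches_analytic_ratio(self, curve):
        # elimination = CL_2D6 + CL_other: the poor-metabolizer AUC ratio is
        # (CL_2D6 + CL_other)/CL_other in the linear regime
        phys = one_compartment(volume=40.0)
        cpd = CompoundProperties("d", 300.0, 1.0)
        mm = ClearanceProcess(
            "michaelis_menten", "d", "mm2d6", enzyme_label="CYP2D6", kcat=0.005, km=10.0
        )
        other = ClearanceProcess("first_order_hepatic", "d", "other", cl_linear=2.0)
        m = build_model(phys, [cpd], [mm, other])
        e0 = phys.enzyme_pools["CYP2D6"].reference_concentration * 40.0
        cl_2d6 = 0.005 * 60 * e0 / 10.0
        reg = DosingRegimen(route="iv_infusion", dose=1.0)
        aucs = {}
        for score in (0.0, 2.0):
            res = engine.simulate(
                apply_activity_score(m, curve, score), reg, 600.0, grid=1.0
            )
            p = res.profile("d")
            aucs[score] = auc_last(p.times, p.concentrations)
        assert aucs[0.0] / aucs[2.0] == pytest.approx((cl_2d6 + 2.0) / 2.0, rel=1e-2)


class TestMechanisticSignatures:
    def test_paroxetine_multiple_dosing_exceeds_superposition(self, curve):
        """Auto-inhibition: repeated dosing suppresses the inactivator's own
        clearance, so the multiple-dose profile exceeds the superposition of
        shifted single-dose profiles."""
        m = make_drug_model("paroxetine")
        grid = 0.5
        n = 5
        reg_m = standard_regimen("paroxetine", n_doses=n)
        reg_s = standard_regimen("paroxetine", n_doses=1)
        multi = engine.simulate(m, reg_m, n * 24.0, grid=grid, rtol=1e-6, atol=1e-9)
        single = engine.simulate(m, reg_s, n * 24.0, grid=grid, rtol=1e-6, atol=1e-9)
        c1 = single.plasma_concentration("paroxetine")
        cm = multi.plasma_concentration("paroxetine")
        shift = int(24.0 / grid)
        super_c = np.zeros_like(c1)
        for k in range(n):
            shifted = np.zeros_like(c1)
            shifted[k * shift :] = c1[: len(c1) - k * shift]
            super_c += shifted
        t = multi.times
        w = t >= (n - 1) * 24.0
        auc_multi = np.trapezoid(cm[w], t[w])
        auc_super = np.trapezoid(super_c[w], t[w])
        assert auc_multi > 1.05 * auc_super

    def test_risperidone_metabolite_share_rises_with_activity_score(self, curve):
        base = make_drug_model("risperidone")
        reg = standard_regimen("risperidone", n_doses=1)
        shares, parent_aucs = [], []
        for score in (0.0, 1.0, 2.0, 3.0):
            m = apply_activity_score(base, curve, score)
            res = engine.simulate(m, reg, 96.0, grid=0.5, rtol=1e-6, atol=1e-9)
            par = res.profile("risperidone", units="umol_per_L")
            met = res.profile("9-hydroxyrisperidone", units="umol_per_L")
            auc_p = auc_last(par.times, par.concentrations)
            auc_m = auc_last(met.times, met.concentrations)
            parent_aucs.append(auc_p)
            shares.append(auc_m / (auc_p + auc_m))
        assert np.all(np.diff(parent_aucs) < 0)
        assert np.all(np.diff(shares) > 0)
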