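"""Whole-body model assembly, integration accuracy and mass balance."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

import malnupbpk as m
from malnupbpk.drug_library import Formulation, Regimen, formulation_for_study
from malnupbpk.pbpk_core.model import OneCompartmentModel
from malnupbpk.trial import nca

TIGHT = {"method": "LSODA", "rtol": 1e-10, "atol": 1e-13}


@pytest.fixture(scope="module")
def child():
    return m.reference_individual(2.75, "male")


class TestOneCompartmentEquivalence:
    def test_iv_bolus_matches_analytic_solution(self):
        v, cl, dose = 12.0, 3.0, 100.0
        model = OneCompartmentModel(volume_L=v, cl_L_h=cl)
        grid = np.linspace(0.0, 10.0, 101)
        res = model.simulate(Regimen(dose_mg=dose, duration_h=10.0),
                             t_grid=grid, solver_opts=TIGHT)
        analytic = dose / v * np.exp(-cl * grid / v)
        assert np.max(np.abs(res.plasma_mg_L - analytic) / analytic) < 1e-6

    def test_auc_equals_dose_over_clearance(self):
        v, cl, dose = 8.0, 2.0, 50.0
        model = OneCompartmentModel(volume_L=v, cl_L_h=cl)
        res = model.simulate(Regimen(dose_mg=dose, duration_h=60.0),
                             t_grid=np.linspace(0, 60, 1200),
                             solver_opts=TIGHT)
        met = nca(res.time_h, res.plasma_mg_L, mode="auc_0_inf")
        assert met["auc_0_inf"] == pytest.approx(dose / cl, rel=2e-3)


@pytest.fixture(scope="module")
def adult_sim(ref_man):
    drug = m.load_drug("cefoxitin")
    model = m.build_model(ref_man, drug, Formulation(route="iv_infusion"))
    grid = np.linspace(0.0, 12.0, 1201)
    res = model.simulate(Regimen(dose_mg=2000.0, duration_h=12.0,
                                 infusion_min=5.0), t_grid=grid)
    return model, res


class TestLinearIvCefoxitin:
    def test_auc_matches_dose_over_renal_clearance(self, adult_sim):
        model, res = adult_sim
        met = nca(res.time_h, res.plasma_mg_L, mode="auc_0_inf")
        assert met["auc_0_inf"] == pytest.approx(
            2000.0 / model.renal.cl_plasma_L_h, rel=0.02)

    def test_mass_balance_tight(self, adult_sim):
        _, res = adult_sim
        assert res.mass_balance_rel_error < 1e-3

    def test_dose_proportionality(self, ref_man):
        drug = m.load_drug("cefoxitin")
        model = m.build_model(ref_man, drug, Formulation(route="iv_infusion"))
        grid = np.linspace(0.0, 12.0, 301)
        auc = []
        for dose in (500.0, 1000.0):
            res = model.simulate(Regimen(dose_mg=dose, duration_h=12.0,
                                         infusion_min=5.0), t_grid=grid)
            auc.append(nca(res.time_h, res.plasma_mg_L)["auc_0_t"])
        assert auc[1] == pytest.approx(2.0 * auc[0], rel=1e-6)

    def test_auc_stable_under_grid_refinement(self, ref_man):
        drug = m.load_drug("cefoxitin")
        model = m.build_model(ref_man, drug, Formulation(route="iv_infusion"))
        reg = Regimen(dose_mg=2000.0, duration_h=12.0, infusion_min=5.0)
        aucs = []
        for npts in (1201, 2401):
            res = model.simulate(reg, t_grid=np.linspace(0, 12, npts))
            aucs.append(nca(res.time_h, res.plasma_mg_L)["auc_0_t"])
        assert abs(aucs[1] / aucs[0] - 1.0) < 0.005


class TestMassBalanceAllDrugs:
    @pytest.mark.parametrize("name", m.DRUG_NAMES)
    def test_pediatric_simulation_conserves_mass(self, name, child):
        drug = m.load_drug(name)
        setup = formulation_for_study(drug, "pediatric")
        model = m.build_model(child, drug, setup.formulation,
                              prandial_state=setup.prandial, meal=setup.meal)
        res = model.simulate(setup.regimen(bwt_kg=child.BWT))
        assert res.mass_balance_rel_error < 1e-3
        assert np.all(res.plasma_mg_L >= 0.0)


class TestSaturableMetabolism:
    def test_caffeine_auc_per_dose_rises_with_dose(self, child):
        drug = m.load_drug("caffeine")
        setup = formulation_for_study(drug, "pediatric")
        model = m.build_model(child, drug, setup.formulation,
                              prandial_state=setup.prandial, meal=setup.meal)
        auc_per_dose = []
        for dose in (10.0, 200.0):
            res = model.simulate(Regimen(dose_mg=dose, duration_h=72.0))
            met = nca(res.time_h, res.plasma_mg_L, mode="auc_0_inf")
            auc_per_dose.append(met["auc_0_inf"] / dose)
        assert auc_per_dose[1] > 1.1 * auc_per_dose[0]

    def test_one_compartment_oracle_shows_same_property(self):
        # independent oracle: direct integration of dC/dt = -Vmax C/(Km+C)/V
        v, vmax, km = 10.0, 50.0, 2.0
        out = []
        for dose in (10.0, 200.0):
            sol = solve_ivp(lambda t, y: [-vmax * y[0] / v
                                          / (km + y[0] / v)],
                            (0, 2000), [dose], rtol=1e-10, atol=1e-12,
                            dense_output=True)
            ts = np.linspace(0, 2000, 20001)
            out.append(np.trapezoid(sol.sol(ts)[0] / v, ts) / dose)
        assert out[1] > out[0]


class TestLimitsAndErrors:
    def test_zero_dose_gives_zero_curves(self, child):
        drug = m.load_drug("caffeine")
        setup = formulation_for_study(drug, "pediatric")
        model = m.build_model(child, drug, setup.formulation,
                              prandial_state=setup.prandial, meal=setup.meal)
        res = model.simulate(Regimen(dose_mg=0.0, duration_h=12.0))
        assert np.all(res.plasma_mg_L == 0.0)
        assert np.all(res.blood_mg_L == 0.0)

    def test_permeable_solution_fully_absorbed(self, child):
        # caffeine's high permeability: essentially complete absorption
        drug = m.load_drug("caffeine")
        setup = formulation_for_study(drug, "pediatric")
        model = m.build_model(child, drug, setup.formulation,
                              prandial_state=setup.prandial, meal=setup.meal)
        res = model.simulate(Regimen(dose_mg=40.0, duration_h=48.0))
        fabs = 1.0 - res.eliminated_mg["fecal"][-1] / 40.0
        assert fabs > 0.99

    def test_unknown_route_rejected(self, child):
        with pytest.raises(ValueError):
            m.build_model(child, m.load_drug("caffeine"),
                          Formulation(route="intramuscular"))

    def test_renal_impairment_raises_exposure(self, child):
        # severe scaling shrinks kidney mass and GFR: same absolute dose
        # of a renally cleared drug must expose more
        drug = m.load_drug("cefoxitin")
        setup = formulation_for_study(drug, "pediatric")
        psps = m.build_psp_table()["severe"]
        scaled = m.apply_psps(child, psps)
        reg = Regimen(dose_mg=200.0, duration_h=12.0, infusion_min=5.0)
        auc = {}
        for tag, ind in (("none", child), ("severe", scaled)):
            model = m.build_model(ind, drug, setup.formulation)
            res = model.simulate(reg)
            auc[tag] = nca(res.time_h, res.plasma_mg_L,
                           mode="auc_0_inf")["auc_0_inf"]
        assert auc["severe"] > auc["none"]
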