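"""Whole-body disposition model and its numerical solution.

The body is assembled from perfusion-limited organ compartments joined by
arterial, venous and portal blood pools: venous blood passes the lung to
the arterial pool; splanchnic organs drain into the portal vein and through
the liver (first pass). Organ partitioning uses composition-predicted Kp
values; the erythrocyte pool is carried through the whole-blood:plasma
ratio. Oral doses enter a 12-segment luminal transit chain with dissolution
and permeability-limited absorption into the portal vein.

Elimination pathways:

* renal — glomerular filtration (GFR fraction) plus specific renal
  clearance normalized to kidney volume, both acting on unbound central
  venous plasma (so a linear drug's AUC is exactly dose/clearance);
* hepatic — Michaelis–Menten or first-order processes on unbound
  liver-outflow plasma (well-stirred, saturable first pass);
* biliary — secreted from the liver into the duodenal lumen
  (enterohepatic recirculation possible);
* fecal — unabsorbed drug leaving the last gut segment.

Units: mg, L, h; concentrations mg/L unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ..physiology import REFERENCE_ALBUMIN_G_L
from .dissolution import NoyesWhitney, Weibull
from .gi import build_gi_tract
from .partition import (blood_plasma_ratio, erythrocyte_partition,
                        kp_for_method, scaled_fu)

#: Microsomal protein per gram of liver (mg/g) for in-vitro/in-vivo scaling.
MPPGL_MG_PER_G = 40.0

_ORGAN_ORDER = ("bone", "brain", "fat", "gonads", "heart", "kidney",
                "muscle", "skin", "stomach", "intestines", "spleen",
                "pancreas", "liver", "lung")
_PORTAL_IDX = slice(8, 12)
_SYSTEMIC_IDX = slice(0, 8)
_LIVER = 12
_LUNG = 13

DEFAULT_SOLVER_OPTS = {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10}


class SimulationError(RuntimeError):
    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class PKResult:
    """Per-individual simulation output with mass-balance bookkeeping."""

    time_h: np.ndarray
    plasma_mg_L: np.ndarray        # venous plasma
    blood_mg_L: np.ndarray         # venous whole blood
    eliminated_mg: dict            # pathway -> cumulative amount
    dose_mg: float
    mass_balance_rel_error: float

    def to_frame(self):
        import pandas as pd
        data = {"time_h": self.time_h, "plasma_mg_L": self.plasma_mg_L,
                "blood_mg_L": self.blood_mg_L}
        for k, v in self.eliminated_mg.items():
            data[f"eliminated_{k}_mg"] = v
        return pd.DataFrame(data)


class _BaseModel:
    """Shared integration/dosing machinery for ODE models."""

    n_states: int

    def rhs(self, t, y):             # pragma: no cover - interface
        raise NotImplementedError

    def initial_bolus(self, y, dose_mg):
        raise NotImplementedError

    def administered(self, t, regimen):
        raise NotImplementedError

    def outputs(self, t, ys, regimen) -> PKResult:
        raise NotImplementedError

    def simulate(self, regimen, t_grid=None, solver_opts=None) -> PKResult:
        opts = dict(DEFAULT_SOLVER_OPTS)
        if solver_opts:
            opts.update(solver_opts)
        if t_grid is None:
            # front-loaded grid: absorption/infusion phases need resolution
            t_early = min(2.0, 0.1 * regimen.duration_h)
            t_grid = np.unique(np.concatenate([
                np.linspace(0.0, t_early, 81),
                np.linspace(t_early, regimen.duration_h, 161)]))
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")

        # integration breakpoints: dose times and infusion ends
        breaks = {0.0, float(t_grid[-1])}
        for td in regimen.schedule_h:
            breaks.add(float(td))
            if regimen.infusion_min > 0:
                breaks.add(float(td) + regimen.infusion_min / 60.0)
        breaks = sorted(b for b in breaks if 0.0 <= b <= t_grid[-1])

        y = np.zeros(self.n_states)
        ts_out, ys_out = [], []
        for a, b in zip(breaks[:-1], breaks[1:]):
            if a in regimen.schedule_h and regimen.infusion_min == 0.0:
                y = self.initial_bolus(y, regimen.dose_mg)
            self._segment_t0 = max(
                [td for td in regimen.schedule_h if td <= a], default=0.0)
            self._infusion_rate = 0.0
            if regimen.infusion_min > 0:
                t_inf = regimen.infusion_min / 60.0
                if any(td <= a < td + t_inf - 1e-12
                       for td in regimen.schedule_h):
                    self._infusion_rate = regimen.dose_mg / t_inf
            mask = (t_grid >= a) & (t_grid <= b)
            t_eval = np.unique(np.concatenate([[a], t_grid[mask], [b]]))
            sol = solve_ivp(self.rhs, (a, b), y, t_eval=t_eval, **opts)
            if not sol.success:
                raise SimulationError(
                    f"ODE solver failed in [{a}, {b}]: {sol.message}",
                    state=y.copy())
            for i, t in enumerate(sol.t):
                if mask.any() and t in t_grid[mask] and (
                        not ts_out or t > ts_out[-1]):
                    ts_out.append(t)
                    ys_out.append(sol.y[:, i])
            y = sol.y[:, -1]
        ts = np.array(ts_out)
        ys = np.array(ys_out).T
        return self.outputs(ts, ys, regimen)


@dataclass
class _RenalParams:
    cl_plasma_L_h: float = 0.0       # acts on unbound arterial plasma


@dataclass
class _HepaticParams:
    vmax_mg_h: float = 0.0
    km_mg_L: float = np.inf
    cl_first_order_L_h: float = 0.0  # pooled first-order processes
    cl_biliary_L_h: float = 0.0


class PBPKModel(_BaseModel):
    """Assembled whole-body model for one individual and one drug."""

    def __init__(self, individual, drug, formulation, prandial="fasted",
                 meal=None):
        self.individual = individual
        self.drug = drug
        self.formulation = formulation
        self.prandial = prandial

        m = individual.organ_masses
        self.V = np.array([m[o] for o in _ORGAN_ORDER])        # L (rho=1)
        q = individual.specific_perfusion
        self.Q = np.array([q[o] * m[o] for o in _ORGAN_ORDER])  # L/h
        self.CO = individual.cardiac_output
        self.Q[_LUNG] = self.CO
        self.Qha = q["liver"] * m["liver"]
        self.Qpv = float(self.Q[_PORTAL_IDX].sum())
        self.V_art = m["blood_arterial"]
        self.V_ven = m["blood_venous"]
        self.V_por = m["blood_portal"]

        # individual unbound fraction from the plasma-protein level
        self.fu = scaled_fu(drug.fu_p,
                            individual.albumin_conc / REFERENCE_ALBUMIN_G_L)
        k_ery = erythrocyte_partition(drug, self.fu)
        self.BP = blood_plasma_ratio(drug, individual.hematocrit, k_ery=k_ery)
        self.kp = np.array([
            kp_for_method(drug.distribution_method, drug, o, self.fu)
            for o in _ORGAN_ORDER])
        self.bpkp = self.BP / self.kp

        ont = individual.ontogeny
        renal = _RenalParams()
        if drug.renal is not None:
            gfr_cl = individual.gfr * drug.renal.gfr_fraction
            ts_cl = (drug.renal.cl_spec_per_min * 60.0 * m["kidney"]
                     * ont.get("tubular_secretion", 1.0))
            renal.cl_plasma_L_h = self.fu * (gfr_cl + ts_cl)
        self.renal = renal

        hep = _HepaticParams()
        h = drug.hepatic
        if h is not None:
            f = ont.get(h.pathway, 1.0) if h.pathway else 1.0
            if h.vmax_pmol_min_mg is not None:
                hep.vmax_mg_h = (h.vmax_pmol_min_mg * drug.mw_g_mol * 2.4e-3
                                 * m["liver"] * f)
                hep.km_mg_L = h.km_um * drug.mw_g_mol / 1000.0
            if h.cl_spec_per_min is not None:
                hep.cl_first_order_L_h += (h.cl_spec_per_min * 60.0
                                           * m["liver"] * f)
            if h.cl_int_ul_min_mg is not None:
                hep.cl_first_order_L_h += (h.cl_int_ul_min_mg * 1e-6
                                           * MPPGL_MG_PER_G * 60.0 * 1000.0
                                           * m["liver"] * f)
            if h.biliary_cl_spec_per_min is not None:
                hep.cl_biliary_L_h = (h.biliary_cl_spec_per_min * 60.0
                                      * m["liver"])
        self.hepatic = hep

        # ---- gut lumen ----
        self.oral = formulation.route in ("oral_solution", "oral_suspension",
                                          "oral_solid", "enteral_solution")
        segs = build_gi_tract(individual, prandial=prandial, meal=meal,
                              saef_overrides=drug.saef_overrides)
        self.segments = segs
        self.k_transit = np.array([1.0 / s.transit_h for s in segs])
        self.V_lum = np.array([s.fluid_volume_ml / 1000.0 for s in segs])
        p_cm_h = drug.p_int_1e6_cm_min * 1e-6 * 60.0
        self.PA = np.array([p_cm_h * s.surface_area_cm2 / 1000.0
                            for s in segs])                     # L/h
        self.c_sol = drug.solubility_mg_ml(prandial) * 1000.0   # mg/L
        self.dissolution_law = None
        if formulation.route == "oral_solid":
            self.dissolution_law = drug.dissolution_law(prandial)
        elif formulation.route == "oral_suspension":
            self.dissolution_law = NoyesWhitney(
                radius_um=formulation.particle_radius_um)

        self.n_states = 45
        self._segment_t0 = 0.0
        self._infusion_rate = 0.0

    # state layout: 0..13 organs | 14 art | 15 ven | 16 por |
    # 17..28 lumen dissolved | 29..40 lumen solid |
    # 41 renal | 42 hepatic | 43 fecal | 44 bile (cumulative transfer)
    def rhs(self, t, y):
        dy = np.zeros_like(y)
        A = y[:14]
        c_t = A / self.V
        c_out = c_t * self.bpkp                      # outflow blood conc
        c_art = y[14] / self.V_art
        c_ven = y[15] / self.V_ven
        c_por = y[16] / self.V_por

        d_org = self.Q * (c_art - c_out)
        d_org[_LUNG] = self.CO * (c_ven - c_out[_LUNG])
        d_org[_LIVER] = (self.Qha * c_art + self.Qpv * c_por
                         - (self.Qha + self.Qpv) * c_out[_LIVER])

        # hepatic elimination on unbound liver-outflow plasma
        cu_liv = self.fu * c_t[_LIVER] / self.kp[_LIVER]
        hep = self.hepatic
        met = hep.cl_first_order_L_h * cu_liv
        if hep.vmax_mg_h > 0.0:
            met += hep.vmax_mg_h * cu_liv / (hep.km_mg_L + cu_liv)
        bile = hep.cl_biliary_L_h * cu_liv
        d_org[_LIVER] -= met + bile

        # renal elimination on unbound central venous plasma (the sampled
        # pool, so a linear drug's AUC is exactly dose/clearance)
        ren = self.renal.cl_plasma_L_h * (c_ven / self.BP)

        dy[:14] = d_org
        dy[14] = (self.CO * c_out[_LUNG]
                  - (self.Q[:13].sum()) * c_art)
        dy[15] = (float(self.Q[_SYSTEMIC_IDX] @ c_out[_SYSTEMIC_IDX])
                  + (self.Qha + self.Qpv) * c_out[_LIVER]
                  - self.CO * c_ven - ren + self._infusion_rate)
        dy[16] = (float(self.Q[_PORTAL_IDX] @ c_out[_PORTAL_IDX])
                  - self.Qpv * c_por)

        if self.oral:
            D = y[17:29]
            S = y[29:41]
            c_lum = D / self.V_lum
            flux = self.PA * c_lum                   # absorption, mg/h
            trans_d = self.k_transit * D
            trans_s = self.k_transit * S
            dD = -trans_d - flux
            dD[1:] += trans_d[:-1]
            dS = -trans_s
            dS[1:] += trans_s[:-1]
            if self.dissolution_law is not None:
                sat = np.clip(1.0 - c_lum / self.c_sol, 0.0, 1.0)
                if isinstance(self.dissolution_law, Weibull):
                    hz = self.dissolution_law.hazard(t - self._segment_t0)
                    dis = hz * np.clip(S, 0.0, None) * sat
                else:
                    m0 = max(self._dose_solid, 1e-12)
                    coef = self.dissolution_law.rate_coefficient
                    # cube root linearized near zero: keeps the RHS
                    # Lipschitz when a segment's solid pool empties
                    x = np.clip(S, 0.0, None)
                    s0 = 1e-6 * m0
                    cube = np.where(x > s0, np.cbrt(x), x * s0 ** (-2.0 / 3.0))
                    dis = (coef * m0 ** (2.0 / 3.0) * cube
                           * (self.c_sol / 1000.0) * sat)
                dD += dis
                dS -= dis
            dD[1] += bile                            # enterohepatic return
            dy[16] += float(flux.sum())
            dy[17:29] = dD
            dy[29:41] = dS
            dy[43] = trans_d[-1] + trans_s[-1]
        dy[41] = ren
        dy[42] = met
        dy[44] = bile
        return dy

    _dose_solid = 0.0

    def initial_bolus(self, y, dose_mg):
        y = y.copy()
        if not self.oral:
            y[15] += dose_mg                          # iv bolus to venous
            return y
        if self.formulation.route in ("oral_solution", "enteral_solution"):
            y[17] += dose_mg
        else:
            y[29] += dose_mg
            self._dose_solid = y[29]
        return y

    def administered(self, t, regimen):
        t = np.asarray(t, dtype=float)
        total = np.zeros_like(t)
        t_inf = regimen.infusion_min / 60.0
        for td in regimen.schedule_h:
            if regimen.infusion_min > 0:
                total += (regimen.dose_mg
                          * np.clip((t - td) / t_inf, 0.0, 1.0))
            else:
                total += np.where(t >= td, regimen.dose_mg, 0.0)
        return total

    def outputs(self, ts, ys, regimen) -> PKResult:
        c_ven_blood = np.clip(ys[15] / self.V_ven, 0.0, None)
        plasma = c_ven_blood / self.BP
        eliminated = {"renal": ys[41], "hepatic": ys[42], "fecal": ys[43],
                      "biliary_secreted": ys[44]}
        body = ys[:17].sum(axis=0)
        lumen = ys[17:41].sum(axis=0)
        accounted = body + lumen + ys[41] + ys[42] + ys[43]
        given = self.administered(ts, regimen)
        dose_total = regimen.dose_mg * len(regimen.schedule_h)
        with np.errstate(invalid="ignore"):
            err = np.nanmax(np.abs(accounted - given)[given > 0]
                            / dose_total) if np.any(given > 0) else 0.0
        return PKResult(time_h=ts, plasma_mg_L=plasma, blood_mg_L=c_ven_blood,
                        eliminated_mg=eliminated, dose_mg=dose_total,
                        mass_balance_rel_error=float(err))


class OneCompartmentModel(_BaseModel):
    """Degenerate single-compartment configuration sharing the solver path.

    Supports first-order clearance and an optional Michaelis–Menten term;
    used to check the integration machinery against closed forms.
    """

    def __init__(self, volume_L, cl_L_h=0.0, vmax_mg_h=0.0, km_mg_L=1.0):
        self.V = volume_L
        self.cl = cl_L_h
        self.vmax = vmax_mg_h
        self.km = km_mg_L
        self.n_states = 2            # amount, eliminated
        self._infusion_rate = 0.0
        self._segment_t0 = 0.0

    def rhs(self, t, y):
        c = y[0] / self.V
        rate = self.cl * c + (self.vmax * c / (self.km + c)
                              if self.vmax else 0.0)
        return np.array([self._infusion_rate - rate, rate])

    def initial_bolus(self, y, dose_mg):
        y = y.copy()
        y[0] += dose_mg
        return y

    def administered(self, t, regimen):
        return PBPKModel.administered(self, t, regimen)

    def outputs(self, ts, ys, regimen) -> PKResult:
        c = ys[0] / self.V
        dose_total = regimen.dose_mg * len(regimen.schedule_h)
        given = self.administered(ts, regimen)
        accounted = ys[0] + ys[1]
        err = (np.max(np.abs(accounted - given)[given > 0] / dose_total)
               if np.any(given > 0) else 0.0)
        return PKResult(time_h=ts, plasma_mg_L=c, blood_mg_L=c,
                        eliminated_mg={"total": ys[1]}, dose_mg=dose_total,
                        mass_balance_rel_error=float(err))


def build_model(individual, drug, formulation, prandial_state="fasted",
                meal=None) -> PBPKModel:
    """Assemble the ODE system for one individual/drug/administration."""
    valid = ("iv_infusion", "oral_solution", "oral_suspension", "oral_solid",
             "enteral_solution")
    if formulation.route not in valid:
        raise ValueError(f"unknown route {formulation.route!r}")
    return PBPKModel(individual, drug, formulation, prandial=prandial_state,
                     meal=meal)


def simulate(model, regimen, t_grid=None, solver_opts=None) -> PKResult:
    """Run a model under a dose regimen; see :meth:`_BaseModel.simulate`."""
    return model.simulate(regimen, t_grid=t_grid, solver_opts=solver_opts)
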