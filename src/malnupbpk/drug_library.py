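"""The shipped drug models, formulations and study setups.

Each drug ships as one structured-text config mirroring its published
parameter set: physico-chemistry (logP, Mw, pKa), plasma binding (fu_p),
solubility by prandial state, distribution method, intestinal permeability,
and the elimination terms of its column. Clearance units follow the source
conventions (CL_spec in 1/min normalized to organ volume, V_max in
pmol/min/mg microsomal protein, CL_int in µL/min/mg microsomal protein);
conversion to L/h happens inside the PBPK model via organ masses and a
microsomal-protein scalar of 40 mg per g liver.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datafiles import drug_config_path, studies_registry
from .pbpk_core.dissolution import NoyesWhitney, Weibull

DRUG_NAMES = ("caffeine", "cefoxitin", "ciprofloxacin", "lumefantrine",
              "pyrimethamine", "sulfadoxine")


class PKaEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    value: float
    type: Literal["acid", "base"]


class SolubilityEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mg_ml: float = Field(gt=0)
    ph: float
    prandial: Literal["any", "fasted", "fed", "fed_high_fat"] = "any"


class RenalParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gfr_fraction: float = Field(default=0.0, ge=0)
    cl_spec_per_min: float = Field(default=0.0, ge=0)


class HepaticParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vmax_pmol_min_mg: Optional[float] = Field(default=None, gt=0)
    km_um: Optional[float] = Field(default=None, gt=0)
    cl_spec_per_min: Optional[float] = Field(default=None, gt=0)
    cl_int_ul_min_mg: Optional[float] = Field(default=None, gt=0)
    biliary_cl_spec_per_min: Optional[float] = Field(default=None, gt=0)
    pathway: Optional[Literal["CYP1A2", "CYP3A4", "unspecific_hepatic"]] = None

    @model_validator(mode="after")
    def _mm_pair(self):
        if (self.vmax_pmol_min_mg is None) != (self.km_um is None):
            raise ValueError("vmax and km must be given together")
        return self


class ErythrocyteFractions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    f_proteins: float = Field(ge=0, le=1)
    f_lipid: float = Field(ge=0, le=1)


class WeibullParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t50_min: float = Field(gt=0)
    shape: float = Field(gt=0)


class DrugModel(BaseModel):
    """One drug's full PBPK parameterization."""

    model_config = ConfigDict(extra="forbid")

    name: str
    logP: float
    fu_p: float = Field(gt=0, le=1)
    mw_g_mol: float = Field(gt=0)
    pka: list[PKaEntry]
    solubility: list[SolubilityEntry]
    distribution_method: Literal["pksim", "rodgers_rowland", "schmitt"]
    p_int_1e6_cm_min: float = Field(gt=0)
    renal: Optional[RenalParams] = None
    hepatic: Optional[HepaticParams] = None
    erythrocytes: ErythrocyteFractions = ErythrocyteFractions(
        f_proteins=0.0, f_lipid=0.0)
    dissolution: Optional[dict[str, WeibullParams]] = None
    saef_overrides: Optional[dict[str, float]] = None

    def solubility_mg_ml(self, prandial: str) -> float:
        """Solubility for a prandial state (state-specific over 'any')."""
        by_state = {e.prandial: e.mg_ml for e in self.solubility}
        for key in (prandial, "any", "fasted"):
            if key in by_state:
                return by_state[key]
        return self.solubility[0].mg_ml

    def dissolution_law(self, prandial: str) -> Weibull:
        if not self.dissolution:
            raise ValueError(f"{self.name}: no dissolution law configured")
        for key in (prandial, "any", "fasted"):
            if key in self.dissolution:
                p = self.dissolution[key]
                return Weibull(t50_h=p.t50_min / 60.0, shape=p.shape)
        raise ValueError(f"{self.name}: no dissolution law for {prandial!r}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(exclude_none=True),
                              sort_keys=True)


@dataclass(frozen=True)
class MealModel:
    """A co-administered meal or nutritional drink."""

    volume_ml: float = 0.0
    kcal: float = 0.0

    def __post_init__(self):
        if self.volume_ml < 0 or self.kcal < 0:
            raise ValueError("meal volume and caloric content must be >= 0")


@dataclass(frozen=True)
class Formulation:
    route: str                        # iv_infusion | oral_* | enteral_solution
    particle_radius_um: float = 10.0  # suspensions only
    dissolution: str | None = None    # 'weibull' for solids


@dataclass(frozen=True)
class Regimen:
    dose_mg: float
    duration_h: float
    infusion_min: float = 0.0
    schedule_h: tuple = (0.0,)

    def __post_init__(self):
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class StudySetup:
    """Administration setup replicating one named reference simulation."""

    drug: str
    study: str
    formulation: Formulation
    prandial: str
    meal: MealModel | None
    dose_mg: float | None
    dose_mg_per_kg: float | None
    age_range: tuple[float, float]
    duration_h: float
    infusion_min: float = 0.0

    def regimen(self, bwt_kg: float | None = None,
                per_kg: bool = False) -> Regimen:
        if per_kg:
            if self.dose_mg_per_kg is None:
                raise ValueError(f"no per-kg dose defined for {self.drug}"
                                 f"/{self.study}")
            if bwt_kg is None:
                raise ValueError("per-kg dosing needs a body weight")
            dose = self.dose_mg_per_kg * bwt_kg
        else:
            if self.dose_mg is None:
                raise ValueError(f"no flat dose defined for {self.drug}"
                                 f"/{self.study}")
            dose = self.dose_mg
        return Regimen(dose_mg=dose, duration_h=self.duration_h,
                       infusion_min=self.infusion_min)


def load_drug(name_or_path: str) -> DrugModel:
    """Load and validate a drug config by shipped name or file path."""
    path = Path(name_or_path)
    if name_or_path in DRUG_NAMES:
        with drug_config_path(name_or_path).open() as fh:
            raw = yaml.safe_load(fh)
    elif path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        raise FileNotFoundError(f"unknown drug or path: {name_or_path!r}")
    return DrugModel.model_validate(raw)


def formulation_for_study(drug: str | DrugModel, study: str) -> StudySetup:
    """Administration setup (formulation + prandial state) for a study key."""
    name = drug.name if isinstance(drug, DrugModel) else drug
    registry = studies_registry()
    if name not in registry or study not in registry[name]:
        raise KeyError(f"unknown study {name!r}/{study!r}")
    cfg = registry[name][study]
    meal = MealModel(**cfg["meal"]) if "meal" in cfg else None
    form = Formulation(route=cfg["route"],
                       particle_radius_um=cfg.get("particle_radius_um", 10.0),
                       dissolution=cfg.get("dissolution"))
    return StudySetup(
        drug=name, study=study, formulation=form, prandial=cfg["prandial"],
        meal=meal, dose_mg=cfg.get("dose_mg"),
        dose_mg_per_kg=cfg.get("dose_mg_per_kg"),
        age_range=tuple(cfg["age_range"]), duration_h=cfg["duration_h"],
        infusion_min=cfg.get("infusion_min", 0.0))
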