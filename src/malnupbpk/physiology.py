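"""Virtual individuals and populations.

A :class:`Physiology` is the complete system parameterization of one virtual
individual: organ masses, specific blood perfusion, hematology, plasma
proteins, glomerular filtration and the maturation state of the clearance
pathways. Reference individuals are interpolated from an embedded age/sex
grid of ICRP-style reference values whose child biometrics are anchored to
growth-standard medians; stochastic populations are built around those
reference bodies with log-normal variability and a shared body-size factor.

Units: kg, cm, L, h throughout; albumin and alpha-1-acid glycoprotein in g/L.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datafiles import reference_physiology

#: Compartments carrying a mass in every Physiology (order is canonical).
COMPARTMENTS = (
    "bone", "brain", "fat", "gonads", "intestines", "lung", "stomach",
    "heart", "kidney", "liver", "muscle", "pancreas", "skin", "spleen",
    "blood_arterial", "blood_venous", "blood_portal",
)

#: Splanchnic organs whose venous outflow drains into the portal vein.
PORTAL_ORGANS = ("stomach", "intestines", "spleen", "pancreas")

ONTOGENY_PATHWAYS = ("CYP1A2", "CYP3A4", "unspecific_hepatic",
                     "tubular_secretion")

# Hill-type maturation constants (T50 in years, Hill coefficient). The curves
# are normalized to their value at ADULT_AGE so adults sit exactly at 1.
_ONTOGENY_HILL = {
    "CYP1A2": (0.40, 2.0),
    "CYP3A4": (0.30, 1.0),
    "unspecific_hepatic": (0.25, 2.0),
    "tubular_secretion": (0.60, 1.5),
}
_GFR_HILL = (0.25, 1.5)
ADULT_AGE = 18.0

AGE_MIN, AGE_MAX = 0.25, 80.0

#: Reference albumin concentration in non-malnourished adults (g/L).
REFERENCE_ALBUMIN_G_L = 42.5
#: Reference hematocrit in non-malnourished adult men.
REFERENCE_HEMATOCRIT = 0.47


class UnsupportedAgeError(ValueError):
    pass


class UnknownPathwayError(KeyError):
    pass


@dataclass(frozen=True)
class Physiology:
    """Full system parameterization of one virtual individual."""

    age: float                       # years
    sex: str                         # "male" | "female"
    HT: float                        # cm
    organ_masses: dict[str, float]   # kg, keyed by COMPARTMENTS
    specific_perfusion: dict[str, float]  # L/h per kg tissue
    hematocrit: float
    albumin_conc: float              # g/L
    agp_conc: float                  # g/L
    gfr: float                       # L/h
    ontogeny: dict[str, float] = field(default_factory=dict)

    @property
    def BWT(self) -> float:
        """Body weight (kg): the exact sum of all compartment masses."""
        return float(sum(self.organ_masses.values()))

    @property
    def cardiac_output(self) -> float:
        """Sum of organ blood flows excluding the lung (L/h)."""
        return float(sum(self.specific_perfusion[c] * self.organ_masses[c]
                         for c in COMPARTMENTS if c != "lung"))

    def organ_flow(self, compartment: str) -> float:
        return self.specific_perfusion[compartment] * self.organ_masses[compartment]

    def validate(self) -> None:
        missing = set(COMPARTMENTS) - set(self.organ_masses)
        if missing:
            raise ValueError(f"missing compartments: {sorted(missing)}")
        if any(m <= 0 for m in self.organ_masses.values()):
            raise ValueError("all organ masses must be strictly positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if min(self.albumin_conc, self.agp_conc, self.gfr, self.HT) <= 0:
            raise ValueError("concentrations, GFR and height must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a stochastic virtual population."""

    n: int
    age_range: tuple[float, float]
    sex_ratio: float = 0.5           # fraction male
    seed: int = 0
    variability: dict[str, float] | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.age_range[0] <= self.age_range[1]:
            raise ValueError("age_range must be ordered")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")


# Default coefficients of variation. The shared body-size factor and the
# organ-specific residual combine to ~15% total CV on an organ mass; height
# co-varies with the size factor so BWT/HT remains realistically correlated.
DEFAULT_VARIABILITY = {
    "shared_size": 0.10,
    "organ": 0.11,
    "height": 0.02,
    "height_size_coupling": 0.25,
    "hematocrit": 0.05,
    "plasma_proteins": 0.05,
    "gfr": 0.15,
}


def _hill_factor(age: float, t50: float, n: float) -> float:
    def hill(a):
        return a ** n / (a ** n + t50 ** n)
    if age >= ADULT_AGE:
        return 1.0
    return min(1.0, hill(age) / hill(ADULT_AGE))


def ontogeny_factor(pathway: str, age: float) -> float:
    """Fraction of adult activity of a clearance pathway at a given age.

    Monotone non-decreasing in age, exactly 1 from adulthood on.
    """
    if pathway not in _ONTOGENY_HILL:
        raise UnknownPathwayError(pathway)
    if age < 0:
        raise UnsupportedAgeError("age must be non-negative")
    t50, n = _ONTOGENY_HILL[pathway]
    return _hill_factor(age, t50, n)


def gfr_maturation(age: float) -> float:
    """Maturation of glomerular filtration toward the adult-specific rate."""
    t50, n = _GFR_HILL
    return _hill_factor(age, t50, n)


def _grid(sex: str):
    df = reference_physiology()
    return df[df.sex == sex]


def _interp_component(sub, component: str, age: float) -> float:
    rows = sub[sub.compartment == component]
    return float(np.interp(age, rows.age_y.to_numpy(), rows.value.to_numpy()))


def reference_individual(age: float, sex: str) -> Physiology:
    """Deterministic reference body for an age and sex.

    Organ masses are interpolated linearly in age between grid anchors;
    fat closes the mass balance against the (growth-anchored) reference
    body weight, so the compartments always sum to the reference BWT.
    """
    if not AGE_MIN <= age <= AGE_MAX:
        raise UnsupportedAgeError(
            f"age {age} outside supported grid [{AGE_MIN}, {AGE_MAX}]")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    sub = _grid(sex)

    bwt = _interp_component(sub, "BWT", age)
    ht = _interp_component(sub, "HT", age)

    masses: dict[str, float] = {}
    perfusion: dict[str, float] = {}
    for comp in COMPARTMENTS:
        rows = sub[sub.compartment == comp]
        perfusion[comp] = float(rows.perfusion_L_per_h_per_kg.iloc[0])
        if comp != "fat":
            masses[comp] = float(np.interp(age, rows.age_y.to_numpy(),
                                           rows.value.to_numpy()))
    fat = bwt - sum(masses.values())
    if fat <= 0:
        raise ValueError(f"non-positive fat residual at age {age} ({sex})")
    masses["fat"] = fat

    hct = _interp_component(sub, "hemoglobin_hct", age)
    alb = _interp_component(sub, "albumin_g_L", age)
    agp = _interp_component(sub, "agp_g_L", age)
    gfr_spec = _interp_component(sub, "gfr_spec_L_h_kg", age)
    gfr = gfr_spec * masses["kidney"] * gfr_maturation(age)

    phys = Physiology(
        age=age, sex=sex, HT=ht, organ_masses=masses,
        specific_perfusion=perfusion, hematocrit=hct, albumin_conc=alb,
        agp_conc=agp, gfr=gfr,
        ontogeny={p: ontogeny_factor(p, age) for p in ONTOGENY_PATHWAYS},
    )
    phys.validate()
    return phys


def generate_population(spec: PopulationSpec) -> list[Physiology]:
    """Stochastic population of reference-anchored virtual individuals.

    Organ masses receive independent log-normal perturbations around the
    age-specific reference plus a shared body-size factor; body weight is
    recomputed as the exact organ-mass sum, preserving mass closure.
    Identical specs (including the seed) reproduce the population exactly.
    """
    cv = dict(DEFAULT_VARIABILITY)
    if spec.variability:
        cv.update(spec.variability)
    rng = np.random.default_rng(spec.seed)
    out: list[Physiology] = []
    for _ in range(spec.n):
        age = float(rng.uniform(*spec.age_range))
        sex = "male" if rng.random() < spec.sex_ratio else "female"
        ref = reference_individual(age, sex)

        z = rng.normal(0.0, cv["shared_size"])
        eps = rng.normal(0.0, cv["organ"], size=len(COMPARTMENTS))
        masses = {c: ref.organ_masses[c] * float(np.exp(z + e))
                  for c, e in zip(COMPARTMENTS, eps)}
        ht = ref.HT * float(np.exp(cv["height_size_coupling"] * z
                                   + rng.normal(0.0, cv["height"])))
        hct = min(0.65, ref.hematocrit * float(np.exp(
            rng.normal(0.0, cv["hematocrit"]))))
        prot = float(np.exp(rng.normal(0.0, cv["plasma_proteins"])))
        gfr = (ref.gfr / ref.organ_masses["kidney"] * masses["kidney"]
               * float(np.exp(rng.normal(0.0, cv["gfr"]))))
        ind = replace(ref, HT=ht, organ_masses=masses, hematocrit=hct,
                      albumin_conc=ref.albumin_conc * prot,
                      agp_conc=ref.agp_conc * prot, gfr=gfr)
        ind.validate()
        out.append(ind)
    return out


def exclude_outliers(population: list[Physiology], k: float = 1.0
                     ) -> list[Physiology]:
    """Drop individuals deviating more than ``k`` SD in BWT/HT from the mean.

    The mean and SD are computed per sex when both sexes are present and
    pooled otherwise; input order is retained.
    """
    if len(population) < 2:
        raise ValueError("need at least 2 individuals to define an SD")
    ratios = np.array([p.BWT / (p.HT / 100.0) for p in population])
    sexes = np.array([p.sex for p in population])
    keep = np.ones(len(population), dtype=bool)
    groups = [sexes == s for s in np.unique(sexes)]
    for mask in groups:
        if mask.sum() < 2:
            continue
        r = ratios[mask]
        mu, sd = r.mean(), r.std(ddof=1)
        keep[mask] = np.abs(r - mu) <= k * sd
    return [p for p, k_ in zip(population, keep) if k_]


def population_table(population: list[Physiology]):
    """Delimited-table view of a population (one row per individual)."""
    import pandas as pd

    rows = []
    for i, p in enumerate(population):
        row = {"id": i, "age": p.age, "sex": p.sex, "BWT": p.BWT, "HT": p.HT}
        row.update(p.organ_masses)
        rows.append(row)
    return pd.DataFrame(rows)
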