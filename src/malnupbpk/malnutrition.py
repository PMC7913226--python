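"""Physiological scaling parameters (PSPs) for malnutrition.

A PSP is a dimensionless multiplicative factor translating one system
parameter of a non-malnourished individual to a defined malnutrition level
(mild, intermediate, severe). Derivable factors (plasma proteins,
hematocrit, skin, and the mild/intermediate organ levels) are computed from
the reference-study measurements; organ factors whose height-conditional
typical values cannot be reconstructed are shipped as canonical fixtures.
The fat/muscle pair is re-adjusted by a common multiplier so that scaling
the adult reference man closes the organ-mass sum exactly on the
percent-of-standard body-weight target, preserving the fat:muscle ratio.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from .datafiles import canonical_psps, reference_measurements
from .physiology import (COMPARTMENTS, Physiology, REFERENCE_ALBUMIN_G_L,
                         REFERENCE_HEMATOCRIT, reference_individual)

LEVELS = ("mild", "intermediate", "severe")

#: Compartments sharing the lean-soft-tissue surrogate factor.
LEAN_GROUP = ("gonads", "intestines", "lung", "stomach")

#: Organ rows whose mild/intermediate levels follow from the severe level by
#: linear deficit interpolation.
_INTERPOLATED = ("bone", "brain", "heart", "kidney", "liver", "spleen",
                 "lean_group", "pancreas")

_SCALAR_KEYS = ("plasma_proteins", "hematocrit")


@dataclass(frozen=True)
class PSPDerivationInput:
    """The four measurements entering a single PSP derivation.

    ``reported_*`` are study measurements; ``typical_*`` are the
    height-conditional reference values for the same quantity. All four
    must be strictly positive and share one unit.
    """

    reported_malnourished: float
    reported_normal: float
    typical_malnourished: float
    typical_normal: float

    def __post_init__(self):
        vals = (self.reported_malnourished, self.reported_normal,
                self.typical_malnourished, self.typical_normal)
        if any(v <= 0 for v in vals):
            raise ValueError("all derivation inputs must be strictly positive")


@dataclass(frozen=True)
class PSPSet:
    """Per-compartment scaling factors for one malnutrition level."""

    level: str
    factors: dict[str, float]        # compartment -> multiplier
    provenance: dict[str, str]       # compartment -> origin label

    def __post_init__(self):
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("PSP factors must be strictly positive")

    @classmethod
    def identity(cls, level: str = "none") -> "PSPSet":
        keys = COMPARTMENTS + _SCALAR_KEYS
        return cls(level=level, factors={k: 1.0 for k in keys},
                   provenance={k: "identity" for k in keys})


def derive_psp(inp: PSPDerivationInput) -> float:
    """Double ratio of reported to typical values, malnourished over normal."""
    return ((inp.reported_malnourished / inp.typical_malnourished)
            / (inp.reported_normal / inp.typical_normal))


def interpolate_level(severe_factor: float, pct_standard_target: float,
                      pct_standard_severe: float = 73.9) -> float:
    """Linear deficit interpolation between no malnutrition and severe.

    The deviation of the factor from 1 scales with the percent-of-standard
    BWT/HT deficit of the target level relative to the severe level.
    """
    if severe_factor <= 0:
        raise ValueError("severe_factor must be positive")
    for pct in (pct_standard_target, pct_standard_severe):
        if not 0 < pct <= 100:
            raise ValueError("percent-of-standard values must lie in (0, 100]")
    if pct_standard_severe == 100:
        raise ValueError("severe percent-of-standard must differ from 100")
    return 1.0 + (severe_factor - 1.0) * ((100.0 - pct_standard_target)
                                          / (100.0 - pct_standard_severe))


def skin_psp(bwt_malnourished: float, bwt_normal: float) -> float:
    """Skin factor from the body-surface-area change at fixed height.

    With height fixed, the Du Bois BSA ratio reduces to the body-weight
    ratio raised to the weight exponent 0.425.
    """
    if bwt_malnourished <= 0 or bwt_normal <= 0:
        raise ValueError("body weights must be positive")
    return (bwt_malnourished / bwt_normal) ** 0.425


def pct_standard_bwt_ht(level: str) -> float:
    """Percent-of-standard BWT/HT of a malnutrition level (reference study)."""
    t1 = reference_measurements()
    return float(t1.loc["pct_standard_bwt_ht", level])


def build_psp_table(reference: Physiology | None = None
                    ) -> dict[str, PSPSet]:
    """Derive the full three-level PSP table.

    ``reference`` is the body used for the fat/muscle mass-balance closure;
    it defaults to the 30-year-old male reference individual.
    """
    t1 = reference_measurements()
    t2 = canonical_psps()
    ref = reference or reference_individual(30.0, "male")

    out: dict[str, PSPSet] = {}
    for level in LEVELS:
        pct = float(t1.loc["pct_standard_bwt_ht", level])
        factors: dict[str, float] = {}
        prov: dict[str, str] = {}

        alb = float(t1.loc["serum_albumin_g_100ml", level]) * 10.0  # g/L
        factors["plasma_proteins"] = derive_psp(PSPDerivationInput(
            alb, REFERENCE_ALBUMIN_G_L, 1.0, 1.0))
        prov["plasma_proteins"] = "measured"

        hct = float(t1.loc["hematocrit_pct", level]) / 100.0
        factors["hematocrit"] = derive_psp(PSPDerivationInput(
            hct, REFERENCE_HEMATOCRIT, 1.0, 1.0))
        prov["hematocrit"] = "measured"

        factors["skin"] = skin_psp(ref.BWT * pct / 100.0, ref.BWT)
        prov["skin"] = "surrogate"

        # Organ factors: severe from the canonical fixture (the underlying
        # height-conditional typicals are not recoverable), other levels by
        # linear deficit interpolation from severe.
        for row in _INTERPOLATED:
            severe = float(t2.loc[row, "severe"])
            if level == "severe":
                val, p = severe, "fixture"
            else:
                val, p = interpolate_level(severe, pct), "interpolated"
            for comp in (LEAN_GROUP if row == "lean_group" else (row,)):
                factors[comp] = val
                prov[comp] = p

        for comp in ("blood_arterial", "blood_venous", "blood_portal"):
            factors[comp] = float(t2.loc[comp, level])
            prov[comp] = "fixture"

        # Fat/muscle closure: common multiplier on the fixture pair so the
        # scaled reference man hits the percent-of-standard BWT exactly.
        fat0 = float(t2.loc["fat", level])
        mus0 = float(t2.loc["muscle", level])
        target = ref.BWT * pct / 100.0
        other = sum(ref.organ_masses[c] * factors[c]
                    for c in COMPARTMENTS if c not in ("fat", "muscle"))
        c_mult = ((target - other)
                  / (fat0 * ref.organ_masses["fat"]
                     + mus0 * ref.organ_masses["muscle"]))
        cap = 1.0 / max(fat0, mus0)
        if c_mult > cap:
            import warnings
            warnings.warn(f"fat/muscle closure multiplier capped at {cap:.3f} "
                          f"for level {level}")
            c_mult = cap
        factors["fat"] = fat0 * c_mult
        factors["muscle"] = mus0 * c_mult
        prov["fat"] = prov["muscle"] = "adjusted"

        out[level] = PSPSet(level=level, factors=factors, provenance=prov)
    return out


def apply_psps(individual: Physiology, psps: PSPSet) -> Physiology:
    """Scale an individual's system parameters to a malnutrition level.

    Organ masses, blood-compartment masses, plasma-protein concentrations
    and hematocrit are multiplied by their factors; specific perfusion
    (flow per kg) is preserved so absolute organ flows — and cardiac
    output — shrink with mass. GFR follows the kidney factor. Height, age,
    sex and pathway maturation are untouched; body weight is recomputed as
    the scaled organ-mass sum.
    """
    missing = [c for c in COMPARTMENTS if c not in psps.factors]
    for key in _SCALAR_KEYS:
        if key not in psps.factors:
            missing.append(key)
    if missing:
        raise KeyError(f"PSP set lacks factors for: {missing}")

    masses = {c: individual.organ_masses[c] * psps.factors[c]
              for c in COMPARTMENTS}
    scaled = replace(
        individual,
        organ_masses=masses,
        hematocrit=individual.hematocrit * psps.factors["hematocrit"],
        albumin_conc=individual.albumin_conc * psps.factors["plasma_proteins"],
        agp_conc=individual.agp_conc * psps.factors["plasma_proteins"],
        gfr=individual.gfr * psps.factors["kidney"],
    )
    scaled.validate()
    return scaled


def psp_table_frame():
    """Three-level PSP table as a tidy DataFrame with provenance."""
    import pandas as pd

    table = build_psp_table()
    rows = []
    for level, pspset in table.items():
        for comp, f in pspset.factors.items():
            rows.append({"level": level, "component": comp, "factor": f,
                         "provenance": pspset.provenance[comp]})
    return pd.DataFrame(rows)
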