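"""Tissue:plasma partition coefficients and blood:plasma partitioning.

Three composition-based prediction methods are provided:

* ``kp_rodgers_rowland`` — ionization-class-specific partitioning into
  tissue water, neutral lipid and phospholipid, with acidic-phospholipid
  binding for strong bases and extracellular-protein binding for acids,
  neutrals and weak bases.
* ``kp_pksim_standard`` — membrane-affinity weighting of tissue water,
  lipid and protein content.
* ``kp_schmitt`` — phospholipid-membrane partitioning with an explicit
  ionized-species contribution.

All methods return total-tissue to total-plasma ratios (Kp) and are
deterministic in their inputs. pH conventions: plasma 7.4, intracellular
water 7.0, erythrocyte interior 7.22.
"""
from __future__ import annotations

from dataclasses import dataclass

from ..datafiles import tissue_composition

PH_PLASMA = 7.4
PH_IW = 7.0
PH_RBC = 7.22
F_WATER_PLASMA = 0.945

#: Physiology compartment -> composition-table tissue.
COMPARTMENT_TISSUE = {
    "bone": "bone", "brain": "brain", "fat": "adipose", "gonads": "gonads",
    "intestines": "gut", "stomach": "stomach", "heart": "heart",
    "kidney": "kidney", "liver": "liver", "lung": "lung", "muscle": "muscle",
    "pancreas": "pancreas", "skin": "skin", "spleen": "spleen",
}


class UnsupportedIonizationError(ValueError):
    """Raised when a method has no equation for the drug's pKa combination."""


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions and binding-protein ratios of one tissue."""

    f_ew: float        # extracellular water
    f_iw: float        # intracellular water
    f_nl: float        # neutral lipid
    f_np: float        # neutral phospholipid
    ap_mg_g: float     # acidic phospholipid content
    ratio_alb: float   # tissue:plasma albumin ratio
    ratio_lip: float   # tissue:plasma lipoprotein ratio
    f_protein: float   # total protein fraction

    def __post_init__(self):
        fracs = (self.f_ew, self.f_iw, self.f_nl, self.f_np, self.f_protein)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("volume fractions must lie in [0, 1]")
        if self.f_ew + self.f_iw + self.f_nl + self.f_np > 1.0 + 1e-9:
            raise ValueError("component fractions exceed unity")

    @property
    def f_water(self) -> float:
        return self.f_ew + self.f_iw

    @classmethod
    def for_tissue(cls, name: str) -> "TissueComposition":
        row = tissue_composition().loc[name]
        return cls(f_ew=row.f_ew, f_iw=row.f_iw, f_nl=row.f_nl,
                   f_np=row.f_np, ap_mg_g=row.ap_mg_g, ratio_alb=row.ratio_alb,
                   ratio_lip=row.ratio_lip, f_protein=row.f_protein)

    @classmethod
    def for_compartment(cls, compartment: str) -> "TissueComposition":
        return cls.for_tissue(COMPARTMENT_TISSUE[compartment])


def _ionization_class(drug) -> tuple[str, float]:
    """Classify (class, pKa) for the single-pKa partition equations."""
    pkas = [(p.value, p.type) for p in drug.pka
            if 2.0 <= p.value <= 12.0]  # outside: effectively neutral
    if not pkas:
        return "neutral", 0.0
    if len(pkas) > 1:
        raise UnsupportedIonizationError(
            f"{drug.name}: multiple ionizable groups in the physiological "
            "range are not supported by this method")
    value, typ = pkas[0]
    if typ == "acid":
        return "acid", value
    return ("strong_base" if value >= 7.0 else "weak_base"), value


def _ion_x(cls: str, pka: float, ph: float) -> float:
    """Ionized:neutral ratio at a pH."""
    if cls == "neutral":
        return 0.0
    if cls == "acid":
        return 10.0 ** (ph - pka)
    return 10.0 ** (pka - ph)


def _olive_oil_partition(logp: float) -> float:
    # Vegetable-oil:water partition used for storage lipid in adipose.
    return 10.0 ** (1.115 * logp - 1.35)


def _lipid_term(drug, tissue_name: str, f_nl: float, f_np: float) -> float:
    p = 10.0 ** drug.logP
    p_nl = _olive_oil_partition(drug.logP) if tissue_name == "adipose" else p
    return p_nl * f_nl + (0.3 * p + 0.7) * f_np


def kp_rodgers_rowland(drug, tissue: TissueComposition, fu_p: float,
                       tissue_name: str = "", kpu_bc: float | None = None
                       ) -> float:
    """Composition-based Kp with ionization-class-specific binding terms.

    For strong monoprotic bases the ionized species binds acidic
    phospholipids with an association constant back-calculated from the
    erythrocyte partition (``kpu_bc``, computed from the drug's blood-cell
    fractions when not given). Acids, neutrals and weak bases instead carry
    an extracellular-protein term back-calculated from fu_p.
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValueError("fu_p must lie in (0, 1]")
    cls, pka = _ionization_class(drug)
    x_p = _ion_x(cls, pka, PH_PLASMA)
    x_iw = _ion_x(cls, pka, PH_IW)
    lip_t = _lipid_term(drug, tissue_name, tissue.f_nl, tissue.f_np)
    plasma = TissueComposition.for_tissue("plasma")
    lip_p = _lipid_term(drug, "plasma", plasma.f_nl, plasma.f_np)

    if cls == "strong_base":
        rbc = TissueComposition.for_tissue("erythrocyte")
        if kpu_bc is None:
            kpu_bc = erythrocyte_partition(drug, fu_p) / fu_p
        x_bc = _ion_x(cls, pka, PH_RBC)
        lip_bc = _lipid_term(drug, "erythrocyte", rbc.f_nl, rbc.f_np)
        ka_ap = (kpu_bc - (1.0 + x_bc) / (1.0 + x_p) * rbc.f_iw
                 - lip_bc / (1.0 + x_p))
        ka_ap = max(0.0, ka_ap * (1.0 + x_p) / (rbc.ap_mg_g * x_bc))
        kpu = (tissue.f_ew
               + (1.0 + x_iw) / (1.0 + x_p) * tissue.f_iw
               + lip_t / (1.0 + x_p)
               + ka_ap * tissue.ap_mg_g * x_iw / (1.0 + x_p))
        return kpu * fu_p

    # Acids, neutrals, weak bases: residual plasma binding assigned to
    # extracellular protein (albumin; lipoproteins for neutrals).
    ka_pr = max(0.0, 1.0 / fu_p - F_WATER_PLASMA - lip_p / (1.0 + x_p))
    ratio = tissue.ratio_lip if cls == "neutral" else tissue.ratio_alb
    kpu = (tissue.f_ew
           + (1.0 + x_iw) / (1.0 + x_p) * tissue.f_iw
           + lip_t / (1.0 + x_p)
           + ka_pr * ratio)
    return kpu * fu_p


def kp_pksim_standard(drug, tissue: TissueComposition, fu_p: float,
                      tissue_name: str = "") -> float:
    """Membrane-affinity weighted partition into water, lipid and protein."""
    if not 0.0 < fu_p <= 1.0:
        raise ValueError("fu_p must lie in (0, 1]")
    k_mem = 10.0 ** drug.logP
    k_nl = (_olive_oil_partition(drug.logP) if tissue_name == "adipose"
            else k_mem)
    k_prot = 0.163 + 0.0221 * k_mem
    kpu = (tissue.f_water + k_nl * tissue.f_nl + k_mem * tissue.f_np
           + k_prot * tissue.f_protein) / F_WATER_PLASMA
    return kpu * fu_p


def kp_schmitt(drug, tissue: TissueComposition, fu_p: float,
               tissue_name: str = "") -> float:
    """Charge-aware phospholipid-membrane partition.

    The neutral species partitions into neutral lipid and phospholipid as
    in the other methods; the ionized species partitions into phospholipid
    membranes with an electrostatically attenuated affinity (factor
    1/(1+X) on lipids replaced by a fixed ion:neutral membrane-affinity
    ratio of 0.05 for same-charge repulsion, 20-fold less than neutral).
    """
    if not 0.0 < fu_p <= 1.0:
        raise ValueError("fu_p must lie in (0, 1]")
    cls, pka = _ionization_class(drug)
    x_p = _ion_x(cls, pka, PH_PLASMA)
    x_iw = _ion_x(cls, pka, PH_IW)
    p = 10.0 ** drug.logP
    p_nl = _olive_oil_partition(drug.logP) if tissue_name == "adipose" else p
    k_ion = 0.05 * (0.3 * p + 0.7)
    fn_p = 1.0 / (1.0 + x_p)            # neutral fraction in plasma
    fn_iw = 1.0 / (1.0 + x_iw)
    memb = tissue.f_np + tissue.ap_mg_g / 1000.0
    kpu = (tissue.f_ew
           + ((1.0 + x_iw) / (1.0 + x_p)) * tissue.f_iw
           + fn_p * (p_nl * tissue.f_nl)
           + memb * (fn_p * (0.3 * p + 0.7)
                     + (1.0 - fn_iw) * (1.0 + x_iw) / (1.0 + x_p) * k_ion)
           ) / F_WATER_PLASMA
    return kpu * fu_p


_METHODS = {
    "rodgers_rowland": kp_rodgers_rowland,
    "pksim": kp_pksim_standard,
    "schmitt": kp_schmitt,
}


def kp_for_method(method: str, drug, compartment: str, fu_p: float) -> float:
    if method not in _METHODS:
        raise KeyError(f"unknown distribution method {method!r}")
    name = COMPARTMENT_TISSUE[compartment]
    tissue = TissueComposition.for_tissue(name)
    return _METHODS[method](drug, tissue, fu_p, tissue_name=name)


def erythrocyte_partition(drug, fu_p: float) -> float:
    """Blood-cell:plasma partition K_ery from erythrocyte composition.

    Uses the drug's optimized blood-cell protein and lipid volume fractions
    with the membrane-affinity weights; falls back to the water fraction
    when both are zero.
    """
    rbc = TissueComposition.for_tissue("erythrocyte")
    k_mem = 10.0 ** drug.logP
    k_prot = 0.163 + 0.0221 * k_mem
    f_prot = drug.erythrocytes.f_proteins
    f_lip = drug.erythrocytes.f_lipid
    kpu = (rbc.f_iw + k_mem * f_lip + k_prot * f_prot) / F_WATER_PLASMA
    return kpu * fu_p


def blood_plasma_ratio(drug, hematocrit: float,
                       k_ery: float | None = None) -> float:
    """Whole-blood to plasma concentration ratio.

    B:P = (1 - Hct) + Hct * K_ery; K_ery derives from the erythrocyte
    composition when not supplied.
    """
    if not 0.0 <= hematocrit < 1.0:
        raise ValueError("hematocrit must lie in [0, 1)")
    if k_ery is None:
        k_ery = erythrocyte_partition(drug, drug.fu_p)
    return (1.0 - hematocrit) + hematocrit * k_ery


def scaled_fu(fu_ref: float, protein_ratio: float) -> float:
    """Unbound plasma fraction after a binding-protein concentration change.

    fu' = 1 / (1 + (1 - fu)/fu * P'/P) — binding proportional to the
    protein concentration ratio P'/P.
    """
    if not 0.0 < fu_ref <= 1.0:
        raise ValueError("fu_ref must lie in (0, 1]")
    if protein_ratio < 0:
        raise ValueError("protein ratio must be non-negative")
    return 1.0 / (1.0 + (1.0 - fu_ref) / fu_ref * protein_ratio)
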