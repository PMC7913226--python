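"""The 12-segment gastrointestinal absorption model.

Segments run stomach -> duodenum -> jejunum (2) -> ileum (2) -> caecum ->
colon (4) -> rectum, each defined by luminal fluid volume, transit time, pH
and an effective surface-area enhancement factor (SAEF). The lumen of each
segment carries the dissolved drug (plus a solid pool for particulate
formulations); absorption flux is permeability x SAEF-scaled cylindrical
surface area x luminal concentration, delivered to the portal vein.

Geometry is scaled from adult defaults by height only, so malnutrition
scaling of the body leaves the absorption apparatus untouched (the scaling
parameters deliberately carry no GI functionality).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

from ..datafiles import gi_defaults

ADULT_HEIGHT_CM = 176.0
#: Gastric residence scales linearly with meal caloric content, anchored so
#: a 300-kcal drink doubles the fasted residence time.
KCAL_DOUBLING = 300.0


@dataclass(frozen=True)
class GISegment:
    index: int
    name: str
    fluid_volume_ml: float
    transit_h: float
    ph: float
    saef: float
    length_cm: float
    radius_cm: float
    mucosal_blood_flow_L_h: float = 0.0

    def __post_init__(self):
        if self.transit_h <= 0:
            raise ValueError("transit time must be positive")
        if self.saef < 0:
            raise ValueError("SAEF must be non-negative")

    @property
    def surface_area_cm2(self) -> float:
        """SAEF-scaled cylindrical surface area."""
        import math
        return 2.0 * math.pi * self.radius_cm * self.length_cm * self.saef


def build_gi_tract(individual, prandial: str = "fasted", meal=None,
                   saef_overrides: dict[str, float] | None = None
                   ) -> list[GISegment]:
    """Instantiate the 12 segments for one individual.

    ``meal`` (volume_ml, kcal) applies in the fed state: the meal volume is
    added to the gastric fluid and gastric residence is prolonged in
    proportion to caloric content; intestinal pH switches to the fed column
    for the stomach and duodenum.
    """
    df = gi_defaults()
    s = individual.HT / ADULT_HEIGHT_CM
    fed = prandial.startswith("fed")
    q_int = individual.organ_flow("intestines")
    total_len = float(df.length_cm.sum())

    segments = []
    for _, row in df.iterrows():
        ph = float(row.ph_fed if fed else row.ph_fasted)
        vol = float(row.fluid_volume_mL) * s ** 3
        transit = float(row.transit_h)
        if row.segment == "stomach" and fed and meal is not None:
            vol += meal.volume_ml
            transit *= 1.0 + meal.kcal / KCAL_DOUBLING
        saef = float(row.saef)
        if saef_overrides and row.segment in saef_overrides:
            saef = float(saef_overrides[row.segment])
        segments.append(GISegment(
            index=int(row["index"]), name=str(row.segment),
            fluid_volume_ml=vol, transit_h=transit, ph=ph, saef=saef,
            length_cm=float(row.length_cm) * s,
            radius_cm=float(row.radius_cm) * s,
            mucosal_blood_flow_L_h=q_int * float(row.length_cm) / total_len,
        ))
    return segments
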