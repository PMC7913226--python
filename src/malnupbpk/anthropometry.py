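"""Derived biometrics, growth z-scores and malnutrition classification."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datafiles import growth_reference_tables


def bsa_du_bois(bwt: float, ht: float) -> float:
    """Du Bois body surface area (m^2): 0.007184 * BWT^0.425 * HT^0.725."""
    if bwt < 0:
        raise ValueError("body weight must be non-negative")
    if ht <= 0:
        raise ValueError("height must be positive")
    return 0.007184 * bwt ** 0.425 * ht ** 0.725


def bmi(bwt: float, ht: float) -> float:
    """Body mass index, kg/m^2."""
    return bwt / (ht / 100.0) ** 2


def z_score(observed: float, median: float, sd: float) -> float:
    """(observed - reference median) / reference SD."""
    if sd <= 0:
        raise ValueError("reference SD must be positive")
    return (observed - median) / sd


def classify_sam(whz: float) -> str:
    """Severe acute malnutrition classification from weight-for-height z.

    Severe iff WHZ < -3 (strict); the mid-upper-arm-circumference branch of
    the clinical criterion has no anatomical surrogate in the model.
    """
    if not np.isfinite(whz):
        raise ValueError("WHZ must be finite")
    return "severe" if whz < -3.0 else "not-severe"


@dataclass(frozen=True)
class GrowthReference:
    """Median/SD growth tables on height and age grids, by sex.

    The z formula uses only the median and SD, so no skewness machinery is
    carried; medians are interpolated linearly and clamped at the grid edges.
    """

    weight_for_height: pd.DataFrame   # sex, height_cm, median_kg, sd_kg
    weight_for_age: pd.DataFrame      # sex, age_months, median_kg, sd_kg

    @classmethod
    def load(cls) -> "GrowthReference":
        wfh, wfa = growth_reference_tables()
        for tab, grid in ((wfh, "height_cm"), (wfa, "age_months")):
            if (tab.median_kg <= 0).any() or (tab.sd_kg <= 0).any():
                raise ValueError("growth-reference medians/SDs must be positive")
            for _, sub in tab.groupby("sex"):
                if not sub[grid].is_monotonic_increasing:
                    raise ValueError("growth-reference grid must be increasing")
        return cls(weight_for_height=wfh, weight_for_age=wfa)

    def _lookup(self, table: pd.DataFrame, grid_col: str, sex: str, x: float):
        sub = table[table.sex == sex]
        if sub.empty:
            raise ValueError(f"unknown sex {sex!r}")
        g = sub[grid_col].to_numpy(float)
        med = float(np.interp(x, g, sub.median_kg.to_numpy(float)))
        sd = float(np.interp(x, g, sub.sd_kg.to_numpy(float)))
        return med, sd

    def whz(self, sex: str, height_cm: float, weight_kg: float) -> float:
        """Weight-for-height z-score."""
        med, sd = self._lookup(self.weight_for_height, "height_cm", sex,
                               height_cm)
        return z_score(weight_kg, med, sd)

    def waz(self, sex: str, age_months: float, weight_kg: float) -> float:
        """Weight-for-age z-score."""
        med, sd = self._lookup(self.weight_for_age, "age_months", sex,
                               age_months)
        return z_score(weight_kg, med, sd)


def population_z_scores(population, reference: GrowthReference | None = None
                        ) -> pd.DataFrame:
    """Per-individual WHZ/WAZ report for a virtual population."""
    ref = reference or GrowthReference.load()
    rows = []
    for i, p in enumerate(population):
        rows.append({
            "id": i, "age": p.age, "sex": p.sex, "BWT": p.BWT, "HT": p.HT,
            "whz": ref.whz(p.sex, p.HT, p.BWT),
            "waz": ref.waz(p.sex, p.age * 12.0, p.BWT),
        })
    return pd.DataFrame(rows)
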