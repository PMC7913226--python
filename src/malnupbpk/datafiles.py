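"""Loaders for the text fixtures shipped with the package."""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml


def _path(name: str):
    return resources.files("malnupbpk.data") / name


@lru_cache(maxsize=None)
def reference_physiology() -> pd.DataFrame:
    """Age/sex grid of organ masses, specific perfusion and scalar physiology."""
    return pd.read_csv(_path("reference_physiology.tsv"), sep="\t")


@lru_cache(maxsize=None)
def reference_measurements() -> pd.DataFrame:
    """Reference-study anthropometry, hematology and organ measurements."""
    return pd.read_csv(_path("reference_measurements.tsv"), sep="\t",
                       index_col="measurement")


@lru_cache(maxsize=None)
def canonical_psps() -> pd.DataFrame:
    """Canonical physiological scaling parameters per malnutrition level."""
    return pd.read_csv(_path("canonical_psps.tsv"), sep="\t",
                       index_col="component")


@lru_cache(maxsize=None)
def gi_defaults() -> pd.DataFrame:
    return pd.read_csv(_path("gi_defaults.tsv"), sep="\t")


@lru_cache(maxsize=None)
def tissue_composition() -> pd.DataFrame:
    return pd.read_csv(_path("tissue_composition.tsv"), sep="\t",
                       index_col="tissue")


@lru_cache(maxsize=None)
def growth_reference_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    wfh = pd.read_csv(_path("growth_weight_for_height.tsv"), sep="\t")
    wfa = pd.read_csv(_path("growth_weight_for_age.tsv"), sep="\t")
    return wfh, wfa


@lru_cache(maxsize=None)
def studies_registry() -> dict:
    with _path("studies.yaml").open() as fh:
        return yaml.safe_load(fh)


def drug_config_path(name: str):
    return _path(f"drugs/{name}.yaml")
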