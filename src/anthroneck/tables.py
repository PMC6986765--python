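"""Packaged reference tables: strength targets, muscle-volume distribution,
original maximum isometric forces, and ANSUR II percentile anthropometry.

All tables ship with the package as plain CSV and are loaded with pandas.
Strength values are N (forces) and N·m (axial-rotation moment); volume
fractions are percent; anthropometry is m / kg / cm.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

MODES = ("extension", "flexion", "lateral_bending", "axial_rotation")

#: column name used for each loading mode in the targets table
_MODE_COLUMNS = {
    "extension": "extension_N",
    "flexion": "flexion_N",
    "lateral_bending": "lateral_bending_N",
    "axial_rotation": "axial_rotation_Nm",
}

#: the sixteen muscle groups of the published volume-distribution table
VOLUME_GROUPS = (
    "sternocleidomastoid",
    "scalenus",
    "longus_capitis",
    "longus_colli",
    "trapezius",
    "splenius",
    "semispinalis_capitis",
    "semispinalis_cervicis_multifidus",
    "longissimus_capitis",
    "longissimus_cervicis",
    "levator_scapulae",
    "rectus_capitis_major",
    "rectus_capitis_minor",
    "obliquus_capitis_superior",
    "obliquus_capitis_inferior",
    "infrahyoid",
)

#: the added deep-flexor group, bounded separately and outside the volume table
RECTCAP_GROUP = "rectus_capitis_anterior_lateralis"

ALL_GROUPS = VOLUME_GROUPS + (RECTCAP_GROUP,)


def _read(name: str) -> pd.DataFrame:
    with resources.files("anthroneck.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def strength_table() -> pd.DataFrame:
    """The published strength table (original / target / optimized rows)."""
    return _read("table1_targets.csv").set_index("row")


def strength_targets(gender: str) -> dict[str, float]:
    """Literature target strengths per mode for one gender."""
    row = strength_table().loc[f"{_check_gender(gender)}_target"]
    return {mode: float(row[col]) for mode, col in _MODE_COLUMNS.items()}


def derive_female_targets(
    male: dict[str, float] | None = None, ratio: float = 0.65
) -> dict[str, float]:
    """Female targets as a fixed female/male strength ratio of the male targets.

    Forces are rounded to whole newtons and the axial moment to 0.1 N·m,
    matching the precision of the published table.
    """
    male = dict(strength_targets("male") if male is None else male)
    out = {}
    for mode, value in male.items():
        scaled = value * ratio
        out[mode] = round(scaled, 1) if mode == "axial_rotation" else round(scaled)
    return out


@lru_cache(maxsize=None)
def volume_fraction_table() -> pd.DataFrame:
    return _read("table2_volume_fractions.csv").set_index("group")


def volume_fraction_targets(gender: str) -> dict[str, float]:
    """Published group volume fractions (as fractions of 1) for one gender."""
    col = f"{_check_gender(gender)}_pct"
    tab = volume_fraction_table()
    return {g: float(tab.loc[g, col]) / 100.0 for g in VOLUME_GROUPS}


def average_volume_fractions(n_female: int = 3, n_male: int = 7) -> dict[str, float]:
    """Sample-size-weighted mean of the female and male fraction columns (%)."""
    tab = volume_fraction_table()
    n = n_female + n_male
    return {
        g: (n_female * float(tab.loc[g, "female_pct"]) + n_male * float(tab.loc[g, "male_pct"])) / n
        for g in VOLUME_GROUPS
    }


def total_muscle_volume(gender: str) -> float:
    """Total neck muscle volume in cm^3 for one gender."""
    col = f"{_check_gender(gender)}_pct"
    return float(volume_fraction_table().loc["total_volume_cm3", col])


@lru_cache(maxsize=None)
def fmax_table() -> pd.DataFrame:
    return _read("table4_fmax.csv").set_index("name")


def original_fmax() -> dict[str, float]:
    """Original-model maximum isometric forces (N) per fascicle base name.

    The two added rectus capitis fascicles have no original value and are
    omitted; their default initial force is 32.5 N (see the model builder).
    """
    tab = fmax_table()
    col = tab["original_N"]
    return {name: float(v) for name, v in col.items() if pd.notna(v)}


@lru_cache(maxsize=None)
def percentile_table(gender: str) -> pd.DataFrame:
    name = {"male": "table5_male_percentiles.csv", "female": "table6_female_percentiles.csv"}
    return _read(name[_check_gender(gender)]).set_index("percentile")


PERCENTILES = (1, 5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 95, 99)


def _check_gender(gender: str) -> str:
    if gender not in ("male", "female"):
        raise ValueError(f"unknown gender {gender!r}; expected 'male' or 'female'")
    return gender
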