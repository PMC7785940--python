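"""Loaders for the bundled study tables (design, ion/response data, media)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stoichiometry import ION_NAMES, MediumRecipe

RESPONSES = ("SN", "SL", "LA", "SQ", "BC", "H")

#: Printed decimals per ion column in the treatment table, used when
#: comparing recomputed profiles against the printed values.
ION_PRINT_DECIMALS = {
    "NH4+": 2, "NO3-": 2, "K+": 2, "Ca2+": 2, "Mg2+": 2, "PO43-": 2,
    "SO42-": 2, "Cl-": 2, "Fe2+": 2, "BO3-": 2, "Mn2+": 2, "Zn2+": 3,
    "Cu2+": 5, "MoO22-": 4, "Na+": 2, "Co2+": 5, "I-": 4, "EDTA-": 2,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("phytomedia.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_design() -> pd.DataFrame:
    """36-run five-factor design (xMS levels) with replicate/control flags."""
    df = _read("design_table2.csv")
    df["replicate_of"] = df["replicate_of"].astype("Int64")
    return df


def load_treatments() -> pd.DataFrame:
    """Per-treatment 18-ion profiles (mM) and response mean +/- SD.

    34 rows: the 33 design treatments plus the MS control, as printed.
    """
    return _read("treatments_table3.csv")


def load_ion_matrix(printed: bool = True) -> pd.DataFrame:
    """34 x 18 model-input ion matrix.

    ``printed=True`` returns the rounded published values; ``printed=False``
    recomputes full-precision profiles from the design and the MS recipe.
    """
    if printed:
        df = load_treatments()
        return df[list(ION_NAMES)].copy()
    from .stoichiometry import design_to_ion_table

    design = load_design().iloc[:34].copy()  # 33 treatments + first MS control
    return design_to_ion_table(design[list(FACTOR_COLS)], ms_recipe())


FACTOR_COLS = ("nh4no3", "kno3", "mesos", "micros", "iron")


def load_response_means() -> pd.DataFrame:
    """34 x 6 per-treatment response means (modeling targets)."""
    df = load_treatments()
    out = df[[f"{r}_mean" for r in RESPONSES]].copy()
    out.columns = list(RESPONSES)
    return out


def load_standard_media() -> pd.DataFrame:
    """Salt recipes (mg/L) of the optimized R medium and MS/B5/St/Ha."""
    return _read("standard_media_table8.csv").set_index("salt")


def standard_recipe(medium: str) -> MediumRecipe:
    """One standard medium as a :class:`MediumRecipe` (zero salts dropped)."""
    table = load_standard_media()
    if medium not in table.columns:
        raise KeyError(f"unknown medium {medium!r}; have {list(table.columns)}")
    col = table[medium]
    return MediumRecipe({s: float(c) for s, c in col.items() if c > 0},
                        label=medium)


def ms_recipe() -> MediumRecipe:
    """The Murashige-Skoog basal salt recipe (the design's 1x reference)."""
    return standard_recipe("MS")


def load_validation_summaries() -> pd.DataFrame:
    """Validation experiment outcomes: response x medium mean/sd/n (n = 45)."""
    return _read("validation_table8.csv")
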