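"""Salt <-> ion stoichiometry for tissue-culture media.

Culture media are mixed from salts (mg/L) but plants respond to ions.
Because several salts contribute the same ion ("ion confounding"), every
medium is decomposed into a fixed 18-ion millimolar profile: each salt at
``c`` mg/L contributes ``count * c / molar_mass`` mM of each ion it yields
on dissolution.  No speciation or chelation equilibria are modeled: Fe2+
and EDTA- from the iron/chelate pair are counted independently, and the
molybdate anion of Na2MoO4 is booked under the "MoO22-" key.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

#: Canonical ion names, in the conventional macro -> micro ordering.
ION_NAMES = (
    "NH4+", "NO3-", "K+", "Ca2+", "Mg2+", "PO43-", "SO42-", "Cl-", "Fe2+",
    "BO3-", "Mn2+", "Zn2+", "Cu2+", "MoO22-", "Na+", "Co2+", "I-", "EDTA-",
)

#: The 14 salts of the Murashige-Skoog basal medium.
MS_SALTS = (
    "NH4NO3", "KNO3", "CaCl2.2H2O", "MgSO4.7H2O", "KH2PO4", "MnSO4.4H2O",
    "ZnSO4.7H2O", "H3BO3", "KI", "CuSO4.5H2O", "Na2MoO4.2H2O", "CoCl2.6H2O",
    "FeSO4.7H2O", "Na2EDTA.2H2O",
)

#: Factor name -> salts scaled together (the design's salt groupings).
FACTOR_GROUPS = {
    "nh4no3": ("NH4NO3",),
    "kno3": ("KNO3",),
    "mesos": ("CaCl2.2H2O", "MgSO4.7H2O", "KH2PO4"),
    "micros": ("MnSO4.4H2O", "ZnSO4.7H2O", "H3BO3", "KI", "CuSO4.5H2O",
               "Na2MoO4.2H2O", "CoCl2.6H2O"),
    "iron": ("FeSO4.7H2O", "Na2EDTA.2H2O"),
}

FACTOR_NAMES = tuple(FACTOR_GROUPS)


class UnknownSaltError(KeyError):
    """A salt name that is not in the registry."""


@dataclass(frozen=True)
class SaltSpec:
    """One registry entry: a salt and the ions it releases.

    ``ion_yield`` maps canonical ion names to integer stoichiometric
    counts per formula unit (e.g. CaCl2.2H2O -> {Ca2+: 1, Cl-: 2}).
    """

    name: str
    formula: str
    molar_mass: float
    ion_yield: dict[str, int]

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar mass must be positive")
        for ion, count in self.ion_yield.items():
            if ion not in ION_NAMES:
                raise ValueError(f"{self.name}: unknown ion {ion!r}")
            if count < 1:
                raise ValueError(f"{self.name}: ion count must be >= 1")


def _load_registry() -> dict[str, SaltSpec]:
    raw = json.loads(
        resources.files("phytomedia.data").joinpath("salts.json").read_text()
    )
    return {
        name: SaltSpec(name=name, formula=d["formula"],
                       molar_mass=d["molar_mass"], ion_yield=d["ion_yield"])
        for name, d in raw.items()
    }


SALT_REGISTRY: dict[str, SaltSpec] = _load_registry()


def get_salt(name: str) -> SaltSpec:
    try:
        return SALT_REGISTRY[name]
    except KeyError:
        raise UnknownSaltError(name) from None


@dataclass
class MediumRecipe:
    """A medium as salt concentrations in mg/L.

    ``passthrough`` carries ingredients (vitamins, PGRs) that are recorded
    but never computed on.
    """

    concentrations: dict[str, float]
    label: str = ""
    passthrough: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for salt, conc in self.concentrations.items():
            get_salt(salt)
            if conc < 0:
                raise ValueError(f"{salt}: negative concentration {conc}")

    def scaled(self, alpha: float) -> "MediumRecipe":
        return MediumRecipe(
            {s: alpha * c for s, c in self.concentrations.items()},
            label=f"{alpha}x {self.label}".strip(),
        )

    def __add__(self, other: "MediumRecipe") -> "MediumRecipe":
        out = dict(self.concentrations)
        for s, c in other.concentrations.items():
            out[s] = out.get(s, 0.0) + c
        return MediumRecipe(out, label=f"{self.label}+{other.label}")


@dataclass
class IonProfile:
    """Millimolar concentrations over the fixed 18-ion set."""

    mM: dict[str, float]

    def __post_init__(self):
        full = {ion: 0.0 for ion in ION_NAMES}
        for ion, v in self.mM.items():
            if ion not in full:
                raise ValueError(f"unknown ion {ion!r}")
            if v < 0:
                raise ValueError(f"{ion}: negative concentration {v}")
            full[ion] = float(v)
        self.mM = full

    def as_series(self) -> pd.Series:
        return pd.Series(self.mM, index=list(ION_NAMES), dtype=float)

    def __getitem__(self, ion: str) -> float:
        return self.mM[ion]


@dataclass(frozen=True)
class FactorLevels:
    """xMS multipliers for the five salt-group factors (1.0 = standard MS)."""

    nh4no3: float = 1.0
    kno3: float = 1.0
    mesos: float = 1.0
    micros: float = 1.0
    iron: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FACTOR_NAMES}


def salt_to_millimolar(salt: SaltSpec | str, conc_mg_per_l: float) -> dict[str, float]:
    """Ion contributions (mM) of one salt at ``conc_mg_per_l``.

    mM of the parent salt is ``conc / molar_mass`` (mg/L over g/mol); each
    yielded ion receives its stoichiometric multiple of that value.
    """
    if isinstance(salt, str):
        salt = get_salt(salt)
    if conc_mg_per_l < 0:
        raise ValueError("concentration must be >= 0")
    base = conc_mg_per_l / salt.molar_mass
    return {ion: count * base for ion, count in salt.ion_yield.items()}


def recipe_to_ion_profile(recipe: MediumRecipe) -> IonProfile:
    """Full-precision 18-ion decomposition of a salt recipe."""
    total = {ion: 0.0 for ion in ION_NAMES}
    for salt, conc in recipe.concentrations.items():
        for ion, mm in salt_to_millimolar(salt, conc).items():
            total[ion] += mm
    return IonProfile(total)


def factors_to_recipe(levels: FactorLevels, base: MediumRecipe,
                      grouping: dict[str, tuple[str, ...]] | None = None) -> MediumRecipe:
    """Scale a base recipe's salt groups by xMS factor levels.

    Salts outside every group are carried through unchanged.  Levels
    outside the design's factor bounds only warn: exploratory use outside
    the sampled region is allowed but flagged.
    """
    grouping = grouping if grouping is not None else FACTOR_GROUPS
    from .doe import load_factor_specs  # local import to avoid a cycle

    bounds = {f.name: (f.low, f.high) for f in load_factor_specs()}
    scale = {}
    for factor, level in levels.as_dict().items():
        lo, hi = bounds.get(factor, (-np.inf, np.inf))
        if not lo <= level <= hi:
            warnings.warn(
                f"factor {factor}={level} outside design range [{lo}, {hi}]",
                stacklevel=2,
            )
        for salt in grouping[factor]:
            scale[salt] = level
    out = {
        salt: conc * scale.get(salt, 1.0)
        for salt, conc in base.concentrations.items()
    }
    return MediumRecipe(out, label=base.label)


def design_to_ion_table(design: pd.DataFrame, base: MediumRecipe) -> pd.DataFrame:
    """Row-wise ion decomposition of a design (xMS levels per factor).

    ``design`` needs one column per factor name; extra columns are ignored.
    Returns a run x 18-ion DataFrame in mM, aligned with the design index.
    """
    rows = []
    for _, row in design.iterrows():
        levels = FactorLevels(**{f: float(row[f]) for f in FACTOR_NAMES})
        profile = recipe_to_ion_profile(factors_to_recipe(levels, base))
        rows.append(profile.as_series())
    return pd.DataFrame(rows, index=design.index)


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (what the printed tables use), elementwise."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
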