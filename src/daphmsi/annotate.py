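"""MS1 lipid annotation: monoisotopic masses, adduct m/z, ppm matching.

Annotation here is putative, MS1-only: a feature m/z is matched against
the theoretical m/z of every (library lipid, positive adduct)
combination within a ppm tolerance, and hits are ranked by absolute ppm
error.  No MS/MS, isotope-pattern or mobility evidence is used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd

# Most-abundant-isotope masses (AME2020), Da.
MONOISOTOPIC_MASS: Dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
    "Na": 22.98976928,
    "K": 38.96370649,
}

ELECTRON_MASS = 0.00054858

# Cation masses for the four common positive-mode DESI adducts,
# *with* electron-mass correction (a cation is one electron short).
ADDUCT_MASS: Dict[str, float] = {
    "[M+H]+": MONOISOTOPIC_MASS["H"] - ELECTRON_MASS,          # 1.007276
    "[M+Na]+": MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS,        # 22.989221
    "[M+K]+": MONOISOTOPIC_MASS["K"] - ELECTRON_MASS,          # 38.963158
    "[M+NH4]+": MONOISOTOPIC_MASS["N"]
    + 4 * MONOISOTOPIC_MASS["H"]
    - ELECTRON_MASS,                                           # 18.033826
}

ADDUCTS = tuple(ADDUCT_MASS)

LIPID_CLASSES = ("PC", "TG", "PE", "SM", "other")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class LipidRecord:
    """A lipid library entry.

    ``name`` uses the standard shorthand, e.g. ``PC(32:0)`` — total acyl
    carbons : double bonds; ``formula`` is the neutral elemental
    composition; ``lipid_class`` is the headgroup class.
    """

    name: str
    formula: str
    lipid_class: str

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        parse_formula(self.formula)  # raises on malformed formula

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class Annotation:
    """A putative match between a feature and a library lipid."""

    feature_mz: float
    lipid: LipidRecord
    adduct: str
    ppm_error: float
    is_best: bool = False


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a molecular formula like ``C40H80NO8P`` into element counts."""
    if not formula:
        raise ValueError("empty molecular formula")
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if not match.group(0):
            continue
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def adduct_mz(neutral_mass: float, adduct: str, electron_correction: bool = True) -> float:
    """Theoretical m/z of ``[M+X]+`` for a neutral monoisotopic mass.

    ``electron_correction=False`` reproduces the convention used for the
    rhodamine 6G calibrant constant (neutral-atom masses summed with no
    electron subtraction).
    """
    if adduct not in ADDUCT_MASS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {list(ADDUCT_MASS)}")
    mass = neutral_mass + ADDUCT_MASS[adduct]
    if not electron_correction:
        mass += ELECTRON_MASS
    return mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error of ``observed`` relative to ``theoretical``, ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def annotate_features(
    feature_mz: Sequence[float],
    library: Sequence[LipidRecord],
    tol_ppm: float = 25.0,
) -> List[List[Annotation]]:
    """Match features to library lipids across all positive adducts.

    For each feature, every (lipid, adduct) whose theoretical m/z lies
    within ``tol_ppm`` is reported, sorted by \\|ppm error\\|; the best hit
    is flagged.  Features with no hit get an empty list.
    """
    if not library:
        raise ValueError("lipid library is empty")
    theoretical = [
        (lipid, adduct, adduct_mz(lipid.monoisotopic_mass, adduct))
        for lipid in library
        for adduct in ADDUCTS
    ]
    out: List[List[Annotation]] = []
    for mz in feature_mz:
        hits = []
        for lipid, adduct, theo in theoretical:
            err = ppm_error(mz, theo)
            if abs(err) <= tol_ppm:
                hits.append(Annotation(float(mz), lipid, adduct, err))
        hits.sort(key=lambda a: (abs(a.ppm_error), a.lipid.name, a.adduct))
        if hits:
            best = hits[0]
            hits[0] = Annotation(best.feature_mz, best.lipid, best.adduct,
                                 best.ppm_error, is_best=True)
        out.append(hits)
    return out


def annotations_table(annotations: Sequence[Sequence[Annotation]]) -> pd.DataFrame:
    """Flatten nested annotation lists into a tidy table."""
    rows = [
        {
            "feature_mz": a.feature_mz,
            "lipid": a.lipid.name,
            "formula": a.lipid.formula,
            "lipid_class": a.lipid.lipid_class,
            "adduct": a.adduct,
            "ppm_error": a.ppm_error,
            "is_best": a.is_best,
        }
        for hits in annotations
        for a in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["feature_mz", "lipid", "formula", "lipid_class",
                 "adduct", "ppm_error", "is_best"],
    )


def _glycerophosphocholine_formula(carbons: int, double_bonds: int) -> str:
    # PC(c:d) = glycerophosphocholine backbone + 2 acyls: C(c+8) H(2c+16-2d) N O8 P
    return f"C{carbons + 8}H{2 * carbons + 16 - 2 * double_bonds}NO8P"


def _triacylglyceride_formula(carbons: int, double_bonds: int) -> str:
    # TG(c:d) = glycerol + 3 acyls - 3 H2O: C(c+3) H(2c+2-2d) O6  (TG(48:0)=C51H98O6)
    return f"C{carbons + 3}H{2 * carbons + 2 - 2 * double_bonds}O6"


def pc_record(carbons: int, double_bonds: int) -> LipidRecord:
    return LipidRecord(
        name=f"PC({carbons}:{double_bonds})",
        formula=_glycerophosphocholine_formula(carbons, double_bonds),
        lipid_class="PC",
    )


def tg_record(carbons: int, double_bonds: int) -> LipidRecord:
    return LipidRecord(
        name=f"TG({carbons}:{double_bonds})",
        formula=_triacylglyceride_formula(carbons, double_bonds),
        lipid_class="TG",
    )


def default_library() -> List[LipidRecord]:
    """The built-in library: the four lipids reported in whole-daphnid
    ion images plus the synthetic phantom's filler panel."""
    pcs = [(32, 0), (34, 3), (30, 0), (32, 1), (34, 1), (34, 2),
           (36, 2), (36, 4), (38, 4), (38, 6)]
    tgs = [(48, 5), (50, 6), (44, 2), (46, 3), (48, 2), (50, 3),
           (52, 4), (52, 6), (54, 6), (54, 8)]
    return [pc_record(*cd) for cd in pcs] + [tg_record(*cd) for cd in tgs]


def read_library(path) -> List[LipidRecord]:
    """Read a lipid library from a tab-separated table (name, formula, class)."""
    df = pd.read_csv(path, sep="\t")
    return [
        LipidRecord(row["name"], row["formula"], row["lipid_class"])
        for _, row in df.iterrows()
    ]


def write_library(library: Sequence[LipidRecord], path) -> None:
    pd.DataFrame(
        [{"name": l.name, "formula": l.formula, "lipid_class": l.lipid_class}
         for l in library]
    ).to_csv(path, sep="\t", index=False)
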