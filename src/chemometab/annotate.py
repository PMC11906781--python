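"""Mass arithmetic for metabolite annotation.

Elemental formula -> monoisotopic mass -> adduct m/z, and the inverse
(neutral mass from an observed m/z), plus the ppm mass error that decides
whether an annotation falls inside the identification tolerance (< 5 ppm
for high-resolution Orbitrap data).

Monoisotopic atomic masses are the IUPAC/CODATA values for the most
abundant isotope.  The proton mass constant (1.007276467 Da) is used for
protonation/deprotonation; the electron mass is absorbed into it, a
difference far below the printed precision of annotation tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

PROTON_MASS = 1.007276467

#: monoisotopic masses, Da
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.007825032,
    "C": 12.0,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071174,
    "P": 30.973761998,
    "Na": 22.989769282,
    "K": 38.963706486,
    "Cl": 34.968852682,
    "F": 18.998403163,
}

WATER_MASS = 2 * ATOMIC_MASSES["H"] + ATOMIC_MASSES["O"]


class AnnotationError(ValueError):
    pass


ElementalComposition = dict[str, int]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalComposition:
    """Parse an element-count formula string into a composition dict.

    Underscore/space decorations (as they appear in typeset tables, e.g.
    ``C_2_H_7_NO_3_S``) are tolerated.  Unknown element symbols are
    rejected.  A zero count removes the element ("C0" -> {}).
    """
    cleaned = re.sub(r"[\s_]+", "", text)
    if not cleaned:
        raise AnnotationError("empty formula")
    pos = 0
    comp: ElementalComposition = {}
    for m in _FORMULA_TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise AnnotationError(f"malformed formula {text!r} near {cleaned[pos:]!r}")
        if not m.group(0):
            break
        el, cnt = m.group(1), int(m.group(2) or 1)
        if el not in ATOMIC_MASSES:
            raise AnnotationError(f"unknown element symbol {el!r} in {text!r}")
        if cnt:
            comp[el] = comp.get(el, 0) + cnt
        pos = m.end()
        if pos == len(cleaned):
            break
    if pos != len(cleaned):
        raise AnnotationError(f"malformed formula {text!r} near {cleaned[pos:]!r}")
    return comp


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Sum of count x atomic monoisotopic mass over the composition."""
    try:
        return sum(ATOMIC_MASSES[el] * n for el, n in comp.items())
    except KeyError as e:  # pragma: no cover - parse_formula already rejects
        raise AnnotationError(f"element {e.args[0]!r} missing from mass table") from e


@dataclass(frozen=True)
class AdductSpec:
    """Singly charged ESI adduct: m/z = m*M + proton_delta*m_p - water_loss*m_H2O."""

    name: str
    multiplicity: int  # m in {1, 2}
    proton_delta: int  # +1 protonated, -1 deprotonated
    water_loss: int  # 0 or 1


ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in [
        AdductSpec("[M+H]+", 1, +1, 0),
        AdductSpec("[M-H]-", 1, -1, 0),
        AdductSpec("[M+H-H2O]+", 1, +1, 1),
        AdductSpec("[M-H-H2O]-", 1, -1, 1),
        AdductSpec("[2M+H]+", 2, +1, 0),
        AdductSpec("[2M-H]-", 2, -1, 0),
    ]
}


def get_adduct(name_or_spec: str | AdductSpec) -> AdductSpec:
    if isinstance(name_or_spec, AdductSpec):
        return name_or_spec
    # normalize typographic variants: spaces, unicode minus, charge suffixes
    key = str(name_or_spec).replace(" ", "").replace("−", "-").replace("–", "-")
    key = re.sub(r"\]([+-])?1$", r"]\1", key)
    key = key.replace("]+1", "]+").replace("]-1", "]-")
    if key not in ADDUCTS:
        raise AnnotationError(f"unregistered adduct {name_or_spec!r}")
    return ADDUCTS[key]


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged adduct ion of a neutral of the given mass."""
    if neutral_mass <= 0:
        raise AnnotationError("neutral mass must be positive")
    a = get_adduct(adduct)
    return a.multiplicity * neutral_mass + a.proton_delta * PROTON_MASS - a.water_loss * WATER_MASS


def neutral_mass_from_mz(mz: float, adduct: str | AdductSpec) -> float:
    """Exact inverse of :func:`adduct_mz`."""
    a = get_adduct(adduct)
    return (mz - a.proton_delta * PROTON_MASS + a.water_loss * WATER_MASS) / a.multiplicity


def theoretical_mz(formula: str | ElementalComposition, adduct: str | AdductSpec) -> float:
    comp = parse_formula(formula) if isinstance(formula, str) else formula
    return adduct_mz(monoisotopic_mass(comp), adduct)


def ppm_error(observed_mz: float, formula: str | ElementalComposition, adduct: str | AdductSpec) -> float:
    """(observed - theoretical) / theoretical x 1e6, theoretical from the formula+adduct."""
    theo = theoretical_mz(formula, adduct)
    return (observed_mz - theo) / theo * 1e6


@dataclass
class AnnotationRecord:
    """One annotated LC-MS feature, mirroring published annotation tables."""

    name: str
    hmdb_id: str
    rt_min: float
    formula: str
    adduct: str
    observed_mz: float
    calc_neutral_mass: float = float("nan")
    theoretical_mass: float = float("nan")
    ppm: float = float("nan")
    pathway_ids: tuple[str, ...] = ()

    def compute(self) -> "AnnotationRecord":
        comp = parse_formula(self.formula)
        self.theoretical_mass = monoisotopic_mass(comp)
        self.calc_neutral_mass = neutral_mass_from_mz(self.observed_mz, self.adduct)
        self.ppm = ppm_error(self.observed_mz, comp, self.adduct)
        return self


def annotate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Recompute neutral mass, theoretical mass and ppm error for a record table.

    Expects columns ``formula``, ``adduct``, ``observed_mz``; returns a copy
    with ``theoretical_mass``, ``calc_neutral_mass``, ``theoretical_mz`` and
    ``ppm_error`` columns added.
    """
    out = records.copy()
    theo_mass, neutral, theo_mz, ppm = [], [], [], []
    for _, row in out.iterrows():
        comp = parse_formula(str(row["formula"]))
        m = monoisotopic_mass(comp)
        theo_mass.append(m)
        theo_mz.append(adduct_mz(m, row["adduct"]))
        neutral.append(neutral_mass_from_mz(float(row["observed_mz"]), row["adduct"]))
        ppm.append(ppm_error(float(row["observed_mz"]), comp, row["adduct"]))
    out["theoretical_mass"] = theo_mass
    out["theoretical_mz"] = theo_mz
    out["calc_neutral_mass"] = neutral
    out["ppm_error"] = ppm
    return out


def bundled_annotations() -> pd.DataFrame:
    """The bundled ten-metabolite annotation table (published printed values).

    Columns include the printed neutral mass (``calc_mw``), observed m/z,
    formula, adduct, printed ppm error, PCA loadings/VIP and the pathway
    memberships used by the over-representation example.
    """
    with resources.files("chemometab.data").joinpath("metabolite_annotations.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"pathway_ids": str})
    df["pathway_ids"] = df["pathway_ids"].fillna("").astype(str)
    return df
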