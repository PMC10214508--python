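"""Adduct-aware annotation of m/z features against a local compound table.

An observed feature m/z is matched by computing, for every compound in the
table and every adduct hypothesis, the theoretical m/z of the adduct ion
from the compound's monoisotopic mass, and keeping candidates whose relative
deviation is within a ppm tolerance (default +-20 ppm). Adduct mass deltas
include the electron mass, so e.g. [M+H]+ adds the mass of a proton
(1.007276 Da), not of a hydrogen atom.

The mass defect (distance of the m/z from the nearest integer) is also
reported: heavily fluorinated synthetic compounds such as PFAS have strongly
negative mass defects, so a large negative defect relative to the ion's mass
flags a candidate exogenous compound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ChemicalFormula",
    "AdductHypothesis",
    "CompoundRecord",
    "AnnotationMatch",
    "ADDUCTS",
    "POSITIVE_MODE_ADDUCTS",
    "NEGATIVE_MODE_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "annotate_mz",
    "mass_defect",
    "read_compound_table",
    "bundled_pd_marker_compounds",
]

#: Monoisotopic (most abundant isotope) atomic masses, Da (IUPAC/CODATA).
ISOTOPE_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.9984031627,
    "Na": 22.9897692809,
    "P": 30.9737616320,
    "S": 31.9720710015,
    "Cl": 34.9688526820,
    "Br": 78.9183371000,
    "I": 126.9044730000,
    "K": 38.9637064864,
}

ELECTRON_MASS = 0.000548579909  # Da

_SUBSCRIPT_DIGITS = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ChemicalFormula:
    """Element symbol -> count mapping (supported elements only)."""

    counts: tuple  # sorted (element, count) pairs

    def __post_init__(self):
        counts = dict(self.counts)
        unknown = set(counts) - set(ISOTOPE_MASS)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        if not counts or all(c == 0 for c in counts.values()):
            raise ValueError("formula must contain at least one atom")
        if any(c < 0 for c in counts.values()):
            raise ValueError("element counts must be non-negative")
        object.__setattr__(
            self, "counts", tuple(sorted((e, c) for e, c in counts.items() if c > 0))
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = self.as_dict()
        for e, c in other.counts:
            merged[e] = merged.get(e, 0) + c
        return ChemicalFormula(tuple(merged.items()))

    def __str__(self) -> str:
        return "".join(f"{e}{c if c != 1 else ''}" for e, c in self.counts)


def parse_formula(text: str) -> ChemicalFormula:
    """Parse ``"C21H8F28O8"`` (underscores / unicode subscripts tolerated)."""
    cleaned = text.translate(_SUBSCRIPT_DIGITS).replace("_", "").strip()
    if not cleaned:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.end() == pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in ISOTOPE_MASS:
            raise ValueError(f"unknown element {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ChemicalFormula(tuple(counts.items()))


def monoisotopic_mass(formula: ChemicalFormula) -> float:
    """Sum of count x most-abundant-isotope mass, in Da."""
    return sum(ISOTOPE_MASS[e] * c for e, c in formula.counts)


@dataclass(frozen=True)
class AdductHypothesis:
    name: str
    delta: float  # Da, electron-corrected
    charge: int  # +-1


_PROTON = ISOTOPE_MASS["H"] - ELECTRON_MASS
_WATER = 2 * ISOTOPE_MASS["H"] + ISOTOPE_MASS["O"]

ADDUCTS: dict[str, AdductHypothesis] = {
    "[M+H]+": AdductHypothesis("[M+H]+", _PROTON, +1),
    "[M+Na]+": AdductHypothesis("[M+Na]+", ISOTOPE_MASS["Na"] - ELECTRON_MASS, +1),
    "[M+H-H2O]+": AdductHypothesis("[M+H-H2O]+", _PROTON - _WATER, +1),
    "[M-H]-": AdductHypothesis("[M-H]-", -_PROTON, -1),
}

#: Default adduct sets: protonation, sodiation, and water loss in positive
#: ionization mode; deprotonation in negative mode.
POSITIVE_MODE_ADDUCTS = [ADDUCTS["[M+H]+"], ADDUCTS["[M+Na]+"], ADDUCTS["[M+H-H2O]+"]]
NEGATIVE_MODE_ADDUCTS = [ADDUCTS["[M-H]-"]]


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    formula: ChemicalFormula

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AnnotationMatch:
    feature_mz: float
    compound: CompoundRecord
    adduct: AdductHypothesis
    theoretical_mz: float
    ppm: float
    mass_defect: float
    exogenous_flag: bool


def adduct_mz(neutral_mass: float, adduct: AdductHypothesis) -> float:
    """Theoretical m/z of the adduct ion of a neutral of the given mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    mz = (neutral_mass + adduct.delta) / abs(adduct.charge)
    if mz <= 0:
        raise ValueError(f"adduct {adduct.name} yields non-positive m/z")
    return mz


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative deviation, parts per million."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def mass_defect(
    mz: float, threshold_per_100da: float = -0.001
) -> tuple[float, bool]:
    """Mass defect (m/z minus nearest integer) and an exogenous-compound flag.

    The flag fires when the defect is more negative than
    ``threshold_per_100da`` per 100 Da of the ion's m/z (default -0.001 Da
    per 100 Da): fluorine-rich synthetic compounds such as PFAS sit well
    below that line, while CHNO metabolites have positive defects. The
    threshold is a heuristic and is configurable.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    defect = mz - round(mz)
    return defect, defect < threshold_per_100da * (mz / 100.0)


def annotate_mz(
    observed_mz: float,
    db: list[CompoundRecord],
    adducts: list[AdductHypothesis] | None = None,
    tolerance_ppm: float = 20.0,
) -> list[AnnotationMatch]:
    """All (compound, adduct) candidates within tolerance, best |ppm| first.

    Ties in |ppm| are ordered by compound id; an empty list is a valid
    result. The default adduct set is the positive-ionization-mode set.
    """
    if not db:
        raise ValueError("compound database is empty")
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if adducts is None:
        adducts = POSITIVE_MODE_ADDUCTS
    defect, flag = mass_defect(observed_mz)
    matches = []
    for compound in db:
        mass = compound.monoisotopic_mass
        for adduct in adducts:
            theo = adduct_mz(mass, adduct)
            ppm = ppm_error(observed_mz, theo)
            if abs(ppm) <= tolerance_ppm:
                matches.append(
                    AnnotationMatch(
                        observed_mz, compound, adduct, theo, ppm, defect, flag
                    )
                )
    matches.sort(key=lambda m: (abs(m.ppm), m.compound.id))
    return matches


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a TSV compound table with columns ``id``, ``name``, ``formula``."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "name", "formula"} - set(frame.columns)
    if missing:
        raise ValueError(f"compound table missing columns {sorted(missing)}")
    return [
        CompoundRecord(row["id"], row["name"], parse_formula(row["formula"]))
        for _, row in frame.iterrows()
    ]


def bundled_pd_marker_compounds() -> list[CompoundRecord]:
    """The packaged table of reported Parkinson's-disease plasma markers."""
    with resources.as_file(
        resources.files("crankms.data").joinpath("pd_plasma_markers.tsv")
    ) as path:
        return read_compound_table(path)
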