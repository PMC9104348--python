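"""Monoisotopic masses, adduct m/z, ppm errors, and exact-mass matching.

Annotation here is exact-mass only: a feature's observed m/z is matched
against candidate (formula, adduct) pairs within a ppm tolerance and ranked
by absolute mass error. Matches made this way carry confidence level 3
(formula match only); levels 1-2 require MS/MS or standard evidence that
must be supplied externally, and unmatched observations are level 4
(unknown). Isotope-pattern scoring and fragment matching are out of scope.

Masses are most-abundant-isotope masses; (de)protonation uses the proton
mass (electron mass is neglected elsewhere, a < 0.002 Da effect below the
4-decimal m/z reporting precision).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import pandas as pd

# most-abundant-isotope masses, Da
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

PROTON_MASS = 1.00727646688  # Da

# singly charged adduct registry: name -> (mass delta in Da, polarity)
# deltas are neutral-gain masses +/- a proton, derived from the table above
_NH4 = MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"]
_ACETIC = 2 * MONOISOTOPIC_MASS["C"] + 4 * MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"]
_FORMIC = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"]
_ELECTRON = 0.00054857990907

ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (+PROTON_MASS, "+"),
    "[M-H]-": (-PROTON_MASS, "-"),
    # NH4+ attaches as a cation: NH4 minus one electron
    "[M+NH4]+": (_NH4 - _ELECTRON, "+"),
    "[M+CH3COOH-H]-": (_ACETIC - PROTON_MASS, "-"),
    "[M+H2CO2-H]-": (_FORMIC - PROTON_MASS, "-"),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class AnnotationError(ValueError):
    """Raised for malformed formulas or unknown adducts."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse compact elemental formula text like ``C6H13N3O3``.

    Repeated element symbols accumulate; counts must be positive.
    """
    if not formula or not formula.strip():
        raise AnnotationError("empty elemental formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise AnnotationError(f"unparseable formula text: {formula!r}")
        pos = m.end()
        element = m.group(1)
        if element not in MONOISOTOPIC_MASS:
            raise AnnotationError(f"unsupported element {element!r} in {formula!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + n
    if pos != len(formula.strip()):
        raise AnnotationError(f"unparseable formula text: {formula!r}")
    if not counts:
        raise AnnotationError("empty elemental formula")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise AnnotationError("empty elemental formula")
    for element in counts:
        if element not in MONOISOTOPIC_MASS:
            raise AnnotationError(f"unsupported element {element!r}")
    return float(sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items()))


def normalize_adduct_name(name: str) -> str:
    """Canonicalize adduct spelling (unicode minus/subscripts -> ASCII)."""
    s = (
        name.replace("−", "-")
        .replace("‒", "-")
        .replace("–", "-")
        .replace("_", "")
        .replace(" ", "")
        .replace("^", "")
    )
    return s


def adduct_mz(formula: str | dict[str, int], adduct: str) -> float:
    """m/z of a singly charged adduct of the neutral formula."""
    key = normalize_adduct_name(adduct)
    if key not in ADDUCTS:
        raise AnnotationError(f"unknown adduct {adduct!r}")
    delta, _pol = ADDUCTS[key]
    return monoisotopic_mass(formula) + delta


def ppm_error(theoretical: float, observed: float) -> float:
    """(observed - theoretical) / theoretical x 1e6."""
    if theoretical <= 0:
        raise AnnotationError(f"theoretical mass must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class Candidate:
    """A database entry that an observed m/z can be matched against."""

    name: str
    formula: str
    adduct: str
    lipid_class: str | None = None

    @property
    def mz(self) -> float:
        return adduct_mz(self.formula, self.adduct)


@dataclass
class MatchResult:
    """Candidate matches for one observed m/z, sorted by |ppm error|."""

    mz_observed: float
    matches: list[tuple[Candidate, float]] = field(default_factory=list)  # (candidate, ppm)
    confidence_level: int = 4  # 4 = unknown until a match is found

    @property
    def best(self) -> tuple[Candidate, float] | None:
        return self.matches[0] if self.matches else None


def match_features(
    observed_mz: Sequence[float],
    candidates: Sequence[Candidate],
    tol_ppm: float = 5.0,
) -> list[MatchResult]:
    """Match each observed m/z against candidates within ``tol_ppm``.

    Matches are sorted by absolute ppm error; exact-mass-only matches get
    confidence level 3, no match leaves the observation at level 4.
    """
    if tol_ppm <= 0:
        raise AnnotationError(f"tol_ppm must be positive, got {tol_ppm}")
    theo = [(c, c.mz) for c in candidates]
    out = []
    for mz in observed_mz:
        hits = []
        for cand, t in theo:
            err = ppm_error(t, mz)
            if abs(err) <= tol_ppm:
                hits.append((cand, err))
        hits.sort(key=lambda h: abs(h[1]))
        out.append(
            MatchResult(
                mz_observed=float(mz),
                matches=hits,
                confidence_level=3 if hits else 4,
            )
        )
    return out


# ---------------------------------------------------------------------------
# packaged reference annotations (published serum panel, used as a
# desk-scale regression suite for the mass computations)

def load_reference_annotations() -> pd.DataFrame:
    """Published serum annotation rows: name, adduct, experimental m/z,
    formula, retention time, reported log2 fold change, source table."""
    with resources.files("metatrack.data").joinpath("reference_annotations.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reference_ppm_errors() -> pd.DataFrame:
    """Theoretical adduct m/z and ppm error vs the printed experimental m/z
    for every packaged reference row."""
    df = load_reference_annotations().copy()
    theo = [adduct_mz(f, a) for f, a in zip(df["formula"], df["adduct"])]
    df["mz_theoretical"] = theo
    df["ppm_error"] = [
        ppm_error(t, o) for t, o in zip(df["mz_theoretical"], df["mz_experimental"])
    ]
    return df
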