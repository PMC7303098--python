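"""Elemental formulas, monoisotopic masses, and adduct arithmetic.

All mass computations in the package flow through this module. Atomic
masses are embedded as constants (most-abundant-isotope values, CODATA/
IUPAC) so results are bit-stable across environments. Only singly charged
ions are supported; that is the working regime of electrospray small-
molecule metabolomics at m/z 50-750.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "C13_C12_DELTA",
    "ElementalFormula",
    "IonSpec",
    "MassConvention",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "imine_adduct_ion",
    "imine_open_chain",
    "peg_ammonium_ion",
    "peg_neutral",
    "isotope_mz",
    "ppm_error",
    "feature_name",
    "PROTON",
    "AMMONIUM_DELTA",
    "WATER",
]

# Most-abundant-isotope atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

ELECTRON_MASS = 0.00054858  # Da

#: Exact mass difference between a 13C and a 12C substitution, Da.
C13_C12_DELTA = 1.003355

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formulas or chemically impossible arithmetic."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map with monoisotopic-mass semantics.

    Supports ``+``, ``-`` and integer ``*``; subtraction that would drive
    any element count negative raises :class:`FormulaError`, signalling a
    chemically impossible operation.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: dict[str, int] | tuple[tuple[str, int], ...] = ()):
        items = dict(counts)
        for el, n in items.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        # drop zero counts; store in Hill order for stable equality/hash
        object.__setattr__(
            self,
            "counts",
            tuple(sorted(((el, n) for el, n in items.items() if n > 0),
                         key=_hill_key)),
        )

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return ElementalFormula(d)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        d = self.as_dict()
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise FormulaError(
                    f"subtraction would give negative {el} count "
                    f"({self} - {other}): chemically impossible pairing"
                )
        return ElementalFormula(d)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative int, got {k!r}")
        return ElementalFormula({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __str__(self) -> str:
        return format_formula(self)

    def __bool__(self) -> bool:
        return bool(self.counts)


def _hill_key(item: tuple[str, int]) -> tuple[int, str]:
    # Hill order: C, then H, then other elements alphabetically.
    el = item[0]
    return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))


def parse_formula(text: str) -> ElementalFormula:
    """Parse a plain Hill-notation formula string such as ``"C14H19NO"``.

    No parentheses, charges, or isotope labels; an omitted count means 1.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos or not m.group(0):
            break
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return ElementalFormula(counts)


def format_formula(f: ElementalFormula) -> str:
    """Hill-notation string; inverse of :func:`parse_formula`."""
    return "".join(f"{el}{n if n != 1 else ''}" for el, n in f.counts)


def monoisotopic_mass(f: ElementalFormula | dict[str, int]) -> float:
    """Sum of most-abundant-isotope atomic masses, Da."""
    if not isinstance(f, ElementalFormula):
        f = ElementalFormula(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.counts)


PROTON = ElementalFormula({"H": 1})
WATER = ElementalFormula({"H": 2, "O": 1})
H2 = ElementalFormula({"H": 2})
AMMONIUM_DELTA = ElementalFormula({"N": 1, "H": 4})
ETHYLENE_OXIDE = ElementalFormula({"C": 2, "H": 4, "O": 1})  # PEG repeat unit


@dataclass(frozen=True)
class MassConvention:
    """Whether ion m/z subtracts the electron mass.

    Instrument software differs here; for singly charged ions above
    m/z 180 the two conventions agree within 3 ppm, inside the 5 ppm
    matching tolerance used throughout.
    """

    electron_correction: bool = True


@dataclass(frozen=True)
class IonSpec:
    """A singly charged ion: neutral composition plus an ionizing delta.

    ``adduct_delta`` is the elemental change applied on ionization (+H for
    protonation, +NH4 for ammoniation, empty for a pre-formed cation whose
    composition is already the ion formula).
    """

    neutral: ElementalFormula
    charge: int = 1
    adduct_delta: ElementalFormula = field(default_factory=ElementalFormula)

    def __post_init__(self):
        if self.charge == 0:
            raise ValueError("ion charge must be nonzero")
        if abs(self.charge) != 1:
            raise ValueError("only |charge| = 1 ions are supported")

    @property
    def ion_formula(self) -> ElementalFormula:
        return self.neutral + self.adduct_delta

    def mz(self, convention: MassConvention | None = None) -> float:
        return ion_mz(self, convention)


def ion_mz(spec: IonSpec, convention: MassConvention | None = None) -> float:
    """m/z of a singly charged ion.

    With ``electron_correction`` on, |charge| electron masses are
    subtracted (positive ion) or added (negative ion).
    """
    if convention is None:
        convention = MassConvention()
    mass = monoisotopic_mass(spec.ion_formula)
    if convention.electron_correction:
        mass -= ELECTRON_MASS * (1 if spec.charge > 0 else -1)
    return mass / abs(spec.charge)


def imine_open_chain(parent: ElementalFormula, amino_acid: ElementalFormula) -> ElementalFormula:
    """Neutral open-chain imine (Schiff base): parent + amino acid - H2O.

    The primary condensation product formed in incubation, before any
    in-source cyclization.
    """
    _check_imine_preconditions(parent, amino_acid)
    return parent + amino_acid - WATER


def imine_adduct_ion(parent: ElementalFormula, amino_acid: ElementalFormula) -> IonSpec:
    """Observed protonated amino-acid adduct ion of a cathinone parent.

    The amine of the amino acid condenses with the parent's carbonyl
    (losing H2O); the species actually detected has additionally lost two
    H2 (cyclization/aromatization in the heated ESI source), so the
    observed ion is ``[parent + AA - H2O - 2 H2 + H]+``. The plain
    open-chain imine is available via :func:`imine_open_chain`.
    """
    _check_imine_preconditions(parent, amino_acid)
    neutral = parent + amino_acid - WATER - 2 * H2
    return IonSpec(neutral=neutral, charge=1, adduct_delta=PROTON)


def _check_imine_preconditions(parent: ElementalFormula, amino_acid: ElementalFormula) -> None:
    if parent.as_dict().get("O", 0) < 1:
        raise FormulaError("parent has no oxygen: no carbonyl to condense at")
    if amino_acid.as_dict().get("N", 0) < 1:
        raise FormulaError("amino acid has no nitrogen: no amine nucleophile")


def peg_neutral(n_repeat: int) -> ElementalFormula:
    """Neutral polyethylene glycol with ``n_repeat`` C2H4O units plus the H2O end group."""
    if n_repeat < 1:
        raise ValueError(f"n_repeat must be >= 1, got {n_repeat}")
    return n_repeat * ETHYLENE_OXIDE + WATER


def peg_ammonium_ion(n_repeat: int) -> IonSpec:
    """Ammoniated PEG homolog [M+NH4]+ with ``n_repeat`` repeat units."""
    return IonSpec(neutral=peg_neutral(n_repeat), charge=1, adduct_delta=AMMONIUM_DELTA)


def isotope_mz(mz: float, n_c13: int) -> float:
    """m/z of the isotopologue with ``n_c13`` carbons replaced by 13C."""
    return mz + n_c13 * C13_C12_DELTA


def ppm_error(observed: float, theoretical: float) -> float:
    """Relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def feature_name(mz: float, rt_seconds: float) -> str:
    """XCMS-style feature name: ``M{rounded m/z}T{rounded RT in s}``.

    Rounding is half-up on both components, e.g. (218.1538, 222) ->
    ``"M218T222"``.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if rt_seconds < 0:
        raise ValueError("retention time must be non-negative")
    return f"M{_round_half_up(mz)}T{_round_half_up(rt_seconds)}"
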