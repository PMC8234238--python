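"""Molecular formula and exact-mass arithmetic for steroid metabolite work.

Provides formula parsing, monoisotopic masses, electrospray adduct m/z
bookkeeping, ppm comparison, and classification of the small formula
differences (oxidation, hydration, methylene gain/loss, succinate
esterification) that link a cortisol metabolite family together.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "MolecularFormula",
    "AdductSpec",
    "DeltaClass",
    "DeltaMatch",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_adduct",
    "ppm_diff",
    "classify_delta",
    "default_adducts",
    "default_delta_classes",
    "load_adducts",
    "load_delta_classes",
]

# Monoisotopic masses of the most abundant isotope (Da), CODATA/IUPAC.
# Restricted to the elements that occur in steroid metabolites and their
# common electrospray adducts.
ELEMENT_MASSES: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.00307400443,
    "O": 15.99491461957,
    "S": 31.97207100,
    "Na": 22.98976928,
    "K": 38.96370649,
    "P": 30.97376199842,
}

ELECTRON_MASS = 0.000548579909  # Da


class FormulaError(ValueError):
    """Raised for malformed formula strings or unknown element symbols."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An element→count mapping; counts must be non-negative integers."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in ELEMENT_MASSES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self):
        return hash(tuple(sorted(self.counts.items())))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(
            self.counts,
            key=lambda el: (el != "C", el != "H", el),
        )
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el
            for el in order
        )


def parse_formula(text: str) -> MolecularFormula:
    """Parse plain Hill-like notation, e.g. ``"C21H34O5"`` or ``"H2O"``.

    Omitted counts default to 1; element symbols are case-sensitive.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def _signed_mass(delta: Mapping[str, int]) -> float:
    """Mass of a signed element-count change (counts may be negative)."""
    total = 0.0
    for el, n in delta.items():
        if el not in ELEMENT_MASSES:
            raise FormulaError(f"unknown element symbol: {el!r}")
        total += ELEMENT_MASSES[el] * n
    return total


def monoisotopic_mass(formula: MolecularFormula | Mapping[str, int] | str) -> float:
    """Sum of monoisotopic element masses × counts, in Da."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    counts = formula.counts if isinstance(formula, MolecularFormula) else formula
    total = 0.0
    for el, n in counts.items():
        if el not in ELEMENT_MASSES:
            raise FormulaError(f"element {el!r} missing from mass table")
        total += ELEMENT_MASSES[el] * n
    return total


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductSpec:
    """An electrospray adduct: signed formula change, charge, polarity.

    ``delta`` holds signed element counts, e.g. ``{"H": -1}`` for [M−H]−.
    """

    name: str
    delta: Mapping[str, int]
    charge: int
    polarity: str  # "positive" | "negative"

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if self.charge > 0 and self.polarity != "positive":
            raise ValueError(f"adduct {self.name}: charge sign contradicts polarity")
        if self.charge < 0 and self.polarity != "negative":
            raise ValueError(f"adduct {self.name}: charge sign contradicts polarity")
        object.__setattr__(self, "delta", dict(self.delta))

    @property
    def delta_mass(self) -> float:
        return _signed_mass(self.delta)


def default_adducts() -> list[AdductSpec]:
    """The adducts observed for steroids in this workflow."""
    return [
        AdductSpec("[M-H]-", {"H": -1}, -1, "negative"),
        AdductSpec("[M+CHO2]-", {"C": 1, "H": 1, "O": 2}, -1, "negative"),
        AdductSpec("[M+H]+", {"H": 1}, 1, "positive"),
        AdductSpec("[M+NH4]+", {"N": 1, "H": 4}, 1, "positive"),
        AdductSpec("[M+Na]+", {"Na": 1}, 1, "positive"),
    ]


def load_adducts(path) -> list[AdductSpec]:
    """Read an adduct registry from JSON: a list of
    ``{"name", "delta": {el: count}, "charge", "polarity"}`` objects."""
    with open(path) as fh:
        raw = json.load(fh)
    specs = [AdductSpec(d["name"], d["delta"], int(d["charge"]), d["polarity"]) for d in raw]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate adduct names in registry")
    return specs


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """m/z of a neutral under a given adduct.

    m/z = (M + Δm − z·mₑ) / |z| — the electron term keeps charged-species
    masses exact rather than proton-approximated.
    """
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct.charge == 0:
        raise ValueError(f"adduct {adduct.name}: charge must be nonzero")
    z = adduct.charge
    return (neutral_mass + adduct.delta_mass - z * ELECTRON_MASS) / abs(z)


def neutral_from_adduct(mz: float, adduct: AdductSpec) -> float:
    """Invert :func:`adduct_mz`: neutral mass from an observed m/z."""
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    if adduct.charge == 0:
        raise ValueError(f"adduct {adduct.name}: charge must be nonzero")
    z = adduct.charge
    return mz * abs(z) - adduct.delta_mass + z * ELECTRON_MASS


def ppm_diff(observed: float, theoretical: float) -> float:
    """(observed − theoretical) / theoretical × 1e6."""
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


# ---------------------------------------------------------------------------
# Formula-delta classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeltaClass:
    """A named formula change linking members of a metabolite family.

    ``expected_delta`` is the monoisotopic mass of ``delta_formula`` and is
    computed, never entered by hand.
    """

    label: str
    delta_formula: Mapping[str, int]  # signed counts; {} for identity/isomer
    expected_delta: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "delta_formula", dict(self.delta_formula))
        object.__setattr__(self, "expected_delta", _signed_mass(self.delta_formula))


@dataclass(frozen=True)
class DeltaMatch:
    """Result of classifying a mass pair: class, direction, ppm error."""

    cls: DeltaClass
    sign: int  # +1 if mass_b > mass_a (or identity), else -1
    ppm_error: float

    @property
    def label(self) -> str:
        return self.cls.label

    @property
    def signed_label(self) -> str:
        if self.cls.label in ("identity/isomer", "unclassified"):
            return self.cls.label
        return ("+" if self.sign >= 0 else "-") + self.cls.label


UNCLASSIFIED = DeltaClass("unclassified", {})


def default_delta_classes() -> list[DeltaClass]:
    """Formula deltas observed between cortisol metabolites.

    Includes succinate esterification (the administered drug is a
    hemisuccinate ester) and its ammonia-neutralised composition as printed
    for ammonium adducts.
    """
    return [
        DeltaClass("identity/isomer", {}),
        DeltaClass("O", {"O": 1}),
        DeltaClass("H2O", {"H": 2, "O": 1}),
        DeltaClass("CH2", {"C": 1, "H": 2}),
        DeltaClass("H2", {"H": 2}),
        DeltaClass("succinate-ester", {"C": 4, "H": 4, "O": 3}),
        DeltaClass("succinate-ester+NH3", {"C": 4, "H": 7, "N": 1, "O": 3}),
    ]


def load_delta_classes(path) -> list[DeltaClass]:
    """Read a delta-class registry from JSON: list of
    ``{"label", "delta_formula": {el: count}}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return [DeltaClass(d["label"], d["delta_formula"]) for d in raw]


def classify_delta(
    mass_a: float,
    mass_b: float,
    tol_ppm: float = 10.0,
    classes: Iterable[DeltaClass] | None = None,
) -> DeltaMatch:
    """Classify the mass difference ``mass_b − mass_a``.

    The winning class is the one whose expected delta matches
    ``|mass_b − mass_a|`` within ``tol_ppm`` (tolerance computed on the
    larger of the two masses); ties go to the smallest absolute ppm error.
    """
    if mass_a <= 0 or mass_b <= 0:
        raise ValueError("masses must be positive")
    if classes is None:
        classes = default_delta_classes()
    delta = mass_b - mass_a
    ref = max(mass_a, mass_b)
    tol_da = tol_ppm * 1e-6 * ref
    best: DeltaMatch | None = None
    for cls in classes:
        err_da = abs(abs(delta) - cls.expected_delta)
        if err_da <= tol_da:
            ppm = err_da / ref * 1e6
            if best is None or ppm < abs(best.ppm_error):
                sign = 1 if (delta >= 0 or cls.label == "identity/isomer") else -1
                best = DeltaMatch(cls, sign, ppm)
    if best is None:
        return DeltaMatch(UNCLASSIFIED, 1 if delta >= 0 else -1, float("nan"))
    return best
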