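"""Exact monoisotopic mass arithmetic for small molecules and their adduct ions.

This module is the numerical foundation of the package: every theoretical m/z
used for calibration, annotation and synthesis is derived here from a molecular
formula, a packaged table of monoisotopic atomic masses, and an adduct
definition.  Charged-species m/z accounts for the electron mass, which at
FTICR accuracy (sub-ppm) is not negligible: a protonated ion is lighter than
the neutral-plus-H-atom by one electron (~0.55 mDa, i.e. ~3 ppm at m/z 184).

Conventions
-----------
* Formulas are flat Hill-style strings ("C10H16N5O13P3"); no parentheses,
  isotope labels or charges.
* Mass errors are signed, ``(observed - theoretical) / theoretical``,
  exposed both in ppm and ppb.
* Display rounding is 6 decimals (round-half-even); all comparisons are done
  at full float precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Iterator, Mapping

__all__ = [
    "ELEMENTS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "Formula",
    "Adduct",
    "MassError",
    "FormulaError",
    "AdductError",
    "parse_formula",
    "parse_adduct",
    "monoisotopic_mass",
    "ion_mz",
    "mass_error",
    "neutral_loss",
    "adducts_for_mode",
]


class FormulaError(ValueError):
    """Raised for unparseable formulas or invalid formula arithmetic."""


class AdductError(ValueError):
    """Raised when an adduct cannot be parsed or applied to a formula."""


def _load_elements() -> Mapping[str, float]:
    table: dict[str, float] = {}
    text = resources.files("msimet.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        symbol, mass = line.split("\t")
        mass_f = float(mass)
        if mass_f <= 0:
            raise ValueError(f"non-positive mass for element {symbol!r}")
        table[symbol] = mass_f
    return MappingProxyType(table)


#: Monoisotopic atomic masses in Da, plus the electron mass under key ``e-``.
#: Immutable after load.
ELEMENTS: Mapping[str, float] = _load_elements()

ELECTRON_MASS: float = ELEMENTS["e-"]
PROTON_MASS: float = ELEMENTS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An element -> count map with exact-mass arithmetic.

    Immutable and hashable.  Addition merges counts; subtraction raises
    :class:`FormulaError` if any count would go negative.  The empty formula
    is valid and has mass zero.
    """

    _items: tuple[tuple[str, int], ...]

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "Formula":
        items = []
        for sym, n in counts.items():
            if n < 0:
                raise FormulaError(f"negative count for element {sym!r}")
            if n > 0:
                items.append((sym, int(n)))
        return cls(tuple(sorted(items)))

    def counts(self) -> dict[str, int]:
        return dict(self._items)

    def __getitem__(self, symbol: str) -> int:
        return dict(self._items).get(symbol, 0)

    def __contains__(self, symbol: str) -> bool:
        return any(sym == symbol for sym, _ in self._items)

    def __bool__(self) -> bool:
        return bool(self._items)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._items)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._items)
        for sym, n in other:
            merged[sym] = merged.get(sym, 0) + n
        return Formula.from_counts(merged)

    def __sub__(self, other: "Formula") -> "Formula":
        merged = dict(self._items)
        for sym, n in other:
            new = merged.get(sym, 0) - n
            if new < 0:
                raise FormulaError(
                    f"cannot remove {n} x {sym} from {self.hill()!r}"
                )
            merged[sym] = new
        return Formula.from_counts(merged)

    def hill(self) -> str:
        """Hill-notation string: C first, then H, then other elements
        alphabetically; alphabetical throughout if there is no carbon."""
        counts = dict(self._items)
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order.extend(sorted(s for s in counts if s not in ("C", "H")))
        else:
            order = sorted(counts)
        return "".join(
            f"{s}{counts[s]}" if counts[s] != 1 else s for s in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill() or "(empty)"


def parse_formula(text: str, table: Mapping[str, float] = ELEMENTS) -> Formula:
    """Parse a flat Hill-style formula string into a :class:`Formula`.

    An element symbol without a trailing digit has implicit count 1
    ("H" -> {H: 1}).  Unknown element symbols and empty or malformed input
    raise :class:`FormulaError` naming the offending token.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(
                f"unparseable token {text[pos:match.start()]!r} in {text!r}"
            )
        sym, digits = match.groups()
        if sym not in table or sym == "e-":
            raise FormulaError(f"unknown element {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"unparseable token {text[pos:]!r} in {text!r}")
    return Formula.from_counts(counts)


def monoisotopic_mass(
    formula: Formula, table: Mapping[str, float] = ELEMENTS
) -> float:
    """Sum of count x monoisotopic atomic mass over the formula, in Da."""
    total = 0.0
    for sym, n in formula:
        try:
            total += n * table[sym]
        except KeyError:
            raise FormulaError(f"element {sym!r} missing from mass table")
    return total


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct, e.g. ``[M+Na]+``: what is added to / removed
    from the neutral molecule and the resulting signed charge."""

    name: str
    added: Formula
    removed: Formula
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise AdductError(f"adduct {self.name!r} has zero charge")


_ADDUCT_RE = re.compile(r"^\[M((?:[+-][A-Za-z0-9]+)*)\](\d*)([+-])$")


def parse_adduct(name: str) -> Adduct:
    """Parse an adduct name like ``[M+H]+``, ``[M+Na]+`` or ``[M-H]-``.

    Multiple terms are allowed (``[M+H-H2O]+``).  The trailing sign (with
    optional magnitude) fixes the charge.  Names round-trip: the parsed
    adduct keeps the input name.
    """
    m = _ADDUCT_RE.match(name.strip())
    if m is None:
        raise AdductError(f"cannot parse adduct name {name!r}")
    terms, zmag, zsign = m.groups()
    charge = (int(zmag) if zmag else 1) * (1 if zsign == "+" else -1)
    added = Formula(())
    removed = Formula(())
    for tm in re.finditer(r"([+-])([A-Za-z0-9]+)", terms):
        sign, frag = tm.groups()
        f = parse_formula(frag)
        if sign == "+":
            added = added + f
        else:
            removed = removed + f
    return Adduct(name=name.strip(), added=added, removed=removed, charge=charge)


def _load_adducts() -> Mapping[str, Adduct]:
    out: dict[str, Adduct] = {}
    text = resources.files("msimet.data").joinpath("adducts.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, added, removed, charge, _mode = line.split("\t")
        adduct = Adduct(
            name=name,
            added=parse_formula(added) if added != "-" else Formula(()),
            removed=parse_formula(removed) if removed != "-" else Formula(()),
            charge=int(charge),
        )
        parsed = parse_adduct(name)
        if (parsed.added, parsed.removed, parsed.charge) != (
            adduct.added,
            adduct.removed,
            adduct.charge,
        ):  # pragma: no cover - packaged-data self check
            raise AdductError(f"adduct table entry {name!r} inconsistent")
        out[name] = adduct
    return MappingProxyType(out)


#: Packaged adduct definitions, keyed by name.
ADDUCTS: Mapping[str, Adduct] = _load_adducts()

_MODE_ADDUCTS = {
    "positive": tuple(a for a in ADDUCTS.values() if a.charge > 0),
    "negative": tuple(a for a in ADDUCTS.values() if a.charge < 0),
}


def adducts_for_mode(mode: str) -> tuple[Adduct, ...]:
    """Adducts searched in a given ionization mode
    (positive: [M+H]+, [M+Na]+, [M+K]+; negative: [M-H]-)."""
    try:
        return _MODE_ADDUCTS[mode]
    except KeyError:
        raise AdductError(f"unknown ionization mode {mode!r}")


def ion_mz(
    formula: Formula,
    adduct: Adduct | str,
    table: Mapping[str, float] = ELEMENTS,
) -> float:
    """Theoretical m/z of an adduct ion of the neutral ``formula``.

    m/z = (M + m(added) - m(removed) - z * m_e) / |z|

    so a positive ion loses one electron mass per charge and a negative ion
    gains one.  Raises :class:`AdductError` when the removal is impossible
    (e.g. [M-H]- of a hydrogen-free molecule).
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS.get(adduct) or parse_adduct(adduct)
    try:
        formula - adduct.removed
    except FormulaError as exc:
        raise AdductError(
            f"adduct {adduct.name} not applicable to {formula.hill()}: {exc}"
        ) from exc
    m = (
        monoisotopic_mass(formula, table)
        + monoisotopic_mass(adduct.added, table)
        - monoisotopic_mass(adduct.removed, table)
        - adduct.charge * table["e-"]
    )
    return m / abs(adduct.charge)


@dataclass(frozen=True)
class MassError:
    """Signed relative mass error between an observed and theoretical m/z.

    Sign convention: (observed - theoretical) / theoretical, so positive
    means the observation is heavy.  ``ppb`` is exactly 1000 x ``ppm``.
    """

    observed: float
    theoretical: float

    def __post_init__(self) -> None:
        if self.theoretical <= 0:
            raise ValueError("theoretical m/z must be positive")

    @property
    def delta_da(self) -> float:
        return self.observed - self.theoretical

    @property
    def ppm(self) -> float:
        return 1e6 * self.delta_da / self.theoretical

    @property
    def ppb(self) -> float:
        return 1e9 * self.delta_da / self.theoretical


def mass_error(observed: float, theoretical: float) -> MassError:
    """Signed relative error of ``observed`` vs ``theoretical`` m/z."""
    return MassError(observed=observed, theoretical=theoretical)


def neutral_loss(precursor_mz: float, fragment_mz: float) -> float:
    """Neutral-loss mass (Da) between singly charged precursor and fragment.

    Requires ``precursor > fragment > 0``; the difference of two singly
    charged m/z values equals the mass of the lost neutral moiety.
    """
    if fragment_mz <= 0:
        raise ValueError("fragment m/z must be positive")
    if fragment_mz >= precursor_mz:
        raise ValueError(
            f"fragment m/z {fragment_mz} must be below precursor {precursor_mz}"
        )
    return precursor_mz - fragment_mz
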