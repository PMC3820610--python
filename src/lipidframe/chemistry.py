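"""Elemental-formula arithmetic, monoisotopic masses, adduct ion m/z and isotope envelopes.

All downstream m/z values in the package derive from the frozen atomic-mass
table in this module. Masses are IUPAC monoisotopic values; ion m/z is always
electron-mass corrected (an [M+H]+ ion is lighter than M+H by one electron).
Internal arithmetic is full double precision; rounding to the conventional
5 decimals happens only at display time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "ISOTOPE_SHIFTS",
    "Adduct",
    "ElementalComposition",
    "DEFAULT_ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "isotope_envelope",
]

#: Monoisotopic atomic masses (Da), IUPAC 2021 / AME2020 values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

#: Electron rest mass (Da).
ELECTRON_MASS: float = 0.000548579909

#: Heavy-isotope abundances per element as (nominal mass shift, fraction).
#: The light-isotope fraction is one minus the listed fractions.
ISOTOPE_SHIFTS: dict[str, tuple[tuple[int, float], ...]] = {
    "H": ((1, 0.000115),),
    "C": ((1, 0.0107),),
    "N": ((1, 0.00364),),
    "O": ((1, 0.00038), (2, 0.00205)),
    "P": (),
    "S": ((1, 0.0075), (2, 0.0425)),
    "Na": (),
    "K": ((1, 0.000117), (2, 0.067302)),
    "Cl": ((2, 0.2424),),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """An element → count mapping, e.g. ``{"C": 40, "H": 80, ...}``.

    Counts are non-negative integers over known element symbols. Addition and
    subtraction are element-wise; subtraction below zero raises, since a
    negative atom count has no chemical meaning.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise ValueError(f"count for {element} must be a non-negative integer, got {count!r}")
            if count:
                clean[element] = int(count)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            new = merged.get(element, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for {element}: "
                    f"{merged.get(element, 0)} - {count}"
                )
            merged[element] = new
        return ElementalComposition(merged)

    def __mul__(self, n: int) -> "ElementalComposition":
        if n < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalComposition({el: c * n for el, c in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def hill_formula(self) -> str:
        """Formula string in Hill order (C, H, then alphabetical)."""
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el for el in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


def parse_formula(text: str) -> ElementalComposition:
    """Parse a molecular formula string such as ``"C40H80NO8P"``.

    An element symbol without a trailing count means one atom. Raises
    :class:`ValueError` on unknown symbols or malformed input.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    text = text.strip()
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {element!r} in formula {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    return ElementalComposition(counts)


@dataclass(frozen=True)
class Adduct:
    """A charge-carrying modification of a neutral molecule, e.g. [M+H]+.

    ``delta`` is the composition added to (``sign=+1``) or removed from
    (``sign=-1``) the neutral molecule; ``charge`` is the signed ion charge.
    Only singly charged ions are supported.
    """

    name: str
    delta: ElementalComposition
    sign: int
    charge: int

    def __post_init__(self) -> None:
        if self.charge not in (-1, 1):
            raise ValueError("only singly charged adducts (charge ±1) are supported")
        if self.sign not in (-1, 1):
            raise ValueError("delta sign must be ±1")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    def apply(self, comp: ElementalComposition) -> ElementalComposition:
        return comp + self.delta if self.sign > 0 else comp - self.delta


#: Adducts exercised by direct-infusion lipidomics. +H and +NH4 carry the
#: positive-mode identifications; -H the negative mode; the rest are optional.
DEFAULT_ADDUCTS: dict[str, Adduct] = {
    "+H": Adduct("+H", parse_formula("H"), +1, +1),
    "+NH4": Adduct("+NH4", parse_formula("NH4"), +1, +1),
    "+Na": Adduct("+Na", parse_formula("Na"), +1, +1),
    "-H": Adduct("-H", parse_formula("H"), -1, -1),
    "-CH3": Adduct("-CH3", parse_formula("CH3"), -1, -1),
}


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass (Da) of a composition: Σ count × atomic mass."""
    return sum(count * ATOMIC_MASSES[el] for el, count in comp.counts.items())


def ion_mz(comp: ElementalComposition, adduct: Adduct) -> float:
    """m/z of the adduct ion of a neutral molecule.

    ``(mass(M ± delta) − z·m_e) / |z|``: the electron mass is subtracted for
    cations and added for anions. Raises if the adduct removes atoms the
    molecule does not have.
    """
    ion = adduct.apply(comp)
    mass = monoisotopic_mass(ion) - adduct.charge * ELECTRON_MASS
    return mass / abs(adduct.charge)


def _single_atom_distribution(element: str, n_peaks: int) -> np.ndarray:
    dist = np.zeros(n_peaks)
    heavy = ISOTOPE_SHIFTS.get(element, ())
    light = 1.0 - sum(frac for _, frac in heavy)
    dist[0] = light
    for shift, frac in heavy:
        if shift < n_peaks:
            dist[shift] += frac
    return dist


def _convolve_truncated(a: np.ndarray, b: np.ndarray, n_peaks: int) -> np.ndarray:
    return np.convolve(a, b)[:n_peaks]


def isotope_envelope(
    comp: ElementalComposition, n_peaks: int, normalize: bool = False
) -> np.ndarray:
    """Relative abundances of the M+0 … M+(n_peaks−1) isotopologue peaks.

    Computed by the exact polynomial expansion over per-element isotope
    abundances, aggregated by nominal mass shift (so M+1 pools 13C, 2H, 15N,
    17O; M+2 pools 18O, 34S and double-heavy combinations). Entries sum to
    ≤ 1 (the truncated tail is dropped); ``normalize=True`` rescales them to
    sum to 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    envelope = np.zeros(n_peaks)
    envelope[0] = 1.0
    for element, count in comp.counts.items():
        if count == 0:
            continue
        # element distribution for `count` atoms by binary exponentiation
        base = _single_atom_distribution(element, n_peaks)
        acc = np.zeros(n_peaks)
        acc[0] = 1.0
        k = count
        while k:
            if k & 1:
                acc = _convolve_truncated(acc, base, n_peaks)
            k >>= 1
            if k:
                base = _convolve_truncated(base, base, n_peaks)
        envelope = _convolve_truncated(envelope, acc, n_peaks)
    if normalize:
        total = envelope.sum()
        if total > 0:
            envelope = envelope / total
    return envelope
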