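"""Forward and reverse m/z queries against the lipid database.

The calibration offset (measured minus theoretical m/z of lock-mass ions, in
Da) is applied to *theoretical* values, shifting search targets toward the
instrument's current calibration; measured values are never altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .chemistry import DEFAULT_ADDUCTS, ion_mz
from .database import LipidDatabase

__all__ = ["OffsetSpec", "SpeciesMz", "Candidate", "species_mz", "candidates_for"]


@dataclass(frozen=True)
class OffsetSpec:
    """A calibration offset in Da, with its provenance.

    ``origin`` is ``"user"`` for a manually supplied constant and
    ``"estimated"`` when it came from lock-mass estimation. Values of 1 Da or
    more are rejected as unit mistakes (offsets are always sub-mDa to low-mDa).
    """

    value: float = 0.0
    origin: str = "user"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("offset must be finite")
        if abs(self.value) >= 1.0:
            raise ValueError(f"offset {self.value} Da looks like a unit mistake (|offset| must be < 1 Da)")


class SpeciesMz(NamedTuple):
    species_name: str
    adduct: str
    theoretical_mz: float
    adjusted_mz: float


class Candidate(NamedTuple):
    species_name: str
    adduct: str
    theoretical_mz: float
    adjusted_mz: float
    delta_mz: float
    delta_ppm: float


def species_mz(
    db: LipidDatabase,
    species_name: str,
    adduct: str,
    offset: OffsetSpec | float = 0.0,
) -> SpeciesMz:
    """Theoretical and offset-adjusted m/z of one species' adduct ion.

    ``species_name`` may be a sum-composition name or an internal-standard
    display label. The adduct must be allowed for the species' class.
    """
    if isinstance(offset, (int, float)):
        offset = OffsetSpec(float(offset))
    sp = db.get(species_name)
    allowed = {a.name for a in db.adducts_for(sp.class_name)}
    if adduct not in allowed:
        raise ValueError(
            f"adduct {adduct!r} not allowed for class {sp.class_name!r} (allowed: {sorted(allowed)})"
        )
    mz = ion_mz(sp.formula, DEFAULT_ADDUCTS[adduct])
    return SpeciesMz(sp.species_name, adduct, mz, mz + offset.value)


def candidates_for(
    db: LipidDatabase,
    measured_mz: float,
    tolerance: float,
    offset: OffsetSpec | float = 0.0,
    polarity: str = "positive",
) -> list[Candidate]:
    """Database species whose offset-adjusted ion m/z matches a measured value.

    Returns every (species, adduct) of the requested polarity with
    ``|measured - (theoretical + offset)| <= tolerance`` (closed interval),
    sorted by |delta_mz| with ties broken by species name. ``delta_ppm`` is
    ``delta_mz / measured_mz * 1e6``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if isinstance(offset, (int, float)):
        offset = OffsetSpec(float(offset))
    hits: list[Candidate] = []
    for sp in db:
        for adduct in db.adducts_for(sp.class_name):
            if adduct.polarity != polarity:
                continue
            theo = ion_mz(sp.formula, adduct)
            adjusted = theo + offset.value
            delta = measured_mz - adjusted
            if abs(delta) <= tolerance:
                hits.append(
                    Candidate(
                        sp.species_name,
                        adduct.name,
                        theo,
                        adjusted,
                        delta,
                        delta / measured_mz * 1e6,
                    )
                )
    hits.sort(key=lambda c: (abs(c.delta_mz), c.species_name))
    return hits
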