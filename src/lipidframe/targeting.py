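"""Per-scan-range target lists: species, adduct ions, accessory features.

A target list is the bridge between the lipid database and targeted peak
extraction: every database species passing the user's filters whose adduct-ion
m/z falls inside the scan range becomes one row, carrying all accessory lipid
features (category, class, C/db/OH indices, formula, monoisotopic mass) plus
the M+0..M+2 isotopologue fractions for downstream isotope correction.

Lock masses — ubiquitous ions of known composition used for calibration-drift
estimation — are ordinary target rows flagged ``is_lock_mass``; non-lipid lock
ions (e.g. the tris(ditert-butylphenyl) phosphate chemical background ion) are
given by explicit formula. Target lists persist as tab-separated text so they
can be audited and hand-edited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .chemistry import (
    DEFAULT_ADDUCTS,
    ElementalComposition,
    ion_mz,
    isotope_envelope,
    monoisotopic_mass,
    parse_formula,
)
from .database import LipidDatabase

__all__ = ["TargetEntry", "TargetList", "FilterSpec", "LockMassSpec", "generate_target_list"]


@dataclass(frozen=True)
class TargetEntry:
    species_name: str
    adduct: str
    theoretical_mz: float
    lipid_class: str
    category: str
    c_index: int
    db_index: int
    oh_index: int
    formula: ElementalComposition
    mono_mass: float
    is_internal_standard: bool = False
    is_lock_mass: bool = False
    isotope_m0: float = 1.0
    isotope_m1: float = 0.0
    isotope_m2: float = 0.0


@dataclass
class TargetList:
    scan_range_id: str
    low_mz: float
    high_mz: float
    entries: list[TargetEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.low_mz < self.high_mz:
            raise ValueError(f"invalid scan range bounds [{self.low_mz}, {self.high_mz}]")
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if not self.low_mz <= e.theoretical_mz <= self.high_mz:
                raise ValueError(
                    f"{e.species_name} {e.adduct}: m/z {e.theoretical_mz:.5f} outside "
                    f"[{self.low_mz}, {self.high_mz}]"
                )
            key = (e.species_name, e.adduct)
            if key in seen:
                raise ValueError(f"duplicate target {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def locks(self) -> list[TargetEntry]:
        return [e for e in self.entries if e.is_lock_mass]

    _COLUMNS = (
        "species_name",
        "adduct",
        "theoretical_mz",
        "lipid_class",
        "category",
        "c_index",
        "db_index",
        "oh_index",
        "formula",
        "mono_mass",
        "is_internal_standard",
        "is_lock_mass",
        "isotope_m0",
        "isotope_m1",
        "isotope_m2",
    )

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# scan_range_id={self.scan_range_id}\tlow={self.low_mz!r}\thigh={self.high_mz!r}\n")
            fh.write("\t".join(self._COLUMNS) + "\n")
            for e in self.entries:
                fh.write(
                    "\t".join(
                        (
                            e.species_name,
                            e.adduct,
                            repr(e.theoretical_mz),
                            e.lipid_class,
                            e.category,
                            str(e.c_index),
                            str(e.db_index),
                            str(e.oh_index),
                            e.formula.hill_formula(),
                            repr(e.mono_mass),
                            str(int(e.is_internal_standard)),
                            str(int(e.is_lock_mass)),
                            repr(e.isotope_m0),
                            repr(e.isotope_m1),
                            repr(e.isotope_m2),
                        )
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "TargetList":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            meta = fh.readline().lstrip("#").split("\t")
            kv = dict(item.strip().split("=", 1) for item in meta)
            header = tuple(fh.readline().rstrip("\n").split("\t"))
            if header != cls._COLUMNS:
                raise ValueError(f"{path}: unexpected header")
            entries = []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                entries.append(
                    TargetEntry(
                        species_name=f[0],
                        adduct=f[1],
                        theoretical_mz=float(f[2]),
                        lipid_class=f[3],
                        category=f[4],
                        c_index=int(f[5]),
                        db_index=int(f[6]),
                        oh_index=int(f[7]),
                        formula=parse_formula(f[8]),
                        mono_mass=float(f[9]),
                        is_internal_standard=bool(int(f[10])),
                        is_lock_mass=bool(int(f[11])),
                        isotope_m0=float(f[12]),
                        isotope_m1=float(f[13]),
                        isotope_m2=float(f[14]),
                    )
                )
        return cls(kv["scan_range_id"], float(kv["low"]), float(kv["high"]), entries)


@dataclass(frozen=True)
class LockMassSpec:
    """A lock-mass ion: either a database species (by name or internal-standard
    label) or a non-lipid composition given by molecular formula."""

    name: str
    adduct: str
    formula: str | None = None  # None -> look the name up in the database


@dataclass
class FilterSpec:
    """Predicates selecting database species for one target list."""

    classes: Sequence[str] | None = None
    adducts: Sequence[str] | None = None
    c_range: tuple[int, int] | None = None
    db_range: tuple[int, int] | None = None
    oh_range: tuple[int, int] | None = None
    explicit_species: Sequence[str] = ()
    lock_masses: Sequence[LockMassSpec] = ()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterSpec":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        locks = [
            LockMassSpec(l["name"], l["adduct"], l.get("formula"))
            for l in raw.get("lock_masses", [])
        ]
        as_pair = lambda v: tuple(v) if v is not None else None
        return cls(
            classes=raw.get("classes"),
            adducts=raw.get("adducts"),
            c_range=as_pair(raw.get("c_range")),
            db_range=as_pair(raw.get("db_range")),
            oh_range=as_pair(raw.get("oh_range")),
            explicit_species=raw.get("explicit_species", ()),
            lock_masses=locks,
        )


def _entry_from_species(
    db: LipidDatabase,
    species_name: str,
    adduct_name: str,
    is_lock: bool = False,
) -> TargetEntry:
    sp = db.get(species_name)
    mz = ion_mz(sp.formula, DEFAULT_ADDUCTS[adduct_name])
    env = isotope_envelope(sp.formula, 3)
    is_standard = sp.species_name in set(db.standard_labels.values())
    return TargetEntry(
        species_name=sp.species_name,
        adduct=adduct_name,
        theoretical_mz=mz,
        lipid_class=sp.class_name,
        category=sp.category,
        c_index=sp.c_index,
        db_index=sp.db_index,
        oh_index=sp.oh_index,
        formula=sp.formula,
        mono_mass=sp.mono_mass,
        is_internal_standard=is_standard,
        is_lock_mass=is_lock,
        isotope_m0=float(env[0]),
        isotope_m1=float(env[1]),
        isotope_m2=float(env[2]),
    )


def generate_target_list(
    db: LipidDatabase,
    filter_spec: FilterSpec,
    scan_range_id: str,
    low_mz: float,
    high_mz: float,
) -> TargetList:
    """Compile the target list for one scan range.

    Database species pass when they satisfy every stated predicate and at
    least one allowed adduct ion falls inside [low_mz, high_mz]. Explicitly
    requested species are added with their class's allowed adducts; lock
    masses are appended last (non-lipid locks with class ``"(lock)"`` and
    zeroed indices).
    """
    if filter_spec.classes is not None:
        unknown = set(filter_spec.classes) - set(db.templates)
        if unknown:
            raise ValueError(f"filter references unknown classes: {sorted(unknown)}")
    entries: dict[tuple[str, str], TargetEntry] = {}

    def in_range(value: int, bounds: tuple[int, int] | None) -> bool:
        return bounds is None or bounds[0] <= value <= bounds[1]

    for sp in db:
        if filter_spec.classes is not None and sp.class_name not in filter_spec.classes:
            continue
        if not (
            in_range(sp.c_index, filter_spec.c_range)
            and in_range(sp.db_index, filter_spec.db_range)
            and in_range(sp.oh_index, filter_spec.oh_range)
        ):
            continue
        for adduct in db.adducts_for(sp.class_name):
            if filter_spec.adducts is not None and adduct.name not in filter_spec.adducts:
                continue
            mz = ion_mz(sp.formula, adduct)
            if low_mz <= mz <= high_mz:
                entries[(sp.species_name, adduct.name)] = _entry_from_species(
                    db, sp.species_name, adduct.name
                )

    for name in filter_spec.explicit_species:
        sp = db.get(name)  # raises on unknown species
        for adduct in db.adducts_for(sp.class_name):
            mz = ion_mz(sp.formula, adduct)
            if low_mz <= mz <= high_mz:
                entries[(sp.species_name, adduct.name)] = _entry_from_species(
                    db, sp.species_name, adduct.name
                )

    for lock in filter_spec.lock_masses:
        if lock.formula is None:
            sp = db.get(lock.name)
            entry = _entry_from_species(db, sp.species_name, lock.adduct, is_lock=True)
            key = (entry.species_name, entry.adduct)
        else:
            comp = parse_formula(lock.formula)
            mz = ion_mz(comp, DEFAULT_ADDUCTS[lock.adduct])
            env = isotope_envelope(comp, 3)
            entry = TargetEntry(
                species_name=lock.name,
                adduct=lock.adduct,
                theoretical_mz=mz,
                lipid_class="(lock)",
                category="non-lipid",
                c_index=0,
                db_index=0,
                oh_index=0,
                formula=comp,
                mono_mass=monoisotopic_mass(comp),
                is_lock_mass=True,
                isotope_m0=float(env[0]),
                isotope_m1=float(env[1]),
                isotope_m2=float(env[2]),
            )
            key = (lock.name, lock.adduct)
        if not low_mz <= entry.theoretical_mz <= high_mz:
            continue  # lock belongs to another scan range
        entries[key] = entry

    ordered = sorted(entries.values(), key=lambda e: (e.theoretical_mz, e.species_name))
    return TargetList(scan_range_id, low_mz, high_mz, ordered)
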