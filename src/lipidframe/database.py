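"""Sum-composition lipid database: enumeration, annotation and text persistence.

Lipid species are enumerated per class from building-block arithmetic: a class
template supplies a backbone composition and a chain model, and each species is
the unique (C index, db index, OH index) combination of total chain carbons,
double bonds and hydroxyls. Two chain models cover the shipped classes:

* ``acyl`` — glycerophospholipids, glycerolipids and sterol esters. The chain
  moieties contribute C_c H_(2c-2db) O_(2n) in total and each esterification
  loses one water. Ether classes (names ending ``O-``) replace one ester bond
  by an ether: minus one O, plus two H.
* ``sphingoid`` — sphingolipids. The combined long-chain base plus N-acyl
  contributes C_c H_(2c+1-2db) N O_(oh+1); the class headgroup (phosphocholine
  for SM, hexose for HexCer, ...) is added on top.

Annotation follows the field's shorthand: ``PI 34:1`` for glycerophospho- and
glycerolipids, ``SM 36:1;2`` (with OH index) for sphingolipids, and
``PC O-34:1`` for ether classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import yaml

from .chemistry import (
    DEFAULT_ADDUCTS,
    Adduct,
    ElementalComposition,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "LipidClassTemplate",
    "LipidSpecies",
    "LipidDatabase",
    "enumerate_class",
    "annotate_species",
    "parse_annotation",
    "build_database",
    "load_class_config",
    "default_database",
]

_H2O = parse_formula("H2O")
_ETHER_ADJUST_ADD = parse_formula("H2")
_ETHER_ADJUST_REMOVE = parse_formula("O")


@dataclass(frozen=True)
class LipidClassTemplate:
    """Generative template for one lipid class."""

    class_name: str
    category: str
    backbone: ElementalComposition
    n_chains: int
    chain_model: str  # "acyl" | "sphingoid"
    adducts: tuple[str, ...]
    c_range: tuple[int, int]
    db_range: tuple[int, int]
    oh_range: tuple[int, int] = (0, 0)
    n_ether: int = 0  # ester bonds replaced by ether linkages

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError(f"{self.class_name}: n_chains must be >= 1")
        if not self.adducts:
            raise ValueError(f"{self.class_name}: at least one adduct required")
        if self.chain_model not in ("acyl", "sphingoid"):
            raise ValueError(f"{self.class_name}: unknown chain model {self.chain_model!r}")

    @property
    def is_sphingolipid(self) -> bool:
        return self.chain_model == "sphingoid"

    def formula_for(self, c: int, db: int, oh: int) -> ElementalComposition:
        """Molecular formula of the (c, db, oh) sum-composition species."""
        if self.chain_model == "acyl":
            h = 2 * c - 2 * db
            if h <= 0:
                raise ValueError(f"{self.class_name} {c}:{db}: no hydrogens left on chains")
            chains = ElementalComposition({"C": c, "H": h, "O": 2 * self.n_chains})
            formula = self.backbone + chains - self.n_chains * _H2O
            for _ in range(self.n_ether):
                formula = formula + _ETHER_ADJUST_ADD - _ETHER_ADJUST_REMOVE
            return formula
        # sphingoid: LCB + N-acyl merged, amide bond already accounted for
        h = 2 * c + 1 - 2 * db
        if h <= 0:
            raise ValueError(f"{self.class_name} {c}:{db}: no hydrogens left on chains")
        core = ElementalComposition({"C": c, "H": h, "N": 1, "O": oh + 1})
        return self.backbone + core


@dataclass(frozen=True)
class LipidSpecies:
    """One sum-composition database row."""

    class_name: str
    c_index: int
    db_index: int
    oh_index: int
    formula: ElementalComposition
    mono_mass: float
    category: str
    species_name: str

    @property
    def key(self) -> tuple[str, int, int, int]:
        return (self.class_name, self.c_index, self.db_index, self.oh_index)


def annotate_species(
    class_name: str, c: int, db: int, oh: int = 0, sphingolipid: bool = False
) -> str:
    """Shorthand species name from indices (``PI 34:1``, ``SM 36:1;2``, ``PC O-34:1``)."""
    sep = "" if class_name.endswith("O-") else " "
    name = f"{class_name}{sep}{c}:{db}"
    if sphingolipid:
        name += f";{oh}"
    return name


def parse_annotation(name: str, class_names: Iterable[str]) -> tuple[str, int, int, int]:
    """Invert :func:`annotate_species` given the set of known class names.

    Returns ``(class_name, c, db, oh)``; ``oh`` is 0 when not annotated.
    Longest class-name match wins, so ``PC O-34:1`` resolves to class
    ``PC O-`` rather than ``PC``.
    """
    for class_name in sorted(class_names, key=len, reverse=True):
        if not name.startswith(class_name):
            continue
        rest = name[len(class_name) :].lstrip(" ")
        parts = rest.split(";")
        if len(parts) > 2 or ":" not in parts[0]:
            continue
        c_txt, db_txt = parts[0].split(":", 1)
        try:
            c, db = int(c_txt), int(db_txt)
            oh = int(parts[1]) if len(parts) == 2 else 0
        except ValueError:
            continue
        return class_name, c, db, oh
    raise ValueError(f"cannot parse species annotation {name!r}")


def enumerate_class(
    template: LipidClassTemplate,
    c_range: Sequence[int] | None = None,
    db_range: Sequence[int] | None = None,
    oh_range: Sequence[int] | None = None,
    max_db_per_c: float = 0.5,
) -> list[LipidSpecies]:
    """All species of a class over inclusive index ranges.

    Ranges default to the template's own; a (c, db) pair is kept only when
    ``db <= floor(c * max_db_per_c)`` (chemical sanity cap).
    """

    def _expand(rng: Sequence[int] | tuple[int, int]) -> range:
        lo, hi = rng
        return range(lo, hi + 1)

    cs = _expand(c_range if c_range is not None else template.c_range)
    dbs = _expand(db_range if db_range is not None else template.db_range)
    ohs = _expand(oh_range if oh_range is not None else template.oh_range)
    species: list[LipidSpecies] = []
    for c in cs:
        for db in dbs:
            if db > int(c * max_db_per_c):
                continue
            for oh in ohs:
                formula = template.formula_for(c, db, oh)
                species.append(
                    LipidSpecies(
                        class_name=template.class_name,
                        c_index=c,
                        db_index=db,
                        oh_index=oh,
                        formula=formula,
                        mono_mass=monoisotopic_mass(formula),
                        category=template.category,
                        species_name=annotate_species(
                            template.class_name, c, db, oh, template.is_sphingolipid
                        ),
                    )
                )
    return species


class LipidDatabase:
    """Collection of :class:`LipidSpecies` keyed by (class, c, db, oh).

    Also carries the class templates (for adduct lookup) and free-text display
    labels for internal-standard species, e.g. ``"TAG 17:1/17:1/17:1"`` →
    ``"TAG 51:3"``.
    """

    def __init__(
        self,
        templates: Mapping[str, LipidClassTemplate],
        species: Iterable[LipidSpecies],
        standard_labels: Mapping[str, str] | None = None,
        provenance: str = "",
    ) -> None:
        self.templates = dict(templates)
        self._by_key: dict[tuple[str, int, int, int], LipidSpecies] = {}
        self._by_name: dict[str, LipidSpecies] = {}
        for sp in species:
            if sp.key in self._by_key:
                raise ValueError(f"duplicate species key {sp.key}")
            self._by_key[sp.key] = sp
            self._by_name[sp.species_name] = sp
        self.standard_labels = dict(standard_labels or {})
        for label, name in self.standard_labels.items():
            if name not in self._by_name:
                raise ValueError(f"standard label {label!r} points at unknown species {name!r}")
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[LipidSpecies]:
        return iter(self._by_key.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name or name in self.standard_labels

    def get(self, name: str) -> LipidSpecies:
        """Look up by species name or internal-standard display label."""
        if name in self._by_name:
            return self._by_name[name]
        if name in self.standard_labels:
            return self._by_name[self.standard_labels[name]]
        raise KeyError(f"unknown species {name!r}")

    def adducts_for(self, class_name: str) -> list[Adduct]:
        template = self.templates[class_name]
        return [DEFAULT_ADDUCTS[a] for a in template.adducts]

    def classes(self) -> list[str]:
        return sorted(self.templates)

    # -- text persistence ---------------------------------------------------

    _COLUMNS = (
        "species_name",
        "class",
        "category",
        "c_index",
        "db_index",
        "oh_index",
        "formula",
        "mono_mass",
    )

    def save(self, directory: str | Path) -> None:
        """One tab-separated file per class plus an ``_index.tsv``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        by_class: dict[str, list[LipidSpecies]] = {}
        for sp in self:
            by_class.setdefault(sp.class_name, []).append(sp)
        for class_name, rows in sorted(by_class.items()):
            path = directory / f"{class_name.replace(' ', '_').replace('-', '')}.tsv"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("\t".join(self._COLUMNS) + "\n")
                for sp in sorted(rows, key=lambda s: s.key):
                    fh.write(
                        "\t".join(
                            (
                                sp.species_name,
                                sp.class_name,
                                sp.category,
                                str(sp.c_index),
                                str(sp.db_index),
                                str(sp.oh_index),
                                sp.formula.hill_formula(),
                                repr(sp.mono_mass),
                            )
                        )
                        + "\n"
                    )
        with open(directory / "_index.tsv", "w", encoding="utf-8") as fh:
            fh.write("label\tspecies_name\n")
            for label, name in sorted(self.standard_labels.items()):
                fh.write(f"{label}\t{name}\n")

    @classmethod
    def load(cls, directory: str | Path, templates: Mapping[str, LipidClassTemplate]) -> "LipidDatabase":
        directory = Path(directory)
        species: list[LipidSpecies] = []
        for path in sorted(directory.glob("*.tsv")):
            if path.name == "_index.tsv":
                continue
            with open(path, encoding="utf-8") as fh:
                header = fh.readline().rstrip("\n").split("\t")
                if tuple(header) != cls._COLUMNS:
                    raise ValueError(f"{path}: unexpected header {header}")
                for line in fh:
                    (name, class_name, category, c, db, oh, formula, mass) = line.rstrip(
                        "\n"
                    ).split("\t")
                    species.append(
                        LipidSpecies(
                            class_name=class_name,
                            c_index=int(c),
                            db_index=int(db),
                            oh_index=int(oh),
                            formula=parse_formula(formula),
                            mono_mass=float(mass),
                            category=category,
                            species_name=name,
                        )
                    )
        labels: dict[str, str] = {}
        index = directory / "_index.tsv"
        if index.exists():
            with open(index, encoding="utf-8") as fh:
                fh.readline()
                for line in fh:
                    label, name = line.rstrip("\n").split("\t")
                    labels[label] = name
        return cls(templates, species, labels, provenance=str(directory))


def load_class_config(path: str | Path | None = None) -> tuple[dict[str, LipidClassTemplate], dict[str, str]]:
    """Read class templates (and standard labels) from a YAML config.

    Defaults to the config shipped with the package.
    """
    if path is None:
        text = resources.files("lipidframe.data").joinpath("classes.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    templates: dict[str, LipidClassTemplate] = {}
    for name, cfg in raw["classes"].items():
        if name in templates:
            raise ValueError(f"duplicate class {name!r}")
        templates[name] = LipidClassTemplate(
            class_name=name,
            category=cfg["category"],
            backbone=parse_formula(cfg["backbone"]) if cfg.get("backbone") else ElementalComposition({}),
            n_chains=int(cfg.get("n_chains", 2)),
            chain_model=cfg.get("chain_model", "acyl"),
            adducts=tuple(cfg["adducts"]),
            c_range=tuple(cfg["c_range"]),
            db_range=tuple(cfg["db_range"]),
            oh_range=tuple(cfg.get("oh_range", (0, 0))),
            n_ether=int(cfg.get("n_ether", 0)),
        )
    labels = {str(k): str(v) for k, v in (raw.get("internal_standards") or {}).items()}
    return templates, labels


def build_database(
    config_path: str | Path | None = None, max_db_per_c: float = 0.5
) -> LipidDatabase:
    """Enumerate the full database from a class-template config."""
    templates, labels = load_class_config(config_path)
    species: list[LipidSpecies] = []
    for template in templates.values():
        species.extend(enumerate_class(template, max_db_per_c=max_db_per_c))
    return LipidDatabase(
        templates, species, labels, provenance=str(config_path or "lipidframe default config")
    )


_default_db: LipidDatabase | None = None


def default_database() -> LipidDatabase:
    """The database built from the shipped class config (cached)."""
    global _default_db
    if _default_db is None:
        _default_db = build_database()
    return _default_db
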