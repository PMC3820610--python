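"""Synthetic multiplexed profile-mode acquisitions with known ground truth.

The generator stands in for the mass spectrometer and the wet lab: it takes a
study design — samples with planted lipid amounts, internal-standard spikes,
per-acquisition calibration offsets, a peak shape and a noise model — and
produces the same folder-of-peak-lists layout a converted acquisition series
would have, together with ground-truth tables (planted amounts, true offsets,
sample metadata) for parameter-recovery testing.

Default design, mirroring a two-genotype, three-brain-region infusion series:
12 tissue samples plus 2 blanks, each analysed twice per polarity (56
acquisitions), positive mode multiplexing m/z 280–580 and 500–1200, negative
mode m/z 370–660 and 550–1700 — 112 averaged peak lists in 4 folders of 28.
One sample is deliberately generated without internal standards (its two
positive-mode injections are 07 and 08), and a background ion matching an
endogenous target (``PI 40:3``) is planted at equal intensity in samples and
blanks, so QC flagging and blank subtraction can be exercised end to end.

Peaks are Gaussian-shaped profile features on a fixed 0.0005 Da grid, with
sigma = m/z / (R · 2.3548) for a resolution R of 100,000 fwhm; spectra are
sparse (points only within ±0.02 Da of a planted ion), which leaves extraction
semantics untouched — a target with no bins in its window reports zero.
Apex intensity is proportional to planted amount (one response factor per
polarity); noise is multiplicative log-normal per peak and scan plus a small
additive floor on the planted windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import DEFAULT_ADDUCTS, ion_mz, parse_formula
from .database import LipidDatabase, default_database
from .quantify import load_is_spikes
from .spectra import AcquisitionSet, ProfileSpectrum, organize_acquisitions
from .targeting import FilterSpec, LockMassSpec, TargetList, generate_target_list

__all__ = [
    "SampleSpec",
    "ScanRange",
    "StudyDesign",
    "StudyResult",
    "SCAN_RANGES",
    "default_filter_specs",
    "default_target_lists",
    "default_study_design",
    "simulate_profile_spectrum",
    "simulate_study",
]

FWHM_FACTOR = 2.3548  # fwhm = FWHM_FACTOR * sigma for a Gaussian

#: Chemical-background lock ion always present in positive mode.
BACKGROUND_LOCK = LockMassSpec("tris(ditert-butylphenyl) phosphate", "+NH4", formula="C42H63O4P")


@dataclass(frozen=True)
class SampleSpec:
    name: str
    tissue: str = ""
    genotype: str = ""
    is_blank: bool = False
    has_is: bool = True  # False emulates a sample never spiked with standards


@dataclass(frozen=True)
class ScanRange:
    scan_range_id: str
    polarity: str
    low_mz: float
    high_mz: float


SCAN_RANGES: tuple[ScanRange, ...] = (
    ScanRange("+FTMS 280-580", "positive", 280.0, 580.0),
    ScanRange("+FTMS 500-1200", "positive", 500.0, 1200.0),
    ScanRange("-FTMS 370-660", "negative", 370.0, 660.0),
    ScanRange("-FTMS 550-1700", "negative", 550.0, 1700.0),
)

#: Lipid classes monitored per scan range (multiplexing boundaries are chosen
#: so each class and its standard fall in one range of the right polarity).
MONITORED_CLASSES: dict[str, tuple[str, ...]] = {
    "+FTMS 280-580": ("LPC", "LPC O-", "LPE"),
    "+FTMS 500-1200": ("SM", "Cer", "DAG", "PC", "PC O-", "PE", "PE O-", "TAG"),
    "-FTMS 370-660": ("LPA", "LPA O-", "LPS", "LPI"),
    "-FTMS 550-1700": ("PA", "PS", "PI", "PG", "SHexCer"),
}

#: Lock masses per scan range (internal standards and, in positive mode, the
#: ubiquitous chemical-background phosphate ion).
DEFAULT_LOCKS: dict[str, tuple[LockMassSpec, ...]] = {
    "+FTMS 280-580": (LockMassSpec("LPC O-17:0", "+H"),),
    "+FTMS 500-1200": (BACKGROUND_LOCK, LockMassSpec("TAG 17:1/17:1/17:1", "+NH4")),
    "-FTMS 370-660": (LockMassSpec("LPS 17:1 (IS)", "-H"),),
    "-FTMS 550-1700": (LockMassSpec("PI 17:0/20:4", "-H"),),
}

#: Endogenous species planted by the default design: base amount in pmol per
#: 10 µg-protein sample aliquot, scaled per tissue below.
DEFAULT_PLANTED: dict[str, float] = {
    "LPC 16:0": 40.0,
    "LPC 18:1": 25.0,
    "LPE 18:1": 12.0,
    "PC 32:0": 90.0,
    "PC 34:1": 150.0,
    "PE 38:4": 110.0,
    "PE 40:6": 95.0,
    "SM 36:1;2": 70.0,
    "DAG 36:1": 15.0,
    "TAG 52:2": 18.0,
    "LPS 18:0": 8.0,
    "LPS 22:6": 6.0,
    "PA 34:1": 20.0,
    "PS 36:1": 85.0,
    "PI 38:4": 75.0,
    "PG 34:1": 10.0,
    "SHexCer 36:1;2": 30.0,
}

#: Tissue-specific abundance multipliers (distinct regional signatures).
TISSUE_FACTORS: dict[str, dict[str, float]] = {
    "hippocampus": {"PE 38:4": 1.4, "LPS 18:0": 1.1},
    "s1bf": {"PE 40:6": 1.5, "LPS 18:0": 1.6, "LPS 22:6": 0.6},
    "cerebellum": {"PE 40:6": 1.3, "PC 34:1": 1.1, "LPS 22:6": 1.2},
}


@dataclass
class StudyDesign:
    """Everything the generator needs; defaults are the study conditions."""

    samples: list[SampleSpec]
    replicates: int = 2
    scan_ranges: tuple[ScanRange, ...] = SCAN_RANGES
    planted: dict[str, dict[str, float]] = field(default_factory=dict)  # species -> sample -> pmol
    background_intensity: dict[str, float] = field(default_factory=dict)  # species -> counts
    n_scans: int = 3
    grid_step: float = 0.0005
    resolution: float = 100_000.0
    response: float = 1.0e4  # apex counts per pmol
    chem_background_intensity: float = 5.0e5  # positive-mode phosphate lock ion
    noise_cv: float = 0.05
    noise_floor: float = 50.0
    offset_spec: object = ("linear", -0.002, 0.002)  # per-acquisition true offset, Da
    window_halfwidth: float = 0.02  # Da of profile kept around each planted ion

    def sigma_at(self, mz: float) -> float:
        return mz / (self.resolution * FWHM_FACTOR)

    def acquisition_ids(self, polarity: str) -> list[str]:
        """Injection-ordered acquisition ids for one polarity."""
        tag = "pos" if polarity == "positive" else "neg"
        ids = []
        injection = 0
        for sample in self.samples:
            for rep in range(1, self.replicates + 1):
                injection += 1
                ids.append(f"{tag}{injection:02d}_{sample.name}_r{rep}")
        return ids

    def sample_of(self, acquisition_id: str) -> SampleSpec:
        stem = acquisition_id.split("_", 1)[1].rsplit("_r", 1)[0]
        for sample in self.samples:
            if sample.name == stem:
                return sample
        raise KeyError(acquisition_id)


def default_study_design(
    tissues: Sequence[str] = ("cerebellum", "hippocampus", "s1bf"),
    genotypes: Sequence[str] = ("wt", "ko"),
    mice_per_group: int = 1,
    n_blanks: int = 2,
    replicates: int = 2,
    noise_cv: float = 0.05,
    no_is_sample: str | None = "cerebellum-ko-2",
    offset_spec: object = ("linear", -0.002, 0.002),
    n_scans: int = 3,
) -> StudyDesign:
    """The full default design: 3 tissues × 2 genotypes × 2 mice + 2 blanks.

    ``no_is_sample`` names the sample generated without internal standards
    (default: the second knockout cerebellum, whose positive-mode injections
    are 07 and 08 in injection order).
    """
    samples: list[SampleSpec] = []
    for tissue in tissues:
        for genotype in genotypes:
            for mouse in range(1, 2 * mice_per_group + 1):
                name = f"{tissue}-{genotype}-{mouse}"
                samples.append(
                    SampleSpec(
                        name=name,
                        tissue=tissue,
                        genotype=genotype,
                        has_is=(name != no_is_sample),
                    )
                )
    for b in range(1, n_blanks + 1):
        samples.append(SampleSpec(name=f"blank-{b}", is_blank=True))

    planted: dict[str, dict[str, float]] = {}
    for species, base in DEFAULT_PLANTED.items():
        per_sample: dict[str, float] = {}
        for sample in samples:
            if sample.is_blank:
                continue
            factor = TISSUE_FACTORS.get(sample.tissue, {}).get(species, 1.0)
            per_sample[sample.name] = base * factor
        planted[species] = per_sample

    return StudyDesign(
        samples=samples,
        replicates=replicates,
        planted=planted,
        background_intensity={"PI 40:3": 2.0e4},
        noise_cv=noise_cv,
        offset_spec=offset_spec,
        n_scans=n_scans,
    )


def default_filter_specs() -> dict[str, FilterSpec]:
    """Per-scan-range filters: monitored classes plus the range's lock ions."""
    return {
        r.scan_range_id: FilterSpec(
            classes=list(MONITORED_CLASSES[r.scan_range_id]),
            lock_masses=list(DEFAULT_LOCKS[r.scan_range_id]),
        )
        for r in SCAN_RANGES
    }


def default_target_lists(db: LipidDatabase | None = None) -> dict[str, TargetList]:
    """Compiled target lists for the four default scan ranges."""
    db = db or default_database()
    specs = default_filter_specs()
    return {
        r.scan_range_id: generate_target_list(
            db, specs[r.scan_range_id], r.scan_range_id, r.low_mz, r.high_mz
        )
        for r in SCAN_RANGES
    }


# ---------------------------------------------------------------------------


def _planted_ions(
    design: StudyDesign,
    sample: SampleSpec,
    scan_range: ScanRange,
    db: LipidDatabase,
    spikes: pd.DataFrame,
) -> list[tuple[float, float, str]]:
    """(ion m/z, apex intensity, species) planted in one sample × range."""
    ions: list[tuple[float, float, str]] = []

    def add(species_name: str, amount_counts: float) -> None:
        sp = db.get(species_name)
        adducts = [a for a in db.adducts_for(sp.class_name) if a.polarity == scan_range.polarity]
        if not adducts:
            return
        mz = ion_mz(sp.formula, adducts[0])
        if scan_range.low_mz <= mz <= scan_range.high_mz:
            ions.append((mz, amount_counts, sp.species_name))

    for species, per_sample in design.planted.items():
        amount = per_sample.get(sample.name, 0.0)
        if amount > 0:
            add(species, amount * design.response)
    if sample.has_is:
        seen: set[str] = set()
        for _, row in spikes.iterrows():
            label = row["standard_label"]
            if label in seen:
                continue
            seen.add(label)
            add(db.standard_labels[label], float(row["spike_pmol"]) * design.response)
    for species, intensity in design.background_intensity.items():
        add(species, intensity)
    if scan_range.polarity == "positive":
        mz = ion_mz(parse_formula("C42H63O4P"), DEFAULT_ADDUCTS["+NH4"])
        if scan_range.low_mz <= mz <= scan_range.high_mz:
            ions.append((mz, design.chem_background_intensity, BACKGROUND_LOCK.name))
    return ions


def _true_offsets(design: StudyDesign, polarity: str, rng: np.random.Generator) -> dict[str, float]:
    ids = design.acquisition_ids(polarity)
    spec = design.offset_spec
    if isinstance(spec, Mapping):
        return {acq: float(spec[acq]) for acq in ids}
    if isinstance(spec, (int, float)):
        return {acq: float(spec) for acq in ids}
    kind = spec[0]
    if kind == "linear":
        values = np.linspace(spec[1], spec[2], num=len(ids))
    elif kind == "uniform":
        values = rng.uniform(spec[1], spec[2], size=len(ids))
    else:
        raise ValueError(f"unknown offset spec {spec!r}")
    return dict(zip(ids, values))


def simulate_profile_spectrum(
    design: StudyDesign,
    ions: Sequence[tuple[float, float, str]],
    scan_range: ScanRange,
    delta: float,
    rng: np.random.Generator,
    acquisition_id: str,
) -> ProfileSpectrum:
    """One simulated scan: sparse Gaussian profile on the range's fixed grid.

    Every planted ion appears at ``ion m/z + delta`` (the acquisition's true
    calibration offset); per-peak amplitude is jittered log-normally with the
    design's CV and a uniform noise floor is laid over the kept windows.
    """
    step = design.grid_step
    low = scan_range.low_mz
    n_grid = int(np.floor((scan_range.high_mz - low) / step)) + 1
    contributions: dict[int, float] = {}
    window_idx: set[int] = set()
    for mz0, amplitude, _name in ions:
        center = mz0 + delta
        sigma = design.sigma_at(center)
        i_lo = max(0, int(np.ceil((center - design.window_halfwidth - low) / step)))
        i_hi = min(n_grid - 1, int(np.floor((center + design.window_halfwidth - low) / step)))
        if i_hi < i_lo:
            continue
        idx = np.arange(i_lo, i_hi + 1)
        x = low + idx * step
        if design.noise_cv > 0:
            amplitude = amplitude * float(np.exp(rng.normal(0.0, design.noise_cv)))
        values = amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        for i, v in zip(idx, values):
            contributions[int(i)] = contributions.get(int(i), 0.0) + float(v)
        window_idx.update(int(i) for i in idx)
    if not window_idx:
        # keep a token empty-but-valid trace so the file format holds
        sorted_idx = np.array([0, 1])
        intensity = np.zeros(2)
    else:
        sorted_idx = np.array(sorted(window_idx))
        intensity = np.array([contributions[i] for i in sorted_idx])
        if design.noise_floor > 0 and design.noise_cv > 0:
            intensity = intensity + rng.uniform(0.0, design.noise_floor, size=intensity.size)
    return ProfileSpectrum(
        low + sorted_idx * step,
        intensity,
        acquisition_id=acquisition_id,
        scan_range_id=scan_range.scan_range_id,
    )


@dataclass
class StudyResult:
    peaklist_dir: Path
    manifest: dict[str, list[str]]
    sample_info: pd.DataFrame
    truth_amounts: pd.DataFrame
    truth_offsets: pd.DataFrame


def simulate_study(
    design: StudyDesign,
    out_dir: str | Path,
    seed: int = 0,
    db: LipidDatabase | None = None,
    spikes: pd.DataFrame | None = None,
) -> StudyResult:
    """Generate the full acquisition tree plus ground-truth tables.

    Writes ``peaklists/<scan range>/<acquisition>.txt`` (averaged over the
    design's scans per range), ``sample_info.tsv``, ``truth_amounts.tsv`` and
    ``truth_offsets.tsv`` under ``out_dir``. Fully deterministic for a fixed
    seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db = db or default_database()
    spikes = spikes if spikes is not None else load_is_spikes()
    rng = np.random.default_rng(seed)

    aset = AcquisitionSet()
    offset_rows = []
    info_rows = []
    polarities = sorted({r.polarity for r in design.scan_ranges}, reverse=True)
    for polarity in polarities:  # positive first: injection series per polarity
        deltas = _true_offsets(design, polarity, rng)
        ranges = [r for r in design.scan_ranges if r.polarity == polarity]
        for acq_id in design.acquisition_ids(polarity):
            sample = design.sample_of(acq_id)
            info_rows.append(
                {
                    "acquisition_id": acq_id,
                    "sample_name": sample.name,
                    "tissue": sample.tissue,
                    "genotype": sample.genotype,
                    "replicate": int(acq_id.rsplit("_r", 1)[1]),
                    "polarity": polarity,
                    "is_blank": sample.is_blank,
                    "has_is": sample.has_is,
                }
            )
            for scan_range in ranges:
                ions = _planted_ions(design, sample, scan_range, db, spikes)
                for _scan in range(design.n_scans):
                    aset.add(
                        simulate_profile_spectrum(
                            design, ions, scan_range, deltas[acq_id], rng, acq_id
                        )
                    )
                offset_rows.append(
                    {
                        "acquisition_id": acq_id,
                        "scan_range_id": scan_range.scan_range_id,
                        "true_offset": deltas[acq_id],
                    }
                )

    peaklist_dir = out_dir / "peaklists"
    manifest = organize_acquisitions(aset, peaklist_dir)

    amount_rows = []
    for species, per_sample in design.planted.items():
        sp = db.get(species)
        for sample in design.samples:
            amount = per_sample.get(sample.name, 0.0)
            amount_rows.append(
                {
                    "sample_name": sample.name,
                    "species_name": sp.species_name,
                    "lipid_class": sp.class_name,
                    "amount_pmol": amount,
                    "amount_fmol": amount * 1000.0,
                }
            )
    sample_info = pd.DataFrame(info_rows)
    truth_amounts = pd.DataFrame(amount_rows)
    truth_offsets = pd.DataFrame(offset_rows)
    sample_info.to_csv(out_dir / "sample_info.tsv", sep="\t", index=False)
    truth_amounts.to_csv(out_dir / "truth_amounts.tsv", sep="\t", index=False)
    truth_offsets.to_csv(out_dir / "truth_offsets.tsv", sep="\t", index=False)
    return StudyResult(peaklist_dir, manifest, sample_info, truth_amounts, truth_offsets)
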