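"""Internal-standard quantification of the long-format result table.

The processing chain mirrors how direct-infusion lipidomics data is turned
into molar amounts: (1) join sample metadata onto the unified result table,
(2) drop sub-threshold intensities, (3) subtract the mean blank signal per
target, (4) optionally correct for intensity carried by heavy isotopologues,
(5) convert intensity to moles via the class-specific internal standard (IS),
(6) express amounts as mol% of a chosen universe per grouping cell.

Amount equation, per acquisition and lipid class::

    amount_fmol = corrected_intensity / IS_corrected_intensity * spike_pmol * 1000

Spikes are given in pmol (the convention of spike mixtures), amounts reported
in fmol. When an acquisition's IS shows no intensity — e.g. a sample that was
never spiked — amounts are *missing*, not zero: the sample cannot be
quantified but its rows are retained.

Internal-standard and lock-mass rows are exempt from blank subtraction: blanks
are spiked with the same IS mixture as samples, so subtracting the blank IS
signal would annihilate the denominators of the amount equation.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_sample_info",
    "load_is_spikes",
    "join_sample_info",
    "filter_intensity",
    "subtract_blank",
    "isotope_correct",
    "compute_amounts",
    "mol_percent",
    "quantify",
]


def read_sample_info(path: str | Path) -> pd.DataFrame:
    """Read the sample-information table (TSV/CSV, one row per acquisition).

    Requires ``acquisition_id`` (unique) and ``is_blank`` columns; any other
    columns (sample_name, tissue, genotype, replicate, ...) ride along as
    free attributes.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    info = pd.read_csv(path, sep=sep)
    return validate_sample_info(info)


def validate_sample_info(info: pd.DataFrame) -> pd.DataFrame:
    for col in ("acquisition_id", "is_blank"):
        if col not in info.columns:
            raise ValueError(f"sample info lacks required column {col!r}")
    if info["acquisition_id"].duplicated().any():
        dupes = info.loc[info["acquisition_id"].duplicated(), "acquisition_id"].tolist()
        raise ValueError(f"duplicate acquisition_id in sample info: {dupes}")
    info = info.copy()
    info["is_blank"] = info["is_blank"].astype(bool)
    return info


def load_is_spikes(path: str | Path | None = None) -> pd.DataFrame:
    """Internal-standard spike table: class, standard_label, spike_pmol.

    Defaults to the spike mixture shipped with the package. Every quantified
    class maps to exactly one standard; several classes may share one
    standard via explicit duplicate rows.
    """
    if path is None:
        text = resources.files("lipidframe.data").joinpath("is_spikes.tsv").read_text()
        from io import StringIO

        spikes = pd.read_csv(StringIO(text), sep="\t")
    else:
        spikes = pd.read_csv(path, sep="\t")
    required = {"class", "standard_label", "spike_pmol"}
    if not required.issubset(spikes.columns):
        raise ValueError(f"spike table needs columns {sorted(required)}")
    if (spikes["spike_pmol"] <= 0).any():
        raise ValueError("spike amounts must be positive")
    if spikes["class"].duplicated().any():
        raise ValueError("each class may map to exactly one standard")
    return spikes


def join_sample_info(table: pd.DataFrame, sample_info: pd.DataFrame) -> pd.DataFrame:
    """Append sample attributes to every result row; row count is preserved.

    Raises when the result table contains an acquisition the sample info does
    not know, naming the offenders.
    """
    sample_info = validate_sample_info(sample_info)
    unmatched = set(table["acquisition_id"]) - set(sample_info["acquisition_id"])
    if unmatched:
        raise ValueError(f"acquisitions missing from sample info: {sorted(unmatched)}")
    return table.merge(sample_info, on="acquisition_id", how="left", validate="many_to_one")


def filter_intensity(table: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Remove rows with intensity strictly below the threshold.

    A threshold of 0 removes nothing (zero-intensity rows survive; they carry
    the information that a target was searched and not found).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return table[table["intensity"] >= threshold].reset_index(drop=True)


def subtract_blank(table: pd.DataFrame) -> pd.DataFrame:
    """Blank-based background subtraction per (species, adduct, rangeID).

    ``corrected_intensity = max(0, intensity − mean blank intensity)`` for
    endogenous targets; internal-standard and lock-mass rows keep their raw
    intensity (blanks carry the same spike). Blank rows are retained and
    flagged ``blank_consumed``. Without any blanks the table passes through
    unchanged (with a warning).
    """
    table = table.copy()
    if "is_blank" not in table.columns:
        raise ValueError("run join_sample_info first: is_blank column required")
    key = ["species_name", "adduct"]
    if "rangeID" in table.columns:
        key.append("rangeID")
    blanks = table[table["is_blank"]]
    table["blank_consumed"] = table["is_blank"]
    if blanks.empty:
        warnings.warn("no blank acquisitions found; corrected_intensity = intensity")
        table["corrected_intensity"] = table["intensity"]
        return table
    blank_mean = blanks.groupby(key)["intensity"].mean().rename("blank_mean_intensity")
    table = table.merge(blank_mean, on=key, how="left")
    table["blank_mean_intensity"] = table["blank_mean_intensity"].fillna(0.0)
    corrected = np.maximum(0.0, table["intensity"] - table["blank_mean_intensity"])
    exempt = table["is_internal_standard"] | table["is_lock_mass"]
    table["corrected_intensity"] = np.where(exempt, table["intensity"], corrected)
    return table


def isotope_correct(table: pd.DataFrame, mode: str = "none") -> pd.DataFrame:
    """Correct intensities for the signal carried by heavy isotopologues.

    ``type2`` divides by the monoisotopic (M+0) fraction, restoring the total
    species signal from its monoisotopic peak; ``none`` is the identity.
    """
    if mode not in ("none", "type2"):
        raise ValueError(f"unknown isotope-correction mode {mode!r}")
    table = table.copy()
    base = table["corrected_intensity"] if "corrected_intensity" in table.columns else table["intensity"]
    if mode == "none":
        table["corrected_intensity"] = base
        return table
    m0 = table["isotope_m0"]
    if (m0 <= 0).any():
        bad = table.loc[m0 <= 0, "species_name"].unique().tolist()
        raise ValueError(f"non-positive M+0 fraction for {bad}")
    table["corrected_intensity"] = base / m0
    return table


def compute_amounts(
    table: pd.DataFrame,
    spikes: pd.DataFrame | None = None,
    standard_species: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Convert intensities to molar amounts via class-specific standards.

    ``spikes`` maps lipid class → (standard display label, spiked pmol);
    ``standard_species`` resolves display labels to sum-composition species
    names (defaults to the shipped database's label table). Per acquisition
    and class the IS denominator is the standard species' corrected
    intensity; a zero or absent denominator yields missing amounts for that
    acquisition × class, with the rows retained. Classes present in the table
    but absent from the spike table are an error (lock-only rows excepted).
    """
    if spikes is None:
        spikes = load_is_spikes()
    if standard_species is None:
        from .database import default_database

        standard_species = default_database().standard_labels
    table = table.copy()
    if "corrected_intensity" not in table.columns:
        table["corrected_intensity"] = table["intensity"]

    lipid_mask = table["lipid_class"] != "(lock)"
    needed = set(table.loc[lipid_mask, "lipid_class"].unique())
    have = set(spikes["class"])
    missing = needed - have
    if missing:
        raise ValueError(f"no internal-standard spike defined for classes: {sorted(missing)}")

    spike_by_class: dict[str, tuple[str, float]] = {}
    for _, row in spikes.iterrows():
        label = row["standard_label"]
        if label not in standard_species:
            raise ValueError(f"spike table references unknown standard label {label!r}")
        spike_by_class[row["class"]] = (standard_species[label], float(row["spike_pmol"]))

    # IS denominator per (acquisition, standard species): max over ranges in
    # case a standard is monitored in more than one multiplexed range.
    is_rows = table[table["is_internal_standard"]]
    denom = (
        is_rows.groupby(["acquisition_id", "species_name"])["corrected_intensity"].max()
        if not is_rows.empty
        else pd.Series(dtype=float)
    )

    std_name = table["lipid_class"].map(lambda c: spike_by_class.get(c, (None, np.nan))[0])
    spike_pmol = table["lipid_class"].map(lambda c: spike_by_class.get(c, (None, np.nan))[1])
    keys = list(zip(table["acquisition_id"], std_name))
    is_intensity = np.array([denom.get(k, np.nan) for k in keys], dtype=float)
    is_intensity[is_intensity <= 0] = np.nan

    table["is_species"] = std_name
    table["is_intensity"] = is_intensity
    table["spike_pmol"] = spike_pmol
    amount_pmol = table["corrected_intensity"] / is_intensity * spike_pmol
    table["amount_fmol"] = amount_pmol * 1000.0
    table.loc[~lipid_mask, "amount_fmol"] = np.nan
    return table


def mol_percent(
    table: pd.DataFrame,
    grouping: Sequence[str],
    universe: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> pd.DataFrame:
    """mol% of each row's amount within its grouping cell.

    ``grouping`` names the columns defining a cell (typically the
    acquisition, or sample × replicate); ``universe`` selects the rows whose
    amounts form the denominator (default: endogenous lipid rows with a
    present amount — internal standards and lock masses excluded). Rows
    outside the universe get no mol% value; a zero denominator yields missing
    values with a warning. Within each cell the universe's mol% sums to 100.
    """
    table = table.copy()
    if "amount_fmol" not in table.columns:
        raise ValueError("run compute_amounts first: amount_fmol column required")
    if universe is None:
        mask = (
            ~table["is_internal_standard"]
            & ~table["is_lock_mass"]
            & table["amount_fmol"].notna()
        )
        if "is_blank" in table.columns:
            mask &= ~table["is_blank"]
    elif callable(universe):
        mask = universe(table).astype(bool)
    else:
        mask = pd.Series(universe, index=table.index).astype(bool)
    mask &= table["amount_fmol"].notna()

    table["mol_percent"] = np.nan
    sub = table[mask]
    totals = sub.groupby(list(grouping))["amount_fmol"].transform("sum")
    if (totals <= 0).any():
        warnings.warn("zero total amount in at least one grouping cell; mol% left missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(totals > 0, sub["amount_fmol"] / totals * 100.0, np.nan)
    table.loc[mask, "mol_percent"] = values
    return table


def quantify(
    table: pd.DataFrame,
    sample_info: pd.DataFrame,
    spikes: pd.DataFrame | None = None,
    standard_species: Mapping[str, str] | None = None,
    intensity_threshold: float = 0.0,
    blank_subtraction: bool = True,
    isotope_mode: str = "none",
) -> pd.DataFrame:
    """The full processing chain from unified table to amounts.

    Order: join → intensity filter → blank subtraction → isotope correction
    → amount computation. Returns the augmented long-format table.
    """
    out = join_sample_info(table, sample_info)
    out = filter_intensity(out, intensity_threshold)
    if blank_subtraction:
        out = subtract_blank(out)
    out = isotope_correct(out, isotope_mode)
    return compute_amounts(out, spikes, standard_species)
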