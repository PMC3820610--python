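"""Targeted identification: lock-mass offset estimation, windowed peak
extraction and multi-range unification.

Calibration of a high-resolution survey scan drifts over an infusion series;
the measured m/z of a known ion can sit a few mDa away from its theoretical
value. The offset is estimated per acquisition (and per scan range) from lock
masses — ubiquitous ions of known composition — by locating each lock's apex
bin, refining it to a centroid with a three-point quadratic interpolation, and
averaging ``centroid − theoretical`` over the locks that were detected.

Lipid targets are then extracted with the offset applied to the *theoretical*
m/z: within a closed tolerance window around the adjusted m/z (±0.0020 Da by
default, matching 100,000 fwhm resolution) the maximum profile intensity is
reported together with its m/z bin value (no centroiding for lipid targets —
only lock masses are centroided), and a trapezoidal peak area over the window.
A row is emitted for *every* target, with zero intensity when no profile bin
falls inside the window, so downstream tables stay dense and aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import ProfileSpectrum, read_peaklist
from .targeting import TargetEntry, TargetList

__all__ = [
    "LockMassResult",
    "OffsetEstimate",
    "RESULT_COLUMNS",
    "centroid_quadratic",
    "estimate_lock_offset",
    "extract_targets",
    "extract_folder",
    "unify",
    "qc_lockmass",
    "offsets_to_frame",
]

#: Default identification tolerance (Da); suits ~100,000 fwhm resolution.
DEFAULT_TOLERANCE = 0.0020
#: Default half-width (Da) of the lock-mass apex search window. Deliberately
#: wider than the identification tolerance so locks are found even when the
#: drift exceeds the tolerance itself.
DEFAULT_LOCK_WINDOW = 0.01


def centroid_quadratic(
    p0: tuple[float, float], p1: tuple[float, float], p2: tuple[float, float]
) -> float:
    """Vertex abscissa of the parabola through three (m/z, intensity) points.

    Handles non-uniform spacing. Raises when the points have no downward
    curvature (flat or valley-shaped triplet): no apex to interpolate.
    """
    x0, y0 = p0
    x1, y1 = p1
    x2, y2 = p2
    if not (x0 < x1 < x2):
        raise ValueError("points must have strictly increasing abscissae")
    d1 = (y1 - y0) / (x1 - x0)
    d2 = (y2 - y1) / (x2 - x1)
    curvature = (d2 - d1) / (x2 - x0)
    if curvature >= 0:
        raise ValueError("no apex: triplet has no downward curvature")
    return 0.5 * (x0 + x1) - d1 / (2.0 * curvature)


@dataclass(frozen=True)
class LockMassResult:
    """Outcome of locating one lock-mass ion in one spectrum."""

    acquisition_id: str
    lock_name: str
    theoretical_mz: float
    centroid_mz: float | None
    offset: float | None  # centroid - theoretical, Da
    apex_intensity: float

    @property
    def detected(self) -> bool:
        return self.offset is not None


@dataclass
class OffsetEstimate:
    """Combined calibration offset for one acquisition × scan range."""

    acquisition_id: str
    scan_range_id: str
    locks: list[LockMassResult] = field(default_factory=list)
    combined_offset: float | None = None
    mode: str = "automatic"

    @property
    def value(self) -> float:
        """Offset to apply to theoretical m/z (0 when nothing was detected)."""
        return 0.0 if self.combined_offset is None else self.combined_offset


def estimate_lock_offset(
    spectrum: ProfileSpectrum,
    locks: Sequence[TargetEntry],
    search_window: float = DEFAULT_LOCK_WINDOW,
    min_intensity: float = 0.0,
) -> OffsetEstimate:
    """Estimate the calibration offset of one spectrum from its lock masses.

    Per lock: the apex bin within ``theoretical_mz ± search_window`` is
    refined by quadratic interpolation with its two neighbours; the per-lock
    offset is ``centroid − theoretical``. Locks with no bins in the window,
    an apex below ``min_intensity`` (or zero), a window-edge apex or a
    degenerate triplet are recorded as missing — missing locks are data, not
    errors. The combined offset is the unweighted mean (in Da) of the per-lock
    offsets that are present, or missing when none is.
    """
    if search_window <= 0:
        raise ValueError("search_window must be > 0")
    results: list[LockMassResult] = []
    mz, inten = spectrum.mz, spectrum.intensity
    for lock in locks:
        theo = lock.theoretical_mz
        lo = int(np.searchsorted(mz, theo - search_window, side="left"))
        hi = int(np.searchsorted(mz, theo + search_window, side="right"))
        centroid: float | None = None
        apex_intensity = 0.0
        if hi > lo:
            apex = lo + int(np.argmax(inten[lo:hi]))
            apex_intensity = float(inten[apex])
            if apex_intensity > 0 and apex_intensity >= min_intensity:
                if 0 < apex < len(mz) - 1:
                    try:
                        centroid = centroid_quadratic(
                            (mz[apex - 1], inten[apex - 1]),
                            (mz[apex], inten[apex]),
                            (mz[apex + 1], inten[apex + 1]),
                        )
                    except ValueError:
                        centroid = None
        results.append(
            LockMassResult(
                acquisition_id=spectrum.acquisition_id,
                lock_name=lock.species_name,
                theoretical_mz=theo,
                centroid_mz=centroid,
                offset=None if centroid is None else centroid - theo,
                apex_intensity=apex_intensity,
            )
        )
    present = [r.offset for r in results if r.offset is not None]
    combined = float(np.mean(present)) if present else None
    return OffsetEstimate(
        acquisition_id=spectrum.acquisition_id,
        scan_range_id=spectrum.scan_range_id,
        locks=results,
        combined_offset=combined,
        mode="automatic",
    )


RESULT_COLUMNS = [
    "acquisition_id",
    "scan_range_id",
    "species_name",
    "adduct",
    "intensity",
    "peak_area",
    "measured_mz",
    "theoretical_mz",
    "adjusted_mz",
    "delta_mz",
    "delta_ppm",
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
]


def _resolve_offset(
    spectrum: ProfileSpectrum,
    targets: TargetList,
    offset: str | float | OffsetEstimate,
    locks: Sequence[TargetEntry] | None,
    search_window: float,
    min_intensity: float,
) -> tuple[float, OffsetEstimate | None]:
    if isinstance(offset, OffsetEstimate):
        return offset.value, offset
    if isinstance(offset, (int, float)):
        return float(offset), None
    if offset == "none":
        return 0.0, None
    if offset == "auto":
        lock_entries = list(locks) if locks is not None else targets.locks
        estimate = estimate_lock_offset(spectrum, lock_entries, search_window, min_intensity)
        return estimate.value, estimate
    raise ValueError(f"offset must be 'none', 'auto', a number or an OffsetEstimate, got {offset!r}")


def extract_targets(
    spectrum: ProfileSpectrum,
    targets: TargetList,
    tolerance: float = DEFAULT_TOLERANCE,
    offset: str | float | OffsetEstimate = "none",
    locks: Sequence[TargetEntry] | None = None,
    search_window: float = DEFAULT_LOCK_WINDOW,
    min_intensity: float = 0.0,
) -> pd.DataFrame:
    """Extract every target from one averaged profile spectrum.

    Returns a long-format table with one row per target (see
    ``RESULT_COLUMNS``). ``offset`` is ``"none"``, a constant in Da,
    ``"auto"`` (lock-mass estimation on this spectrum) or a precomputed
    :class:`OffsetEstimate`. Ties on the window maximum report the lowest m/z
    bin; targets with no bins in the window get intensity 0 and missing
    measured m/z.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    offset_value, _ = _resolve_offset(
        spectrum, targets, offset, locks, search_window, min_intensity
    )
    mz, inten = spectrum.mz, spectrum.intensity
    rows = []
    for e in targets.entries:
        adjusted = e.theoretical_mz + offset_value
        lo = int(np.searchsorted(mz, adjusted - tolerance, side="left"))
        hi = int(np.searchsorted(mz, adjusted + tolerance, side="right"))
        if hi > lo:
            apex = lo + int(np.argmax(inten[lo:hi]))  # first max -> lowest m/z
            intensity = float(inten[apex])
            measured = float(mz[apex])
            delta = measured - adjusted
            ppm = delta / measured * 1e6
            area = float(np.trapezoid(inten[lo:hi], mz[lo:hi])) if hi - lo >= 2 else 0.0
        else:
            intensity, measured, delta, ppm, area = 0.0, math.nan, math.nan, math.nan, 0.0
        rows.append(
            (
                spectrum.acquisition_id,
                spectrum.scan_range_id,
                e.species_name,
                e.adduct,
                intensity,
                area,
                measured,
                e.theoretical_mz,
                adjusted,
                delta,
                ppm,
                e.lipid_class,
                e.category,
                e.c_index,
                e.db_index,
                e.oh_index,
                e.formula.hill_formula(),
                e.mono_mass,
                e.is_internal_standard,
                e.is_lock_mass,
                e.isotope_m0,
                e.isotope_m1,
                e.isotope_m2,
            )
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def extract_folder(
    folder: str | Path,
    targets: TargetList,
    tolerance: float = DEFAULT_TOLERANCE,
    offset: str | float = "auto",
    search_window: float = DEFAULT_LOCK_WINDOW,
    min_intensity: float = 0.0,
) -> tuple[pd.DataFrame, list[OffsetEstimate]]:
    """Run extraction over every peak-list ``.txt`` in one scan-range folder.

    Files are processed in name order (the injection order when acquisitions
    are named sequentially). Returns the concatenated result table and the
    per-acquisition offset estimates (empty when ``offset`` is not ``"auto"``).
    """
    folder = Path(folder)
    frames: list[pd.DataFrame] = []
    estimates: list[OffsetEstimate] = []
    paths = sorted(folder.glob("*.txt"))
    if not paths:
        raise ValueError(f"no peak-list .txt files in {folder}")
    for path in paths:
        spectrum = read_peaklist(path, scan_range_id=targets.scan_range_id)
        if offset == "auto":
            estimate = estimate_lock_offset(spectrum, targets.locks, search_window, min_intensity)
            estimates.append(estimate)
            frames.append(extract_targets(spectrum, targets, tolerance, estimate))
        else:
            frames.append(extract_targets(spectrum, targets, tolerance, offset))
    return pd.concat(frames, ignore_index=True), estimates


def unify(range_outputs: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-scan-range result tables into the long 'database table'.

    Adds a ``rangeID`` column copied from each table's ``scan_range_id``.
    All inputs must share an identical column set.
    """
    tables = list(range_outputs)
    if not tables:
        raise ValueError("need at least one table to unify")
    columns = list(tables[0].columns)
    for i, t in enumerate(tables[1:], start=2):
        if list(t.columns) != columns:
            raise ValueError(f"column-set mismatch between table 1 and table {i}")
    out = pd.concat(tables, ignore_index=True)
    out["rangeID"] = out["scan_range_id"]
    return out


def offsets_to_frame(estimates: Iterable[OffsetEstimate]) -> pd.DataFrame:
    """Flatten offset estimates to one row per (acquisition × lock)."""
    rows = []
    for est in estimates:
        for lock in est.locks:
            rows.append(
                (
                    est.acquisition_id,
                    est.scan_range_id,
                    lock.lock_name,
                    lock.theoretical_mz,
                    lock.centroid_mz,
                    lock.offset,
                    lock.apex_intensity,
                    lock.detected,
                    est.combined_offset,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "acquisition_id",
            "scan_range_id",
            "lock_name",
            "theoretical_mz",
            "centroid_mz",
            "offset",
            "apex_intensity",
            "detected",
            "combined_offset",
        ],
    )


def qc_lockmass(
    estimates: Iterable[OffsetEstimate],
    injection_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Lock-mass QC table: offset and intensity per injection, missing flags.

    One row per (acquisition × lock), with an ``injection`` index taken from
    ``injection_order`` (explicit acquisition-id sequence) or from the sorted
    acquisition ids. A lock that was not detected in an injection is flagged
    (``missing == True``) — the classic symptom of a sample that was never
    spiked with internal standards.
    """
    frame = offsets_to_frame(estimates)
    if injection_order is None:
        injection_order = sorted(frame["acquisition_id"].unique())
    order = {acq: i + 1 for i, acq in enumerate(injection_order)}
    unknown = set(frame["acquisition_id"]) - set(order)
    if unknown:
        raise ValueError(f"acquisitions missing from injection_order: {sorted(unknown)}")
    frame.insert(1, "injection", frame["acquisition_id"].map(order))
    frame["missing"] = ~frame["detected"]
    return frame.sort_values(["injection", "lock_name"], ignore_index=True)
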