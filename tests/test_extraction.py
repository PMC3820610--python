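"""Quadratic centroiding, lock-mass offsets, windowed extraction, unification."""

import math

import numpy as np
import pandas as pd
import pytest

from lipidframe.chemistry import parse_formula
from lipidframe.database import default_database
from lipidframe.extraction import (
    centroid_quadratic,
    estimate_lock_offset,
    extract_targets,
    qc_lockmass,
    unify,
)
from lipidframe.spectra import ProfileSpectrum
from lipidframe.targeting import FilterSpec, LockMassSpec, generate_target_list

DB = default_database()


class TestCentroidQuadratic:
    def test_symmetric_triplet(self):
        assert centroid_quadratic((1, 1), (2, 4), (3, 1)) == pytest.approx(2.0)

    def test_general_parabola_vertex(self):
        # y = -x^2 + 4x: vertex at x = 2
        assert centroid_quadratic((0, 0), (1, 3), (2, 4)) == pytest.approx(2.0)

    def test_flat_triplet_has_no_apex(self):
        with pytest.raises(ValueError, match="no apex"):
            centroid_quadratic((0, 1), (1, 1), (2, 1))

    def test_random_parabolas_recover_vertex(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = -rng.uniform(0.5, 5.0)
            v = rng.uniform(-3, 3)
            c = rng.uniform(0, 10)
            xs = np.sort(rng.uniform(-5, 5, size=3))
            if len(set(xs)) < 3:
                continue
            ys = a * (xs - v) ** 2 + c
            got = centroid_quadratic((xs[0], ys[0]), (xs[1], ys[1]), (xs[2], ys[2]))
            assert got == pytest.approx(v, abs=1e-9)


def _lock_targets():
    spec = FilterSpec(
        classes=[],
        lock_masses=[
            LockMassSpec("phosphate background", "+NH4", formula="C42H63O4P"),
            LockMassSpec("TAG 17:1/17:1/17:1", "+NH4"),
        ],
    )
    return generate_target_list(DB, spec, "+FTMS 500-1200", 500, 1200)


def _peak_on_local_grid(center, amp, sigma=0.003, step=0.0005, half=20):
    """Gaussian sampled on a grid that contains `center` exactly, so the
    three-point quadratic centroid lands on `center` by symmetry."""
    offsets = np.arange(-half, half + 1) * step
    return center + offsets, amp * np.exp(-0.5 * (offsets / sigma) ** 2)


def _spectrum_with_peaks(peaks, acq="inj01"):
    mz = np.concatenate([p[0] for p in peaks])
    inten = np.concatenate([p[1] for p in peaks])
    order = np.argsort(mz)
    return ProfileSpectrum(mz[order], inten[order], acq, "+FTMS 500-1200")


class TestLockMassOffset:
    def test_known_measured_positions_reproduce_printed_offsets(self):
        """Locks measured at 680.47945 / 860.76889 give per-lock offsets
        -0.00077 / -0.00128 and a combined offset of -0.0010 (4 decimals)."""
        targets = _lock_targets()
        spectrum = _spectrum_with_peaks(
            [_peak_on_local_grid(680.47945, 5e5), _peak_on_local_grid(860.76889, 2e6)]
        )
        est = estimate_lock_offset(spectrum, targets.locks)
        offsets = {r.lock_name: round(r.offset, 5) for r in est.locks}
        assert offsets == {"phosphate background": -0.00077, "TAG 51:3": -0.00128}
        assert round(est.combined_offset, 4) == -0.0010

    def test_no_signal_marks_all_locks_missing(self):
        targets = _lock_targets()
        spectrum = ProfileSpectrum(
            np.array([500.0, 500.0005, 500.001]), np.zeros(3), "inj07", "+FTMS 500-1200"
        )
        est = estimate_lock_offset(spectrum, targets.locks)
        assert est.combined_offset is None
        assert all(not r.detected for r in est.locks)

    def test_min_intensity_threshold_excludes_weak_locks(self):
        targets = _lock_targets()
        spectrum = _spectrum_with_peaks(
            [_peak_on_local_grid(680.47945, 100.0), _peak_on_local_grid(860.76889, 2e6)]
        )
        est = estimate_lock_offset(spectrum, targets.locks, min_intensity=1000.0)
        detected = {r.lock_name for r in est.locks if r.detected}
        assert detected == {"TAG 51:3"}


def _pc_target_list():
    spec = FilterSpec(classes=["PC"], c_range=(32, 32), db_range=(0, 0))
    return generate_target_list(DB, spec, "+FTMS 500-1200", 500, 1200)


class TestExtractTargets:
    def test_max_intensity_and_bin_value_reported(self):
        """A peak with apex bin at 734.56872 against offset-adjusted PC 32:0."""
        targets = _pc_target_list()
        spectrum = _spectrum_with_peaks([_peak_on_local_grid(734.56872, 5.0e6)])
        rows = extract_targets(spectrum, targets, tolerance=0.0020, offset=-0.0010)
        row = rows.iloc[0]
        assert row.intensity == pytest.approx(5.0e6)
        assert row.measured_mz == pytest.approx(734.56872, abs=1e-9)
        assert round(row.delta_mz, 5) == 0.00029
        assert row.peak_area > 0

    def test_row_emitted_for_every_target_even_without_signal(self):
        targets = _lock_targets()
        spectrum = _spectrum_with_peaks([_peak_on_local_grid(680.47945, 5e5)])
        rows = extract_targets(spectrum, targets, offset="none")
        assert len(rows) == len(targets)
        empty = rows[rows.species_name == "TAG 51:3"].iloc[0]
        assert empty.intensity == 0.0
        assert math.isnan(empty.measured_mz)

    def test_tie_breaks_to_lower_mz(self):
        targets = _pc_target_list()
        theo = targets.entries[0].theoretical_mz
        mz = np.array([theo - 0.001, theo, theo + 0.001])
        inten = np.array([7.0, 7.0, 3.0])
        rows = extract_targets(ProfileSpectrum(mz, inten, "a", "+FTMS 500-1200"), targets)
        assert rows.iloc[0].measured_mz == pytest.approx(theo - 0.001)

    def test_auto_offset_uses_lock_masses(self):
        spec = FilterSpec(
            classes=["PC"],
            c_range=(32, 32),
            db_range=(0, 0),
            lock_masses=[LockMassSpec("phosphate background", "+NH4", formula="C42H63O4P")],
        )
        targets = generate_target_list(DB, spec, "+FTMS 500-1200", 500, 1200)
        delta = -0.0015
        pc = [e for e in targets.entries if e.species_name == "PC 32:0"][0]
        spectrum = _spectrum_with_peaks(
            [
                _peak_on_local_grid(680.48022 + delta, 5e5),
                _peak_on_local_grid(pc.theoretical_mz + delta, 1e6),
            ]
        )
        rows = extract_targets(spectrum, targets, offset="auto")
        row = rows[rows.species_name == "PC 32:0"].iloc[0]
        assert row.adjusted_mz == pytest.approx(pc.theoretical_mz + delta, abs=5e-6)
        assert abs(row.delta_mz) < 5e-6

    def test_empty_spectrum_rejected(self):
        targets = _pc_target_list()
        with pytest.raises(ValueError):
            extract_targets(
                ProfileSpectrum(np.array([]), np.array([]), "a", "r"), targets
            )


class TestUnify:
    def _frame(self, n, rng):
        return pd.DataFrame(
            {"scan_range_id": [rng] * n, "species_name": [f"s{i}" for i in range(n)], "intensity": 1.0}
        )

    def test_row_conservation_and_range_id(self):
        out = unify([self._frame(10, "A"), self._frame(15, "B")])
        assert len(out) == 25
        assert set(out.rangeID) == {"A", "B"}

    def test_single_table_gets_range_id(self):
        out = unify([self._frame(3, "A")])
        assert list(out.rangeID) == ["A"] * 3

    def test_column_mismatch_rejected(self):
        a = self._frame(2, "A")
        b = self._frame(2, "B").rename(columns={"intensity": "other"})
        with pytest.raises(ValueError, match="mismatch"):
            unify([a, b])


def test_qc_lockmass_flags_missing_locks():
    targets = _lock_targets()
    estimates = []
    for i in range(1, 5):
        if i in (3, 4):  # injections without the IS lock
            peaks = [_peak_on_local_grid(680.47945, 5e5)]
        else:
            peaks = [_peak_on_local_grid(680.47945, 5e5), _peak_on_local_grid(860.76889, 2e6)]
        spectrum = _spectrum_with_peaks(peaks, acq=f"inj{i:02d}")
        estimates.append(estimate_lock_offset(spectrum, targets.locks))
    qc = qc_lockmass(estimates)
    missing = qc[qc.missing]
    assert set(missing.acquisition_id) == {"inj03", "inj04"}
    assert set(missing.lock_name) == {"TAG 51:3"}
    assert list(qc.injection.unique()) == [1, 2, 3, 4]
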