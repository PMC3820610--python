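"""Sample joins, filtering, blank subtraction, isotope correction, amounts, mol%."""

import numpy as np
import pandas as pd
import pytest

from lipidframe.chemistry import isotope_envelope, parse_formula
from lipidframe.quantify import (
    compute_amounts,
    filter_intensity,
    isotope_correct,
    join_sample_info,
    load_is_spikes,
    mol_percent,
    subtract_blank,
)


def _table(rows):
    defaults = dict(
        acquisition_id="a1",
        species_name="PC 34:1",
        adduct="+H",
        lipid_class="PC",
        rangeID="+FTMS 500-1200",
        intensity=1000.0,
        is_internal_standard=False,
        is_lock_mass=False,
        isotope_m0=0.6,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


def _info(acqs, blanks=()):
    return pd.DataFrame(
        {
            "acquisition_id": acqs,
            "sample_name": [a.split("_")[0] for a in acqs],
            "is_blank": [a in blanks for a in acqs],
        }
    )


class TestJoinSampleInfo:
    def test_row_count_preserved_and_columns_appended(self):
        t = _table([{"acquisition_id": f"a{i % 4}"} for i in range(100)])
        out = join_sample_info(t, _info(["a0", "a1", "a2", "a3"]))
        assert len(out) == 100
        assert "sample_name" in out.columns

    def test_unknown_acquisition_named_in_error(self):
        t = _table([{"acquisition_id": "mystery"}])
        with pytest.raises(ValueError, match="mystery"):
            join_sample_info(t, _info(["a1"]))

    def test_projection_recovers_input(self):
        t = _table([{"acquisition_id": "a1"}, {"acquisition_id": "a2"}])
        out = join_sample_info(t, _info(["a1", "a2"]))
        pd.testing.assert_frame_equal(out[t.columns], t)


class TestFilterIntensity:
    def test_zero_threshold_removes_nothing(self):
        t = _table([{"intensity": 0.0}, {"intensity": 5.0}])
        assert len(filter_intensity(t, 0.0)) == 2

    def test_all_below_threshold_empties_table(self):
        t = _table([{"intensity": 1.0}, {"intensity": 2.0}])
        assert len(filter_intensity(t, 10.0)) == 0

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(3)
        intensities = rng.uniform(0, 100, size=200)
        t = _table([{"intensity": float(v), "acquisition_id": f"a{i}"} for i, v in enumerate(intensities)])
        for threshold in (0.0, 10.0, 50.0, 99.9):
            expected = int(sum(1 for v in intensities if v >= threshold))
            assert len(filter_intensity(t, threshold)) == expected


class TestSubtractBlank:
    def _joined(self, sample_int, blank_int, **kw):
        rows = [
            {"acquisition_id": "s1", "intensity": sample_int, **kw},
            {"acquisition_id": "b1", "intensity": blank_int, **kw},
        ]
        return join_sample_info(_table(rows), _info(["s1", "b1"], blanks=("b1",)))

    def test_sample_equal_to_blank_mean_is_zeroed(self):
        out = subtract_blank(self._joined(1000.0, 1000.0))
        assert out[out.acquisition_id == "s1"].corrected_intensity.iloc[0] == 0.0

    def test_blank_exceeding_sample_floors_at_zero(self):
        out = subtract_blank(self._joined(500.0, 1000.0))
        assert out[out.acquisition_id == "s1"].corrected_intensity.iloc[0] == 0.0

    def test_internal_standards_exempt(self):
        out = subtract_blank(self._joined(1000.0, 1000.0, is_internal_standard=True))
        assert out[out.acquisition_id == "s1"].corrected_intensity.iloc[0] == 1000.0

    def test_no_blanks_warns_and_passes_through(self):
        t = join_sample_info(_table([{"acquisition_id": "s1"}]), _info(["s1"]))
        with pytest.warns(UserWarning, match="no blank"):
            out = subtract_blank(t)
        assert (out.corrected_intensity == out.intensity).all()


class TestIsotopeCorrect:
    def test_mode_none_is_identity(self):
        t = _table([{"intensity": 123.0}])
        out = isotope_correct(t, "none")
        assert out.corrected_intensity.iloc[0] == 123.0

    def test_carbon_free_species_unchanged_under_type2(self):
        t = _table([{"intensity": 10.0, "isotope_m0": 1.0}])
        assert isotope_correct(t, "type2").corrected_intensity.iloc[0] == 10.0

    def test_type2_matches_envelope_oracle(self):
        comp = parse_formula("C40H80NO8P")
        m0 = float(isotope_envelope(comp, 1)[0])
        t = _table([{"intensity": 1000.0, "isotope_m0": m0}])
        out = isotope_correct(t, "type2")
        assert out.corrected_intensity.iloc[0] == pytest.approx(1000.0 / m0)

    def test_non_positive_m0_rejected(self):
        t = _table([{"isotope_m0": 0.0}])
        with pytest.raises(ValueError):
            isotope_correct(t, "type2")


SPIKES = pd.DataFrame(
    {"class": ["PC"], "standard_label": ["PC 18:3/18:3"], "spike_pmol": [137.0]}
)
LABELS = {"PC 18:3/18:3": "PC 36:6"}


def _quant_table(species_int, is_int):
    rows = [
        {"species_name": "PC 34:1", "intensity": species_int},
        {"species_name": "PC 36:6", "intensity": is_int, "is_internal_standard": True},
    ]
    t = _table(rows)
    t["corrected_intensity"] = t["intensity"]
    return t


class TestComputeAmounts:
    def test_intensity_equal_to_standard_gives_spike_amount(self):
        out = compute_amounts(_quant_table(5000.0, 5000.0), SPIKES, LABELS)
        assert out[out.species_name == "PC 34:1"].amount_fmol.iloc[0] == pytest.approx(137000.0)

    def test_half_intensity_gives_half_spike(self):
        out = compute_amounts(_quant_table(2500.0, 5000.0), SPIKES, LABELS)
        assert out[out.species_name == "PC 34:1"].amount_fmol.iloc[0] == pytest.approx(68500.0)

    def test_missing_standard_yields_missing_amounts_not_zero(self):
        out = compute_amounts(_quant_table(2500.0, 0.0), SPIKES, LABELS)
        assert out.amount_fmol.isna().all()
        assert len(out) == 2  # rows retained

    def test_unmapped_class_is_an_error_naming_it(self):
        t = _quant_table(1.0, 1.0)
        t.loc[0, "lipid_class"] = "PE"
        with pytest.raises(ValueError, match="PE"):
            compute_amounts(t, SPIKES, LABELS)

    def test_lock_rows_are_exempt_from_spike_requirement(self):
        t = _quant_table(1.0, 1.0)
        lock = t.iloc[[0]].assign(lipid_class="(lock)", species_name="bg ion", is_lock_mass=True)
        out = compute_amounts(pd.concat([t, lock], ignore_index=True), SPIKES, LABELS)
        assert out[out.lipid_class == "(lock)"].amount_fmol.isna().all()

    def test_scale_invariance(self):
        """Multiplying all intensities of an acquisition by a constant leaves amounts unchanged."""
        a = compute_amounts(_quant_table(2500.0, 5000.0), SPIKES, LABELS)
        b = compute_amounts(_quant_table(2500.0 * 7.3, 5000.0 * 7.3), SPIKES, LABELS)
        pd.testing.assert_series_equal(a.amount_fmol, b.amount_fmol)


class TestMolPercent:
    def _amount_table(self, amounts, acq="a1"):
        rows = [
            {"species_name": f"sp{i}", "acquisition_id": acq, "intensity": 1.0}
            for i in range(len(amounts))
        ]
        t = _table(rows)
        t["amount_fmol"] = amounts
        t["is_blank"] = False
        return t

    def test_single_species_is_100_percent(self):
        out = mol_percent(self._amount_table([42.0]), ["acquisition_id"])
        assert out.mol_percent.iloc[0] == pytest.approx(100.0)

    def test_two_equal_amounts_split_evenly(self):
        out = mol_percent(self._amount_table([5.0, 5.0]), ["acquisition_id"])
        np.testing.assert_allclose(out.mol_percent, [50.0, 50.0])

    def test_cells_sum_to_100(self):
        rng = np.random.default_rng(5)
        t = pd.concat(
            [self._amount_table(rng.uniform(1, 100, size=6), acq=f"a{i}") for i in range(4)],
            ignore_index=True,
        )
        out = mol_percent(t, ["acquisition_id"])
        sums = out.groupby("acquisition_id").mol_percent.sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_universe_predicate_restricts_denominator(self):
        t = self._amount_table([30.0, 70.0, 900.0])
        universe = t.species_name.isin(["sp0", "sp1"])
        out = mol_percent(t, ["acquisition_id"], universe=universe)
        np.testing.assert_allclose(out.mol_percent[:2], [30.0, 70.0])
        assert np.isnan(out.mol_percent.iloc[2])

    def test_zero_denominator_warns_and_leaves_missing(self):
        with pytest.warns(UserWarning, match="zero total"):
            out = mol_percent(self._amount_table([0.0, 0.0]), ["acquisition_id"])
        assert out.mol_percent.isna().all()
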