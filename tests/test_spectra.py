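"""Peak-list IO, scan averaging and the folder-per-scan-range layout."""

import base64
import zlib

import numpy as np
import pytest

from lipidframe.spectra import (
    AcquisitionSet,
    ProfileSpectrum,
    average_scans,
    organize_acquisitions,
    read_mzml,
    read_peaklist,
    write_peaklist,
)


def _spectrum(mz, inten, acq="acq1", rng="+FTMS 500-1200"):
    return ProfileSpectrum(np.asarray(mz), np.asarray(inten), acq, rng)


class TestProfileSpectrum:
    def test_rejects_unsorted_mz(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _spectrum([2.0, 1.0], [1, 1])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            _spectrum([1.0, 2.0], [1])

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError):
            _spectrum([1.0, 2.0], [1, -1])


class TestReadPeaklist:
    def test_three_line_file(self, tmp_path):
        p = tmp_path / "sampleA.txt"
        p.write_text("700.0 10\n700.001 20\n700.002 5\n")
        s = read_peaklist(p)
        assert len(s) == 3
        assert s.acquisition_id == "sampleA"

    def test_unsorted_input_is_sorted(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("700.002\t5\n700.0\t10\n700.001\t20\n")
        s = read_peaklist(p)
        assert list(s.mz) == [700.0, 700.001, 700.002]
        assert list(s.intensity) == [10.0, 20.0, 5.0]

    def test_garbage_row_names_line_number(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("700.0 10\nnot a number here\n")
        with pytest.raises(ValueError, match=":2:"):
            read_peaklist(p)

    def test_header_row_tolerated(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("mz\tintensity\n700.0\t10\n")
        assert len(read_peaklist(p)) == 1

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_peaklist(p)

    def test_write_read_round_trip(self, tmp_path):
        s = _spectrum([700.0, 700.0005], [10.5, 20.25])
        write_peaklist(s, tmp_path / "acq1.txt")
        back = read_peaklist(tmp_path / "acq1.txt")
        np.testing.assert_allclose(back.mz, s.mz)
        np.testing.assert_allclose(back.intensity, s.intensity)


class TestAverageScans:
    def test_single_scan_identity(self):
        s = _spectrum([1.0, 2.0], [3.0, 4.0])
        avg = average_scans([s])
        np.testing.assert_array_equal(avg.intensity, s.intensity)

    def test_mean_of_identical_grids(self):
        a = _spectrum([1.0, 2.0], [1.0, 2.0])
        b = _spectrum([1.0, 2.0], [3.0, 6.0])
        np.testing.assert_allclose(average_scans([a, b]).intensity, [2.0, 4.0])

    def test_25_scans_match_per_point_mean_oracle(self):
        """Averaging a 25-scan acquisition equals the brute-force per-point mean."""
        rng = np.random.default_rng(7)
        grid = 500.0 + 0.0005 * np.arange(200)
        stack = rng.uniform(0, 1e6, size=(25, grid.size))
        scans = [_spectrum(grid, stack[i]) for i in range(25)]
        avg = average_scans(scans)
        np.testing.assert_allclose(avg.intensity, stack.mean(axis=0), atol=1e-9 * 1e6)
        np.testing.assert_array_equal(avg.mz, grid)  # reference grid preserved exactly

    def test_non_identical_grids_interpolated(self):
        a = _spectrum([1.0, 2.0, 3.0], [0.0, 2.0, 0.0])
        b = _spectrum([1.5, 2.5], [2.0, 2.0])
        avg = average_scans([a, b])
        np.testing.assert_array_equal(avg.mz, a.mz)  # first scan's grid
        # at mz=2.0, b interpolates to 2.0 -> mean of (2, 2)
        assert avg.intensity[1] == pytest.approx(2.0)

    def test_mixed_scan_ranges_rejected(self):
        a = _spectrum([1.0], [1.0], rng="+FTMS 280-580")
        b = _spectrum([1.0], [1.0], rng="+FTMS 500-1200")
        with pytest.raises(ValueError, match="scan ranges"):
            average_scans([a, b])


class TestOrganizeAcquisitions:
    def test_folder_and_file_counts(self, tmp_path):
        aset = AcquisitionSet()
        for acq in ("s1", "s2", "s3"):
            for rng in ("+FTMS 280-580", "+FTMS 500-1200"):
                for _ in range(2):
                    aset.add(_spectrum([500.0, 500.0005], [1.0, 2.0], acq, rng))
        manifest = organize_acquisitions(aset, tmp_path / "out")
        assert len(manifest) == 2
        assert all(len(files) == 3 for files in manifest.values())
        total = sum(len(files) for files in manifest.values())
        assert total == 6  # sum over acquisitions of their scan-range count

    def test_single_acquisition_single_range(self, tmp_path):
        aset = AcquisitionSet()
        aset.add(_spectrum([1.0, 2.0], [1.0, 1.0], "only", "+FTMS 280-580"))
        manifest = organize_acquisitions(aset, tmp_path / "out")
        assert manifest == {"+FTMS_280-580": ["only.txt"]}

    def test_empty_set_is_empty_manifest(self, tmp_path):
        manifest = organize_acquisitions(AcquisitionSet(), tmp_path / "out")
        assert manifest == {}
        assert not (tmp_path / "out").exists() or not any((tmp_path / "out").iterdir())


def _write_mzml(path, spectra, compress=False, float32=False):
    """Generate a minimal mzML document (synthetic fixture, built in-test)."""

    def enc(arr):
        raw = np.asarray(arr, dtype="<f4" if float32 else "<f8").tobytes()
        if compress:
            raw = zlib.compress(raw)
        return base64.b64encode(raw).decode()

    dtype_cv = (
        '<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>'
        if float32
        else '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
    )
    comp_cv = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
        if compress
        else '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
    )
    chunks = []
    for i, (filt, mz, inten) in enumerate(spectra):
        chunks.append(
            f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <scanList count="1"><scan>
          <cvParam cvRef="MS" accession="MS:1000512" name="filter string" value="{filt}"/>
        </scan></scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray>
            {dtype_cv}{comp_cv}
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{enc(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray>
            {dtype_cv}{comp_cv}
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{enc(inten)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>"""
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="r"><spectrumList count="{len(spectra)}">{"".join(chunks)}\n'
        "  </spectrumList></run>\n</mzML>\n"
    )
    path.write_text(doc)


@pytest.mark.parametrize("compress", [False, True])
def test_read_mzml_round_trip(tmp_path, compress):
    mz1 = [500.0, 500.0005, 500.001]
    i1 = [1.0, 5.0, 2.0]
    mz2 = [300.0, 300.0005]
    i2 = [7.0, 3.0]
    path = tmp_path / "acqX.mzML"
    _write_mzml(
        path,
        [("FTMS + p NSI Full ms [500.00-1200.00]", mz1, i1), ("FTMS + p NSI Full ms [280.00-580.00]", mz2, i2)],
        compress=compress,
    )
    spectra = read_mzml(path)
    assert [s.acquisition_id for s in spectra] == ["acqX", "acqX"]
    assert spectra[0].scan_range_id == "FTMS + p NSI Full ms [500.00-1200.00]"
    np.testing.assert_allclose(spectra[0].mz, mz1)
    np.testing.assert_allclose(spectra[1].intensity, i2)


def test_read_mzml_custom_range_mapping(tmp_path):
    path = tmp_path / "a.mzML"
    _write_mzml(path, [("FTMS + p NSI Full ms [500.00-1200.00]", [500.0, 500.1], [1.0, 2.0])])
    spectra = read_mzml(path, scan_range_of=lambda f: "+FTMS 500-1200")
    assert spectra[0].scan_range_id == "+FTMS 500-1200"
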