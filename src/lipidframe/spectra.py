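"""Profile peak lists: reading, writing, scan averaging and folder layout.

A :class:`ProfileSpectrum` is an ordered (m/z, intensity) trace from one
survey scan or scan average, tagged with the acquisition it came from and the
scan range it covers (e.g. ``"+FTMS 500-1200"``). Acquisitions are organised
on disk as one folder per scan range, each holding one averaged peak-list
``.txt`` per acquisition — overlapping scan ranges are deliberately never
merged, so the same ion may appear in two folders.

Text peak lists are two numeric columns (m/z, intensity), whitespace- or
tab-separated, optional header, ``.`` decimal separator. mzML input is read
by a small built-in reader (uncompressed or zlib 32/64-bit float arrays),
mapping each spectrum's filter string to a scan-range id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProfileSpectrum",
    "AcquisitionSet",
    "read_peaklist",
    "write_peaklist",
    "read_mzml",
    "average_scans",
    "organize_acquisitions",
]


@dataclass
class ProfileSpectrum:
    """One profile-mode trace: strictly increasing m/z, non-negative intensity."""

    mz: np.ndarray
    intensity: np.ndarray
    acquisition_id: str = ""
    scan_range_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"length mismatch: {self.mz.size} m/z values vs {self.intensity.size} intensities"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class AcquisitionSet:
    """Scans of several acquisitions, grouped per acquisition and scan range."""

    #: acquisition_id -> scan_range_id -> list of scans
    acquisitions: dict[str, dict[str, list[ProfileSpectrum]]] = field(default_factory=dict)

    def add(self, scan: ProfileSpectrum) -> None:
        self.acquisitions.setdefault(scan.acquisition_id, {}).setdefault(
            scan.scan_range_id, []
        ).append(scan)


def read_peaklist(path: str | Path, scan_range_id: str = "") -> ProfileSpectrum:
    """Read a two-column text peak list; the file stem names the acquisition.

    Rows are sorted ascending on m/z; a non-numeric row raises with its line
    number (a first-line header of two non-numeric tokens is tolerated).
    """
    path = Path(path)
    mz: list[float] = []
    intensity: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.replace(",", "\t").split()
            if not parts:
                continue
            try:
                values = [float(p) for p in parts]
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-numeric row {line.strip()!r}") from None
            if len(values) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(values)}")
            mz.append(values[0])
            intensity.append(values[1])
    if not mz:
        raise ValueError(f"{path}: empty peak list")
    order = np.argsort(mz, kind="stable")
    return ProfileSpectrum(
        np.asarray(mz)[order],
        np.asarray(intensity)[order],
        acquisition_id=path.stem,
        scan_range_id=scan_range_id,
    )


def write_peaklist(spectrum: ProfileSpectrum, path: str | Path) -> None:
    """Write a spectrum as tab-separated ``m/z<TAB>intensity`` text."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{mz:.6f}\t{inten:.6f}\n")


_MZML_ACC = {
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "float64": "MS:1000523",
    "float32": "MS:1000521",
    "zlib": "MS:1000574",
    "no_compression": "MS:1000576",
    "filter_string": "MS:1000512",
    "positive_scan": "MS:1000130",
    "negative_scan": "MS:1000129",
    "window_low": "MS:1000501",
    "window_high": "MS:1000500",
}


def _decode_binary_array(node, ns: str) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (array kind, values)."""
    import base64
    import zlib

    accessions = {cv.get("accession") for cv in node.iter(f"{ns}cvParam")}
    kind = None
    if _MZML_ACC["mz_array"] in accessions:
        kind = "mz"
    elif _MZML_ACC["intensity_array"] in accessions:
        kind = "intensity"
    dtype = "<f4" if _MZML_ACC["float32"] in accessions else "<f8"
    binary = node.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _MZML_ACC["zlib"] in accessions:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(
    path: str | Path,
    scan_range_of: Callable[[str], str] | None = None,
) -> list[ProfileSpectrum]:
    """Read profile spectra from an mzML file (built-in minimal reader).

    Supports uncompressed and zlib-compressed 32/64-bit float arrays.
    ``scan_range_of`` maps each spectrum's filter string (falling back to
    ``"{polarity}FTMS {low:g}-{high:g}"`` from the scan-window metadata) to a
    scan-range id; the default uses that string verbatim.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    out: list[ProfileSpectrum] = []
    ns = ""
    for event, node in ET.iterparse(str(path), events=("start", "end")):
        if event == "start" and node.tag.endswith("mzML") and "}" in node.tag:
            ns = node.tag.split("}")[0] + "}"
        if event != "end" or node.tag != f"{ns}spectrum":
            continue
        params = {cv.get("accession"): cv.get("value", "") for cv in node.iter(f"{ns}cvParam")}
        filter_string = params.get(_MZML_ACC["filter_string"], "")
        if not filter_string:
            polarity = "-" if _MZML_ACC["negative_scan"] in params else "+"
            low = params.get(_MZML_ACC["window_low"])
            high = params.get(_MZML_ACC["window_high"])
            if low and high:
                filter_string = f"{polarity}FTMS {float(low):g}-{float(high):g}"
        arrays: dict[str, np.ndarray] = {}
        for array_node in node.iter(f"{ns}binaryDataArray"):
            kind, values = _decode_binary_array(array_node, ns)
            if kind:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            node.clear()
            continue
        scan_range_id = scan_range_of(filter_string) if scan_range_of else filter_string
        mz = arrays["mz"]
        inten = arrays["intensity"]
        order = np.argsort(mz, kind="stable")
        out.append(
            ProfileSpectrum(
                mz[order], inten[order], acquisition_id=path.stem, scan_range_id=scan_range_id
            )
        )
        node.clear()
    return out


def average_scans(scans: Sequence[ProfileSpectrum]) -> ProfileSpectrum:
    """Point-wise mean of repeated scans of one scan range.

    Identical m/z grids are averaged directly; otherwise every scan is
    linearly interpolated onto the first scan's grid (zero outside its own
    support) before averaging. Mixing scan ranges is an error.
    """
    if not scans:
        raise ValueError("need at least one scan to average")
    ranges = {s.scan_range_id for s in scans}
    if len(ranges) > 1:
        raise ValueError(f"cannot average across scan ranges: {sorted(ranges)}")
    ref = scans[0]
    if len(scans) == 1:
        return replace(ref, mz=ref.mz.copy(), intensity=ref.intensity.copy())
    same_grid = all(
        s.mz.size == ref.mz.size and np.array_equal(s.mz, ref.mz) for s in scans[1:]
    )
    if same_grid:
        stack = np.vstack([s.intensity for s in scans])
    else:
        stack = np.vstack(
            [ref.intensity]
            + [np.interp(ref.mz, s.mz, s.intensity, left=0.0, right=0.0) for s in scans[1:]]
        )
    return ProfileSpectrum(
        ref.mz.copy(), stack.mean(axis=0), acquisition_id=ref.acquisition_id, scan_range_id=ref.scan_range_id
    )


def _safe_folder(scan_range_id: str) -> str:
    return scan_range_id.replace("/", "_").replace(" ", "_")


def organize_acquisitions(
    aset: AcquisitionSet, out_dir: str | Path
) -> dict[str, list[str]]:
    """Average each acquisition's scans per range and lay them out on disk.

    Creates one folder per scan range containing one averaged peak-list
    ``.txt`` per acquisition; returns the manifest ``{folder: [file, ...]}``.
    """
    out_dir = Path(out_dir)
    manifest: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    for acq_id, by_range in aset.acquisitions.items():
        for scan_range_id, scans in by_range.items():
            folder = _safe_folder(scan_range_id)
            if (folder, acq_id) in seen:
                raise ValueError(f"name collision: {acq_id!r} twice in range {scan_range_id!r}")
            seen.add((folder, acq_id))
            averaged = average_scans(scans)
            folder_path = out_dir / folder
            folder_path.mkdir(parents=True, exist_ok=True)
            filename = f"{acq_id}.txt"
            write_peaklist(averaged, folder_path / filename)
            manifest.setdefault(folder, []).append(filename)
    for files in manifest.values():
        files.sort()
    return manifest
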