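"""Minimal centroided mzML writing and reading.

Simulated runs are serialized as uncompressed 64-bit mzML 1.1.0 with the
per-scan precursor isolation window recorded. The reader handles the
standard subset needed for centroided peak lists (32/64-bit float arrays,
optional zlib compression, minute- or second-valued scan start times), so
conforming files from other converters load as well.
"""

from __future__ import annotations

import base64
import struct
import zlib
from typing import Sequence

import numpy as np
from lxml import etree

from .acquisition import SpectrumScan

__all__ = ["write_mzml", "read_mzml"]

_NS = "http://psi.hupo.org/ms/mzml"

_CV = {
    "ms_level": "MS:1000511",
    "centroid": "MS:1000127",
    "ms1": "MS:1000579",
    "msn": "MS:1000580",
    "scan_start": "MS:1000016",
    "iso_target": "MS:1000827",
    "iso_lower": "MS:1000828",
    "iso_upper": "MS:1000829",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "f64": "MS:1000523",
    "no_compression": "MS:1000576",
}


def _cv(parent, accession: str, name: str, value: str = "",
        unit: tuple[str, str] | None = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit:
        attrs.update({"unitCvRef": "UO", "unitAccession": unit[0],
                      "unitName": unit[1]})
    etree.SubElement(parent, f"{{{_NS}}}cvParam", attrs)


def _binary(parent, values: np.ndarray, accession: str, name: str) -> None:
    data = base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()
    arr = etree.SubElement(parent, f"{{{_NS}}}binaryDataArray",
                           encodedLength=str(len(data)))
    _cv(arr, _CV["f64"], "64-bit float")
    _cv(arr, _CV["no_compression"], "no compression")
    _cv(arr, accession, name)
    etree.SubElement(arr, f"{{{_NS}}}binary").text = data


def write_mzml(scans: Sequence[SpectrumScan], path: str,
               run_id: str = "run") -> None:
    """Write centroided scans as a (non-indexed) mzML file."""
    root = etree.Element(f"{{{_NS}}}mzML", nsmap={None: _NS}, version="1.1.0")
    run = etree.SubElement(root, f"{{{_NS}}}run", id=run_id)
    speclist = etree.SubElement(run, f"{{{_NS}}}spectrumList",
                                count=str(len(scans)))
    for i, scan in enumerate(scans):
        spec = etree.SubElement(
            speclist, f"{{{_NS}}}spectrum", index=str(i),
            id=f"cycle={scan.cycle_index} scan={i}",
            defaultArrayLength=str(scan.n_peaks))
        _cv(spec, _CV["ms_level"], "ms level", str(scan.ms_level))
        _cv(spec, _CV["centroid"], "centroid spectrum")
        _cv(spec, _CV["ms1" if scan.ms_level == 1 else "msn"],
            "MS1 spectrum" if scan.ms_level == 1 else "MSn spectrum")
        scanlist = etree.SubElement(spec, f"{{{_NS}}}scanList", count="1")
        sc = etree.SubElement(scanlist, f"{{{_NS}}}scan")
        _cv(sc, _CV["scan_start"], "scan start time", repr(scan.rt),
            unit=("UO:0000010", "second"))
        if scan.ms_level == 2 and scan.window is not None:
            center, width = scan.window
            precursors = etree.SubElement(spec, f"{{{_NS}}}precursorList",
                                          count="1")
            prec = etree.SubElement(precursors, f"{{{_NS}}}precursor")
            iso = etree.SubElement(prec, f"{{{_NS}}}isolationWindow")
            _cv(iso, _CV["iso_target"], "isolation window target m/z",
                repr(center))
            _cv(iso, _CV["iso_lower"], "isolation window lower offset",
                repr(width / 2))
            _cv(iso, _CV["iso_upper"], "isolation window upper offset",
                repr(width / 2))
        arrays = etree.SubElement(spec, f"{{{_NS}}}binaryDataArrayList",
                                  count="2")
        _binary(arrays, scan.mz, _CV["mz_array"], "m/z array")
        _binary(arrays, scan.intensity, _CV["intensity_array"],
                "intensity array")
    etree.ElementTree(root).write(path, xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def _decode_array(elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: (array kind, values)."""
    kind = None
    dtype = "<f8"
    compressed = False
    for cv in elem.iter(f"{{{_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == _CV["mz_array"]:
            kind = "mz"
        elif acc == _CV["intensity_array"]:
            kind = "intensity"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000574":
            compressed = True
    binary = elem.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str) -> list[SpectrumScan]:
    """Read a centroided mzML file into :class:`SpectrumScan` objects.

    Cycle indices are reconstructed by counting MS1 scans (MS2 scans
    preceding the first survey scan fall in cycle 0).
    """
    scans: list[SpectrumScan] = []
    cycle = -1
    for _event, spec in etree.iterparse(path, events=("end",),
                                        tag=f"{{{_NS}}}spectrum"):
        ms_level = 1
        rt = 0.0
        window = None
        target = lower = upper = None
        mz = intensity = np.empty(0)
        for cv in spec.iter(f"{{{_NS}}}cvParam"):
            acc = cv.get("accession")
            if acc == _CV["ms_level"]:
                ms_level = int(cv.get("value"))
            elif acc == _CV["scan_start"]:
                rt = float(cv.get("value"))
                if cv.get("unitName") == "minute":
                    rt *= 60.0
            elif acc == _CV["iso_target"]:
                target = float(cv.get("value"))
            elif acc == _CV["iso_lower"]:
                lower = float(cv.get("value"))
            elif acc == _CV["iso_upper"]:
                upper = float(cv.get("value"))
        for arr in spec.iter(f"{{{_NS}}}binaryDataArray"):
            kind, values = _decode_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
        if ms_level == 2 and target is not None:
            window = (target, (lower or 0.0) + (upper or 0.0))
        if ms_level == 1:
            cycle += 1
        scans.append(SpectrumScan(
            ms_level=ms_level, rt=rt, mz=mz, intensity=intensity,
            window=window, cycle_index=max(cycle, 0)))
        spec.clear(keep_tail=True)
    return scans
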