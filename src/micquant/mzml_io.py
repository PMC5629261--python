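"""Reading and writing centroided MS¹ spectra as mzML.

The reader streams spectra with :mod:`xml.etree.ElementTree` ``iterparse``,
decoding base64 binary arrays (64- or 32-bit little-endian floats, plain or
zlib-compressed) — the subset of mzML emitted by the common converters for
centroided data.  The writer produces a minimal standards-conformant
document (one run, centroided MS¹ spectra, uncompressed 64-bit arrays)
that round-trips through independent readers such as Bioconductor's mzR.
Scan start times are stored in seconds, the mzML convention, and converted
to minutes on read.
"""

from __future__ import annotations

import base64
import struct
import zlib
from typing import Iterable, Iterator
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

from .scoring import CentroidedSpectrum

__all__ = ["read_spectra", "write_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"

# CV accessions understood by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _decode_array(bda: ElementTree.Element) -> tuple[str, np.ndarray] | None:
    """Decode one <binaryDataArray>; returns None for unneeded array types."""
    accessions = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    if _ACC_MZ_ARRAY in accessions:
        kind = "mz"
    elif _ACC_INTENSITY_ARRAY in accessions:
        kind = "intensity"
    else:
        return None
    binary = bda.find(f"{_NS}binary")
    text = (binary.text or "") if binary is not None else ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_FLOAT32 in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    return kind, arr


def _parse_spectrum(elem: ElementTree.Element, index: int) -> CentroidedSpectrum:
    level = 1
    rt_minutes = 0.0
    scan_no = index + 1
    for token in (elem.get("id") or "").split():
        if token.startswith("scan="):
            scan_no = int(token[5:])
    for cv in elem.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_MS_LEVEL:
            level = int(cv.get("value", "1"))
        elif acc == _ACC_SCAN_START:
            t = float(cv.get("value", "0"))
            unit = (cv.get("unitName") or "second").lower()
            rt_minutes = t if unit.startswith("minute") else t / 60.0
    mz = intensity = np.empty(0)
    for bda in elem.iter(f"{_NS}binaryDataArray"):
        decoded = _decode_array(bda)
        if decoded is None:
            continue
        kind, arr = decoded
        if kind == "mz":
            mz = arr
        else:
            intensity = arr
    return CentroidedSpectrum(spectrum_id=scan_no, retention_time=rt_minutes,
                              mzs=mz, intensities=intensity, ms_level=level)


def read_spectra(path: str, ms_level: int | None = 1) -> Iterator[CentroidedSpectrum]:
    """Stream spectra from an mzML file, one at a time.

    ``ms_level=1`` (the default) yields only MS¹ spectra, the level used for
    quantification; pass ``None`` to yield everything.
    """
    index = 0
    for _, elem in ElementTree.iterparse(path, events=("end",)):
        if elem.tag != f"{_NS}spectrum":
            continue
        spectrum = _parse_spectrum(elem, index)
        index += 1
        elem.clear()  # free the subtree; memory stays flat over long runs
        if ms_level is None or spectrum.ms_level == ms_level:
            yield spectrum


def _encode(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_seconds:.6f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(path: str, spectra: Iterable[CentroidedSpectrum],
               run_id: str = "run") -> None:
    """Write centroided MS¹ spectra as a minimal plain mzML document."""
    spectra = list(spectra)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(run_id=escape(run_id, {'"': "&quot;"}),
                                count=len(spectra)))
        for idx, s in enumerate(spectra):
            mz_b64 = _encode(s.mzs)
            int_b64 = _encode(s.intensities)
            fh.write(_SPECTRUM.format(
                index=idx, scan=s.spectrum_id, n=len(s),
                ms_level=s.ms_level, rt_seconds=s.retention_time * 60.0,
                mz_len=len(mz_b64), mz_b64=mz_b64,
                int_len=len(int_b64), int_b64=int_b64,
            ))
        fh.write(_FOOTER)
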